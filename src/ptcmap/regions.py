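"""Active-site region definitions and the single-point mutant catalogue.

The study regions are named nucleotide sets of the E. coli 23S rRNA around
the peptidyl transferase center (PTC): the central PTC-ring, the A-loop
(contacts A-site tRNA) and the P-loop (base-pairs the P-site tRNA CCA end).
Positions use 1-based E. coli 23S numbering with inclusive intervals, so the
familiar nucleotide names (A2451, U2585, ...) read off directly.

The bundled region config (``data/regions.yaml``) covers the 61 study
positions; pass your own file to :func:`load_regions` for other organisms
or numbering schemes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import yaml

RNA_BASES: tuple[str, ...] = ("A", "C", "G", "U")

_MUTANT_RE = re.compile(r"^([ACGU])(\d+)([ACGU])$")


class RegionError(ValueError):
    """Invalid region definition (overlapping/inverted ranges, missing bases)."""


@dataclass(frozen=True, order=True)
class MutantId:
    """A single-point 23S rRNA mutant, e.g. ``A2451C``."""

    position: int
    wt_base: str
    mut_base: str

    def __post_init__(self) -> None:
        if self.wt_base not in RNA_BASES or self.mut_base not in RNA_BASES:
            raise ValueError(f"bases must be RNA (A/C/G/U): {self.wt_base}, {self.mut_base}")
        if self.mut_base == self.wt_base:
            raise ValueError(f"mutant base equals wild type at {self.position}")

    @property
    def name(self) -> str:
        return f"{self.wt_base}{self.position}{self.mut_base}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name

    @classmethod
    def parse(cls, name: str) -> "MutantId":
        m = _MUTANT_RE.match(name.strip().upper().replace("T", "U"))
        if m is None:
            raise ValueError(f"not a valid mutant name: {name!r}")
        wt, pos, mut = m.groups()
        return cls(position=int(pos), wt_base=wt, mut_base=mut)


@dataclass
class RegionDefinition:
    """A named set of 23S positions with their wild-type identities."""

    name: str
    ranges: list[tuple[int, int]]
    reference_bases: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for start, end in self.ranges:
            if start > end:
                raise RegionError(f"{self.name}: inverted range {start}-{end}")
            span = set(range(start, end + 1))
            if span & seen:
                raise RegionError(f"{self.name}: overlapping ranges at {sorted(span & seen)[:3]}")
            seen |= span
        for pos, base in self.reference_bases.items():
            if base not in RNA_BASES:
                raise RegionError(f"{self.name}: non-RNA reference base {base!r} at {pos}")

    def positions(self) -> list[int]:
        return enumerate_positions(self)

    def mutants(self) -> list[MutantId]:
        return enumerate_mutants(self)


def enumerate_positions(region: RegionDefinition) -> list[int]:
    """All positions of a region, ascending, each once.

    The PTC-ring ranges of the study enumerate 43 positions, the A-loop 13
    and the P-loop 5.
    """
    out: list[int] = []
    for start, end in region.ranges:
        out.extend(range(start, end + 1))
    return sorted(out)


def enumerate_mutants(region: RegionDefinition) -> list[MutantId]:
    """The three possible point mutants at every region position.

    Ordered by position, then mutant base A<C<G<U, so outputs are
    reproducible. Raises :class:`RegionError` if a position has no
    reference base.
    """
    mutants: list[MutantId] = []
    for pos in enumerate_positions(region):
        wt = region.reference_bases.get(pos)
        if wt is None:
            raise RegionError(f"{region.name}: no reference base for position {pos}")
        for base in RNA_BASES:
            if base != wt:
                mutants.append(MutantId(position=pos, wt_base=wt, mut_base=base))
    return mutants


def _region_from_config(name: str, node: dict) -> RegionDefinition:
    ranges = [(int(a), int(b)) for a, b in node["ranges"]]
    bases: dict[int, str] = {}
    for (start, _end), seq in zip(ranges, node["reference_bases"]):
        for offset, base in enumerate(str(seq).upper().replace("T", "U")):
            bases[start + offset] = base
    region = RegionDefinition(name=name, ranges=ranges, reference_bases=bases)
    missing = [p for p in enumerate_positions(region) if p not in bases]
    if missing:
        raise RegionError(f"{name}: reference_bases do not cover {missing}")
    return region


def load_regions(source) -> dict[str, RegionDefinition]:
    """Load region definitions from a YAML config (path or file object).

    The config maps region name to ``ranges`` (list of [start, end]) and
    ``reference_bases`` (one base string per range, 5'→3').
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    regions = {name: _region_from_config(name, node) for name, node in doc.items()}
    _check_disjoint(regions.values())
    return regions


def default_regions() -> dict[str, RegionDefinition]:
    """The study's three regions: PTC-ring (43 nt), A-loop (13 nt), P-loop (5 nt)."""
    with resources.files("ptcmap.data").joinpath("regions.yaml").open() as fh:
        return load_regions(fh)


def _check_disjoint(regions: Iterable[RegionDefinition]) -> None:
    seen: dict[int, str] = {}
    for region in regions:
        for pos in enumerate_positions(region):
            if pos in seen:
                raise RegionError(f"position {pos} in both {seen[pos]} and {region.name}")
            seen[pos] = region.name


def mutant_catalogue(regions: dict[str, RegionDefinition] | None = None) -> list[MutantId]:
    """Every point mutant across all regions (183 for the default panel)."""
    if regions is None:
        regions = default_regions()
    out: list[MutantId] = []
    for region in regions.values():
        out.extend(enumerate_mutants(region))
    return sorted(out, key=lambda m: (m.position, m.mut_base))


def reference_bases(regions: dict[str, RegionDefinition] | None = None) -> dict[int, str]:
    """Position → wild-type base over all regions."""
    if regions is None:
        regions = default_regions()
    merged: dict[int, str] = {}
    for region in regions.values():
        merged.update(region.reference_bases)
    return merged
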