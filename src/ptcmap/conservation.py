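"""Per-column Shannon entropy of an LSU rRNA alignment at study positions.

Conservation of each active-site nucleotide is summarized as the Shannon
entropy of its alignment column, H = −Σ_i p_i ln p_i over i ∈ {A,U,G,C},
where p_i is the count of nucleotide i divided by the number of sequences
remaining after excluding, at that column, every sequence carrying a gap
(and, under the default strict rule, any non-ACGU symbol). H is reported in
nats: 0 for a fully conserved column, ln 4 ≈ 1.386 when the four bases are
equally likely. No phylogenetic weighting is applied — each sequence counts
once, so entropy is a variance-like score, not a tree-aware one.

Study positions are located in the alignment by walking the ungapped
coordinates of a named reference record (the E. coli sequence in the
original alignment), so the profile is reported in reference numbering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from scipy.stats import entropy as _scipy_entropy

from .regions import RNA_BASES, RegionDefinition, enumerate_positions

GAP_CHARS = {"-", "."}


class UndefinedEntropyError(ValueError):
    """Every sequence was excluded at a column; H is undefined, not 0."""


@dataclass
class AlignmentColumnProfile:
    """Nucleotide counts of one alignment column after the exclusion rule."""

    position: int
    column_index: int
    counts: Mapping[str, int]
    n_excluded: int

    @property
    def n_included(self) -> int:
        return sum(self.counts.values())


def read_alignment(path) -> MultipleSeqAlignment:
    """Read an aligned FASTA; all records must share one length."""
    alignment = AlignIO.read(path, "fasta")
    if len(alignment) == 0:
        raise ValueError("empty alignment")
    return alignment


def map_reference_positions(
    alignment: MultipleSeqAlignment,
    reference_id: str,
    positions: Sequence[int],
) -> dict[int, int]:
    """Map 1-based ungapped reference positions to 0-based alignment columns.

    Walks the reference row, counting only non-gap characters, so the
    reference character at each mapped column is exactly the reference
    sequence's ungapped character at that position.
    """
    ref = next((rec for rec in alignment if rec.id == reference_id), None)
    if ref is None:
        raise KeyError(f"reference record {reference_id!r} not in alignment")
    wanted = set(positions)
    bad = [p for p in wanted if p < 1]
    if bad:
        raise ValueError(f"positions must be ≥ 1: {sorted(bad)}")
    mapping: dict[int, int] = {}
    ungapped = 0
    for col, ch in enumerate(str(ref.seq)):
        if ch in GAP_CHARS:
            continue
        ungapped += 1
        if ungapped in wanted:
            mapping[ungapped] = col
    missing = sorted(wanted - mapping.keys())
    if missing:
        raise ValueError(
            f"positions {missing} exceed the ungapped reference length ({ungapped})"
        )
    return {p: mapping[p] for p in sorted(mapping)}


def column_profile(
    alignment: MultipleSeqAlignment,
    column_index: int,
    position: int | None = None,
    gap_only: bool = False,
) -> AlignmentColumnProfile:
    """Count A/C/G/U in one column, applying the exclusion rule.

    ``gap_only=True`` reproduces the literal rule of excluding only '-'
    records (any other non-ACGU symbol then raises); the default also
    excludes ambiguity codes and '.', which is the stricter, auditable
    generalization. T is read as U.
    """
    counts = {b: 0 for b in RNA_BASES}
    n_excluded = 0
    for rec in alignment:
        ch = str(rec.seq[column_index]).upper().replace("T", "U")
        if ch in counts:
            counts[ch] += 1
        elif gap_only and ch not in GAP_CHARS:
            raise ValueError(
                f"unexpected symbol {ch!r} at column {column_index} under gap-only rule"
            )
        else:
            n_excluded += 1
    return AlignmentColumnProfile(
        position=position if position is not None else -1,
        column_index=column_index,
        counts=counts,
        n_excluded=n_excluded,
    )


def column_entropy(profile: AlignmentColumnProfile) -> float:
    """Shannon entropy H = −Σ p_i ln p_i (nats) of a column profile."""
    total = profile.n_included
    if total < 1:
        raise UndefinedEntropyError(
            f"all sequences excluded at column {profile.column_index}"
        )
    return float(_scipy_entropy([profile.counts[b] for b in RNA_BASES]))


def entropy_profile(
    alignment: MultipleSeqAlignment,
    reference_id: str,
    region: RegionDefinition | Iterable[int],
    gap_only: bool = False,
) -> pd.DataFrame:
    """Entropy at every region position, in region order.

    Returns a frame with position, column, per-base counts, excluded count
    and H (nats).
    """
    if isinstance(region, RegionDefinition):
        positions = enumerate_positions(region)
    else:
        positions = list(region)
    mapping = map_reference_positions(alignment, reference_id, positions)
    rows = []
    for pos in positions:
        prof = column_profile(alignment, mapping[pos], position=pos, gap_only=gap_only)
        rows.append(
            {
                "position": pos,
                "column": prof.column_index,
                **{b: prof.counts[b] for b in RNA_BASES},
                "excluded": prof.n_excluded,
                "entropy_nats": column_entropy(prof),
            }
        )
    return pd.DataFrame(rows)
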