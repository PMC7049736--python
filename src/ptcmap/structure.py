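"""Nucleotide geometric centers, tRNA-distance mapping and flexibility shells.

Each 23S nucleotide is reduced to the unweighted mean of its heavy-atom
coordinates; the A-site and P-site reference points are the analogous mean
over the tRNA's 3'-terminal A76 (plus the attached amino-acid moiety when
present). Euclidean center-to-center distances in Å place every study
position relative to the two tRNA CCA ends. Where tRNA coordinates come
from a different crystal form than the ribosome, a Kabsch least-squares
superposition over a shared atom selection (by default phosphorus atoms of
residues common to both structures) brings them into one frame.

Scored positions are binned into four ordered flexibility shells (quantile
binning, ties toward the lower shell) and can be exported as a
B-factor-annotated PDB so any molecular viewer renders the flexibility
heat map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

SHELL_LABELS = ("lowest", "medium/low", "medium/high", "highest")
UNMAPPED_SENTINEL = -1.0


class Atom(NamedTuple):
    name: str
    element: str
    pos: tuple[float, float, float]
    occupancy: float
    altloc: str


@dataclass
class ResidueCoordinates:
    """Heavy-atom coordinates of one residue, author numbering."""

    chain: str
    number: int
    name: str
    atoms: list[Atom]

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float)


def _filter_atoms(residue: gemmi.Residue) -> list[Atom]:
    """Drop hydrogens; among altloc duplicates keep the highest occupancy."""
    best: dict[str, Atom] = {}
    for atom in residue:
        if atom.element.is_hydrogen:
            continue
        rec = Atom(
            name=atom.name,
            element=atom.element.name,
            pos=(atom.pos.x, atom.pos.y, atom.pos.z),
            occupancy=atom.occ,
            altloc=atom.altloc,
        )
        kept = best.get(atom.name)
        if kept is None or rec.occupancy > kept.occupancy:
            best[atom.name] = rec
    return list(best.values())


def load_structure(
    path, chains: Sequence[str] | None = None
) -> list[ResidueCoordinates]:
    """Read a PDB/mmCIF file into per-residue heavy-atom records.

    Hydrogens are excluded; altloc duplicates resolve to the
    highest-occupancy atom; residues are kept under author chain names and
    sequence numbers (so 23S position 2451 is residue 2451). A residue
    whose atoms are all hydrogens is an error, not a silent skip.
    """
    return load_structure_from_gemmi(gemmi.read_structure(str(path)), chains=chains, label=str(path))


def load_structure_from_gemmi(
    structure: gemmi.Structure,
    chains: Sequence[str] | None = None,
    label: str = "<structure>",
) -> list[ResidueCoordinates]:
    """Same residue extraction as :func:`load_structure`, from an in-memory model."""
    path = label
    if len(structure) == 0:
        raise ValueError(f"{path}: no models in structure")
    wanted = set(chains) if chains is not None else None
    out: list[ResidueCoordinates] = []
    for chain in structure[0]:
        if wanted is not None and chain.name not in wanted:
            continue
        for residue in chain:
            atoms = _filter_atoms(residue)
            if not atoms:
                raise ValueError(
                    f"{path}: residue {chain.name}/{residue.seqid.num} has no heavy atoms"
                )
            out.append(
                ResidueCoordinates(
                    chain=chain.name,
                    number=residue.seqid.num,
                    name=residue.name.strip(),
                    atoms=atoms,
                )
            )
    if not out:
        raise ValueError(f"{path}: selection is empty (chains={chains})")
    return out


def geometric_center(residues: ResidueCoordinates | Iterable[ResidueCoordinates]) -> np.ndarray:
    """Unweighted mean of all heavy-atom coordinates of the selection."""
    if isinstance(residues, ResidueCoordinates):
        residues = [residues]
    coords = np.vstack([r.coords() for r in residues])
    if coords.size == 0:
        raise ValueError("empty selection has no geometric center")
    return coords.mean(axis=0)


@dataclass
class ReferencePoint:
    """A tRNA-site reference: the mean of the A76 (+ amino acid) heavy atoms."""

    site: str  # "A-site" or "P-site"
    center: np.ndarray
    source: list[str]


def reference_point(site: str, residues: Iterable[ResidueCoordinates]) -> ReferencePoint:
    residues = list(residues)
    return ReferencePoint(
        site=site,
        center=geometric_center(residues),
        source=[f"{r.chain}/{r.number}:{r.name}" for r in residues],
    )


@dataclass
class RigidTransform:
    """Least-squares rigid motion y ≈ R x + t, with achieved RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def apply_residues(
        self, residues: Iterable[ResidueCoordinates]
    ) -> list[ResidueCoordinates]:
        out = []
        for r in residues:
            moved = self.apply(r.coords())
            atoms = [
                Atom(a.name, a.element, tuple(p), a.occupancy, a.altloc)
                for a, p in zip(r.atoms, moved)
            ]
            out.append(ResidueCoordinates(r.chain, r.number, r.name, atoms))
        return out


def _shared_points(
    mobile: Iterable[ResidueCoordinates],
    fixed: Iterable[ResidueCoordinates],
    selector: Callable[[ResidueCoordinates, Atom], bool],
) -> tuple[np.ndarray, np.ndarray]:
    def keyed(residues):
        table = {}
        for r in residues:
            for a in r.atoms:
                if selector(r, a):
                    table[(r.chain, r.number, a.name)] = np.asarray(a.pos, dtype=float)
        return table

    mob, fix = keyed(mobile), keyed(fixed)
    keys = sorted(mob.keys() & fix.keys())
    if len(keys) < 3:
        raise ValueError(f"superposition needs ≥ 3 shared points, found {len(keys)}")
    return (np.vstack([mob[k] for k in keys]), np.vstack([fix[k] for k in keys]))


def phosphorus_selector(residue: ResidueCoordinates, atom: Atom) -> bool:
    """Default shared selection for rRNA superposition: backbone P atoms."""
    return atom.element == "P" or atom.name == "P"


def superpose(
    mobile: Iterable[ResidueCoordinates],
    fixed: Iterable[ResidueCoordinates],
    selector: Callable[[ResidueCoordinates, Atom], bool] = phosphorus_selector,
) -> RigidTransform:
    """Kabsch least-squares rigid transform taking mobile onto fixed.

    Shared points are atoms matched by (chain, residue number, atom name)
    under the selector; ≥ 3 non-collinear points required.
    """
    mob, fix = _shared_points(mobile, fixed, selector)
    mob_c, fix_c = mob.mean(axis=0), fix.mean(axis=0)
    mob0, fix0 = mob - mob_c, fix - fix_c
    if np.linalg.matrix_rank(fix0, tol=1e-8) < 2 or np.linalg.matrix_rank(mob0, tol=1e-8) < 2:
        raise ValueError("shared selection is collinear; superposition is degenerate")
    rot, rssd = Rotation.align_vectors(fix0, mob0)
    R = rot.as_matrix()
    translation = fix_c - R @ mob_c
    rmsd = float(rssd / np.sqrt(len(mob)))
    return RigidTransform(rotation=R, translation=translation, rmsd=rmsd)


def nucleotide_distances(
    nucleotides: Mapping[int, ResidueCoordinates],
    ref_a: ReferencePoint,
    ref_p: ReferencePoint,
    positions: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, list[int]]:
    """Center-to-center Å distances of each nucleotide to both tRNA sites.

    Positions absent from the structure are reported in the returned
    missing list rather than raising.
    """
    if positions is None:
        positions = sorted(nucleotides)
    rows, missing = [], []
    for pos in positions:
        res = nucleotides.get(pos)
        if res is None:
            missing.append(pos)
            continue
        center = geometric_center(res)
        rows.append(
            {
                "position": pos,
                "distance_to_A_site": float(np.linalg.norm(center - ref_a.center)),
                "distance_to_P_site": float(np.linalg.norm(center - ref_p.center)),
            }
        )
    return pd.DataFrame(rows), missing


def assign_shells(
    scores: Mapping[int, float] | pd.Series,
    n_shells: int = 4,
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Bin scored positions into ordered flexibility shells (1 = lowest).

    Default is quantile (equal-count) binning with ties broken toward the
    lower shell; explicit ascending score thresholds may be given instead
    (shell k+1 starts strictly above thresholds[k-1]).
    """
    series = pd.Series(dict(scores)).sort_index()
    if len(series) < n_shells:
        raise ValueError(f"need ≥ {n_shells} scored positions, have {len(series)}")
    if thresholds is None:
        qs = np.quantile(series.to_numpy(), np.arange(1, n_shells) / n_shells)
    else:
        if len(thresholds) != n_shells - 1:
            raise ValueError(f"need {n_shells - 1} thresholds for {n_shells} shells")
        qs = np.asarray(thresholds, dtype=float)
    labels = (
        SHELL_LABELS if n_shells == len(SHELL_LABELS)
        else tuple(f"shell{i}" for i in range(1, n_shells + 1))
    )
    shells = 1 + (series.to_numpy()[:, None] > qs[None, :]).sum(axis=1)
    return pd.DataFrame(
        {
            "position": series.index.to_numpy(),
            "score": series.to_numpy(),
            "shell": shells,
            "label": [labels[s - 1] for s in shells],
        }
    )


def export_attribute_map(
    structure_path,
    values: Mapping[tuple[str, int], float],
    out_path,
    sentinel: float = UNMAPPED_SENTINEL,
) -> None:
    """Write a copy of the structure with per-residue scores as B-factors.

    ``values`` maps (chain, author residue number) → score; every atom of a
    mapped residue carries its score, all other atoms carry the sentinel.
    Round-trips through :func:`load_structure` to PDB B-factor precision
    (2 decimals).
    """
    structure = gemmi.read_structure(str(structure_path))
    structure.setup_entities()
    unresolved = dict(values)
    for model in structure:
        for chain in model:
            for residue in chain:
                key = (chain.name, residue.seqid.num)
                score = values.get(key, sentinel)
                unresolved.pop(key, None)
                for atom in residue:
                    atom.b_iso = score
    if unresolved:
        raise KeyError(f"positions not in structure: {sorted(unresolved)}")
    structure.write_pdb(str(out_path))
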