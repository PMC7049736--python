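"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the study's
measurements so that each analysis stage — and the pipeline end to end —
can be tested for parameter recovery without any downloads:

* :func:`synth_alignment` — alignment columns drawn from specified
  per-position nucleotide frequencies with a gap rate, plus a gap-free
  reference record (emulating the 1,614-sequence pre-aligned LSU set);
* :func:`synth_kinetics` — saturating sfGFP-like traces
  c(t) = plateau·(1 − exp(−(rate/plateau)·t)), emitted in RFU through a
  linear standard curve, with multiplicative Gaussian noise;
* :func:`synth_gradient` — A254 traces as Gaussian mixtures over the
  species windows plus linear baseline drift and a stray background peak;
* :func:`synth_structure` — a toy 3D structure whose nucleotide heavy-atom
  centers sit at prescribed distances from two A76-like reference points;
* :func:`synth_panel` — the full study design in one bundle: wild type +
  183 mutants × replicate kinetic traces, readthrough signals on 4 stop
  constructs, 5 gradient samples, the alignment and the toy structure,
  with a self-consistent :class:`PanelGroundTruth`.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .activity import KineticTrace, StandardCurve
from .readthrough import DEFAULT_STOP_POSITIONS
from .regions import RNA_BASES, MutantId, default_regions, mutant_catalogue
from .sedimentation import DEFAULT_BOUNDARIES, GradientTrace

REFERENCE_ID = "EC_REF"

# Wild-type study conditions: bulk rate ~1 μM/h rising toward a ~10 μM
# plateau over a 16 h run, read every 15 min; calibration slope 0.01 μM/RFU.
# The plateau/rate ratio keeps the 0-2 h window close to the initial slope,
# so the early-window OLS rate recovers the generating rate.
WT_RATE_UM_PER_H = 1.03
WT_PLATEAU_UM = 10.0
DEFAULT_HORIZON_H = 16.0
DEFAULT_DT_H = 0.25
DEFAULT_CURVE = StandardCurve(slope=0.01, intercept=0.0, r_squared=1.0)
DEFAULT_N_REPLICATES = 3


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# alignment


def synth_alignment(
    column_frequencies: pd.DataFrame,
    n_records: int = 2000,
    gap_rate: float = 0.05,
    seed: int | np.random.Generator = 0,
    reference_id: str = REFERENCE_ID,
) -> tuple[MultipleSeqAlignment, pd.DataFrame]:
    """Draw an aligned record set from per-column nucleotide frequencies.

    ``column_frequencies`` is indexed by position with columns A/C/G/U
    summing to 1 per row. Each record draws every column independently,
    then gaps replace bases at ``gap_rate``. The reference record (first in
    the alignment) is gap-free and carries each column's most probable
    base. Returns the alignment and a truth frame with the generating
    distribution's entropy per position.
    """
    rng = _rng(seed)
    freqs = column_frequencies[list(RNA_BASES)].to_numpy(dtype=float)
    if np.any(freqs < 0) or not np.allclose(freqs.sum(axis=1), 1.0):
        raise ValueError("column frequencies must be non-negative and sum to 1")
    if not 0 <= gap_rate < 1:
        raise ValueError("gap_rate must lie in [0, 1)")
    n_cols = freqs.shape[0]
    bases = np.array(RNA_BASES)

    ref_seq = "".join(bases[np.argmax(freqs, axis=1)])
    records = [SeqRecord(Seq(ref_seq), id=reference_id, description="")]
    cum = freqs.cumsum(axis=1)
    draws = rng.random((n_records, n_cols))
    picks = (draws[:, :, None] > cum[None, :, :]).sum(axis=2)
    gap_mask = rng.random((n_records, n_cols)) < gap_rate
    for i in range(n_records):
        chars = bases[picks[i]]
        chars = np.where(gap_mask[i], "-", chars)
        records.append(SeqRecord(Seq("".join(chars)), id=f"rec{i:05d}", description=""))

    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(freqs > 0, np.log(freqs), 0.0)
    truth = pd.DataFrame(
        {
            "position": column_frequencies.index.to_numpy(),
            "true_entropy_nats": -(freqs * logp).sum(axis=1),
        }
    )
    return MultipleSeqAlignment(records), truth


# ---------------------------------------------------------------------------
# kinetics


def saturating_concentration(
    times: np.ndarray, rate: float, plateau: float
) -> np.ndarray:
    """c(t) = plateau·(1 − exp(−(rate/plateau)·t)); initial slope = rate."""
    times = np.asarray(times, dtype=float)
    if plateau < 0 or rate < 0:
        raise ValueError("rate and plateau must be non-negative")
    if plateau == 0:
        return np.zeros_like(times)
    return plateau * (1.0 - np.exp(-(rate / plateau) * times))


def synth_kinetics(
    true_rate: float = WT_RATE_UM_PER_H,
    plateau: float = WT_PLATEAU_UM,
    noise_cv: float = 0.0,
    horizon: float = DEFAULT_HORIZON_H,
    dt: float = DEFAULT_DT_H,
    seed: int | np.random.Generator = 0,
    sample_id: str = "WT",
    curve: StandardCurve = DEFAULT_CURVE,
) -> tuple[KineticTrace, StandardCurve, dict]:
    """One saturating reporter trace in RFU plus its standard curve and truth."""
    if plateau <= 0:
        raise ValueError("plateau must be positive")
    rng = _rng(seed)
    times = np.arange(0.0, horizon + dt / 2, dt)
    conc = saturating_concentration(times, true_rate, plateau)
    rfu = (conc - curve.intercept) / curve.slope
    if noise_cv > 0:
        rfu = rfu * (1.0 + noise_cv * rng.standard_normal(rfu.shape))
        rfu = np.clip(rfu, 0.0, None)
    trace = KineticTrace(sample_id=sample_id, times=times, signal=rfu, unit="RFU")
    return trace, curve, {"rate": true_rate, "plateau": plateau}


def standard_curve_points(
    curve: StandardCurve = DEFAULT_CURVE,
    rfu_levels: tuple[float, ...] = (0.0, 100.0, 200.0, 400.0, 600.0, 800.0),
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Calibration points (RFU, μM) on (or noisily around) the given line."""
    rng = _rng(seed)
    rfu = np.asarray(rfu_levels, dtype=float)
    um = curve.slope * rfu + curve.intercept
    if noise_cv > 0:
        um = um * (1.0 + noise_cv * rng.standard_normal(um.shape))
    return pd.DataFrame({"rfu": rfu, "uM": um})


# ---------------------------------------------------------------------------
# gradient traces


def synth_gradient(
    peaks: dict[str, tuple[float, float, float]],
    baseline_drift: tuple[float, float] = (0.05, 0.002),
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
    sample_id: str = "WT",
    x_range: tuple[float, float, float] = (5.0, 65.0, 0.25),
    background_peak: tuple[float, float, float] = (8.0, 1.0, 0.2),
    boundaries: dict[str, tuple[float, float]] | None = None,
) -> tuple[dict[str, GradientTrace], pd.DataFrame]:
    """Gaussian-mixture A254 traces with known per-species areas.

    ``peaks`` maps species → (center mm, σ mm, area absorbance·mm). The
    sample trace is Σ Gaussians + linear drift + a stray background peak
    (+ noise); the blank carries only the drift and the background trace
    only the stray peak, so correction recovers the pure mixture.
    """
    import warnings

    rng = _rng(seed)
    if boundaries is None:
        boundaries = DEFAULT_BOUNDARIES
    for species, (center, _sigma, _area) in peaks.items():
        lo, hi = boundaries.get(species, (-np.inf, np.inf))
        if not lo <= center <= hi:
            warnings.warn(
                f"{sample_id}: {species} peak center {center} outside window [{lo}, {hi}]",
                stacklevel=2,
            )
    x = np.arange(*x_range[:2], x_range[2])

    def gaussian(center, sigma, area):
        return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-((x - center) ** 2) / (2 * sigma**2))

    signal = np.zeros_like(x)
    for center, sigma, area in peaks.values():
        signal += gaussian(center, sigma, area)
    drift = baseline_drift[0] + baseline_drift[1] * x
    stray = gaussian(*background_peak)
    sample = signal + drift + stray
    if noise_cv > 0:
        sample = sample * (1.0 + noise_cv * rng.standard_normal(sample.shape))
    sample = np.clip(sample, 0.0, None)

    traces = {
        "sample": GradientTrace(sample_id, x, sample, kind="sample"),
        "blank": GradientTrace(f"{sample_id}-blank", x, drift, kind="blank"),
        "background": GradientTrace(f"{sample_id}-background", x, stray, kind="background"),
    }
    truth = pd.DataFrame(
        [
            {"sample_id": sample_id, "species": sp, "true_area": area}
            for sp, (_c, _s, area) in peaks.items()
        ]
    )
    return traces, truth


# ---------------------------------------------------------------------------
# toy structure


def synth_structure(
    radii: dict[int, tuple[float, float]],
    seed: int | np.random.Generator = 0,
    ref_separation: float = 30.0,
    cluster_delta: float = 0.6,
) -> tuple[gemmi.Structure, pd.DataFrame]:
    """Toy PDB-writable structure with exact center-to-reference distances.

    ``radii`` maps 23S position → (distance to A-site ref, distance to
    P-site ref) in Å; the pair must satisfy the triangle inequality with
    the reference separation. Each nucleotide is a 4-atom cluster placed
    symmetrically about the solved center, so its heavy-atom mean sits at
    the prescribed distances exactly. Reference residues are A76-like
    8-atom clusters on chains ``A`` (A-site tRNA) and ``P`` (P-site tRNA);
    nucleotides live on chain ``B`` under their 23S numbers.
    """
    import warnings

    rng = _rng(seed)
    D = float(ref_separation)
    ref_a = np.zeros(3)
    ref_p = np.array([D, 0.0, 0.0])

    centers: dict[int, np.ndarray] = {}
    for pos, (d_a, d_p) in sorted(radii.items()):
        if d_a <= 0 or d_p <= 0:
            raise ValueError(f"position {pos}: radii must be positive")
        if not abs(d_a - d_p) <= D <= d_a + d_p:
            raise ValueError(
                f"position {pos}: radii ({d_a}, {d_p}) violate the triangle "
                f"inequality with reference separation {D}"
            )
        xc = (d_a**2 - d_p**2 + D**2) / (2 * D)
        r2 = max(d_a**2 - xc**2, 0.0)
        theta = rng.uniform(0, 2 * np.pi)
        center = np.array([xc, np.sqrt(r2) * np.cos(theta), np.sqrt(r2) * np.sin(theta)])
        for other, c in centers.items():
            if np.linalg.norm(center - c) < 1e-6:
                warnings.warn(f"positions {other} and {pos} share a center", stacklevel=2)
        centers[pos] = center

    structure = gemmi.Structure()
    structure.name = "synthetic toy active site"
    model = gemmi.Model("1")

    def cluster(center: np.ndarray, offsets: np.ndarray, names: list[str]) -> list[gemmi.Atom]:
        atoms = []
        for name, off in zip(names, offsets):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            p = center + off
            atom.pos = gemmi.Position(*p)
            atom.occ = 1.0
            atoms.append(atom)
        return atoms

    # zero-sum offsets: the heavy-atom mean is exactly the cluster center
    nuc_offsets = cluster_delta * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], dtype=float
    )
    ref_offsets = cluster_delta * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
    )

    for chain_name, center in (("A", ref_a), ("P", ref_p)):
        chain = gemmi.Chain(chain_name)
        residue = gemmi.Residue()
        residue.name = "A"
        residue.seqid = gemmi.SeqId(76, " ")
        for atom in cluster(center, ref_offsets, [f"C{i+1}" for i in range(8)]):
            residue.add_atom(atom)
        chain.add_residue(residue)
        model.add_chain(chain)

    chain_b = gemmi.Chain("B")
    for pos in sorted(centers):
        residue = gemmi.Residue()
        residue.name = "N"
        residue.seqid = gemmi.SeqId(pos, " ")
        for atom in cluster(centers[pos], nuc_offsets, ["C1", "C2", "N1", "N2"]):
            residue.add_atom(atom)
        chain_b.add_residue(residue)
    model.add_chain(chain_b)
    structure.add_model(model)
    structure.setup_entities()

    truth = pd.DataFrame(
        [
            {"position": pos, "true_distance_A_site": d_a, "true_distance_P_site": d_p}
            for pos, (d_a, d_p) in sorted(radii.items())
        ]
    )
    return structure, truth


# ---------------------------------------------------------------------------
# full panel


@dataclass
class PanelGroundTruth:
    """Self-consistent truths behind one synthetic study panel."""

    mutant_activity: pd.DataFrame  # sample_id, position, mut_base, true_relative_activity
    readthrough_propensity: pd.DataFrame  # sample_id, true_readthrough
    gradient_fractions: pd.DataFrame  # sample_id, species, true_area
    distances: pd.DataFrame  # position, true_distance_A_site, true_distance_P_site
    column_frequencies: pd.DataFrame  # indexed by position, columns A/C/G/U

    @property
    def flexibility(self) -> pd.DataFrame:
        """Per-position true flexibility = sum of the three mutant activities."""
        flex = (
            self.mutant_activity.groupby("position")["true_relative_activity"]
            .agg(["sum", "count"])
            .rename(columns={"sum": "true_flexibility"})
        )
        if (flex["count"] != 3).any():
            raise ValueError("ground truth inconsistent: not 3 mutants per position")
        return flex.drop(columns="count").reset_index()


@dataclass
class PanelBundle:
    """Everything the pipeline consumes, with its generating truth."""

    traces: pd.DataFrame  # sample_id, replicate, time_h, rfu
    standard_curve_points: pd.DataFrame  # rfu, uM
    readthrough_signals: pd.DataFrame  # sample_id, stop_codon, aa_position, replicate, signal
    gradient_traces: dict[str, dict[str, GradientTrace]]
    alignment: MultipleSeqAlignment
    structure: gemmi.Structure
    truth: PanelGroundTruth
    wt_id: str = "WT"
    reference_id: str = REFERENCE_ID


def default_panel_truth(seed: int | np.random.Generator = 0) -> PanelGroundTruth:
    """Ground truth shaped like the study panel.

    61 positions × 3 mutants. Positions split into flexibility tiers so
    that roughly half score ≥ 1 with a broad 0–3 spread; per-column
    alignment diversity correlates loosely with flexibility (conserved
    columns near-monomorphic, ~75% of them at entropy ≈ 0); A/P-loop
    distances to the P-site reference form a gradient anti-correlated with
    flexibility spanning 4–36 Å; a subset of mutants carries elevated
    readthrough propensity; gradient samples include one severe assembly
    defect (subunit-heavy) alongside wild-type-like profiles.
    """
    rng = _rng(seed)
    regions = default_regions()
    mutants = mutant_catalogue(regions)
    positions = sorted({m.position for m in mutants})

    # per-position flexibility tier: inflexible / intermediate / flexible
    tier = rng.choice([0, 1, 2], size=len(positions), p=[0.45, 0.25, 0.30])
    tier_mean = {0: 0.05, 1: 0.35, 2: 0.85}
    act_rows = []
    for pos, t in zip(positions, tier):
        for m in (m for m in mutants if m.position == pos):
            base = tier_mean[t]
            act = float(np.clip(rng.normal(base, 0.12), 0.0, 1.1))
            act_rows.append(
                {
                    "sample_id": m.name,
                    "position": pos,
                    "mut_base": m.mut_base,
                    "true_relative_activity": act,
                }
            )
    mutant_activity = pd.DataFrame(act_rows)

    flex = mutant_activity.groupby("position")["true_relative_activity"].sum()

    # readthrough: most mutants near wild type, ~15% elevated 3-8x
    rt_rows = []
    for m in mutants:
        elevated = rng.random() < 0.15
        prop = rng.uniform(3.0, 8.0) if elevated else rng.lognormal(0.0, 0.15)
        rt_rows.append({"sample_id": m.name, "true_readthrough": float(prop)})
    readthrough_propensity = pd.DataFrame(rt_rows)

    # gradients: WT-like profiles plus one assembly-defective sample
    def areas(frac_30s, frac_50s, frac_70s, frac_poly, total=10.0):
        return {
            "30S": total * frac_30s,
            "50S": total * frac_50s,
            "70S": total * frac_70s,
            "polysomes": total * frac_poly,
        }

    grad_samples = {
        "WT": areas(0.28, 0.30, 0.155, 0.265),       # subunits/(70S+poly) ≈ 1.4
        "high_activity": areas(0.27, 0.30, 0.16, 0.27),
        "medium_activity": areas(0.33, 0.33, 0.17, 0.17),
        "low_activity": areas(0.38, 0.38, 0.16, 0.08),
        "assembly_defect": areas(0.47, 0.474, 0.037, 0.019),  # ratio ≈ 16.8
    }
    gradient_fractions = pd.DataFrame(
        [
            {"sample_id": sid, "species": sp, "true_area": a}
            for sid, sp_areas in grad_samples.items()
            for sp, a in sp_areas.items()
        ]
    )

    # distances: A/P-loop gradient anti-correlated with flexibility (4-36 Å
    # from the P-site ref); PTC-ring positions scattered without trend
    loop_positions = sorted(
        set(regions["A-loop"].positions()) | set(regions["P-loop"].positions())
    )
    dist_rows = []
    loop_flex = flex[loop_positions]
    lo, hi = loop_flex.min(), loop_flex.max()
    for pos in positions:
        if pos in loop_positions:
            rel = (flex[pos] - lo) / max(hi - lo, 1e-9)
            d_p = 4.0 + rel * 32.0  # least flexible at 4 Å, most flexible at 36 Å
        else:
            d_p = rng.uniform(6.0, 34.0)
        d_a = max(30.0, d_p)  # feasible by construction with 30 Å separation
        dist_rows.append(
            {"position": pos, "true_distance_A_site": d_a, "true_distance_P_site": d_p}
        )
    distances = pd.DataFrame(dist_rows)

    # conservation: ~75% of columns effectively monomorphic for the wild-type
    # base; diversity rises with flexibility tier
    bases = list(RNA_BASES)
    ref_bases = {}
    for region in regions.values():
        ref_bases.update(region.reference_bases)
    freq_rows = {}
    for pos, t in zip(positions, tier):
        wt = ref_bases[pos]
        if t == 0 or rng.random() < 0.5:
            major = 1.0
        else:
            major = rng.uniform(0.55, 0.95) if t == 2 else rng.uniform(0.85, 0.99)
        rest = rng.dirichlet(np.ones(3)) * (1.0 - major)
        freqs = {}
        k = 0
        for b in bases:
            if b == wt:
                freqs[b] = major
            else:
                freqs[b] = float(rest[k])
                k += 1
        freq_rows[pos] = freqs
    column_frequencies = pd.DataFrame.from_dict(freq_rows, orient="index")[bases]

    return PanelGroundTruth(
        mutant_activity=mutant_activity,
        readthrough_propensity=readthrough_propensity,
        gradient_fractions=gradient_fractions,
        distances=distances,
        column_frequencies=column_frequencies,
    )


def synth_panel(
    truth: PanelGroundTruth | None = None,
    noise_cv: float = 0.1,
    seed: int | np.random.Generator = 0,
    n_replicates: int = DEFAULT_N_REPLICATES,
    n_alignment_records: int = 400,
    gap_rate: float = 0.05,
    horizon: float = DEFAULT_HORIZON_H,
    dt: float = DEFAULT_DT_H,
) -> PanelBundle:
    """Generate the complete study-panel input bundle from a ground truth.

    Mutant kinetic plateaus and rates scale with true relative activity
    (shared saturation constant), so the endpoint-yield ratio recovers the
    truth exactly in the noiseless limit. Readthrough signals are
    proportional to (propensity × activity), as fluorescence requires both
    readthrough and translation.
    """
    rng = _rng(seed)
    if truth is None:
        truth = default_panel_truth(rng)
    # validate self-consistency (raises if not 3 mutants/position)
    _ = truth.flexibility

    trace_rows = []
    samples = [("WT", 1.0)] + [
        (r.sample_id, r.true_relative_activity)
        for r in truth.mutant_activity.itertuples()
    ]
    times = np.arange(0.0, horizon + dt / 2, dt)
    for sample_id, act in samples:
        conc = saturating_concentration(times, WT_RATE_UM_PER_H * act, max(WT_PLATEAU_UM * act, 1e-12))
        rfu0 = (conc - DEFAULT_CURVE.intercept) / DEFAULT_CURVE.slope
        for rep in range(1, n_replicates + 1):
            rfu = rfu0
            if noise_cv > 0:
                rfu = np.clip(rfu0 * (1.0 + noise_cv * rng.standard_normal(rfu0.shape)), 0.0, None)
            trace_rows.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_id,
                        "replicate": rep,
                        "time_h": times,
                        "rfu": rfu,
                    }
                )
            )
    traces = pd.concat(trace_rows, ignore_index=True)

    curve_points = standard_curve_points(DEFAULT_CURVE)

    rt_truth = truth.readthrough_propensity.set_index("sample_id")["true_readthrough"]
    act_truth = truth.mutant_activity.set_index("sample_id")["true_relative_activity"]
    rt_rows = []
    base_signal = {pos: 120.0 / (i + 1) for i, pos in enumerate(DEFAULT_STOP_POSITIONS)}
    for sample_id in ["WT", *rt_truth.index]:
        prop = 1.0 if sample_id == "WT" else float(rt_truth[sample_id])
        act = 1.0 if sample_id == "WT" else float(act_truth[sample_id])
        for aa_pos in DEFAULT_STOP_POSITIONS:
            for codon in ("UAG",) if aa_pos != 100 else ("UAG", "UGA", "UAA"):
                for rep in range(1, n_replicates + 1):
                    signal = base_signal[aa_pos] * prop * act
                    if noise_cv > 0:
                        signal = max(signal * (1.0 + noise_cv * rng.standard_normal()), 0.0)
                    rt_rows.append(
                        {
                            "sample_id": sample_id,
                            "stop_codon": codon,
                            "aa_position": aa_pos,
                            "replicate": rep,
                            "signal": signal,
                        }
                    )
    readthrough_signals = pd.DataFrame(rt_rows)

    # peaks sit ≥ 3σ inside their windows so integration captures full mass
    peak_geometry = {"30S": (17.0, 1.3), "50S": (25.0, 1.0), "70S": (35.0, 1.6),
                     "polysomes": (50.0, 2.5)}
    gradient_traces = {}
    for sample_id, group in truth.gradient_fractions.groupby("sample_id"):
        peaks = {
            r.species: (*peak_geometry[r.species], r.true_area)
            for r in group.itertuples()
        }
        trs, _ = synth_gradient(
            peaks, noise_cv=noise_cv, seed=rng, sample_id=str(sample_id)
        )
        gradient_traces[str(sample_id)] = trs

    alignment, _ = synth_alignment(
        truth.column_frequencies,
        n_records=n_alignment_records,
        gap_rate=gap_rate,
        seed=rng,
    )

    radii = {
        r.position: (r.true_distance_A_site, r.true_distance_P_site)
        for r in truth.distances.itertuples()
    }
    structure, _ = synth_structure(radii, seed=rng)

    return PanelBundle(
        traces=traces,
        standard_curve_points=curve_points,
        readthrough_signals=readthrough_signals,
        gradient_traces=gradient_traces,
        alignment=alignment,
        structure=structure,
        truth=truth,
    )


def write_bundle(bundle: PanelBundle, out_dir) -> dict[str, Path]:
    """Write a panel bundle as plain-text files (FASTA, TSVs, PDB)."""
    from Bio import AlignIO

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": out / "kinetic_traces.tsv",
        "standard_curve": out / "standard_curve.tsv",
        "readthrough": out / "readthrough_signals.tsv",
        "gradients": out / "gradient_traces.tsv",
        "alignment": out / "alignment.fasta",
        "structure": out / "toy_structure.pdb",
        "truth_activity": out / "truth_mutant_activity.tsv",
        "truth_distances": out / "truth_distances.tsv",
    }
    bundle.traces.to_csv(paths["traces"], sep="\t", index=False)
    bundle.standard_curve_points.to_csv(paths["standard_curve"], sep="\t", index=False)
    bundle.readthrough_signals.to_csv(paths["readthrough"], sep="\t", index=False)
    grad_rows = []
    for sample_id, trs in bundle.gradient_traces.items():
        for kind, tr in trs.items():
            grad_rows.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_id,
                        "kind": kind,
                        "distance_mm": tr.distance,
                        "a254": tr.a254,
                    }
                )
            )
    pd.concat(grad_rows, ignore_index=True).to_csv(paths["gradients"], sep="\t", index=False)
    with open(paths["alignment"], "w") as fh:
        AlignIO.write(bundle.alignment, fh, "fasta")
    bundle.structure.write_pdb(str(paths["structure"]))
    bundle.truth.mutant_activity.to_csv(paths["truth_activity"], sep="\t", index=False)
    bundle.truth.distances.to_csv(paths["truth_distances"], sep="\t", index=False)
    return paths
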