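"""Sucrose-gradient A254 trace quantification.

A sedimentation run resolves 30S and 50S subunits, 70S monosomes and
polysomes along the gradient; the A254-vs-distance trace is quantified by:

1. baseline/background correction — a blank-sucrose trace and a no-operon
   background trace are linearly interpolated onto the sample grid and
   subtracted (negative absorbance clipped to 0, clip count logged);
2. rectangle-rule (Riemann-sum) integration of the corrected trace inside
   per-species distance windows. The default windows follow the study's
   approximate boundaries: 30S 13–21 mm, 50S 22–28 mm, 70S 30–40 mm,
   polysomes 42–59 mm, treated half-open [start, end) so adjacent windows
   never double-count a grid point. Signal between windows is reported as
   unassigned mass.

From the per-species areas come the assembly ratios: (30S+50S)/(70S+polysomes)
— sensitive to assembly defects — and 70S/polysomes. Both are invariant
under global rescaling of the trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np

logger = logging.getLogger(__name__)

SPECIES = ("30S", "50S", "70S", "polysomes")

DEFAULT_BOUNDARIES: dict[str, tuple[float, float]] = {
    "30S": (13.0, 21.0),
    "50S": (22.0, 28.0),
    "70S": (30.0, 40.0),
    "polysomes": (42.0, 59.0),
}


@dataclass
class GradientTrace:
    """One A254 absorbance trace along the gradient distance axis (mm)."""

    sample_id: str
    distance: np.ndarray
    a254: np.ndarray
    kind: Literal["sample", "blank", "background"] = "sample"

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.a254 = np.asarray(self.a254, dtype=float)
        if self.distance.shape != self.a254.shape:
            raise ValueError("distance and a254 must have equal length")
        if np.any(np.diff(self.distance) <= 0):
            raise ValueError("distance axis must be strictly increasing")
        if self.distance.size < 20:
            raise ValueError("gradient trace needs at least 20 points")


def traces_from_table(df) -> dict[str, dict[str, GradientTrace]]:
    """Group a long table (sample_id, kind, distance_mm, a254) into traces."""
    out: dict[str, dict[str, GradientTrace]] = {}
    for (sid, kind), group in df.groupby(["sample_id", "kind"]):
        group = group.sort_values("distance_mm")
        out.setdefault(str(sid), {})[str(kind)] = GradientTrace(
            str(sid),
            group["distance_mm"].to_numpy(),
            group["a254"].to_numpy(),
            kind=kind,
        )
    return out


def validate_boundaries(boundaries: Mapping[str, tuple[float, float]]) -> None:
    intervals = []
    for species, (start, end) in boundaries.items():
        if not start < end:
            raise ValueError(f"{species}: window start must precede end")
        intervals.append((start, end, species))
    intervals.sort()
    for (s0, e0, n0), (s1, e1, n1) in zip(intervals, intervals[1:]):
        if s1 < e0:
            raise ValueError(f"windows {n0} and {n1} overlap")


def correct_trace(
    sample: GradientTrace,
    blank: GradientTrace,
    background: GradientTrace,
) -> GradientTrace:
    """Subtract interpolated blank and background from the sample trace.

    The output is restricted to the distance span shared by all three
    traces (linear interpolation only; no extrapolation) and clipped at 0.
    """
    lo = max(t.distance[0] for t in (sample, blank, background))
    hi = min(t.distance[-1] for t in (sample, blank, background))
    if lo >= hi:
        raise ValueError("traces do not overlap on a common distance span")
    mask = (sample.distance >= lo) & (sample.distance <= hi)
    x = sample.distance[mask]
    corrected = (
        sample.a254[mask]
        - np.interp(x, blank.distance, blank.a254)
        - np.interp(x, background.distance, background.a254)
    )
    n_clipped = int(np.sum(corrected < 0))
    if n_clipped:
        clipped_mass = float(-corrected[corrected < 0].sum())
        logger.info("%s: clipped %d negative points (mass %.4g) to 0",
                    sample.sample_id, n_clipped, clipped_mass)
        corrected = np.clip(corrected, 0.0, None)
    return replace(sample, distance=x, a254=corrected)


def window_area(
    trace: GradientTrace,
    start: float,
    end: float,
    rule: Literal["left", "trapezoid"] = "left",
) -> float:
    """Area (absorbance·mm) of the trace over the half-open window [start, end)."""
    x, y = trace.distance, trace.a254
    if start < x[0] or end > x[-1]:
        raise ValueError(f"window [{start}, {end}) outside trace span [{x[0]}, {x[-1]}]")
    if rule == "left":
        idx = np.nonzero((x[:-1] >= start) & (x[:-1] < end))[0]
        if idx.size == 0:
            raise ValueError(f"no grid points inside window [{start}, {end})")
        return float(np.sum(y[idx] * np.diff(x)[idx]))
    if rule == "trapezoid":
        mask = (x >= start) & (x < end)
        if mask.sum() < 2:
            raise ValueError(f"too few grid points inside window [{start}, {end})")
        return float(np.trapezoid(y[mask], x[mask]))
    raise ValueError(f"unknown integration rule {rule!r}")


@dataclass
class SpeciesAreas:
    """Integrated per-species areas of one corrected gradient trace."""

    sample_id: str
    areas: dict[str, float]
    unassigned: float = 0.0
    fractions: dict[str, float] = field(init=False)
    ratio_subunits_to_70S_plus_polysomes: float = field(init=False)
    ratio_70S_to_polysomes: float = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.areas.values())
        self.fractions = {
            sp: (a / total if total > 0 else float("nan"))
            for sp, a in self.areas.items()
        }
        subunits = self.areas.get("30S", 0.0) + self.areas.get("50S", 0.0)
        bound = self.areas.get("70S", 0.0) + self.areas.get("polysomes", 0.0)
        self.ratio_subunits_to_70S_plus_polysomes = (
            subunits / bound if bound > 0 else float("nan")
        )
        poly = self.areas.get("polysomes", 0.0)
        self.ratio_70S_to_polysomes = (
            self.areas.get("70S", 0.0) / poly if poly > 0 else float("nan")
        )


def integrate_species(
    trace: GradientTrace,
    boundaries: Mapping[str, tuple[float, float]] | None = None,
    rule: Literal["left", "trapezoid"] = "left",
) -> SpeciesAreas:
    """Integrate a corrected trace into named species areas and ratios."""
    if boundaries is None:
        boundaries = DEFAULT_BOUNDARIES
    validate_boundaries(boundaries)
    areas = {
        species: window_area(trace, start, end, rule=rule)
        for species, (start, end) in boundaries.items()
    }
    span = (min(s for s, _ in boundaries.values()),
            max(e for _, e in boundaries.values()))
    total = window_area(trace, *span, rule=rule)
    unassigned = max(total - sum(areas.values()), 0.0)
    return SpeciesAreas(sample_id=trace.sample_id, areas=areas, unassigned=unassigned)
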