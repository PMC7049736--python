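"""Reporter kinetics → yields, bulk rates, relative activity, flexibility.

Each in vitro ribosome-synthesis reaction is monitored as sfGFP fluorescence
(RFU) over 16–20 h. Raw traces are converted to reporter concentration (μM)
through a linear standard curve, replicates averaged, and two summaries
taken per sample:

* bulk translation rate — OLS slope of concentration vs time over an early
  window (default 0–2 h), in μM protein/h;
* endpoint yield — plateau estimate, the mean concentration over the final
  10% of the time axis (configurable to the last point).

Relative activity normalizes the wild-type yield to one; mutant yields
divide by it. The per-position mutational flexibility score is the sum of
the three mutants' relative activities (0 when no mutant translates, 3 when
all three are wild-type-active; values above 3 are possible and kept if a
mutant out-performs wild type). Two classification flags follow the study's
thresholds: score ≥ 1, and any single mutant ≥ 75% of wild type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .regions import MutantId

logger = logging.getLogger(__name__)

Unit = Literal["RFU", "uM"]


@dataclass
class KineticTrace:
    """One fluorescence or concentration time course."""

    sample_id: str
    times: np.ndarray  # hours, strictly increasing from 0
    signal: np.ndarray
    unit: Unit = "RFU"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have equal length")
        if self.times.size < 4:
            raise ValueError("a kinetic trace needs at least 4 time points")
        if self.times[0] < 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if self.unit not in ("RFU", "uM"):
            raise ValueError(f"unknown unit {self.unit!r}")


@dataclass
class StandardCurve:
    """Linear fluorescence→concentration calibration, μM = slope·RFU + intercept."""

    slope: float  # μM per RFU
    intercept: float  # μM
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("standard-curve slope must be positive")


@dataclass
class ActivityRecord:
    sample_id: str
    endpoint_yield: float  # μM
    bulk_rate: float  # μM/h
    relative_activity: float
    yield_sd: float = float("nan")  # across replicates


def fit_standard_curve(points: Iterable[tuple[float, float]]) -> StandardCurve:
    """OLS line through (RFU, μM) calibration points."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("standard curve needs at least 2 calibration points")
    rfu, um = pts[:, 0], pts[:, 1]
    if np.ptp(rfu) == 0:
        raise ValueError("calibration RFU values are all identical")
    fit = linregress(rfu, um)
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue) ** 2)


def convert_trace(trace: KineticTrace, curve: StandardCurve) -> KineticTrace:
    """Pointwise RFU→μM through the standard curve; negatives floored at 0."""
    if trace.unit != "RFU":
        raise ValueError(f"expected an RFU trace, got unit {trace.unit!r}")
    conc = curve.slope * trace.signal + curve.intercept
    n_floored = int(np.sum(conc < 0))
    if n_floored:
        logger.warning("%s: floored %d negative concentrations at 0",
                       trace.sample_id, n_floored)
        conc = np.clip(conc, 0.0, None)
    return replace(trace, signal=conc, unit="uM")


def estimate_bulk_rate(
    trace: KineticTrace, window: tuple[float, float] = (0.0, 2.0)
) -> float:
    """Bulk translation rate: OLS slope of μM vs h inside the window."""
    if trace.unit != "uM":
        raise ValueError("bulk rate requires a concentration (uM) trace")
    t_start, t_end = window
    mask = (trace.times >= t_start) & (trace.times <= t_end)
    if mask.sum() < 3:
        raise ValueError(
            f"{trace.sample_id}: need ≥ 3 points in window {window}, have {int(mask.sum())}"
        )
    if np.ptp(trace.signal[mask]) == 0:
        return 0.0
    return float(linregress(trace.times[mask], trace.signal[mask]).slope)


def endpoint_yield(
    trace: KineticTrace,
    method: Literal["plateau", "last"] = "plateau",
    plateau_fraction: float = 0.1,
) -> float:
    """Endpoint protein yield in μM.

    ``plateau`` averages the signal over the final ``plateau_fraction`` of
    the time axis (robust to noise once the trace has saturated);
    ``last`` takes the final point.
    """
    if trace.unit != "uM":
        raise ValueError("endpoint yield requires a concentration (uM) trace")
    if method == "last":
        return float(trace.signal[-1])
    if method != "plateau":
        raise ValueError(f"unknown endpoint method {method!r}")
    t0, t1 = trace.times[0], trace.times[-1]
    cutoff = t1 - plateau_fraction * (t1 - t0)
    tail = trace.signal[trace.times >= cutoff]
    return float(tail.mean())


def relative_activity(mutant_yield: float, wt_yield: float) -> float:
    """Mutant yield normalized to wild type (WT ≡ 1)."""
    if not wt_yield > 0:
        raise ValueError("wild-type yield must be positive to normalize")
    if mutant_yield < 0:
        raise ValueError("yields cannot be negative")
    return mutant_yield / wt_yield


def average_replicates(traces: Iterable[KineticTrace]) -> tuple[KineticTrace, float]:
    """Pointwise mean of replicate traces on a common time grid.

    Returns the averaged trace and the replicate standard deviation of the
    final time point (propagated to the activity record).
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no replicate traces")
    base = traces[0]
    for tr in traces[1:]:
        if tr.unit != base.unit or not np.allclose(tr.times, base.times):
            raise ValueError(f"{base.sample_id}: replicates disagree on time grid/unit")
    stack = np.vstack([tr.signal for tr in traces])
    sd = float(stack[:, -1].std(ddof=1)) if len(traces) > 1 else float("nan")
    return replace(base, signal=stack.mean(axis=0)), sd


def activity_records(
    traces_df: pd.DataFrame,
    curve: StandardCurve,
    wt_id: str = "WT",
    rate_window: tuple[float, float] = (0.0, 2.0),
    endpoint_method: Literal["plateau", "last"] = "plateau",
) -> pd.DataFrame:
    """Full activity pipeline over a long-format trace table.

    ``traces_df`` columns: sample_id, replicate, time_h, rfu. Replicates are
    converted to μM, averaged pointwise, then summarized; relative activity
    divides every endpoint yield by the wild-type yield.
    """
    required = {"sample_id", "replicate", "time_h", "rfu"}
    missing = required - set(traces_df.columns)
    if missing:
        raise ValueError(f"trace table lacks columns {sorted(missing)}")
    if wt_id not in set(traces_df["sample_id"]):
        raise ValueError(f"wild-type sample {wt_id!r} not in trace table")

    summaries: dict[str, ActivityRecord] = {}
    for sample_id, group in traces_df.groupby("sample_id", sort=True):
        reps = []
        for _, rep in group.groupby("replicate"):
            rep = rep.sort_values("time_h")
            reps.append(
                convert_trace(
                    KineticTrace(sample_id=str(sample_id),
                                 times=rep["time_h"].to_numpy(),
                                 signal=rep["rfu"].to_numpy(),
                                 unit="RFU"),
                    curve,
                )
            )
        mean_trace, sd = average_replicates(reps)
        summaries[str(sample_id)] = ActivityRecord(
            sample_id=str(sample_id),
            endpoint_yield=endpoint_yield(mean_trace, method=endpoint_method),
            bulk_rate=estimate_bulk_rate(mean_trace, window=rate_window),
            relative_activity=float("nan"),
            yield_sd=sd,
        )

    wt_yield = summaries[wt_id].endpoint_yield
    rows = []
    for rec in summaries.values():
        rows.append(
            {
                "sample_id": rec.sample_id,
                "endpoint_yield_uM": rec.endpoint_yield,
                "bulk_rate_uM_per_h": rec.bulk_rate,
                "relative_activity": relative_activity(rec.endpoint_yield, wt_yield),
                "yield_sd_uM": rec.yield_sd,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FlexibilityScore:
    position: int
    per_mutant_relative_activity: Mapping[str, float]
    score: float
    flag_flex_ge_1: bool
    flag_any_ge_75pct: bool


def flexibility_scores(
    activity_df: pd.DataFrame, wt_id: str = "WT"
) -> pd.DataFrame:
    """Per-position mutational flexibility from mutant activity records.

    Requires exactly the three possible mutants at every position present in
    ``activity_df`` (sample_id parseable as e.g. ``A2451C``; the wild-type
    row is ignored). Score = Σ of the three relative activities; flags mark
    score ≥ 1 and max single-mutant activity ≥ 0.75.
    """
    mutants = activity_df[activity_df["sample_id"] != wt_id]
    parsed = [MutantId.parse(s) for s in mutants["sample_id"]]
    table = mutants.assign(
        position=[m.position for m in parsed],
        mut_base=[m.mut_base for m in parsed],
        wt_base=[m.wt_base for m in parsed],
    )
    rows = []
    for pos, group in table.groupby("position", sort=True):
        if group["mut_base"].duplicated().any():
            dup = group.loc[group["mut_base"].duplicated(), "mut_base"].iloc[0]
            raise ValueError(f"position {pos}: duplicate mutant base {dup}")
        if len(group) != 3:
            raise ValueError(
                f"position {pos}: expected 3 mutants, found {len(group)}"
            )
        acts = dict(zip(group["mut_base"], group["relative_activity"]))
        score = float(sum(acts.values()))
        rows.append(
            {
                "position": int(pos),
                "wt_base": group["wt_base"].iloc[0],
                **{f"activity_{b}": acts.get(b, float("nan")) for b in "ACGU"},
                "score": score,
                "flag_flex_ge_1": score >= 1.0,
                "flag_any_ge_75pct": max(acts.values()) >= 0.75,
            }
        )
    return pd.DataFrame(rows)
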