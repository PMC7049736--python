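"""Standard curve, trace conversion, rates, yields and flexibility scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import linregress

from ptcmap.activity import (
    KineticTrace,
    StandardCurve,
    activity_records,
    convert_trace,
    endpoint_yield,
    estimate_bulk_rate,
    fit_standard_curve,
    flexibility_scores,
    relative_activity,
)
from ptcmap.synth import saturating_concentration, synth_kinetics


def um_trace(times, signal, sample_id="s"):
    return KineticTrace(sample_id, np.asarray(times), np.asarray(signal), unit="uM")


# --- standard curve --------------------------------------------------------


def test_exact_line_recovered():
    curve = fit_standard_curve([(0, 0.0), (100, 1.0), (200, 2.0)])
    assert curve.slope == pytest.approx(0.01, abs=1e-12)
    assert curve.intercept == pytest.approx(0.0, abs=1e-12)
    assert curve.r_squared == pytest.approx(1.0, abs=1e-12)


def test_degenerate_calibration_rejected():
    with pytest.raises(ValueError):
        fit_standard_curve([(100, 1.0), (100, 2.0)])
    with pytest.raises(ValueError):
        fit_standard_curve([(100, 1.0)])


def test_noisy_calibration_slope_within_ci():
    rng = np.random.default_rng(5)
    rfu = np.linspace(0, 800, 20)
    um = 0.01 * rfu + 0.2 + rng.normal(0, 0.05, rfu.size)
    curve = fit_standard_curve(list(zip(rfu, um)))
    stderr = linregress(rfu, um).stderr
    assert abs(curve.slope - 0.01) < 1.96 * stderr


# --- conversion ------------------------------------------------------------


def test_zero_rfu_zero_intercept_gives_zero():
    trace = KineticTrace("s", [0, 1, 2, 3], [0, 0, 0, 0], unit="RFU")
    out = convert_trace(trace, StandardCurve(0.01, 0.0))
    assert np.all(out.signal == 0.0)
    assert out.unit == "uM"


def test_affine_conversion_arithmetic():
    trace = KineticTrace("s", [0, 1, 2, 3], [100, 100, 100, 100], unit="RFU")
    out = convert_trace(trace, StandardCurve(0.01, 0.0))
    assert np.all(out.signal == pytest.approx(1.0))


def test_negative_concentrations_floored(caplog):
    trace = KineticTrace("s", [0, 1, 2, 3], [10, 10, 10, 1000], unit="RFU")
    with caplog.at_level("WARNING"):
        out = convert_trace(trace, StandardCurve(0.01, -0.5))
    assert np.all(out.signal >= 0.0)
    assert out.signal[0] == 0.0 and out.signal[-1] == pytest.approx(9.5)
    assert "floored 3" in caplog.text


def test_unit_mismatch_rejected():
    trace = um_trace([0, 1, 2, 3], [1, 2, 3, 4])
    with pytest.raises(ValueError):
        convert_trace(trace, StandardCurve(0.01, 0.0))


# --- bulk rate -------------------------------------------------------------


def test_noiseless_linear_rate_is_exact():
    t = np.linspace(0, 2, 9)
    assert estimate_bulk_rate(um_trace(t, 0.5 * t)) == pytest.approx(0.5, abs=1e-12)


def test_saturating_trace_rate_within_ten_percent():
    trace, curve, truth = synth_kinetics(true_rate=1.03, noise_cv=0.0, seed=0)
    conc = convert_trace(trace, curve)
    rate = estimate_bulk_rate(conc, window=(0.0, 2.0))
    assert abs(rate - truth["rate"]) / truth["rate"] < 0.10


def test_too_few_points_in_window():
    trace = um_trace([0, 1, 5, 6], [0, 1, 2, 3])
    with pytest.raises(ValueError):
        estimate_bulk_rate(trace, window=(0.0, 2.0))


# --- endpoint yield --------------------------------------------------------


def test_constant_trace_yield():
    trace = um_trace([0, 5, 10, 16], [5, 5, 5, 5])
    assert endpoint_yield(trace) == pytest.approx(5.0)
    assert endpoint_yield(trace, method="last") == pytest.approx(5.0)


def test_saturated_plateau_within_two_percent():
    # k * t_end = (2.0 / 5.0) * 16 = 6.4 >= 5, so the tail sits on the plateau
    t = np.arange(0, 16.25, 0.25)
    trace = um_trace(t, saturating_concentration(t, 2.0, 5.0))
    assert endpoint_yield(trace) == pytest.approx(5.0, rel=0.02)


def test_unsaturated_trace_plateau_exceeds_midpoint():
    t = np.linspace(0, 16, 65)
    trace = um_trace(t, 0.1 * t)  # still rising
    midpoint = trace.signal[len(t) // 2]
    assert endpoint_yield(trace) > midpoint


# --- relative activity -----------------------------------------------------


@pytest.mark.parametrize(
    "mutant, wt, expected", [(5.0, 5.0, 1.0), (0.0, 5.0, 0.0), (1.05, 5.0, 0.21)]
)
def test_relative_activity_ratios(mutant, wt, expected):
    assert relative_activity(mutant, wt) == pytest.approx(expected)


def test_nonpositive_wild_type_yield_rejected():
    with pytest.raises(ValueError):
        relative_activity(1.0, 0.0)


# --- flexibility scores ----------------------------------------------------


def make_activity_df(per_position: dict[str, float]) -> pd.DataFrame:
    rows = [{"sample_id": "WT", "relative_activity": 1.0}]
    rows += [{"sample_id": k, "relative_activity": v} for k, v in per_position.items()]
    return pd.DataFrame(rows)


def test_all_wild_type_activity_scores_three():
    df = make_activity_df({"A2451C": 1.0, "A2451G": 1.0, "A2451U": 1.0})
    out = flexibility_scores(df)
    assert out.loc[0, "score"] == pytest.approx(3.0)
    assert bool(out.loc[0, "flag_flex_ge_1"]) and bool(out.loc[0, "flag_any_ge_75pct"])


def test_dead_position_scores_zero():
    df = make_activity_df({"A2451C": 0.0, "A2451G": 0.0, "A2451U": 0.0})
    out = flexibility_scores(df)
    assert out.loc[0, "score"] == 0.0
    assert not bool(out.loc[0, "flag_flex_ge_1"])
    assert not bool(out.loc[0, "flag_any_ge_75pct"])


def test_mixed_position_score_and_flags():
    df = make_activity_df({"A2062C": 0.10, "A2062G": 0.05, "A2062U": 0.94})
    out = flexibility_scores(df)
    assert out.loc[0, "score"] == pytest.approx(1.09)
    assert bool(out.loc[0, "flag_flex_ge_1"]) and bool(out.loc[0, "flag_any_ge_75pct"])


def test_missing_or_duplicate_mutants_rejected():
    with pytest.raises(ValueError, match="3 mutants"):
        flexibility_scores(make_activity_df({"A2451C": 1.0, "A2451G": 1.0}))
    dup = pd.DataFrame(
        [
            {"sample_id": "A2451C", "relative_activity": 1.0},
            {"sample_id": "A2451C", "relative_activity": 0.5},
            {"sample_id": "A2451G", "relative_activity": 1.0},
        ]
    )
    with pytest.raises(ValueError):
        flexibility_scores(dup)


@given(
    acts=st.tuples(*[st.floats(0, 1.5)] * 3),
    bump=st.floats(0.0, 1.0),
    which=st.integers(0, 2),
)
def test_score_monotone_in_each_mutant_activity(acts, bump, which):
    def score(a):
        df = make_activity_df(dict(zip(["A2451C", "A2451G", "A2451U"], a)))
        return flexibility_scores(df).loc[0, "score"]

    bumped = list(acts)
    bumped[which] += bump
    assert score(bumped) >= score(list(acts))


# --- pipeline-level invariants --------------------------------------------


def panel_df(curve: StandardCurve, scale: float = 1.0) -> pd.DataFrame:
    t = np.arange(0, 16.25, 0.25)
    rows = []
    for sid, act in [("WT", 1.0), ("A2451C", 0.3), ("A2451G", 0.6), ("A2451U", 0.9)]:
        conc = saturating_concentration(t, 1.03 * act, max(5.0 * act, 1e-9))
        rfu = (conc - curve.intercept) / curve.slope * scale
        rows.append(pd.DataFrame({"sample_id": sid, "replicate": 1, "time_h": t, "rfu": rfu}))
    return pd.concat(rows, ignore_index=True)


def test_results_invariant_under_standard_curve_rescaling():
    curve_a = StandardCurve(0.01, 0.0)
    curve_b = StandardCurve(0.001, 0.0)  # 10x more RFU per uM
    rec_a = activity_records(panel_df(curve_a), curve_a)
    rec_b = activity_records(panel_df(curve_b), curve_b)
    for col in ("bulk_rate_uM_per_h", "relative_activity", "endpoint_yield_uM"):
        np.testing.assert_allclose(rec_a[col], rec_b[col], rtol=1e-9)


def test_wild_type_relative_activity_is_exactly_one():
    curve = StandardCurve(0.01, 0.0)
    rec = activity_records(panel_df(curve), curve)
    wt = rec[rec["sample_id"] == "WT"]["relative_activity"].iloc[0]
    assert wt == 1.0
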