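"""Simple linear regression for flexibility-vs-entropy / -distance analyses.

Ordinary least squares with a two-sided t test on the slope (n − 2 degrees
of freedom); R² is the squared Pearson correlation, as always in simple
regression. No multiple-testing correction is applied — relationships are
reported per comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    stderr: float


def linear_regression(x, y) -> RegressionResult:
    """OLS fit of y on x with slope t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    if np.ptp(y) == 0:
        # flat response: zero slope explains nothing, by convention R^2 = 0
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0,
            p_value=1.0, n=int(x.size), stderr=0.0,
        )
    fit = linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n=int(x.size),
        stderr=float(fit.stderr),
    )
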