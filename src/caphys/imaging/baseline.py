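"""Pre-drug baseline models: flat, or an extrapolated sloping line.

The sloping model is selected only when the least-squares slope over the
baseline window is statistically significant (two-sided t test on the slope,
default alpha 0.05); otherwise the baseline is flat at the window mean.  The
selected model is extrapolated across the post-drug window for detrending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from caphys.imaging.traces import DffSeries

MIN_BASELINE_SPAN_S = 300.0  # the >5-min baseline requirement


@dataclass
class BaselineModel:
    kind: str  # "flat" or "sloping"
    intercept: float  # dF/F at t = 0
    slope: float  # dF/F per second (0 for flat)
    baseline_sd: float  # SD of residuals over the baseline window
    # extrapolation guard for sloping fits: standard error of the slope and
    # the centre of the fit window, so downstream thresholds can widen with
    # extrapolation distance instead of treating a noisy slope as exact
    slope_se: float = 0.0
    t_center_s: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "sloping"):
            raise ValueError("kind must be 'flat' or 'sloping'")
        if self.kind == "flat" and self.slope != 0.0:
            raise ValueError("flat baseline must have zero slope")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")

    def predict(self, t_s) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t_s, dtype=float)


def fit_baseline(dff: DffSeries, alpha: float = 0.05) -> BaselineModel:
    """Fit flat and sloping candidates on the baseline window and select.

    Raises ``ValueError`` when the baseline window is shorter than the
    required 5 minutes (300 s) or holds fewer than 2 valid cycles.
    """
    lo, hi = dff.baseline_window_s
    if hi - lo < MIN_BASELINE_SPAN_S:
        raise ValueError(
            f"baseline window spans {hi - lo:.0f} s but the responder criterion "
            "requires a >5 min (>=300 s) pre-drug baseline"
        )
    mask = dff.baseline_mask()
    t = dff.cycle_times_s[mask]
    v = dff.values[mask]
    if v.size < 2:
        raise ValueError("baseline window must contain at least 2 valid cycles")

    use_sloping = False
    slope = 0.0
    slope_se = 0.0
    intercept = float(np.mean(v))
    if v.size >= 3 and np.ptp(v) > 0:
        fit = stats.linregress(t, v)
        if np.isfinite(fit.pvalue) and fit.pvalue < alpha:
            use_sloping = True
            slope = float(fit.slope)
            intercept = float(fit.intercept)
            slope_se = float(fit.stderr) if np.isfinite(fit.stderr) else 0.0

    if use_sloping:
        resid = v - (intercept + slope * t)
        ddof = min(2, v.size - 1)
    else:
        resid = v - intercept
        ddof = 1
    sd = float(np.std(resid, ddof=ddof)) if v.size > ddof else 0.0
    return BaselineModel(
        kind="sloping" if use_sloping else "flat",
        intercept=intercept,
        slope=slope,
        baseline_sd=sd,
        slope_se=slope_se,
        t_center_s=float(np.mean(t)) if use_sloping else 0.0,
    )
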