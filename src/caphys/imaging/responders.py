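"""Responder detection: the k-SD criterion with a persistence rule.

A cell is a responder when at least ``min_consecutive`` consecutive
post-drug cycles of the detrended dF/F exceed ``k_sd`` baseline standard
deviations.  Onset is the first cycle of the first qualifying run; the
percent change averages the detrended values from onset to the end of the
recording, relative to the baseline mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from caphys.imaging.baseline import BaselineModel
from caphys.imaging.traces import DffSeries


@dataclass
class ResponderCall:
    is_responder: bool
    percent_change: float  # % of baseline dF/F
    onset_s: float  # seconds from drug application; NaN for non-responders
    threshold_used: float  # k_sd * baseline_sd, in dF/F units

    def __post_init__(self) -> None:
        if self.is_responder and not np.isnan(self.onset_s) and self.onset_s < 0:
            raise ValueError("onset must not precede drug application")


def _first_run_start(flags: np.ndarray, min_consecutive: int) -> int | None:
    run = 0
    for i, f in enumerate(flags):
        run = run + 1 if f else 0
        if run >= min_consecutive:
            return i - min_consecutive + 1
    return None


def detect_responder(
    dff: DffSeries,
    baseline: BaselineModel,
    k_sd: float = 3.0,
    min_consecutive: int = 3,
) -> ResponderCall:
    """Classify one cell against its own baseline.

    With ``baseline_sd == 0`` (degenerate noiseless case) any positive
    detrended excursion qualifies and the threshold is reported as 0.
    """
    t = dff.cycle_times_s
    resid = dff.values - baseline.predict(t)
    post = dff.post_mask()
    threshold = k_sd * baseline.baseline_sd
    # For sloping baselines the per-cycle threshold widens with the slope's
    # extrapolation uncertainty, so a noisy slope extrapolated far past the
    # baseline window cannot manufacture spurious excursions.
    per_cycle_threshold = k_sd * np.sqrt(
        baseline.baseline_sd**2 + (baseline.slope_se * (t - baseline.t_center_s)) ** 2
    )
    # absolute floor far below any physical dF/F change: keeps the
    # degenerate zero-SD convention while ignoring float-level residue
    per_cycle_threshold = np.maximum(per_cycle_threshold, 1e-12)

    base_mask = dff.baseline_mask()
    base_mean = float(np.mean(baseline.predict(t[base_mask]))) if base_mask.any() else np.nan

    post_idx = np.flatnonzero(post)
    exceed = np.zeros(t.shape, dtype=bool)
    exceed[post_idx] = resid[post_idx] > per_cycle_threshold[post_idx]
    # invalid (dropped) cycles break runs: only flags on valid post cycles count
    start_rel = _first_run_start(exceed[post_idx], min_consecutive) if post_idx.size else None

    if start_rel is None:
        pct = np.nan
        if post_idx.size and np.isfinite(base_mean) and base_mean != 0:
            pct = 100.0 * float(np.nanmean(resid[post_idx])) / base_mean
        return ResponderCall(
            is_responder=False, percent_change=pct, onset_s=np.nan, threshold_used=threshold
        )

    onset_idx = post_idx[start_rel]
    onset_s = float(t[onset_idx] - dff.drug_time_s)
    window = post_idx[post_idx >= onset_idx]
    pct = 100.0 * float(np.mean(resid[window])) / base_mean
    return ResponderCall(
        is_responder=True, percent_change=pct, onset_s=onset_s, threshold_used=threshold
    )
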