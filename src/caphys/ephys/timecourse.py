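"""Drug-response time course: responder vs. rundown vs. flat.

Per-sweep peak magnitudes form the time series.  The baseline is the mean of
the pre-drug peaks; onset is the first of >= 2 consecutive post-drug sweeps
beyond +/- 2 SD of the baseline peaks; the percent change compares the
plateau (last third of the post-drug epoch by default) to baseline, on
magnitudes, so it is invariant to amplifier gain rescaling.

Because rundown co-occurs with drug responses and is geometric rather than
linear, the responder/rundown boundary extrapolates a log-linear (geometric)
trend fitted on the pre-drug peaks: a plateau sitting above that trend beyond
the pre-drug residual noise is a responder; otherwise a significantly
negative overall slope is rundown, and anything else is flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from caphys.ephys.iv import sweep_peak
from caphys.ephys.leak import correct_sweepset
from caphys.synth.ephys import SweepSet

CLASS_RESPONDER = "responder"
CLASS_RUNDOWN = "rundown"
CLASS_FLAT = "flat"


@dataclass
class DrugResponse:
    baseline_peak: float  # mean pre-drug |peak|, pA
    percent_change: float  # plateau vs baseline, % of baseline magnitude
    onset_min: float  # minutes from drug application; NaN if none detected
    peak_response_min: float
    classification: str
    peak_magnitudes: np.ndarray = field(default_factory=lambda: np.array([]))
    sweep_times_s: np.ndarray = field(default_factory=lambda: np.array([]))


def _onset_sweep(post_mag: np.ndarray, mean: float, sd: float, eps: float) -> int | None:
    outside = np.abs(post_mag - mean) > (2.0 * sd + eps)
    run = 0
    for i, o in enumerate(outside):
        run = run + 1 if o else 0
        if run >= 2:
            return i - 1
    return None


def drug_response_timecourse(
    sweepset: SweepSet,
    n_baseline_sweeps: int | None = None,
    plateau_fraction: float = 1.0 / 3.0,
    apply_pn: bool = True,
) -> DrugResponse:
    """Classify one cell's repeated-test-pulse time course."""
    ss = correct_sweepset(sweepset) if apply_pn else sweepset
    protocol = ss.protocol
    times = np.array([s.start_time_s for s in ss.sweeps])
    mags = np.array([abs(sweep_peak(s, protocol)[0]) for s in ss.sweeps])

    pre = times < ss.drug_time_s
    post = ~pre
    if pre.sum() < 3:
        raise ValueError("need at least 3 pre-drug sweeps for a baseline")
    pre_mag = mags[pre]
    if n_baseline_sweeps is not None:
        pre_mag = pre_mag[-n_baseline_sweeps:]
    baseline = float(pre_mag.mean())
    base_sd = float(pre_mag.std(ddof=1))
    eps = 1e-9 * (baseline + 1.0)

    post_mag = mags[post]
    post_times = times[post]
    if post_mag.size == 0:
        return DrugResponse(
            baseline_peak=baseline,
            percent_change=0.0,
            onset_min=np.nan,
            peak_response_min=np.nan,
            classification=CLASS_FLAT,
            peak_magnitudes=mags,
            sweep_times_s=times,
        )

    n_plateau = max(int(np.ceil(plateau_fraction * post_mag.size)), 1)
    plateau = post_mag[-n_plateau:]
    percent_change = 100.0 * (float(plateau.mean()) - baseline) / baseline

    onset_rel = _onset_sweep(post_mag, baseline, base_sd, eps)
    onset_min = (
        (post_times[onset_rel] - ss.drug_time_s) / 60.0 if onset_rel is not None else np.nan
    )
    peak_response_min = (post_times[np.argmax(post_mag)] - ss.drug_time_s) / 60.0

    # geometric (log-linear) pre-drug trend, extrapolated to the plateau
    idx = np.arange(mags.size)
    pre_idx = idx[pre][-pre_mag.size:]
    plateau_idx = idx[post][-n_plateau:]
    if np.all(pre_mag > 0):
        coef = np.polyfit(pre_idx, np.log(pre_mag), 1)
        trend_pre = np.exp(np.polyval(coef, pre_idx))
        resid_sd = float(np.std(pre_mag - trend_pre, ddof=1)) if pre_mag.size > 2 else 0.0
        expected_plateau = float(np.exp(np.polyval(coef, plateau_idx)).mean())
    else:
        resid_sd = base_sd
        expected_plateau = baseline
    deviation = float(plateau.mean()) - expected_plateau

    if deviation > 2.0 * resid_sd + eps:
        classification = CLASS_RESPONDER
    else:
        fit = stats.linregress(idx, mags)
        if fit.slope < 0 and np.isfinite(fit.pvalue) and fit.pvalue < 0.05:
            classification = CLASS_RUNDOWN
        else:
            classification = CLASS_FLAT

    return DrugResponse(
        baseline_peak=baseline,
        percent_change=percent_change,
        onset_min=onset_min,
        peak_response_min=peak_response_min,
        classification=classification,
        peak_magnitudes=mags,
        sweep_times_s=times,
    )
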