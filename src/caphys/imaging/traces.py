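"""Per-ROI fluorescence traces and the instantaneous dF/F statistic.

Frames are paired per stimulation cycle as (unstimulated F1, immediately
following stimulated F2); the cycle time is the stimulated frame's
acquisition time.  The activity statistic is the instantaneous
``(F2 - F1) / F1`` per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from caphys.imaging.rois import RoiSet


@dataclass
class RoiTrace:
    """Resting (F1) and stimulated (F2) mask-mean fluorescence per cycle."""

    f1_series: np.ndarray
    f2_series: np.ndarray
    cycle_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.f1_series = np.asarray(self.f1_series, dtype=float)
        self.f2_series = np.asarray(self.f2_series, dtype=float)
        self.cycle_times_s = np.asarray(self.cycle_times_s, dtype=float)
        if not (self.f1_series.shape == self.f2_series.shape == self.cycle_times_s.shape):
            raise ValueError("F1, F2 and cycle time series must have equal length")


@dataclass
class DffSeries:
    """Instantaneous dF/F per stimulation cycle.

    Cycles with nonpositive F1 are flagged invalid (NaN value, ``valid``
    False) and excluded from all downstream windows; a dropped cycle is
    never re-paired with a neighbour.
    """

    values: np.ndarray
    cycle_times_s: np.ndarray
    drug_time_s: float
    baseline_window_s: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cycle_times_s = np.asarray(self.cycle_times_s, dtype=float)
        if self.values.shape != self.cycle_times_s.shape:
            raise ValueError("values and cycle_times_s must have equal length")
        if self.baseline_window_s is None:
            start = float(self.cycle_times_s[0]) if self.values.size else 0.0
            self.baseline_window_s = (start, float(self.drug_time_s))
        if self.baseline_window_s[1] > self.drug_time_s + 1e-9:
            raise ValueError("baseline window must precede drug application")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)

    def baseline_mask(self) -> np.ndarray:
        lo, hi = self.baseline_window_s
        return (self.cycle_times_s >= lo) & (self.cycle_times_s < hi) & self.valid

    def post_mask(self) -> np.ndarray:
        return (self.cycle_times_s >= self.drug_time_s) & self.valid


def roi_means(frame: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Mask-mean intensity of one frame for each ROI."""
    flat = frame.reshape(-1)
    return np.array([flat[m.reshape(-1)].mean() for m in masks])


def extract_roi_traces(
    cal_stack: np.ndarray,
    stim_flags: np.ndarray,
    times_s: np.ndarray,
    rois: RoiSet,
) -> list[RoiTrace]:
    """Mask-mean F1/F2 pairs per cycle for every ROI.

    Requires strictly alternating stimulation flags starting unstimulated; a
    trailing unpaired frame is dropped.
    """
    stack = np.asarray(cal_stack, dtype=float)
    flags = np.asarray(stim_flags, dtype=bool)
    times = np.asarray(times_s, dtype=float)
    t = stack.shape[0]
    if flags.shape != (t,) or times.shape != (t,):
        raise ValueError("stim_flags and times_s must have one entry per frame")
    if not np.array_equal(flags, np.arange(t) % 2 == 1):
        raise ValueError("stim_flags must strictly alternate starting unstimulated")
    n_cycles = t // 2

    # (T, n_cells) matrix of mask means, computed per frame
    masks_flat = rois.masks.reshape(rois.n_cells, -1)
    counts = masks_flat.sum(axis=1).astype(float)
    sums = stack.reshape(t, -1) @ masks_flat.T.astype(float)
    means = sums / counts[None, :]

    f1 = means[0 : 2 * n_cycles : 2]
    f2 = means[1 : 2 * n_cycles : 2]
    cycle_times = times[1 : 2 * n_cycles : 2]
    return [
        RoiTrace(f1_series=f1[:, i], f2_series=f2[:, i], cycle_times_s=cycle_times)
        for i in range(rois.n_cells)
    ]


def instantaneous_dff(
    trace: RoiTrace,
    drug_time_s: float,
    baseline_window_s: tuple[float, float] | None = None,
) -> DffSeries:
    """``(F2 - F1) / F1`` per cycle; cycles with F1 <= 0 flagged invalid."""
    f1 = trace.f1_series
    f2 = trace.f2_series
    valid = f1 > 0
    values = np.full(f1.shape, np.nan)
    values[valid] = (f2[valid] - f1[valid]) / f1[valid]
    return DffSeries(
        values=values,
        cycle_times_s=trace.cycle_times_s,
        drug_time_s=drug_time_s,
        baseline_window_s=baseline_window_s,
        valid=valid,
    )
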