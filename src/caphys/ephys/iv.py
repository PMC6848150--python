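"""Peak currents and I-V curves from P/N-corrected sweeps.

Peak detection pre-smooths with a 2-ms boxcar and skips the first 2 ms after
step onset (residual capacitive transient), then takes the largest-magnitude
deflection within the step window.  Inward currents are negative by
convention, so peaks are reported signed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from caphys.config import VoltageProtocol
from caphys.synth.ephys import Sweep, SweepSet
from caphys.ephys.leak import correct_sweepset


def sweep_peak(
    sweep: Sweep,
    protocol: VoltageProtocol,
    smooth_ms: float = 2.0,
    blank_ms: float = 2.0,
) -> tuple[float, float]:
    """(signed peak current, peak time in ms from sweep start)."""
    fs = protocol.sampling_khz
    i_on = int(round(protocol.pre_ms * fs))
    i_off = int(round((protocol.pre_ms + protocol.step_duration_ms) * fs))
    i_start = i_on + int(round(blank_ms * fs))
    if i_start >= i_off:
        raise ValueError("blanking window longer than the step")
    seg = sweep.current[i_start:i_off]
    size = max(int(round(smooth_ms * fs)), 1)
    sm = uniform_filter1d(seg, size=size, mode="nearest")
    k = int(np.argmax(np.abs(sm)))
    return float(sm[k]), float(sweep.time_ms[i_start + k])


@dataclass
class IVCurve:
    step_mv: np.ndarray
    peak_current: np.ndarray  # signed, inward negative; NaN at gaps
    peak_time_ms: np.ndarray
    missing_levels: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.step_mv = np.asarray(self.step_mv, dtype=float)
        self.peak_current = np.asarray(self.peak_current, dtype=float)
        self.peak_time_ms = np.asarray(self.peak_time_ms, dtype=float)
        if not (self.step_mv.shape == self.peak_current.shape == self.peak_time_ms.shape):
            raise ValueError("I-V arrays must have equal length")


def build_iv_curve(sweepset: SweepSet, apply_pn: bool = True) -> IVCurve:
    """One peak per protocol step level, ordered by level; gaps flagged."""
    ss = correct_sweepset(sweepset) if apply_pn else sweepset
    protocol = ss.protocol
    by_level: dict[float, Sweep] = {}
    for s in ss.sweeps:
        by_level.setdefault(s.level_mv, s)

    levels = sorted(protocol.step_levels_mv)
    peaks, times, missing = [], [], []
    for v in levels:
        if v in by_level:
            p, tm = sweep_peak(by_level[v], protocol)
            peaks.append(p)
            times.append(tm)
        else:
            peaks.append(np.nan)
            times.append(np.nan)
            missing.append(v)
    return IVCurve(
        step_mv=np.array(levels),
        peak_current=np.array(peaks),
        peak_time_ms=np.array(times),
        missing_levels=missing,
    )
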