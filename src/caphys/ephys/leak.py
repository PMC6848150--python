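"""P/N leak subtraction.

Linear leak and capacitive currents scale with step amplitude, so the
averaged response to the small P/N sub-steps, scaled by the ratio of test to
sub-step amplitude, cancels both from a test sweep.  For a -80 -> 0 mV test
pulse with -80 -> -100 mV sub-steps the scale factor is 80 / (-20) = -4.
"""

from __future__ import annotations

import numpy as np

from caphys.config import VoltageProtocol
from caphys.synth.ephys import Sweep, SweepSet


def pn_scale_factor(protocol: VoltageProtocol, level_mv: float) -> float:
    pn_amp = protocol.pn_amplitude_mv
    if pn_amp == 0:
        raise ValueError("P/N step amplitude must be nonzero")
    return (level_mv - protocol.holding_mv) / pn_amp


def pn_leak_subtract(
    test_sweep: Sweep,
    pn_sweeps: list[np.ndarray],
    protocol: VoltageProtocol,
) -> Sweep:
    """Subtract the scaled mean P/N sub-sweep from one test sweep."""
    if not pn_sweeps:
        raise ValueError("at least one P/N sub-sweep required")
    template = np.mean(np.asarray(pn_sweeps, dtype=float), axis=0)
    if template.shape != test_sweep.current.shape:
        raise ValueError("P/N sub-sweeps must share the test sweep's sample grid")
    scale = pn_scale_factor(protocol, test_sweep.level_mv)
    return Sweep(
        time_ms=test_sweep.time_ms,
        current=test_sweep.current - scale * template,
        level_mv=test_sweep.level_mv,
        start_time_s=test_sweep.start_time_s,
    )


def correct_sweepset(sweepset: SweepSet) -> SweepSet:
    """P/N-correct every test sweep (no-op when no sub-sweeps recorded)."""
    if not sweepset.pn_sweeps:
        return sweepset
    corrected = [
        pn_leak_subtract(s, sweepset.pn_sweeps, sweepset.protocol) for s in sweepset.sweeps
    ]
    return SweepSet(
        sweeps=corrected,
        protocol=sweepset.protocol,
        pn_sweeps=[],
        drug_time_s=sweepset.drug_time_s,
    )
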