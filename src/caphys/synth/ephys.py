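"""Synthetic voltage-clamp sweep sets: Boltzmann-gated current + artifacts.

Each test sweep is the gated channel current plus a linear leak, biexponential
capacitive transients at the step edges, and Gaussian noise.  The conductance
is multiplied per sweep by a geometric rundown factor and, after drug onset,
by a factor saturating at ``drug_gain``.  P/N sub-sweeps contain the leak and
capacitive components only, at the (small) P/N step amplitude; both artifact
terms are exactly linear in step amplitude, which is the assumption P/N
subtraction relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from caphys.config import ChannelModel, VoltageProtocol


def steady_state_activation(model: ChannelModel, v_mv) -> np.ndarray:
    """Boltzmann steady-state activation m_inf(v)."""
    v = np.asarray(v_mv, dtype=float)
    return 1.0 / (1.0 + np.exp(-(v - model.v_half) / model.slope_k))


def channel_current(model: ChannelModel, v_mv, t_ms) -> np.ndarray:
    """Gated current ``g_max * m(t)**p * (v - e_rev)`` (pA for nS, mV).

    ``m(t)`` relaxes first-order from 0 toward ``m_inf(v)`` with time
    constant ``tau_activation_ms``.  Leak and noise are not included.
    """
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_ms must be >= 0")
    m = steady_state_activation(model, v_mv) * (1.0 - np.exp(-t / model.tau_activation_ms))
    v = np.asarray(v_mv, dtype=float)
    return model.g_max * m**model.p_exponent * (v - model.e_rev)


@dataclass
class Sweep:
    """One sweep: uniform time base (ms), current (pA) and the command step."""

    time_ms: np.ndarray
    current: np.ndarray
    level_mv: float
    start_time_s: float

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time_ms.shape != self.current.shape:
            raise ValueError("time and current arrays must match")
        if self.time_ms.size >= 2:
            dt = np.diff(self.time_ms)
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("sampling must be uniform within a sweep")


@dataclass
class SweepSet:
    """Test sweeps + P/N sub-sweeps for one recorded cell."""

    sweeps: list[Sweep]
    protocol: VoltageProtocol
    pn_sweeps: list[np.ndarray] = field(default_factory=list)
    drug_time_s: float = np.inf

    def __post_init__(self) -> None:
        starts = [s.start_time_s for s in self.sweeps]
        if np.any(np.diff(starts) <= 0):
            raise ValueError("sweep start times must be strictly increasing")


@dataclass
class GroundTruthEphys:
    """Per-sweep planted conductance scaling and noise-free peak currents."""

    g_effective: np.ndarray  # g_max * rundown * drug factor, per sweep
    rundown_factor: np.ndarray
    drug_factor: np.ndarray
    true_peak_pa: np.ndarray  # extremum of the noise-free gated current
    channel_only: list[np.ndarray]  # noise-free gated current per sweep
    drug_time_s: float


def _edges(protocol: VoltageProtocol) -> tuple[np.ndarray, int, int]:
    n = int(round((protocol.pre_ms + protocol.step_duration_ms + protocol.post_ms)
                  * protocol.sampling_khz))
    t = np.arange(n) / protocol.sampling_khz
    i_on = int(round(protocol.pre_ms * protocol.sampling_khz))
    i_off = int(round((protocol.pre_ms + protocol.step_duration_ms) * protocol.sampling_khz))
    return t, i_on, i_off


def command_waveform(protocol: VoltageProtocol, level_mv: float) -> tuple[np.ndarray, np.ndarray]:
    """(time_ms, v_mv) command for one sweep: holding / step / holding."""
    t, i_on, i_off = _edges(protocol)
    v = np.full_like(t, protocol.holding_mv)
    v[i_on:i_off] = level_mv
    return t, v


def _capacitive(model: ChannelModel, t_rel_ms: np.ndarray, dv_mv: float) -> np.ndarray:
    """Biexponential edge transient, linear in the voltage jump dv."""
    out = np.zeros_like(t_rel_ms)
    mask = t_rel_ms >= 0
    tr = t_rel_ms[mask]
    for w, tau in zip(model.cap_weights, model.cap_tau_ms):
        out[mask] += model.c_membrane * dv_mv * (w / tau) * np.exp(-tr / tau)
    return out


def _artifact_current(model: ChannelModel, protocol: VoltageProtocol, from_mv: float,
                      to_mv: float) -> np.ndarray:
    """Leak + capacitive current for a from->to->from step (no channel)."""
    t, i_on, i_off = _edges(protocol)
    dv = to_mv - from_mv
    i = np.zeros_like(t)
    i[i_on:i_off] += model.g_leak * dv
    i += _capacitive(model, t - t[i_on], dv)
    i += _capacitive(model, t - t[i_off], -dv)
    return i


def _gated_current(model: ChannelModel, protocol: VoltageProtocol, level_mv: float,
                   g_scale: float) -> np.ndarray:
    t, i_on, i_off = _edges(protocol)
    i = np.zeros_like(t)
    i[i_on:i_off] = g_scale * channel_current(model, level_mv, t[i_on:i_off] - t[i_on])
    return i  # instantaneous deactivation at step offset (no tail current)


def drug_factor(model: ChannelModel, t_s: float, drug_onset_s: float) -> float:
    """Saturating conductance multiplier rising to ``drug_gain`` after onset."""
    if t_s < drug_onset_s or model.drug_gain == 1.0:
        return 1.0
    return 1.0 + (model.drug_gain - 1.0) * (1.0 - np.exp(-(t_s - drug_onset_s) / model.drug_tau_s))


def generate_ephys_experiment(
    model: ChannelModel,
    protocol: VoltageProtocol,
    n_baseline_sweeps: int,
    n_post_sweeps: int,
) -> tuple[SweepSet, GroundTruthEphys]:
    """Generate a sweep set and its ground truth.

    Step levels cycle through ``protocol.step_levels_mv`` (a single level
    gives the repeated test-pulse time course; the full I-V ladder gives one
    sweep per level when ``n_baseline_sweeps == len(levels)`` and
    ``n_post_sweeps == 0``).  Drug onset defaults to the end of the baseline
    epoch unless ``model.drug_onset_s`` is set.
    """
    if n_baseline_sweeps < 1 or n_post_sweeps < 0:
        raise ValueError("need at least one baseline sweep and n_post_sweeps >= 0")
    rng = np.random.default_rng(model.seed)
    n_sweeps = n_baseline_sweeps + n_post_sweeps
    interval = protocol.inter_sweep_interval_s
    drug_onset_s = (
        model.drug_onset_s if model.drug_onset_s is not None else n_baseline_sweeps * interval
    )

    levels = protocol.step_levels_mv
    sweeps: list[Sweep] = []
    g_eff, run_f, drug_f, true_peak, channel_only = [], [], [], [], []
    for k in range(n_sweeps):
        level = levels[k % len(levels)]
        t_start = k * interval
        rf = (1.0 - model.rundown_rate) ** k
        df = drug_factor(model, t_start, drug_onset_s)
        g_scale = rf * df
        t, _, _ = _edges(protocol)
        chan = _gated_current(model, protocol, level, g_scale)
        i = chan + _artifact_current(model, protocol, protocol.holding_mv, level)
        if model.noise_sd > 0:
            i = i + rng.normal(0.0, model.noise_sd, size=i.shape)
        sweeps.append(Sweep(time_ms=t, current=i, level_mv=level, start_time_s=t_start))
        g_eff.append(model.g_max * g_scale)
        run_f.append(rf)
        drug_f.append(df)
        peak_idx = np.argmax(np.abs(chan))
        true_peak.append(chan[peak_idx])
        channel_only.append(chan)

    pn_sweeps = []
    for _ in range(protocol.pn_n_reps):
        i = _artifact_current(model, protocol, protocol.pn_step_mv[0], protocol.pn_step_mv[1])
        if model.noise_sd > 0:
            i = i + rng.normal(0.0, model.noise_sd, size=i.shape)
        pn_sweeps.append(i)

    sweepset = SweepSet(
        sweeps=sweeps, protocol=protocol, pn_sweeps=pn_sweeps, drug_time_s=drug_onset_s
    )
    truth = GroundTruthEphys(
        g_effective=np.asarray(g_eff),
        rundown_factor=np.asarray(run_f),
        drug_factor=np.asarray(drug_f),
        true_peak_pa=np.asarray(true_peak),
        channel_only=channel_only,
        drug_time_s=drug_onset_s,
    )
    return sweepset, truth
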