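"""Configuration dataclasses for the generators and the analysis pipelines.

All configs validate their invariants in ``__post_init__`` and raise
``ValueError`` with a specific message on violation.  Every config can be
built from a plain dict (e.g. parsed YAML) via ``from_dict``; unknown keys
are rejected so typos in config files fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence


def _from_dict(cls, d: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass
class ImagingConfig:
    """Parameters of a synthetic two-channel imaging session.

    Frames alternate unstimulated/stimulated: acquisition at 0.1 Hz
    (``frame_interval_s=10``) with every second frame stimulus-locked, so
    stimulation cycles run at 0.05 Hz.  Amplitudes are percent change of the
    evoked dF/F; onsets are minutes after drug application.
    """

    image_height_px: int = 128
    image_width_px: int = 128
    n_cells: int = 40
    txred_positive_fraction: float = 0.15
    responder_fraction: float = 0.073
    responder_amplitude_mean: float = 24.0
    responder_amplitude_sd: float = 5.0
    responder_onset_mean_min: float = 6.7
    responder_onset_sd_min: float = 1.5
    baseline_dff_mean: float = 0.30
    baseline_dff_sd: float = 0.05
    photobleach_rate: float = 2e-4
    noise_sd: float = 1.0
    frame_interval_s: float = 10.0
    drug_time_min: float | None = None  # default: end of baseline epoch
    baseline_duration_min: float = 6.0
    post_duration_min: float = 14.0
    cell_radius_px: float = 4.0
    background_level: float = 8.0
    z_drift_events: Sequence[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("txred_positive_fraction", "responder_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.responder_fraction > 1.0 - self.txred_positive_fraction + 1e-12:
            raise ValueError(
                "responder_fraction exceeds the TxRed-negative fraction: "
                "responders must be TxRed-negative"
            )
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.baseline_duration_min <= 0:
            raise ValueError("baseline_duration_min must be > 0")
        if self.post_duration_min <= 0:
            raise ValueError("post_duration_min must be > 0")
        for name in (
            "responder_amplitude_sd",
            "responder_onset_sd_min",
            "baseline_dff_sd",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.photobleach_rate < 1.0:
            raise ValueError("photobleach_rate must be in [0, 1)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cell_radius_px <= 0:
            raise ValueError("cell_radius_px must be > 0")
        if self.drug_time_min is None:
            self.drug_time_min = self.baseline_duration_min
        self.z_drift_events = [(int(f), float(m)) for f, m in self.z_drift_events]

    @property
    def drug_time_s(self) -> float:
        return float(self.drug_time_min) * 60.0

    @classmethod
    def from_dict(cls, d: dict) -> "ImagingConfig":
        return _from_dict(cls, d)


@dataclass
class ChannelModel:
    """Macroscopic Boltzmann-gated conductance plus recording artifacts.

    The gated current is ``g_max * m(t)**p * (v - e_rev)`` with first-order
    activation toward ``1 / (1 + exp(-(v - v_half)/slope_k))``.  Leak is
    linear in the step from holding; capacitive transients are biexponential
    and linear in step amplitude (the linearity that P/N subtraction
    assumes).  ``rundown_rate`` is a geometric per-sweep conductance loss;
    the drug multiplies conductance by a factor saturating at ``drug_gain``.
    """

    g_max: float = 10.0  # nS
    v_half: float = -10.0  # mV
    slope_k: float = 6.0  # mV
    p_exponent: int = 2
    e_rev: float = 60.0  # mV
    tau_activation_ms: float = 2.0
    g_leak: float = 1.0  # nS
    c_membrane: float = 5.0  # pF
    cap_tau_ms: tuple[float, float] = (0.2, 1.0)
    cap_weights: tuple[float, float] = (0.7, 0.3)
    rundown_rate: float = 0.0  # fraction per sweep
    drug_gain: float = 1.0
    drug_onset_s: float | None = None
    drug_tau_s: float = 30.0
    noise_sd: float = 0.0  # pA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope_k <= 0:
            raise ValueError("slope_k must be > 0")
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        if not 0.0 <= self.rundown_rate < 1.0:
            raise ValueError("rundown_rate must be in [0, 1)")
        if self.drug_gain <= 0:
            raise ValueError("drug_gain must be > 0")
        if self.tau_activation_ms <= 0:
            raise ValueError("tau_activation_ms must be > 0")
        if self.p_exponent < 1:
            raise ValueError("p_exponent must be a positive integer")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.cap_tau_ms = tuple(float(t) for t in self.cap_tau_ms)
        self.cap_weights = tuple(float(w) for w in self.cap_weights)

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelModel":
        return _from_dict(cls, d)


@dataclass
class VoltageProtocol:
    """Step protocol: 50-ms depolarisations from a -80 mV holding level,
    one sweep every 20 s, with P/N leak sub-sweeps stepping -80 to -100 mV.
    """

    holding_mv: float = -80.0
    step_levels_mv: Sequence[float] = field(default_factory=lambda: [0.0])
    step_duration_ms: float = 50.0
    inter_sweep_interval_s: float = 20.0
    pn_n_reps: int = 15
    pn_step_mv: tuple[float, float] = (-80.0, -100.0)
    sampling_khz: float = 10.0
    pre_ms: float = 10.0
    post_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.pn_n_reps < 1:
            raise ValueError("pn_n_reps must be >= 1")
        if self.step_duration_ms <= 0:
            raise ValueError("step_duration_ms must be > 0")
        if self.sampling_khz <= 0:
            raise ValueError("sampling_khz must be > 0")
        if self.inter_sweep_interval_s <= 0:
            raise ValueError("inter_sweep_interval_s must be > 0")
        self.step_levels_mv = [float(v) for v in self.step_levels_mv]
        if not self.step_levels_mv:
            raise ValueError("step_levels_mv must not be empty")
        self.pn_step_mv = (float(self.pn_step_mv[0]), float(self.pn_step_mv[1]))
        if self.pn_step_mv[1] == self.pn_step_mv[0]:
            raise ValueError("P/N step amplitude must be nonzero")

    @property
    def pn_amplitude_mv(self) -> float:
        return self.pn_step_mv[1] - self.pn_step_mv[0]

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sampling_khz

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        d = dict(d)
        for key in ("step_levels_mv",):
            if key in d:
                d[key] = list(d[key])
        if "pn_step_mv" in d:
            d["pn_step_mv"] = tuple(d["pn_step_mv"])
        return _from_dict(cls, d)

    @classmethod
    def iv_default(cls, **kw) -> "VoltageProtocol":
        """The I-V protocol: -90 to +40 mV in 10-mV increments."""
        levels = [float(v) for v in range(-90, 50, 10)]
        return cls(step_levels_mv=levels, **kw)


@dataclass
class AnalysisParams:
    """Tunable parameters of the imaging analysis pipeline."""

    rolling_ball_radius_px: int = 50
    register: bool = True
    registration_upsample: int = 20
    k_sd: float = 3.0
    min_consecutive: int = 3
    baseline_alpha: float = 0.05
    responsiveness_factor: float = 2.0
    zdrift_threshold: float = 0.10
    zdrift_min_frames: int = 2

    def __post_init__(self) -> None:
        if self.rolling_ball_radius_px <= 0:
            raise ValueError("rolling_ball_radius_px must be > 0")
        if self.k_sd <= 0:
            raise ValueError("k_sd must be > 0")
        if self.min_consecutive < 1:
            raise ValueError("min_consecutive must be >= 1")
        if not 0 < self.baseline_alpha < 1:
            raise ValueError("baseline_alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        return _from_dict(cls, d)
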