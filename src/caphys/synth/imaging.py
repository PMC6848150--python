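"""Synthetic two-channel imaging sessions with planted responders.

The generator emulates the statistical structure the screening analysis
assumes:

* frames alternate unstimulated (F1) / stimulated (F2) at a fixed frame
  interval, so stimulation cycles run at half the frame rate;
* every cell shows a stable evoked fractional change (its baseline dF/F);
* a minority responder subpopulation, always counterstain-negative, ramps
  its evoked dF/F up by a planted percent amplitude with a logistic onset
  after drug application (10-90% rise over ~1 min by default);
* the counterstain channel is static except for configured z-drift events
  (simultaneous blur + intensity loss), which is what session QC monitors;
* photobleaching decays cell fluorescence geometrically per frame; Gaussian
  read noise is added per pixel.

All random draws come from one ``numpy.random.default_rng(seed)`` stream and
are consumed in a fixed, documented order (placement, per-cell draws in cell
index order, then whole-stack noise), so identical configs give bit-identical
sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from caphys.config import ImagingConfig
from caphys.imaging.rois import RoiSet, disk_mask

# logistic scale giving a 10-90% rise over 60 s: 60 / (2 * ln 9)
_ONSET_RAMP_SCALE_S = 60.0 / (2.0 * np.log(9.0))


@dataclass
class ImagingSession:
    """Two-channel frame stack with per-frame stimulation flags.

    ``stim_flags`` strictly alternates starting unstimulated; ``times_s`` are
    acquisition-start times and strictly increase; intensities are >= 0.
    """

    cal_stack: np.ndarray
    txred_stack: np.ndarray
    stim_flags: np.ndarray
    times_s: np.ndarray
    drug_time_s: float
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.cal_stack = np.asarray(self.cal_stack, dtype=np.float64)
        self.txred_stack = np.asarray(self.txred_stack, dtype=np.float64)
        self.stim_flags = np.asarray(self.stim_flags, dtype=bool)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        t = self.cal_stack.shape[0]
        if self.txred_stack.shape != self.cal_stack.shape:
            raise ValueError("cal and TxRed stacks must share shape")
        if self.stim_flags.shape != (t,) or self.times_s.shape != (t,):
            raise ValueError("per-frame metadata must have one entry per frame")
        expected = np.arange(t) % 2 == 1
        if not np.array_equal(self.stim_flags, expected):
            raise ValueError("stim_flags must strictly alternate, first frame unstimulated")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")
        if np.any(self.cal_stack < 0) or np.any(self.txred_stack < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return int(self.cal_stack.shape[0])


@dataclass
class GroundTruthImaging:
    """Generator-side record of every planted parameter (recovery oracle)."""

    cell_centers: np.ndarray  # (n, 2) row, col
    cell_radii: np.ndarray
    txred_positive: np.ndarray
    responder: np.ndarray
    planted_amplitude: np.ndarray  # percent; NaN for non-responders
    planted_onset_s: np.ndarray  # absolute seconds; NaN for non-responders
    planted_baseline_dff: np.ndarray
    planted_f1: np.ndarray  # clean mask-mean resting fluorescence at frame 0
    drug_time_s: float

    def __post_init__(self) -> None:
        if np.any(self.responder & self.txred_positive):
            raise AssertionError("planted responders must be TxRed-negative")
        onsets = self.planted_onset_s[self.responder]
        if np.any(onsets < self.drug_time_s):
            raise AssertionError("planted onsets must follow drug application")

    @property
    def n_cells(self) -> int:
        return int(self.cell_centers.shape[0])

    def roi_set(self, shape: tuple[int, int]) -> RoiSet:
        return RoiSet.from_disks(
            shape, self.cell_centers, self.cell_radii, self.txred_positive
        )


def _place_cells(rng: np.random.Generator, cfg: ImagingConfig) -> np.ndarray:
    """Jittered-grid cell centres with a guaranteed minimum separation.

    A square grid with pitch ``1.3 * min_sep`` and per-site jitter of
    ``0.15 * min_sep`` keeps every pair at least ``min_sep`` apart while
    avoiding a perfectly regular layout; placement is feasible whenever the
    grid holds enough sites, independent of the seed.
    """
    h, w = cfg.image_height_px, cfg.image_width_px
    margin = 2.0 * cfg.cell_radius_px
    min_sep = 3.5 * cfg.cell_radius_px
    pitch = 1.3 * min_sep
    jitter = 0.15 * min_sep
    rows = np.arange(margin, h - margin + 1e-9, pitch)
    cols = np.arange(margin, w - margin + 1e-9, pitch)
    sites = np.array([(r, c) for r in rows for c in cols])
    if sites.shape[0] < cfg.n_cells:
        raise ValueError(
            f"cannot place {cfg.n_cells} non-overlapping cells on a {h}x{w} "
            f"field (only {sites.shape[0]} sites at separation {min_sep:.1f} px); "
            "reduce n_cells or cell_radius_px"
        )
    chosen = sites[rng.choice(sites.shape[0], size=cfg.n_cells, replace=False)]
    return chosen + rng.uniform(-jitter, jitter, size=chosen.shape)


def _gaussian_patch(shape, center, sigma, cutoff_sigmas: float = 2.75) -> np.ndarray:
    # Continuously truncated Gaussian: zero beyond cutoff_sigmas, so cells
    # separated by the placement minimum cannot leak into each other's masks.
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    d2 = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2.0 * sigma**2)
    floor = np.exp(-(cutoff_sigmas**2) / 2.0)
    return np.clip(np.exp(-d2) - floor, 0.0, None) / (1.0 - floor)


def _smooth_background(shape, level: float) -> np.ndarray:
    """Deterministic smooth background: gentle diagonal gradient."""
    h, w = shape
    rr = np.arange(h)[:, None] / max(h - 1, 1)
    cc = np.arange(w)[None, :] / max(w - 1, 1)
    return level * (0.8 + 0.2 * rr + 0.2 * cc)


def onset_ramp(t_s: np.ndarray, onset_s: float, ramp_scale_s: float = _ONSET_RAMP_SCALE_S) -> np.ndarray:
    """Logistic 0->1 ramp centred at ``onset_s`` (10-90% rise over ~1 min)."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(t_s, dtype=float) - onset_s) / ramp_scale_s))


def generate_imaging_session(
    config: ImagingConfig, condition_label: str = ""
) -> tuple[ImagingSession, GroundTruthImaging]:
    """Render a synthetic session and its ground truth.

    Unstimulated frames carry resting fluorescence (cells + smooth
    background) under geometric photobleach; each stimulated frame scales
    every cell's fluorescence by ``1 + dff_cell(t)``.  Responder cells ramp
    ``dff`` from the planted baseline value to ``baseline * (1 + A/100)``
    with a logistic onset after the drug time.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_height_px, cfg.image_width_px
    n = cfg.n_cells

    cycle_s = 2.0 * cfg.frame_interval_s
    n_cycles = int(round((cfg.baseline_duration_min + cfg.post_duration_min) * 60.0 / cycle_s))
    if n_cycles < 2:
        raise ValueError("session too short: fewer than 2 stimulation cycles")
    n_frames = 2 * n_cycles
    times_s = np.arange(n_frames) * cfg.frame_interval_s
    stim_flags = np.arange(n_frames) % 2 == 1
    drug_time_s = cfg.drug_time_s

    # --- seeded draws, fixed order -------------------------------------
    centers = _place_cells(rng, cfg)
    peaks = np.clip(rng.normal(100.0, 10.0, size=n), 40.0, None)
    base_dff = np.clip(
        rng.normal(cfg.baseline_dff_mean, cfg.baseline_dff_sd, size=n), 0.05, None
    )

    n_pos = int(round(cfg.txred_positive_fraction * n))
    txred_positive = np.zeros(n, dtype=bool)
    if n_pos:
        txred_positive[rng.choice(n, size=n_pos, replace=False)] = True

    n_resp = int(round(cfg.responder_fraction * n))
    negatives = np.flatnonzero(~txred_positive)
    if n_resp > negatives.size:
        raise ValueError(
            "responder_fraction exceeds the TxRed-negative fraction: "
            "responders must be TxRed-negative"
        )
    responder = np.zeros(n, dtype=bool)
    if n_resp:
        responder[rng.choice(negatives, size=n_resp, replace=False)] = True

    amplitude = np.full(n, np.nan)
    onset_s = np.full(n, np.nan)
    ridx = np.flatnonzero(responder)
    if ridx.size:
        amplitude[ridx] = np.clip(
            rng.normal(cfg.responder_amplitude_mean, cfg.responder_amplitude_sd, ridx.size),
            5.0,
            None,
        )
        post_end = times_s[-1] - drug_time_s
        onset_s[ridx] = drug_time_s + np.clip(
            rng.normal(
                cfg.responder_onset_mean_min * 60.0,
                cfg.responder_onset_sd_min * 60.0,
                ridx.size,
            ),
            30.0,
            max(post_end - 120.0, 30.0),
        )

    # counterstain texture field (static), drawn before frame noise
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 1.0)

    cal_noise = (
        rng.normal(0.0, cfg.noise_sd, size=(n_frames, h, w)) if cfg.noise_sd > 0 else None
    )
    tx_noise = (
        rng.normal(0.0, 0.5 * cfg.noise_sd, size=(n_frames, h, w))
        if cfg.noise_sd > 0
        else None
    )

    # --- render --------------------------------------------------------
    sigma = cfg.cell_radius_px / 2.0
    units = np.stack([_gaussian_patch((h, w), c, sigma) for c in centers])
    cell_rest = np.tensordot(peaks, units, axes=1)  # sum_c peak_c * unit_c
    cell_evoked = np.tensordot(peaks * base_dff, units, axes=1)
    bg = _smooth_background((h, w), cfg.background_level)

    radii = np.full(n, cfg.cell_radius_px)
    planted_f1 = np.array(
        [
            (bg + peaks[i] * units[i])[disk_mask((h, w), tuple(centers[i]), radii[i])].mean()
            for i in range(n)
        ]
    )

    cal = np.empty((n_frames, h, w))
    bleach = (1.0 - cfg.photobleach_rate) ** np.arange(n_frames)
    for f in range(n_frames):
        cells = cell_rest * bleach[f]
        if stim_flags[f]:
            evoked = cell_evoked.copy()
            for i in ridx:
                ramp = onset_ramp(times_s[f], onset_s[i])
                evoked += (peaks[i] * base_dff[i] * amplitude[i] / 100.0 * ramp) * units[i]
            cells = cells + evoked * bleach[f]
        cal[f] = bg + cells
    if cal_noise is not None:
        cal += cal_noise
        np.clip(cal, 0.0, None, out=cal)

    # counterstain channel: positive cells + texture, static except z-drift
    tx_clean = (
        _smooth_background((h, w), 0.5 * cfg.background_level)
        + np.tensordot(peaks * txred_positive, units, axes=1)
        + 3.0 * np.abs(texture)
    )
    txred = np.repeat(tx_clean[None], n_frames, axis=0).copy()
    for frame_idx, magnitude in sorted(cfg.z_drift_events):
        if frame_idx >= n_frames:
            continue
        drifted = ndimage.gaussian_filter(txred[frame_idx], 2.0 * magnitude)
        drifted *= 1.0 - 0.3 * magnitude
        txred[frame_idx:] = drifted[None]
    if tx_noise is not None:
        txred += tx_noise
        np.clip(txred, 0.0, None, out=txred)

    session = ImagingSession(
        cal_stack=cal,
        txred_stack=txred,
        stim_flags=stim_flags,
        times_s=times_s,
        drug_time_s=drug_time_s,
        condition_label=condition_label,
    )
    truth = GroundTruthImaging(
        cell_centers=centers,
        cell_radii=radii,
        txred_positive=txred_positive,
        responder=responder,
        planted_amplitude=amplitude,
        planted_onset_s=onset_s,
        planted_baseline_dff=base_dff,
        planted_f1=planted_f1,
        drug_time_s=drug_time_s,
    )
    return session, truth
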