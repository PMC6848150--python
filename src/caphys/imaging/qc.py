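"""Session and cell quality control.

Two checks gate the slice summary:

* z-drift: the counterstain channel is static in a well-held session, so a
  sustained change in its high-frequency energy (a sharpness proxy) marks a
  focal-plane drift and excludes the whole session;
* electrical responsiveness: a cell whose baseline-window evoked dF/F does
  not rise above the pooled per-cycle noise floor is excluded from the total
  cell count.

Counterstain-positive cells are flagged ineligible as responders but stay in
the denominator of the slice summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from caphys.imaging.rois import RoiSet
from caphys.imaging.traces import DffSeries, RoiTrace


@dataclass
class QCReport:
    evaluable: bool
    session_pass: bool
    zdrift_detected: bool
    zdrift_frame: int | None
    zdrift_metric: np.ndarray | None
    electrically_responsive: np.ndarray | None
    noise_floor_dff: float | None
    notes: list[str] = field(default_factory=list)


def _hf_energy(frame: np.ndarray, blur_sigma: float = 2.0) -> float:
    return float(np.var(frame - ndimage.gaussian_filter(frame, blur_sigma)))


def zdrift_metric(txred_stack: np.ndarray, n_reference_frames: int = 3) -> np.ndarray:
    """Relative change of per-frame high-frequency energy vs. early frames."""
    hf = np.array([_hf_energy(f) for f in txred_stack])
    ref = np.median(hf[:n_reference_frames])
    if ref <= 0:
        return np.zeros_like(hf)
    return hf / ref - 1.0


def _pooled_noise_dff(traces: list[RoiTrace], baseline_end_s: float) -> float:
    """Per-cycle dF/F noise floor from unstimulated-frame (F1) fluctuations.

    The SD of successive F1 differences over the baseline window, divided by
    sqrt(2) and the mean F1, estimates the per-frame relative noise; the
    dF/F noise carries two frames (F1 and F2), hence the sqrt(2) factor back.
    """
    per_cell = []
    for tr in traces:
        m = tr.cycle_times_s < baseline_end_s
        f1 = tr.f1_series[m]
        f1 = f1[f1 > 0]
        if f1.size < 3:
            continue
        frame_sd = np.std(np.diff(f1), ddof=1) / np.sqrt(2.0)
        per_cell.append(np.sqrt(2.0) * frame_sd / f1.mean())
    return float(np.median(per_cell)) if per_cell else 0.0


def qc_session(
    txred_stack: np.ndarray | None,
    rois: RoiSet,
    traces: list[RoiTrace],
    dff_list: list[DffSeries],
    zdrift_threshold: float = 0.10,
    zdrift_min_frames: int = 2,
    responsiveness_factor: float = 2.0,
) -> QCReport:
    """Evaluate session-level z-drift and per-cell electrical responsiveness."""
    notes: list[str] = []
    if txred_stack is None:
        return QCReport(
            evaluable=False,
            session_pass=False,
            zdrift_detected=False,
            zdrift_frame=None,
            zdrift_metric=None,
            electrically_responsive=None,
            noise_floor_dff=None,
            notes=["counterstain stack missing: session unevaluable"],
        )

    metric = zdrift_metric(np.asarray(txred_stack, dtype=float))
    over = np.abs(metric) > zdrift_threshold
    drift_frame = None
    run = 0
    for i, o in enumerate(over):
        run = run + 1 if o else 0
        if run >= zdrift_min_frames:
            drift_frame = i - zdrift_min_frames + 1
            break
    zdrift_detected = drift_frame is not None
    if zdrift_detected:
        notes.append(f"z-drift detected at frame {drift_frame}: session excluded")

    drug_time = dff_list[0].drug_time_s if dff_list else np.inf
    noise_floor = _pooled_noise_dff(traces, drug_time)
    responsive = np.zeros(rois.n_cells, dtype=bool)
    for i, dff in enumerate(dff_list):
        base = dff.baseline_mask()
        if base.any():
            responsive[i] = float(np.mean(dff.values[base])) > responsiveness_factor * noise_floor

    return QCReport(
        evaluable=True,
        session_pass=not zdrift_detected,
        zdrift_detected=zdrift_detected,
        zdrift_frame=drift_frame,
        zdrift_metric=metric,
        electrically_responsive=responsive,
        noise_floor_dff=noise_floor,
        notes=notes,
    )
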