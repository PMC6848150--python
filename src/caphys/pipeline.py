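"""End-to-end orchestration: raw stacks/sweeps -> calls -> summaries -> report.

``analyze_imaging_session`` runs the full imaging chain (background
subtraction, XY stabilisation, trace extraction, dF/F, baselining, k-SD
responder calls, QC, slice summary).  ``analyze_sweepset`` handles both the
repeated-pulse drug time course and the I-V ladder.  ``run_all`` simulates a
small two-condition study plus ephys cells from one master seed, analyses
everything and writes a deterministic report bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from caphys import io
from caphys.config import AnalysisParams, ChannelModel, ImagingConfig, VoltageProtocol
from caphys.ephys.iv import IVCurve, build_iv_curve
from caphys.ephys.timecourse import DrugResponse, drug_response_timecourse
from caphys.imaging.background import subtract_background_rolling_ball
from caphys.imaging.baseline import BaselineModel, fit_baseline
from caphys.imaging.qc import QCReport, qc_session
from caphys.imaging.register import register_translation
from caphys.imaging.responders import ResponderCall, detect_responder
from caphys.imaging.rois import RoiSet
from caphys.imaging.summary import SliceSummary, summarize_slice
from caphys.imaging.traces import (
    DffSeries,
    RoiTrace,
    extract_roi_traces,
    instantaneous_dff,
)
from caphys.report import ReportBundle, build_report
from caphys.stats import welch_t_test
from caphys.synth.ephys import SweepSet, generate_ephys_experiment
from caphys.synth.imaging import ImagingSession, generate_imaging_session


@dataclass
class ImagingResult:
    traces: list[RoiTrace]
    dff: list[DffSeries]
    baselines: list[BaselineModel]
    calls: list[ResponderCall]
    qc: QCReport
    summary: SliceSummary

    def trace_table(self) -> pd.DataFrame:
        rows = []
        for cell_id, (tr, d) in enumerate(zip(self.traces, self.dff)):
            for i in range(tr.f1_series.size):
                rows.append(
                    (
                        cell_id,
                        tr.cycle_times_s[i],
                        tr.f1_series[i],
                        tr.f2_series[i],
                        d.values[i],
                    )
                )
        return pd.DataFrame(rows, columns=["cell_id", "cycle_time_s", "F1", "F2", "dff"])

    def call_table(self) -> pd.DataFrame:
        resp = (
            self.qc.electrically_responsive
            if self.qc.electrically_responsive is not None
            else [True] * len(self.calls)
        )
        return pd.DataFrame(
            {
                "cell_id": np.arange(len(self.calls)),
                "is_responder": [c.is_responder for c in self.calls],
                "percent_change": [c.percent_change for c in self.calls],
                "onset_s": [c.onset_s for c in self.calls],
                "threshold_used": [c.threshold_used for c in self.calls],
                "electrically_responsive": list(resp),
            }
        )


def analyze_imaging_session(
    session: ImagingSession,
    rois: RoiSet,
    params: AnalysisParams | None = None,
) -> ImagingResult:
    params = params or AnalysisParams()
    stack = session.cal_stack

    stack = np.stack(
        [
            subtract_background_rolling_ball(frame, params.rolling_ball_radius_px)
            for frame in stack
        ]
    )
    if params.register:
        stack = register_translation(
            stack, upsample_factor=params.registration_upsample
        ).corrected

    traces = extract_roi_traces(stack, session.stim_flags, session.times_s, rois)
    dff = [instantaneous_dff(tr, session.drug_time_s) for tr in traces]
    baselines = [fit_baseline(d, alpha=params.baseline_alpha) for d in dff]
    calls = [
        detect_responder(d, b, k_sd=params.k_sd, min_consecutive=params.min_consecutive)
        for d, b in zip(dff, baselines)
    ]
    qc = qc_session(
        session.txred_stack,
        rois,
        traces,
        dff,
        zdrift_threshold=params.zdrift_threshold,
        zdrift_min_frames=params.zdrift_min_frames,
        responsiveness_factor=params.responsiveness_factor,
    )
    summary = summarize_slice(calls, rois, qc, condition_label=session.condition_label)
    return ImagingResult(
        traces=traces, dff=dff, baselines=baselines, calls=calls, qc=qc, summary=summary
    )


def analyze_sweepset(
    sweepset: SweepSet, n_baseline_sweeps: int | None = None
) -> tuple[IVCurve | None, DrugResponse | None]:
    """I-V curve for ladder protocols, drug time course for repeated pulses."""
    levels = set(s.level_mv for s in sweepset.sweeps)
    if len(levels) > 1:
        return build_iv_curve(sweepset), None
    return None, drug_response_timecourse(sweepset, n_baseline_sweeps=n_baseline_sweeps)


# --- run-all orchestration -------------------------------------------


def _child_seed(master_seed: int, *path: int) -> int:
    return int(np.random.SeedSequence([master_seed, *path]).generate_state(1)[0])


DEFAULT_STUDY = {
    "imaging": {
        "conditions": [
            {"label": "synblock", "responder_fraction": 0.15},
            {"label": "no_synblock", "responder_fraction": 0.15},
        ],
        "session": {
            "image_height_px": 96,
            "image_width_px": 96,
            "n_cells": 20,
            "baseline_duration_min": 6.0,
            "post_duration_min": 12.0,
        },
        "analysis": {"rolling_ball_radius_px": 12},
    },
    "ephys": {
        "cells": [
            {"label": "responder_cell", "drug_gain": 1.33, "noise_sd": 2.0},
            {"label": "rundown_cell", "rundown_rate": 0.012, "noise_sd": 2.0},
        ],
        "n_baseline_sweeps": 6,
        "n_post_sweeps": 24,
    },
}


def run_all(config: dict | None, seed: int, out_dir: str | Path) -> Path:
    """Simulate -> analyse -> report with one master seed; returns report dir."""
    cfg = config or DEFAULT_STUDY
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    img_cfg = cfg.get("imaging", {})
    base_session = dict(img_cfg.get("session", {}))
    params = AnalysisParams.from_dict(dict(img_cfg.get("analysis", {})))

    summaries, results = [], {}
    for i, cond in enumerate(img_cfg.get("conditions", [])):
        cond = dict(cond)
        label = cond.pop("label", f"condition_{i}")
        session_cfg = ImagingConfig.from_dict(
            {**base_session, **cond, "seed": _child_seed(seed, 0, i)}
        )
        session, truth = generate_imaging_session(session_cfg, condition_label=label)
        rois = truth.roi_set(session.cal_stack.shape[1:])
        sim_dir = out / "sim" / label
        io.write_imaging_session(session, sim_dir)
        io.write_rois(rois, sim_dir)
        result = analyze_imaging_session(session, rois, params)
        results[label] = result
        summaries.append(result.summary)
        ana_dir = out / "analysis" / label
        ana_dir.mkdir(parents=True, exist_ok=True)
        result.trace_table().to_csv(ana_dir / "traces.csv", index=False)
        result.call_table().to_csv(ana_dir / "calls.csv", index=False)

    comparisons = []
    labels = list(results)
    if len(labels) >= 2:
        a, b = labels[0], labels[1]
        amp_a = [c.percent_change for c in results[a].calls if c.is_responder]
        amp_b = [c.percent_change for c in results[b].calls if c.is_responder]
        if len(amp_a) >= 2 and len(amp_b) >= 2:
            comparisons.append(
                welch_t_test(
                    amp_a, amp_b, a, b, measure="responder_percent_change", units="%"
                )
            )
        on_a = [c.onset_s / 60.0 for c in results[a].calls if c.is_responder]
        on_b = [c.onset_s / 60.0 for c in results[b].calls if c.is_responder]
        if len(on_a) >= 2 and len(on_b) >= 2:
            comparisons.append(
                welch_t_test(on_a, on_b, a, b, measure="responder_onset", units="min")
            )

    eph_cfg = cfg.get("ephys", {})
    drug_rows = []
    for j, cell in enumerate(eph_cfg.get("cells", [])):
        cell = dict(cell)
        label = cell.pop("label", f"cell_{j}")
        model = ChannelModel.from_dict({**cell, "seed": _child_seed(seed, 1, j)})
        protocol = VoltageProtocol()
        sweepset, _ = generate_ephys_experiment(
            model,
            protocol,
            eph_cfg.get("n_baseline_sweeps", 6),
            eph_cfg.get("n_post_sweeps", 24),
        )
        io.write_sweepset(sweepset, out / "sim" / f"ephys_{label}")
        _, resp = analyze_sweepset(sweepset)
        drug_rows.append(
            {
                "cell": label,
                "baseline_peak_pa": resp.baseline_peak,
                "percent_change": resp.percent_change,
                "onset_min": resp.onset_min,
                "peak_response_min": resp.peak_response_min,
                "classification": resp.classification,
            }
        )

    bundle: ReportBundle = build_report(summaries, comparisons)
    report_dir = out / "report"
    bundle.write(report_dir)
    if drug_rows:
        pd.DataFrame(drug_rows).to_csv(report_dir / "drug_responses.csv", index=False)

    log = {
        "seed": seed,
        "config_hash": io.config_hash(cfg),
        "analysis_params": dataclasses.asdict(params),
    }
    (report_dir / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return report_dir
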