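import numpy as np
import pytest

from caphys.config import AnalysisParams, ImagingConfig
from caphys.imaging.qc import QCReport, qc_session
from caphys.imaging.responders import ResponderCall
from caphys.imaging.rois import RoiSet
from caphys.imaging.summary import summarize_slice
from caphys.imaging.traces import extract_roi_traces, instantaneous_dff
from caphys.pipeline import analyze_imaging_session
from caphys.synth import generate_imaging_session


def _session_inputs(session, truth):
    rois = truth.roi_set(session.cal_stack.shape[1:])
    traces = extract_roi_traces(session.cal_stack, session.stim_flags, session.times_s, rois)
    dff = [instantaneous_dff(tr, session.drug_time_s) for tr in traces]
    return rois, traces, dff


def test_static_txred_passes(small_session):
    session, truth = small_session
    rois, traces, dff = _session_inputs(session, truth)
    qc = qc_session(session.txred_stack, rois, traces, dff)
    assert qc.evaluable and qc.session_pass and not qc.zdrift_detected


def test_planted_zdrift_recovered_within_two_frames():
    cfg = ImagingConfig(
        n_cells=10, image_height_px=80, image_width_px=80,
        z_drift_events=[(40, 0.8)], seed=4,
    )
    session, truth = generate_imaging_session(cfg)
    rois, traces, dff = _session_inputs(session, truth)
    qc = qc_session(session.txred_stack, rois, traces, dff)
    assert qc.zdrift_detected and not qc.session_pass
    assert abs(qc.zdrift_frame - 40) <= 2


def test_missing_txred_unevaluable(small_session):
    session, truth = small_session
    rois, traces, dff = _session_inputs(session, truth)
    qc = qc_session(None, rois, traces, dff)
    assert not qc.evaluable
    with pytest.raises(ValueError, match="unevaluable"):
        summarize_slice([ResponderCall(False, 0.0, np.nan, 0.0)] * rois.n_cells,
                        rois, qc)


def _qc_all_good(n):
    return QCReport(
        evaluable=True, session_pass=True, zdrift_detected=False, zdrift_frame=None,
        zdrift_metric=None, electrically_responsive=np.ones(n, dtype=bool),
        noise_floor_dff=0.01,
    )


def _rois(n, txpos=None, in_focus=None):
    masks = np.zeros((n, 10, 10), dtype=bool)
    for i in range(n):
        masks[i, i % 10, (3 * i) % 10] = True
    return RoiSet(
        masks=masks,
        txred_positive=txpos if txpos is not None else np.zeros(n, bool),
        in_focus=in_focus,
    )


def _calls(flags):
    return [ResponderCall(bool(f), 10.0 if f else 0.0, 60.0 if f else np.nan, 0.01)
            for f in flags]


def test_paper_count_examples():
    # 53 responders among 730 in-focus cells -> 7.3%
    n = 730
    rois = _rois(n)
    flags = np.zeros(n, bool)
    flags[:53] = True
    s = summarize_slice(_calls(flags), rois, _qc_all_good(n), "synblock")
    assert s.n_vdrn == 53 and s.n_total_cells == 730
    assert s.responding_percent == pytest.approx(7.3)


def test_26_of_428_rounds_to_6_1():
    n = 428
    rois = _rois(n)
    flags = np.zeros(n, bool)
    flags[:26] = True
    s = summarize_slice(_calls(flags), rois, _qc_all_good(n))
    assert s.responding_percent == pytest.approx(6.1)


def test_zero_responders_zero_percent():
    n = 100
    s = summarize_slice(_calls(np.zeros(n, bool)), _rois(n), _qc_all_good(n))
    assert s.responding_percent == 0.0


def test_txred_positive_never_counted_as_responder():
    # a responder-like call on a TxRed-positive cell is ineligible but stays
    # in the denominator
    n = 10
    txpos = np.zeros(n, bool)
    txpos[0] = True
    rois = _rois(n, txpos=txpos)
    flags = np.zeros(n, bool)
    flags[0] = True  # the TxRed-positive cell "responds"
    s = summarize_slice(_calls(flags), rois, _qc_all_good(n))
    assert s.n_vdrn == 0
    assert s.n_total_cells == 10


def test_denominator_rule_never_exceeds_txneg_percent():
    n = 20
    txpos = np.zeros(n, bool)
    txpos[:5] = True
    rois = _rois(n, txpos=txpos)
    flags = np.zeros(n, bool)
    flags[6:9] = True
    s = summarize_slice(_calls(flags), rois, _qc_all_good(n))
    assert s.responding_percent <= s.responding_percent_txneg


def test_unresponsive_cells_excluded_from_totals():
    n = 10
    qc = _qc_all_good(n)
    qc.electrically_responsive[:4] = False
    s = summarize_slice(_calls(np.zeros(n, bool)), _rois(n), qc)
    assert s.n_total_cells == 6
    assert s.excluded_cells["electrically_unresponsive"] == 4


def test_zero_eligible_cells_flagged():
    n = 5
    qc = _qc_all_good(n)
    qc.electrically_responsive[:] = False
    s = summarize_slice(_calls(np.zeros(n, bool)), _rois(n), qc)
    assert not s.percent_defined
    assert np.isnan(s.responding_percent)


def test_electrical_responsiveness_flags_silent_cell(fast_params):
    # rebuild a session but silence one cell's evoked response by giving it
    # near-zero baseline dff via a doctored dff series
    cfg = ImagingConfig(n_cells=12, image_height_px=80, image_width_px=80,
                        responder_fraction=0.0, seed=9)
    session, truth = generate_imaging_session(cfg)
    rois, traces, dff = _session_inputs(session, truth)
    silent = dff[0]
    silent.values[:] = np.random.default_rng(0).normal(0, 0.001, silent.values.size)
    qc = qc_session(session.txred_stack, rois, traces, dff)
    assert not qc.electrically_responsive[0]
    assert qc.electrically_responsive[1:].all()
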