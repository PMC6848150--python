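import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caphys.imaging.rois import RoiSet, disk_mask
from caphys.imaging.traces import RoiTrace, extract_roi_traces, instantaneous_dff


def _single_roi(shape=(8, 8)):
    mask = np.zeros(shape, dtype=bool)
    mask[2:4, 2:4] = True
    return RoiSet(masks=mask[None], txred_positive=np.array([False]))


def test_uniform_frame_mean():
    rois = _single_roi()
    stack = np.full((4, 8, 8), 7.0)
    flags = np.array([False, True, False, True])
    times = np.arange(4.0) * 10
    traces = extract_roi_traces(stack, flags, times, rois)
    np.testing.assert_allclose(traces[0].f1_series, 7.0)
    np.testing.assert_allclose(traces[0].f2_series, 7.0)
    np.testing.assert_array_equal(traces[0].cycle_times_s, [10.0, 30.0])


def test_two_pixel_mask_mean():
    mask = np.zeros((4, 4), dtype=bool)
    mask[0, 0] = mask[0, 1] = True
    rois = RoiSet(masks=mask[None], txred_positive=np.array([False]))
    frame = np.zeros((4, 4))
    frame[0, 0], frame[0, 1] = 3.0, 5.0
    stack = np.stack([frame, frame])
    traces = extract_roi_traces(stack, np.array([False, True]), np.array([0.0, 10.0]), rois)
    assert traces[0].f1_series[0] == pytest.approx(4.0)


def test_non_alternating_flags_rejected():
    rois = _single_roi()
    stack = np.zeros((4, 8, 8))
    with pytest.raises(ValueError, match="alternate"):
        extract_roi_traces(stack, np.array([True, False, True, False]),
                           np.arange(4.0), rois)


def test_empty_mask_rejected():
    with pytest.raises(ValueError, match="empty"):
        RoiSet(masks=np.zeros((1, 8, 8), dtype=bool), txred_positive=np.array([False]))


def test_noise_free_f1_matches_planted(clean_session):
    session, truth = clean_session
    rois = truth.roi_set(session.cal_stack.shape[1:])
    traces = extract_roi_traces(
        session.cal_stack, session.stim_flags, session.times_s, rois
    )
    for i, tr in enumerate(traces):
        assert tr.f1_series[0] == pytest.approx(truth.planted_f1[i], abs=1e-6)
        # no bleach: F1 constant over the whole session
        np.testing.assert_allclose(tr.f1_series, tr.f1_series[0], atol=1e-9)


def test_dff_formula_trivial_cases():
    tr = RoiTrace(
        f1_series=np.array([100.0, 100.0]),
        f2_series=np.array([100.0, 150.0]),
        cycle_times_s=np.array([10.0, 30.0]),
    )
    d = instantaneous_dff(tr, drug_time_s=40.0)
    assert d.values[0] == 0.0
    assert d.values[1] == pytest.approx(0.5)


def test_dff_matches_loop_oracle(rng):
    n = 50
    f1 = rng.uniform(10, 200, n)
    f2 = rng.uniform(10, 200, n)
    t = np.arange(n) * 20.0
    d = instantaneous_dff(RoiTrace(f1, f2, t), drug_time_s=t[-1] + 20)
    oracle = np.array([(f2[i] - f1[i]) / f1[i] for i in range(n)])  # element loop
    np.testing.assert_array_equal(d.values, oracle)


def test_nonpositive_f1_flagged_invalid():
    tr = RoiTrace(
        f1_series=np.array([100.0, 0.0, -5.0, 50.0]),
        f2_series=np.array([110.0, 10.0, 10.0, 60.0]),
        cycle_times_s=np.arange(4.0) * 20,
    )
    d = instantaneous_dff(tr, drug_time_s=100.0)
    assert np.isnan(d.values[1]) and np.isnan(d.values[2])
    np.testing.assert_array_equal(d.valid, [True, False, False, True])


@given(
    f1=st.lists(st.floats(1.0, 1e4), min_size=3, max_size=20),
    ratio=st.lists(st.floats(0.5, 3.0), min_size=3, max_size=20),
    scale=st.floats(0.01, 100.0),
)
@settings(max_examples=50, deadline=None)
def test_dff_ratio_invariance(f1, ratio, scale):
    n = min(len(f1), len(ratio))
    f1 = np.asarray(f1[:n])
    f2 = f1 * np.asarray(ratio[:n])
    t = np.arange(n) * 20.0
    d1 = instantaneous_dff(RoiTrace(f1, f2, t), drug_time_s=1e6)
    d2 = instantaneous_dff(RoiTrace(scale * f1, scale * f2, t), drug_time_s=1e6)
    # global gain c > 0 leaves dF/F unchanged
    np.testing.assert_allclose(d1.values, d2.values, rtol=1e-9, atol=1e-12)


def test_dff_identity_when_f2_equals_f1(rng):
    f1 = rng.uniform(1, 1e4, 20)
    t = np.arange(20.0) * 20
    d = instantaneous_dff(RoiTrace(f1, f1.copy(), t), drug_time_s=1e6)
    np.testing.assert_array_equal(d.values, 0.0)


def test_trailing_unpaired_frame_dropped():
    rois = _single_roi()
    stack = np.full((5, 8, 8), 3.0)
    flags = np.array([False, True, False, True, False])
    times = np.arange(5.0) * 10
    traces = extract_roi_traces(stack, flags, times, rois)
    assert traces[0].f1_series.size == 2
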