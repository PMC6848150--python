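import numpy as np
import pytest

from caphys.config import ChannelModel, VoltageProtocol
from caphys.ephys.iv import build_iv_curve, sweep_peak
from caphys.ephys.leak import correct_sweepset, pn_leak_subtract, pn_scale_factor
from caphys.synth import channel_current, generate_ephys_experiment
from caphys.synth.ephys import Sweep, _artifact_current, _edges


def test_scale_factor_minus_four():
    # -80 -> 0 mV test pulse against -80 -> -100 mV sub-steps
    protocol = VoltageProtocol()
    assert pn_scale_factor(protocol, 0.0) == pytest.approx(-4.0)


def test_pure_linear_leak_cancels_exactly(protocol):
    model = ChannelModel(g_max=0.0, g_leak=2.5, c_membrane=4.0, noise_sd=0.0)
    sweepset, _ = generate_ephys_experiment(model, protocol, 2, 0)
    corrected = pn_leak_subtract(sweepset.sweeps[0], sweepset.pn_sweeps, protocol)
    np.testing.assert_allclose(corrected.current, 0.0, atol=1e-9)


def test_corrected_sweep_equals_planted_channel_current(protocol):
    model = ChannelModel(g_leak=1.5, c_membrane=5.0, noise_sd=0.0)
    sweepset, truth = generate_ephys_experiment(model, protocol, 3, 0)
    for sweep, chan in zip(sweepset.sweeps, truth.channel_only):
        corrected = pn_leak_subtract(sweep, sweepset.pn_sweeps, protocol)
        np.testing.assert_allclose(corrected.current, chan, atol=1e-9)


@pytest.mark.parametrize("level", [-60.0, -30.0, 0.0, 20.0, 40.0])
def test_linearity_across_step_amplitudes(level):
    # P/N cancellation is exact for any step amplitude when leak and
    # capacitive terms are linear in the step
    protocol = VoltageProtocol(step_levels_mv=[level])
    model = ChannelModel(g_max=0.0, g_leak=3.0, c_membrane=6.0, noise_sd=0.0)
    sweepset, _ = generate_ephys_experiment(model, protocol, 1, 0)
    corrected = pn_leak_subtract(sweepset.sweeps[0], sweepset.pn_sweeps, protocol)
    np.testing.assert_allclose(corrected.current, 0.0, atol=1e-9)


def test_zero_pn_amplitude_rejected():
    with pytest.raises(ValueError):
        VoltageProtocol(pn_step_mv=(-80.0, -80.0))


def test_no_pn_sweeps_rejected(protocol, clean_model):
    sweepset, _ = generate_ephys_experiment(clean_model, protocol, 1, 0)
    with pytest.raises(ValueError, match="P/N"):
        pn_leak_subtract(sweepset.sweeps[0], [], protocol)


def test_iv_has_14_levels():
    protocol = VoltageProtocol.iv_default()
    assert len(protocol.step_levels_mv) == 14
    assert protocol.step_levels_mv[0] == -90.0
    assert protocol.step_levels_mv[-1] == 40.0
    model = ChannelModel(noise_sd=0.0)
    sweepset, _ = generate_ephys_experiment(model, protocol, 14, 0)
    iv = build_iv_curve(sweepset)
    assert iv.step_mv.size == 14
    assert not iv.missing_levels


def test_ohmic_model_linear_iv():
    # fully activated ohmic conductance: v_half far below the step range
    protocol = VoltageProtocol.iv_default()
    model = ChannelModel(
        v_half=-200.0, slope_k=1.0, tau_activation_ms=0.01, p_exponent=1,
        g_max=5.0, e_rev=60.0, g_leak=0.0, c_membrane=0.0, noise_sd=0.0,
    )
    sweepset, _ = generate_ephys_experiment(model, protocol, 14, 0)
    iv = build_iv_curve(sweepset, apply_pn=False)
    fit = np.polyfit(iv.step_mv, iv.peak_current, 1)
    assert fit[0] == pytest.approx(5.0, rel=1e-3)  # slope = g_max
    assert -fit[1] / fit[0] == pytest.approx(60.0, abs=0.1)  # zero crossing at e_rev


def test_iv_matches_dense_grid_oracle():
    protocol = VoltageProtocol.iv_default()
    model = ChannelModel(
        v_half=-10.0, slope_k=6.0, e_rev=60.0, p_exponent=2,
        g_leak=2.0, c_membrane=5.0, noise_sd=0.0,
    )
    sweepset, _ = generate_ephys_experiment(model, protocol, 14, 0)
    iv = build_iv_curve(sweepset)
    # oracle: fine-grid (1 us) simulation of the gated current per step
    t_fine = np.arange(2.0, 50.0, 1e-3)
    for v, peak in zip(iv.step_mv, iv.peak_current):
        trace = channel_current(model, v, t_fine)
        oracle = trace[np.argmax(np.abs(trace))]
        if abs(oracle) > 1.0:
            assert peak == pytest.approx(oracle, rel=1e-3)
        else:
            assert abs(peak - oracle) < 0.05


def test_iv_bell_shaped_interior_maximum():
    protocol = VoltageProtocol.iv_default()
    model = ChannelModel(noise_sd=0.0)
    sweepset, _ = generate_ephys_experiment(model, protocol, 14, 0)
    iv = build_iv_curve(sweepset)
    k = int(np.argmax(np.abs(iv.peak_current)))
    assert 0 < k < iv.step_mv.size - 1


def test_missing_level_flagged():
    protocol = VoltageProtocol.iv_default()
    model = ChannelModel(noise_sd=0.0)
    sweepset, _ = generate_ephys_experiment(model, protocol, 13, 0)  # one short
    iv = build_iv_curve(sweepset)
    assert iv.missing_levels == [40.0]
    assert np.isnan(iv.peak_current[-1])


def test_peak_skips_capacitive_blank(protocol):
    # a huge capacitive spike in the first 2 ms must not be reported as peak
    model = ChannelModel(g_leak=0.0, c_membrane=50.0, noise_sd=0.0)
    sweepset, truth = generate_ephys_experiment(model, protocol, 1, 0)
    peak, t_peak = sweep_peak(sweepset.sweeps[0], protocol)
    assert t_peak - protocol.pre_ms >= 2.0
    assert abs(peak) < 1.5 * abs(truth.true_peak_pa[0])
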