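import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ca1sim import features as feat
from ca1sim.simulator import SimulationConfig, make_single_compartment, \
    simulate

from conftest import make_trace


def gaussian_bumps(peaks_ms, amp=60.0, width=2.0, base=-65.0,
                   t_stop=400.0, dt=0.1):
    t = np.arange(0.0, t_stop, dt)
    v = np.full_like(t, base)
    for p in peaks_ms:
        v += amp * np.exp(-0.5 * ((t - p) / width) ** 2)
    return t, v


class TestDetectSpikes:
    def test_three_bumps(self):
        t, v = gaussian_bumps([100.0, 200.0, 300.0])
        st_ = feat.detect_spikes(make_trace(t, v))
        assert np.allclose(st_, [100.0, 200.0, 300.0], atol=0.11)

    def test_subthreshold_trace_empty(self):
        t = np.arange(0.0, 100.0, 0.1)
        v = np.full_like(t, -50.0)
        assert len(feat.detect_spikes(make_trace(t, v))) == 0

    def test_double_peak_window_single_spike_at_higher_peak(self):
        t = np.arange(0.0, 50.0, 0.01)
        v = np.full_like(t, -65.0)
        # one suprathreshold window with two local maxima, second higher
        win = (t > 10) & (t < 20)
        v[win] = -10.0 + 5 * np.sin((t[win] - 10) * 2 * np.pi / 5)
        spikes = feat.detect_spikes(make_trace(t, v))
        assert len(spikes) == 1
        assert v[np.searchsorted(t, spikes[0])] == pytest.approx(
            v[win].max(), abs=1e-9)

    def test_time_shift_invariance(self):
        t, v = gaussian_bumps([100.0, 250.0])
        s1 = feat.detect_spikes(make_trace(t, v))
        s2 = feat.detect_spikes(make_trace(t + 37.0, v))
        assert np.allclose(s2 - s1, 37.0)


class TestTimingFeatures:
    def test_mean_frequency(self):
        spikes = np.linspace(110, 490, 8)
        out = feat.timing_features(spikes, (100.0, 500.0))
        assert out["spikecount_stimint"] == 8
        assert out["mean_frequency"] == pytest.approx(20.0)

    def test_first_spike_and_inv_first_isi(self):
        out = feat.timing_features([120.0, 170.0], (100.0, 600.0))
        assert out["time_to_first_spike"] == pytest.approx(20.0)
        assert out["inv_first_ISI"] == pytest.approx(20.0)

    def test_single_spike_has_no_isi_features(self):
        out = feat.timing_features([150.0], (100.0, 600.0))
        assert "inv_first_ISI" not in out
        assert "inv_last_ISI" not in out
        assert out["spikecount_stimint"] == 1

    def test_counts_restricted_to_stimulus(self):
        out = feat.timing_features([50.0, 150.0, 700.0], (100.0, 600.0))
        assert out["spikecount_stimint"] == 1

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            feat.timing_features([1.0], (100.0, 50.0))


class TestAdaptationIndex:
    def test_regular_train_zero(self):
        assert feat.adaptation_index(np.arange(0, 500, 50)) == pytest.approx(
            0.0, abs=1e-12)

    def test_hand_value(self):
        spikes = np.array([0.0, 10.0, 22.0, 36.0])  # ISIs 10, 12, 14
        expect = (2 / 22 + 2 / 26) / 2
        assert feat.adaptation_index(spikes) == pytest.approx(expect)
        assert expect == pytest.approx(0.0839, abs=1e-4)

    def test_reversal_flips_sign(self):
        spikes = np.array([0.0, 10.0, 22.0, 36.0])
        rev = np.sort(36.0 - spikes)
        assert feat.adaptation_index(rev) == pytest.approx(
            -feat.adaptation_index(spikes))

    def test_fewer_than_three_spikes_absent(self):
        assert feat.adaptation_index([1.0, 2.0]) is None


class TestShapeFeatures:
    def _triangle(self):
        # linear rise -60 -> +20 over 4 ms, fall back over 4 ms; crosses
        # -20 mV at 2 ms before and after the peak -> width 2+2 = 4 ms? no:
        # slope is 20 mV/ms, crossing at -20 happens 2 ms before peak.
        t = np.arange(0.0, 20.0, 0.01)
        v = np.full_like(t, -60.0)
        rise = (t >= 5) & (t < 9)
        fall = (t >= 9) & (t < 13)
        v[rise] = -60 + (t[rise] - 5) * 20
        v[fall] = 20 - (t[fall] - 9) * 20
        return t, v

    def test_triangle_width_and_amplitude(self):
        t, v = self._triangle()
        out = feat.shape_features(make_trace(t, v))
        # -20 crossed upward at t=7, downward at t=11 -> width 4 ms
        assert out["AP_width"] == pytest.approx(4.0, abs=0.02)
        assert out["AP_amplitude"] == pytest.approx(40.0, abs=0.2)

    def test_truncated_spike_absent(self):
        t = np.arange(0.0, 10.0, 0.01)
        v = np.linspace(-60.0, 30.0, t.size)  # still rising at trace end
        out = feat.shape_features(make_trace(t, v))
        assert "AP_width" not in out

    def test_phase_plot_sinusoid_ellipse(self):
        amp, freq = 30.0, 0.05  # mV, kHz
        t = np.arange(0.0, 200.0, 0.01)
        v = -40.0 + amp * np.sin(2 * np.pi * freq * t)
        out = feat.shape_features(make_trace(t, v), spike_times=[])
        dvdt = out["phase_plot"][:, 1]
        assert np.max(np.abs(dvdt)) == pytest.approx(
            amp * 2 * np.pi * freq, rel=1e-3)


class TestSubthreshold:
    def test_hand_values(self):
        t = np.arange(0.0, 1000.0, 0.5)
        v = np.full_like(t, -65.0)
        stim = (t >= 200) & (t <= 800)
        v[stim] = -75.0
        dip = (t >= 220) & (t <= 260)
        v[dip] = -80.0
        out = feat.subthreshold_features(make_trace(t, v),
                                         stim_window=(200.0, 800.0))
        assert out["voltage_base"] == pytest.approx(-65.0)
        assert out["steady_state_voltage"] == pytest.approx(-75.0)
        assert out["voltage_deflection"] == pytest.approx(-10.0)
        assert out["sag_amplitude"] == pytest.approx(5.0)

    def test_flat_trace_zero_sag(self):
        t = np.arange(0.0, 100.0, 0.5)
        out = feat.subthreshold_features(
            make_trace(t, np.full_like(t, -70.0)), stim_window=(20.0, 90.0))
        assert out["sag_amplitude"] == 0.0

    def test_constructed_double_exponential_sag(self):
        t = np.arange(0.0, 1000.1, 0.1)
        base, steady, over = -65.0, -75.0, 4.0
        v = np.full_like(t, base)
        stim = t >= 200
        ts = t[stim] - 200
        shape = np.exp(-ts / 40) - np.exp(-ts / 8)  # transient dip shape
        v[stim] = steady - over * shape / shape.max()
        out = feat.subthreshold_features(make_trace(t, v),
                                         stim_window=(200.0, 1000.0))
        assert out["sag_amplitude"] == pytest.approx(over, rel=0.02)

    def test_window_outside_trace_rejected(self):
        t = np.arange(0.0, 100.0, 0.5)
        with pytest.raises(ValueError):
            feat.subthreshold_features(
                make_trace(t, np.full_like(t, -70.0)),
                stim_window=(50.0, 500.0))

    def test_sag_never_negative_property(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 600.0, 0.5)
        for _ in range(20):
            v = -70 + np.cumsum(rng.normal(0, 0.2, t.size))
            out = feat.subthreshold_features(make_trace(t, v),
                                             stim_window=(100.0, 500.0))
            assert out["sag_amplitude"] >= 0.0


class TestMembraneTimeConstant:
    def _exp_trace(self, tau, noise=0.0, seed=0):
        t = np.arange(0.0, 600.0, 0.1)
        v = np.full_like(t, -65.0)
        stim = t >= 100
        v[stim] = -65.0 - 10.0 * (1 - np.exp(-(t[stim] - 100) / tau))
        if noise:
            v = v + np.random.default_rng(seed).normal(0, noise, v.shape)
        return make_trace(t, v)

    def test_pure_exponential_within_one_percent(self):
        tau = feat.membrane_time_constant(self._exp_trace(15.0),
                                          stim_window=(100.0, 500.0))
        assert tau == pytest.approx(15.0, rel=0.01)

    def test_noisy_within_five_percent_across_seeds(self):
        taus = [feat.membrane_time_constant(
            self._exp_trace(15.0, noise=0.1, seed=s),
            stim_window=(100.0, 500.0)) for s in range(10)]
        for tau in taus:
            assert tau == pytest.approx(15.0, rel=0.05)

    def test_depolarizing_trace_rejected(self):
        t = np.arange(0.0, 600.0, 0.1)
        v = np.full_like(t, -65.0)
        v[t >= 100] = -55.0
        with pytest.raises(ValueError):
            feat.membrane_time_constant(make_trace(t, v),
                                        stim_window=(100.0, 500.0))


class TestInputResistance:
    def test_hand_value(self):
        t = np.arange(0.0, 800.0, 0.5)
        v = np.full_like(t, -65.0)
        v[(t >= 200) & (t <= 600)] = -70.0
        tr = make_trace(t, v, amplitude=-0.05, delay=200.0, duration=400.0)
        assert feat.input_resistance([tr]) == pytest.approx(100.0)

    def test_rc_simulation_matches_one_over_g(self):
        cell = make_single_compartment(c_pF=100.0, g_leak_nS=10.0)
        cell.inject_step_current("soma", -0.05, 100.0, 400.0)
        res = simulate(cell, SimulationConfig(t_stop=600.0))
        tr = res.soma
        tr.meta.update(amplitude=-0.05, delay=100.0, duration=400.0)
        assert feat.input_resistance([tr]) == pytest.approx(100.0, rel=0.01)

    def test_smallest_magnitude_negative_selected(self):
        t = np.arange(0.0, 800.0, 0.5)

        def mk(amp, defl):
            v = np.full_like(t, -65.0)
            v[(t >= 200) & (t <= 600)] = -65.0 + defl
            return make_trace(t, v, amplitude=amp, delay=200.0,
                              duration=400.0)

        # -0.05 nA / -5 mV -> 100 MOhm ; -0.2 nA / -30 mV -> 150 MOhm
        r = feat.input_resistance([mk(-0.2, -30.0), mk(-0.05, -5.0)])
        assert r == pytest.approx(100.0)

    def test_no_negative_injection_rejected(self):
        t = np.arange(0.0, 100.0, 0.5)
        tr = make_trace(t, np.full_like(t, -65.0), amplitude=0.1)
        with pytest.raises(ValueError):
            feat.input_resistance([tr])


class TestTrendAndGroupStats:
    def test_slope_hand_value(self):
        rows = []
        for cell, sp in (("a", "mouse"), ("b", "mouse")):
            for amp, val in ((0.1, 1.0), (0.2, 2.0), (0.3, 3.0)):
                rows.append(dict(cell=cell, species=sp, amplitude=amp,
                                 value=val))
        out = feat.trend_and_group_stats(rows, "value")
        assert out["slopes"]["mouse"] == pytest.approx(10.0)

    def test_identical_groups_high_p(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 12)
        rows = []
        for sp in ("mouse", "rat"):
            for i, v in enumerate(vals):
                rows.append(dict(cell=f"{sp}{i}", species=sp, amplitude=0.1,
                                 value=float(v)))
        out = feat.trend_and_group_stats(rows, "value")
        assert out["per_amplitude"][0.1]["p_value"] > 0.9

    def test_shifted_gaussians_low_p(self):
        rng = np.random.default_rng(2)
        rows = []
        for sp, shift in (("mouse", 0.0), ("rat", 5.0)):
            for i in range(40):
                rows.append(dict(cell=f"{sp}{i}", species=sp, amplitude=0.1,
                                 value=float(rng.normal(shift, 1.0))))
        out = feat.trend_and_group_stats(rows, "value")
        assert out["per_amplitude"][0.1]["p_value"] < 1e-6


class TestExtractAll:
    def test_timing_features_shift_with_trace(self):
        t, v = gaussian_bumps([150.0, 200.0, 260.0, 330.0], t_stop=620.0)
        tr1 = make_trace(t, v, amplitude=0.3, delay=100.0, duration=400.0)
        out1 = feat.extract_all(tr1)
        tr2 = make_trace(t + 50.0, v, amplitude=0.3, delay=150.0,
                         duration=400.0)
        out2 = feat.extract_all(tr2)
        assert out1["time_to_first_spike"] == pytest.approx(
            out2["time_to_first_spike"], abs=1e-9)
        assert out1["inv_first_ISI"] == pytest.approx(out2["inv_first_ISI"])

    def test_spike_features_absent_without_spikes(self):
        t = np.arange(0.0, 800.0, 0.5)
        v = np.full_like(t, -70.0)
        out = feat.extract_all(make_trace(t, v, amplitude=0.1, delay=200.0,
                                          duration=400.0))
        assert "inv_first_ISI" not in out
        assert "AP_width" not in out
        assert out["spikecount_stimint"] == 0


@settings(max_examples=40, deadline=None)
@given(isis=st.lists(st.floats(min_value=1.0, max_value=200.0),
                     min_size=3, max_size=30))
def test_adaptation_index_bounded_property(isis):
    spikes = np.concatenate([[0.0], np.cumsum(isis)])
    ai = feat.adaptation_index(spikes)
    assert -1.0 < ai < 1.0
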