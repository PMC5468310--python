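"""Protocols: spike detection, rates, threshold search, EPSC, diagnostics."""
import numpy as np
import pytest

from efneuron.errors import ParameterError
from efneuron.field_solver import Trace
from efneuron.morphology import build_artificial_neuron
from efneuron.protocols import (EPSCStimulus, SpikeTrain, detect_spikes,
                                f_E_curve, find_EF_threshold, firing_rate,
                                ap_site_diagnostics, polarization_vs_E,
                                run_ap_diagnostics, sweep_threshold,
                                threshold_with_epsc)


def synthetic_trace(v, dt=0.1, site=("soma", 0.5)):
    v = np.asarray(v, dtype=float)
    return Trace(times=dt * np.arange(len(v)), sites=[site], V=v[None, :])


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        tr = synthetic_trace(np.full(1000, -65.0))
        assert len(detect_spikes(tr)) == 0

    def test_five_cycle_oscillation_gives_five_spikes(self):
        t = np.arange(0.0, 50.0, 0.1)
        v = -30.0 + 50.0 * np.sin(2 * np.pi * t / 10.0)  # 5 cycles above 0 mV
        tr = synthetic_trace(v)
        assert len(detect_spikes(tr)) == 5

    def test_refractory_suppresses_alternate_crossings(self):
        # crossings 1 ms apart; 2 ms refractory keeps every second one
        t = np.arange(0.0, 10.0, 0.05)
        v = np.where((t * 1000) % 1000 < 500, 10.0, -65.0)  # 1 ms period square
        tr = Trace(times=t, sites=[("soma", 0.5)], V=v[None, :])
        naive = detect_spikes(tr, refractory_ms=0.0)
        gated = detect_spikes(tr, refractory_ms=2.0)
        assert len(gated) == (len(naive) + 1) // 2

    def test_unknown_site_rejected(self):
        tr = synthetic_trace(np.zeros(10))
        with pytest.raises(ParameterError):
            detect_spikes(tr, site=("axon", 0.5))


class TestFiringRate:
    def test_definition(self):
        st = SpikeTrain(np.array([10.0, 200.0, 400.0, 600.0, 900.0]), 0.0, 2.0)
        assert firing_rate(st, (0.0, 1000.0)) == pytest.approx(5.0)

    def test_empty_train_and_shifted_window(self):
        st = SpikeTrain(np.array([]), 0.0, 2.0)
        assert firing_rate(st, (0.0, 500.0)) == 0.0
        st2 = SpikeTrain(np.array([10.0, 20.0]), 0.0, 2.0)
        assert firing_rate(st2, (100.0, 600.0)) == 0.0

    def test_degenerate_window_rejected(self):
        with pytest.raises(ParameterError):
            firing_rate(SpikeTrain(np.array([]), 0.0, 2.0), (100.0, 100.0))


class TestThresholdSearch:
    def test_passive_membrane_has_no_threshold(self, default_tree, passive):
        res = find_EF_threshold(default_tree, passive, "+", E_max=1000.0,
                                resolution=1.0)
        assert not res.found
        assert res.E_threshold is None and res.bracket is None
        assert all(n == 0 for _, n in res.search_log)

    def test_bracket_is_sound_and_tight(self, default_tree, kinetics):
        res = find_EF_threshold(default_tree, kinetics, "+", resolution=0.5)
        lo, hi = res.bracket
        assert hi - lo <= res.resolution + 1e-9
        assert res.E_threshold == hi
        logged = dict(res.search_log)
        assert logged[lo] == 0 and logged[hi] >= 1

    def test_search_is_deterministic(self, default_tree, kinetics):
        a = find_EF_threshold(default_tree, kinetics, "+", resolution=2.0)
        b = find_EF_threshold(default_tree, kinetics, "+", resolution=2.0)
        assert a == b

    def test_negative_polarity_is_signed(self, default_tree, kinetics):
        res = find_EF_threshold(default_tree, kinetics, "-", resolution=2.0)
        assert res.found and res.E_threshold < 0
        lo, hi = res.bracket
        assert abs(lo) < abs(hi) and hi == res.E_threshold


class TestFECurve:
    def test_subthreshold_grid_is_silent(self, default_tree, kinetics):
        curve = f_E_curve(default_tree, kinetics, [-100.0, -50.0, 0.0, 50.0, 100.0])
        assert np.all(curve.f == 0.0)

    def test_curve_reproduces_exactly(self, default_tree, kinetics):
        grid = [0.0, 240.0]
        c1 = f_E_curve(default_tree, kinetics, grid)
        c2 = f_E_curve(default_tree, kinetics, grid)
        assert np.array_equal(c1.f, c2.f)
        assert c1.f[-1] > 0  # just above threshold


class TestSweep:
    def test_unknown_parameter_rejected(self, default_params, kinetics):
        with pytest.raises(ParameterError, match="unknown sweep parameter"):
            sweep_threshold(default_params, "soma_voltage", [1, 2],
                            biophys=kinetics)

    def test_sweep_table_shape_and_determinism(self, default_params, kinetics):
        sw = sweep_threshold(default_params, "axon_length", [40.0, 80.0],
                             resolution=2.0, biophys=kinetics)
        assert len(sw.values) == len(sw.thresholds) == 2
        again = sweep_threshold(default_params, "axon_length", [40.0, 80.0],
                                resolution=2.0, biophys=kinetics)
        assert sw.thresholds == again.thresholds
        frame = sw.to_frame()
        assert list(frame.columns) == ["axon_length", "E_threshold_mV_per_mm"]


class TestEPSC:
    def test_zero_amplitude_equals_plain_threshold(self, default_tree, kinetics):
        plain = find_EF_threshold(default_tree, kinetics, "+", resolution=2.0)
        with_e = threshold_with_epsc(default_tree, kinetics,
                                     EPSCStimulus(amplitude=0.0), "+",
                                     resolution=2.0)
        assert plain.E_threshold == with_e.E_threshold
        assert plain.search_log == with_e.search_log

    def test_suprathreshold_epsc_rejected(self, default_tree, kinetics):
        with pytest.raises(ParameterError, match="subthreshold"):
            threshold_with_epsc(default_tree, kinetics,
                                EPSCStimulus(amplitude=0.5), "+")

    def test_epsp_lowers_threshold(self, default_tree, kinetics):
        plain = find_EF_threshold(default_tree, kinetics, "+", resolution=0.5)
        helped = threshold_with_epsc(default_tree, kinetics,
                                     EPSCStimulus(amplitude=0.01), "+",
                                     resolution=0.5)
        assert helped.E_threshold < plain.E_threshold


class TestAPDiagnostics:
    def test_no_spike_rejected(self):
        tr = synthetic_trace(np.full(100, -65.0))
        with pytest.raises(ParameterError, match="no spike"):
            ap_site_diagnostics(tr)

    def test_single_site_is_trivially_initiation_site(self):
        v = np.concatenate([np.full(50, -65.0), np.full(10, 30.0),
                            np.full(40, -65.0)])
        tr = synthetic_trace(v, site=("soma", 0.5))
        diag = ap_site_diagnostics(tr)
        assert diag.initiation_site == ("soma", 0.5)
        assert diag.table.peak_mV.iloc[0] == pytest.approx(30.0)

    def test_suprathreshold_run_initiates_in_axon(self, default_tree, kinetics):
        diag = run_ap_diagnostics(default_tree, kinetics, 260.0)
        assert diag.initiation_site[0] == "axon"
        assert diag.peak_at("axon") > diag.peak_at("soma")


class TestPolarizationFit:
    def test_passive_response_is_exactly_linear(self, default_tree, passive):
        fit = polarization_vs_E(default_tree, passive, [-60.0, -30.0, 30.0, 60.0])
        assert fit.max_residual < 1e-6 * np.abs(fit.soma_delta_v).max()

    def test_active_response_is_nearly_linear(self, default_tree, kinetics):
        fit = polarization_vs_E(default_tree, kinetics,
                                [-50.0, -25.0, 0.0, 25.0, 50.0])
        assert fit.max_residual < 0.05 * np.abs(fit.soma_delta_v).max()

    def test_slope_sensitive_to_dendritic_length(self, default_params, passive):
        short = build_artificial_neuron(default_params)
        long_ = build_artificial_neuron(default_params.with_(
            proximal_dend_length=16.0, distal_dend_length=4.0))
        grid = [-40.0, 40.0]
        f1 = polarization_vs_E(short, passive, grid)
        f2 = polarization_vs_E(long_, passive, grid)
        assert f1.slope != pytest.approx(f2.slope, rel=1e-3)
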