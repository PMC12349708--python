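"""Integrator correctness: gates, currents, closed-form trajectories,
refractoriness, determinism, and qualitative network behaviour."""

import dataclasses

import numpy as np
import pytest

import v1micro as vm
from v1micro.params import CellClass, default_parameters


def quiet_params(**overrides):
    """Parameters with all external drive silenced (and optional overrides)."""
    p = default_parameters()
    silent_bg = dataclasses.replace(p.background, rates=(0.0, 0.0, 0.0, 0.0))
    silent_ff = dataclasses.replace(p.feedforward, rates=(0.0,) * 4)
    return dataclasses.replace(p, background=silent_bg, feedforward=silent_ff,
                               **overrides)


def single_neuron_net():
    sizes = vm.PopulationSizes(1, 0, 0, 0)
    empty = np.empty(0)
    return vm.NetworkModel(sizes, empty.astype(np.int32), empty.astype(np.int32),
                           empty.copy(), empty.copy())


class TestPoissonTrain:
    def test_zero_rate_is_empty(self):
        assert len(vm.poisson_train(0.0, 1000.0, rng=0)) == 0

    def test_negative_rate_raises(self):
        with pytest.raises(ValueError):
            vm.poisson_train(-1.0, 100.0)

    def test_count_within_poisson_band(self):
        # PV background rate over a full trial: mean 770 * 3 = 2310 events
        t = vm.poisson_train(770.0, 3000.0, rng=1)
        assert abs(len(t) - 2310) < 5 * np.sqrt(2310)
        assert np.all((t >= 0) & (t <= 3000.0))
        assert np.all(np.diff(t) >= 0)

    def test_dispersion_is_poisson(self, rng):
        counts = np.array([len(vm.poisson_train(25.0, 1000.0, rng)) for _ in range(2000)])
        # variance/mean ~ 1 for a Poisson count
        assert abs(counts.var() / counts.mean() - 1.0) < 0.15


class TestGateAndCurrent:
    def test_gate_decay_closed_form(self):
        assert vm.update_gate(0.0, 2.0, 1.0) == 0.0
        assert vm.update_gate(1.0, 2.0, 2.0) == pytest.approx(np.exp(-1.0), abs=1e-15)
        assert vm.update_gate(0.0, 2.0, 0.1, n_arrivals=3) == 3.0

    def test_gate_multi_step_decay_exact(self):
        s, tau, dt = 1.7, 6.4, 0.1
        for k in range(1, 50):
            s = vm.update_gate(s, tau, dt)
        assert s == pytest.approx(1.7 * np.exp(-49 * dt / tau), rel=1e-12)

    def test_current_zero_cases(self):
        assert vm.synaptic_current(-60.0, np.zeros(5), np.ones(5), 0.0) == 0.0
        # at the reversal potential the driving force vanishes
        assert vm.synaptic_current(0.0, np.ones(3), np.ones(3), 0.0) == 0.0

    def test_current_units(self):
        # 1 nS * 70 mV driving force = 70 pA
        i = vm.synaptic_current(-70.0, np.array([1.0]), np.array([1.0]), 0.0)
        assert i == pytest.approx(-70.0)
        assert abs(i) == 70.0


class TestSingleNeuronTrajectories:
    def test_no_input_stays_at_rest(self):
        net = single_neuron_net()
        cfg = vm.SimulationConfig(duration=200.0, discard=0.0, n_trials=1)
        rec = vm.integrate_trial(net, cfg, 0, params=quiet_params(), monitor_neuron=0)
        assert rec.n_spikes == 0
        np.testing.assert_allclose(rec.v_trace, -70.0, atol=1e-12)

    def test_constant_conductance_matches_closed_form(self):
        """RK4 with a constant conductance clamp vs. the exact linear-ODE
        solution: subthreshold relaxation to the conductance-weighted
        steady state, within 1e-6 mV at dt = 0.1 ms."""
        net = single_neuron_net()
        cfg = vm.SimulationConfig(duration=100.0, discard=0.0, n_trials=1)
        p = quiet_params()
        g_c = 5.0  # nS, excitatory clamp; steady state stays below threshold
        rec = vm.integrate_trial(
            net, cfg, 0, params=p, g_const=np.array([g_c]), monitor_neuron=0
        )
        nrn = p.neurons[CellClass.PYR]
        k = 1.0 / nrn.tau_m + g_c / nrn.C_m
        v_inf = (nrn.E_l / nrn.tau_m) / k
        t = np.arange(len(rec.v_trace)) * cfg.dt
        analytic = v_inf + (nrn.E_l - v_inf) * np.exp(-k * t)
        assert v_inf < nrn.V_thr
        assert np.max(np.abs(rec.v_trace - analytic)) < 1e-6

    def test_rk4_error_shrinks_with_dt(self):
        """Halving dt should reduce the trajectory error by ~2^4."""
        net = single_neuron_net()
        p = quiet_params()
        g_c = np.array([5.0])
        errs = []
        for dt in (0.2, 0.1):
            cfg = vm.SimulationConfig(dt=dt, duration=50.0, discard=0.0, n_trials=1)
            rec = vm.integrate_trial(net, cfg, 0, params=p, g_const=g_c,
                                     monitor_neuron=0)
            nrn = p.neurons[CellClass.PYR]
            k = 1.0 / nrn.tau_m + g_c[0] / nrn.C_m
            v_inf = (nrn.E_l / nrn.tau_m) / k
            t = np.arange(len(rec.v_trace)) * dt
            analytic = v_inf + (nrn.E_l - v_inf) * np.exp(-k * t)
            errs.append(np.max(np.abs(rec.v_trace - analytic)))
        assert errs[1] < errs[0] / 8

    def test_suprathreshold_clamp_fires_regularly(self):
        """A strong clamp drives periodic firing; ISIs respect tau_ref and
        equal the closed-form threshold-crossing interval."""
        net = single_neuron_net()
        cfg = vm.SimulationConfig(duration=500.0, discard=0.0, n_trials=1)
        p = quiet_params()
        g_c = 40.0
        rec = vm.integrate_trial(net, cfg, 0, params=p, g_const=np.array([g_c]))
        assert rec.n_spikes > 5
        isi = np.diff(np.sort(rec.times))
        nrn = p.neurons[CellClass.PYR]
        assert np.all(isi >= nrn.tau_ref)
        # closed form: from V_reset, time to reach V_thr, plus refractory
        k = 1.0 / nrn.tau_m + g_c / nrn.C_m
        v_inf = (nrn.E_l / nrn.tau_m) / k
        t_cross = np.log((nrn.V_reset - v_inf) / (nrn.V_thr - v_inf)) / k
        expected = nrn.tau_ref + t_cross
        assert np.allclose(isi[1:], isi[1], atol=cfg.dt + 1e-9)
        assert abs(isi[2] - expected) <= 2 * cfg.dt


class TestNetworkInvariants:
    def test_refractory_isi_invariant(self, tiny_record):
        p = default_parameters()
        tau_ref = {int(c): p.neurons[c].tau_ref for c in CellClass}
        for nid, isis in tiny_record.isi_by_neuron().items():
            assert np.all(isis >= tau_ref[int(tiny_record.class_of[nid])] - 1e-9)

    def test_determinism(self, tiny_network):
        cfg = vm.SimulationConfig(duration=400.0, discard=0.0, scale=0.05, n_trials=1)
        a = vm.integrate_trial(tiny_network, cfg, trial_seed=5)
        b = vm.integrate_trial(tiny_network, cfg, trial_seed=5)
        np.testing.assert_array_equal(a.neuron_ids, b.neuron_ids)
        np.testing.assert_array_equal(a.times, b.times)
        c = vm.integrate_trial(tiny_network, cfg, trial_seed=6)
        assert c.n_spikes != a.n_spikes or not np.array_equal(a.times, c.times)

    def test_spike_times_within_trial(self, tiny_record):
        assert np.all(tiny_record.times > 0)
        assert np.all(tiny_record.times <= tiny_record.duration)

    def test_feedforward_excitation_monotonicity(self):
        """On a Pyr-only network, raising the stimulus rate raises the rate."""
        sizes = vm.PopulationSizes(100, 0, 0, 0)
        net = vm.build_connectivity(sizes, seed=2)
        cfg = vm.SimulationConfig(duration=600.0, discard=100.0, n_trials=1)
        rates = []
        for ff_rate in (10.0, 60.0):
            p = default_parameters()
            ff = dataclasses.replace(p.feedforward, rates=(ff_rate,) * 4)
            p = dataclasses.replace(p, feedforward=ff)
            rec = vm.integrate_trial(net, cfg, 3, params=p)
            rates.append(vm.compute_rates(rec, (100.0, 600.0))[CellClass.PYR])
        assert rates[1] > rates[0]

    def test_inhibition_cannot_push_below_reversal(self):
        """With only inhibitory input the membrane never crosses V_I=-70."""
        sizes = vm.PopulationSizes(1, 1, 0, 0)
        # single strong PV->Pyr synapse; PV driven by its background input
        net = vm.NetworkModel(
            sizes,
            pre=np.array([1], dtype=np.int32),
            post=np.array([0], dtype=np.int32),
            weight=np.array([50.0]),
            delay=np.array([1.0]),
        )
        p = default_parameters()
        bg = dataclasses.replace(p.background, rates=(0.0, 770.0, 0.0, 0.0))
        ff = dataclasses.replace(p.feedforward, rates=(0.0,) * 4)
        p = dataclasses.replace(p, background=bg, feedforward=ff)
        cfg = vm.SimulationConfig(duration=500.0, discard=0.0, n_trials=1)
        rec = vm.integrate_trial(net, cfg, 8, params=p, monitor_neuron=0)
        ids, _ = rec.spikes_of("PV")
        assert len(ids) > 0  # the inhibitory afferent actually fired
        assert np.all(rec.v_trace >= -70.0 - 1e-9)

    def test_rate_computation_definitions(self, tiny_record):
        rates = vm.compute_rates(tiny_record, (0.0, tiny_record.duration))
        manual = {}
        for c in CellClass:
            _, t = tiny_record.spikes_of(c)
            manual[c] = len(t) / tiny_record.sizes.count(c) / (
                tiny_record.duration / 1000.0
            )
        for c in CellClass:
            assert rates[c] == pytest.approx(manual[c])

    def test_empty_record_rates_zero(self):
        rec = vm.SpikeRecord(
            neuron_ids=np.empty(0, np.int32), times=np.empty(0),
            sizes=vm.PopulationSizes(10, 5, 3, 2), duration=100.0,
        )
        assert all(v == 0.0 for v in vm.compute_rates(rec).values())

    def test_control_network_stimulus_response(self, tiny_network):
        """Stimulation activates Pyr, PV and SOM; VIP does not increase."""
        cfg = vm.SimulationConfig(duration=1200.0, scale=0.05, n_trials=1)
        stim = vm.integrate_trial(tiny_network, cfg, trial_seed=21)
        p = default_parameters()
        no_ff = dataclasses.replace(
            p, feedforward=dataclasses.replace(p.feedforward, rates=(0.0,) * 4)
        )
        spont = vm.integrate_trial(tiny_network, cfg, trial_seed=21, params=no_ff)
        w = (500.0, 1200.0)
        r_stim = vm.compute_rates(stim, w)
        r_spont = vm.compute_rates(spont, w)
        for c in (CellClass.PYR, CellClass.PV, CellClass.SOM):
            assert r_stim[c] > r_spont[c]
        assert r_stim[CellClass.VIP] <= r_spont[CellClass.VIP] * 1.10
        for c in CellClass:
            assert r_stim[c] > 0


def test_compute_rates_window_validation(tiny_record):
    with pytest.raises(ValueError):
        vm.compute_rates(tiny_record, (-5.0, 100.0))
    with pytest.raises(ValueError):
        vm.compute_rates(tiny_record, (0.0, tiny_record.duration + 1))
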