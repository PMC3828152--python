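"""End-to-end preset behaviour: tracking, persistence, tuning, E/I balance."""

import numpy as np
import pytest

from spikepc import PerturbationPlan, run
from spikepc.model_spec import ConfigurationError
from spikepc.presets import (charge_integrator, get_preset, preset_arm,
                             preset_differentiator_oscillator,
                             preset_integrator, run_checklist)
from spikepc.spike_stats import ei_currents, tuning_curve_integrator


class TestChecklists:
    @pytest.mark.parametrize("name", ["fig1c", "fig1d", "fig2", "fig5",
                                      "fig6a", "fig6b"])
    def test_preset_checklist_all_pass(self, name):
        p = get_preset(name)
        checks = run_checklist(p, seed=0)
        assert checks, "checklist must not be empty"
        assert all(checks.values()), checks

    def test_unknown_preset(self):
        with pytest.raises(ConfigurationError):
            get_preset("fig99")


class TestIntegrator:
    def test_homogeneous_perfect_tracks_within_kernel_norm(self):
        p = preset_integrator("homogeneous-perfect")
        res = p.simulate(seed=1, record_traces=True, trace_stride=10)
        tr = res.traces
        sel = tr["time"] > 0.1
        err = np.abs(tr["x"][sel, 0] - tr["xhat"][sel, 0])
        assert err.max() <= 2 * p.kernel_cfg.norm

    def test_leaky_variant_decays_after_offset(self):
        p = preset_integrator("homogeneous-leaky")
        res = p.simulate(seed=1, record_traces=True, trace_stride=10)
        tr = res.traces
        on = (tr["time"] > 0.4) & (tr["time"] < 0.6)
        off = tr["time"] > 0.7
        assert np.abs(tr["xhat"][off, 0]).max() < 0.2 * np.abs(
            tr["xhat"][on, 0]).mean()

    def test_inhomogeneous_deterministic_without_noise(self):
        p = preset_integrator("inhomogeneous")
        a = p.simulate(seed=3)
        b = p.simulate(seed=3)
        assert np.array_equal(a.spike_times, b.spike_times)
        # chaos: a different sensory-noise seed reshuffles the delay spikes
        c = p.simulate(seed=4)
        assert a.n_spikes != c.n_spikes or not np.array_equal(
            a.spike_times, c.spike_times)

    def test_rectified_linear_tuning(self):
        # delay-epoch response grows with the charged value for
        # positive-kernel units and is rectified at zero
        p = preset_integrator("inhomogeneous")
        net, system = p.build()

        def run_trial(stim, seed):
            cmd = p.command(seed)
            pars = dict(p.command_params, amplitude=stim * 4)
            from spikepc.simulate import make_command
            cmd = make_command("noisy-step", pars, J=net.J, seed=seed)
            res = run(net, system, duration=0.85, dt=p.dt, seed=seed,
                      command=cmd)
            sel = res.spike_times > 0.35
            return np.bincount(res.spike_neurons[sel], minlength=net.N) / 0.5

        tc = tuning_curve_integrator(run_trial, grid=[-1.0, 0.0, 1.0, 2.0],
                                     n_trials=3)
        pos = np.flatnonzero(net.Gamma.sum(axis=0) > 0)
        mean_pos = tc.response[:, pos].mean(axis=1)
        # monotone increasing for positive stimuli, near-silent for negative
        assert mean_pos[3] > mean_pos[2] > mean_pos[1]
        assert mean_pos[0] < 0.2 * mean_pos[3]

    def test_sustained_rate_scale(self):
        p = preset_integrator("inhomogeneous")
        st, x_off = charge_integrator(p, seed=2)
        net, system = p.build()
        res = run(net, system, duration=2.0, dt=p.dt, seed=5,
                  initial_state=st)
        rates = res.rates((0.25, 2.0))
        active = rates[rates > 0.5]
        assert 50 < active.size < 350
        assert 2.0 < np.median(active) < 10.0


class TestInactivation:
    def test_clamping_half_the_active_neurons_is_tolerated(self):
        # survivors fire faster and the readout error stays bounded
        p = preset_integrator("inhomogeneous")
        st, x_off = charge_integrator(p, seed=7)
        net, system = p.build()
        free = run(net, system, duration=1.5, dt=p.dt, seed=8,
                   initial_state=st.copy(), record_traces=True,
                   trace_stride=10)
        rates = free.rates((0.0, 0.5))
        active = np.flatnonzero(rates > 1.0)
        victims = active[::2]
        plan = PerturbationPlan(clamps=[(0.5, 1.5, victims.tolist(), 0.0)])
        les = run(net, system, duration=1.5, dt=p.dt, seed=8,
                  initial_state=st.copy(), plan=plan, record_traces=True,
                  trace_stride=10)
        survivors = np.setdiff1d(active, victims)
        r_before = les.rates((0.0, 0.5))[survivors].mean()
        r_after = les.rates((0.6, 1.5))[survivors].mean()
        assert r_after > 1.3 * r_before
        tr = les.traces
        sel = tr["time"] > 0.6
        err = np.abs(tr["x"][sel].mean(1) - tr["xhat"][sel].mean(1))
        kernel_norm = float(np.linalg.norm(net.Gamma, axis=0).mean())
        assert err.max() < 3 * kernel_norm


class TestEICurrents:
    def test_balance_and_conservation(self):
        # drive the integrator with a slowly wandering stimulus: excitation
        # and inhibition both track it, so at the stimulus timescale the two
        # currents are tightly anti-correlated and nearly cancel
        from spikepc.simulate import make_command
        p = preset_integrator("inhomogeneous")
        net, system = p.build()
        cmd = make_command("white-noise-filtered",
                           {"mean": 2.0, "sd": 40.0, "tau": 0.15},
                           J=net.J, seed=1)
        res = run(net, system, duration=3.0, dt=p.dt, seed=0, command=cmd,
                  record_traces=True, trace_stride=1)
        rates = res.rates((0.3, 3.0))
        neuron = int(np.argmax(rates))
        # reconstruct with the same command sequence
        cmd2 = make_command("white-noise-filtered",
                            {"mean": 2.0, "sd": 40.0, "tau": 0.15},
                            J=net.J, seed=1)
        sys2 = type(system)(A=system.A, command=cmd2, x0=system.x0)
        out = ei_currents(res, net, sys2, neuron, smoothing_s=0.02)
        sel = out["time"] > 0.3
        assert out["E"][sel].mean() > 0
        assert out["I"][sel].mean() < 0
        corr = np.corrcoef(out["E"][sel], -out["I"][sel])[0, 1]
        assert corr > 0.9
        assert np.abs(out["net"][sel]).mean() < 0.2 * out["E"][sel].mean()

    def test_invalid_neuron(self):
        p = preset_integrator("inhomogeneous")
        net, system = p.build()
        res = run(net, system, duration=0.05, dt=p.dt, seed=0,
                  record_traces=True, trace_stride=1)
        with pytest.raises(ConfigurationError):
            ei_currents(res, net, system, net.N + 3)


class TestArmAndHeterogeneous:
    def test_arm_reach_decodes_trajectory(self):
        p = preset_arm()
        res = p.simulate(seed=0, record_traces=True, trace_stride=10)
        tr = res.traces
        sel = tr["time"] > 0.2
        err = np.linalg.norm(tr["x"][sel] - tr["xhat"][sel], axis=1)
        move = np.linalg.norm(tr["x"][sel], axis=1).max()
        assert move > 0.3                      # the arm actually moved
        assert np.median(err) < 0.05 * move    # trajectories superpose

    def test_arm_direction_tuning_is_bell_shaped_and_speed_scaled(self):
        p = preset_arm()
        net, system = p.build()
        from spikepc.simulate import make_command
        dirs = np.linspace(0, 2 * np.pi, 8, endpoint=False)

        def counts(force):
            out = []
            for th in dirs:
                cmd = make_command("push-pull-2d",
                                   dict(p.command_params, direction=th,
                                        force=force), J=4)
                res = run(net, system, duration=0.6, dt=p.dt, seed=3,
                          command=cmd)
                sel = (res.spike_times > 0.1) & (res.spike_times < 0.6)
                out.append(np.bincount(res.spike_neurons[sel],
                                       minlength=net.N))
            return np.array(out)          # (8 dirs, N)

        slow = counts(10.0)
        fast = counts(20.0)
        # pick a well-driven unit: clear direction preference at high speed
        unit = int(np.argmax(fast.max(axis=0)))
        prof = fast[:, unit].astype(float)
        pref = int(np.argmax(prof))
        anti = (pref + 4) % 8
        assert prof[pref] > 2 * prof[anti]          # bell-shaped
        assert fast[pref, unit] > slow[pref, unit]  # gain grows with speed

    def test_differentiator_tracks_scaled_derivative(self):
        p = preset_differentiator_oscillator("differentiator")
        res = p.simulate(seed=0, record_traces=True, trace_stride=10)
        tr = res.traces
        # x2 approximates tau_f * dc/dt; compare the decoded second
        # component against the finite difference of the smoothed command
        x1 = tr["x"][:, 0]
        dt = float(np.diff(tr["time"]).mean())
        deriv = np.gradient(x1, dt) * 0.02 / 1.0
        sel = (tr["time"] > 0.15) & (tr["time"] < 0.95)
        c = np.corrcoef(tr["xhat"][sel, 1], deriv[sel])[0, 1]
        assert c > 0.9

    def test_oscillator_rings_down_with_reference(self):
        p = preset_differentiator_oscillator("oscillator")
        res = p.simulate(seed=0, record_traces=True, trace_stride=10)
        tr = res.traces
        sel = tr["time"] > 0.2
        err = np.linalg.norm(tr["x"][sel] - tr["xhat"][sel], axis=1)
        amp = np.abs(tr["x"][sel, 0]).max()
        assert amp > 0.3
        assert np.median(err) < 0.1 * amp
        # zero crossings of the reference are matched by the estimate
        zc_x = np.signbit(tr["x"][sel, 0][:-1]) != np.signbit(
            tr["x"][sel, 0][1:])
        zc_e = np.signbit(tr["xhat"][sel, 0][:-1]) != np.signbit(
            tr["xhat"][sel, 0][1:])
        assert abs(zc_x.sum() - zc_e.sum()) <= 2
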