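"""Solver unit and property tests: reaction, diffusion, full S1S2 runs."""

import math

import numpy as np
import pytest

from mmscalib.forward_model import (
    GridSpec,
    PacingProtocol,
    SimulationState,
    StimulusWindow,
    TissueParameters,
    apply_diffusion,
    default_cable_grid,
    run_stimuli,
    simulate,
    simulate_cell,
    step_reaction,
)
from mmscalib.observables import build_observation, extract_lat


def _cell_state(v, gate):
    grid = GridSpec(dimensionality=0, node_counts=(1,))
    s = SimulationState.resting(grid)
    s.v[...] = v
    s.gate[...] = gate
    return s


class TestReaction:
    def test_resting_state_is_fixed_point(self, midpoint_params):
        s = _cell_state(0.0, 1.0)
        out = step_reaction(s, midpoint_params, dt=1.0)
        assert out.v == pytest.approx(0.0, abs=0.0)
        assert out.gate == pytest.approx(1.0, abs=0.0)

    @pytest.mark.parametrize(
        "v, gate, tau_open, tau_close, expected",
        [
            # sub-threshold: recovery towards 1 with the open time constant
            (0.05, 0.5, 100.0, 150.0, 1.0 - 0.5 * math.exp(-0.01)),
            # supra-threshold: pure exponential closing
            (0.5, 1.0, 100.0, 150.0, math.exp(-1.0 / 150.0)),
        ],
    )
    def test_gate_closed_form_single_step(self, v, gate, tau_open, tau_close, expected):
        p = TissueParameters(0.3, 7.0, tau_open, tau_close, 0.2)
        out = step_reaction(_cell_state(v, gate), p, dt=1.0)
        assert out.gate == pytest.approx(expected, rel=1e-12)

    def test_gate_trajectory_matches_analytic_exponential(self, midpoint_params):
        """Constant-sign voltage: many numeric steps track the exact solution."""
        p = midpoint_params
        dt = 0.05
        for v0, tau, target in [(0.0, p.tau_open, 1.0), (0.6, p.tau_close, 0.0)]:
            s = _cell_state(v0, 0.5)
            g0 = 0.5
            for k in range(1, 201):
                # hold the voltage fixed so the branch never switches
                s = SimulationState(v=np.full_like(s.v, v0), gate=s.gate, time=s.time)
                s = step_reaction(s, p, dt)
                exact = target + (g0 - target) * math.exp(-k * dt / tau)
                assert s.gate[0, 0] == pytest.approx(exact, rel=1e-12)

    def test_non_finite_state_reports_node_and_time(self, midpoint_params):
        s = _cell_state(np.nan, 1.0)
        s.time = 42.0
        with pytest.raises(FloatingPointError, match="node 0.*42"):
            step_reaction(s, midpoint_params, dt=0.1)


class TestDiffusion:
    def test_uniform_field_unchanged(self):
        grid = GridSpec(dimensionality=1, node_counts=(20,), dx=0.2)
        s = SimulationState(v=np.full((1, 20), 0.37), gate=np.ones((1, 20)))
        out = apply_diffusion(s, grid, D=0.2, dt=0.05)
        assert np.allclose(out.v, 0.37, atol=0.0)

    def test_two_node_no_flux_stencil(self):
        # lambda = D dt / dx^2 = 0.25: (1, 0) -> (0.75, 0.25), sum preserved
        grid = GridSpec(dimensionality=1, node_counts=(2,), dx=1.0)
        s = SimulationState(v=np.array([[1.0, 0.0]]), gate=np.ones((1, 2)))
        out = apply_diffusion(s, grid, D=0.25, dt=1.0)
        assert out.v == pytest.approx(np.array([[0.75, 0.25]]))
        assert out.v.sum() == pytest.approx(1.0, abs=0.0)

    def test_zero_diffusivity_is_identity(self):
        grid = GridSpec(dimensionality=1, node_counts=(5,), dx=0.2)
        v = np.random.default_rng(0).uniform(size=(1, 5))
        s = SimulationState(v=v.copy(), gate=np.ones((1, 5)))
        out = apply_diffusion(s, grid, D=0.0, dt=5.0)
        assert np.array_equal(out.v, v)

    @pytest.mark.parametrize("dimensionality", [1, 2])
    def test_sum_conserved_over_many_steps(self, dimensionality):
        """No-flux symmetric stencil keeps the voltage sum to <= 1e-9 drift."""
        rng = np.random.default_rng(1)
        if dimensionality == 1:
            grid = GridSpec(dimensionality=1, node_counts=(101,), dx=0.2)
            v = rng.uniform(size=(1, 101))
        else:
            grid = GridSpec(dimensionality=2, node_counts=(21, 21), dx=0.5)
            v = rng.uniform(size=(21, 21))
        s = SimulationState(v=v, gate=np.ones_like(v))
        total0 = s.v.sum()
        for _ in range(10_000):
            s = apply_diffusion(s, grid, D=0.2, dt=grid.max_stable_dt(0.2) * 0.9)
        assert abs(s.v.sum() - total0) / abs(total0) <= 1e-9

    def test_unstable_dt_refused_with_admissible_limit(self):
        grid = GridSpec(dimensionality=1, node_counts=(10,), dx=0.2)
        s = SimulationState(v=np.zeros((1, 10)), gate=np.ones((1, 10)))
        with pytest.raises(ValueError, match="0.05"):
            apply_diffusion(s, grid, D=0.4, dt=0.2)


class TestSimulate:
    def test_single_cell_action_potential_shape(self, midpoint_params, short_protocol):
        """One S1: the voltage fires above 0.75 and then recovers below 10%."""
        rec = simulate_cell(midpoint_params, short_protocol)
        v = rec.site_traces[0]
        assert v.max() > 0.75
        i_max = int(np.argmax(v))
        assert v[i_max:].min() < 0.1 * v.max()

    def test_s1_lat_increases_with_distance(self, midpoint_params, cable_grid, short_protocol):
        rec = simulate(midpoint_params, cable_grid, short_protocol)
        obs = build_observation(rec, types=("S1",), noise_sd=1.0)
        lats = obs.values
        assert obs.feasible
        assert np.all(np.diff(lats) > 0)

    def test_bit_identical_reruns(self, midpoint_params, cable_grid, short_protocol):
        a = simulate(midpoint_params, cable_grid, short_protocol)
        b = simulate(midpoint_params, cable_grid, short_protocol)
        assert np.array_equal(a.site_traces, b.site_traces)

    def test_cell_trace_independent_of_diffusivity(self, short_protocol):
        p1 = TissueParameters(0.3, 7.0, 140.0, 140.0, 0.05)
        p2 = TissueParameters(0.3, 7.0, 140.0, 140.0, 0.4)
        a = simulate_cell(p1, short_protocol)
        b = simulate_cell(p2, short_protocol)
        assert np.array_equal(a.site_traces, b.site_traces)

    def test_zero_stimulus_stays_at_rest(self, midpoint_params):
        proto = PacingProtocol(n_s1=1, stim_amplitude=0.0)
        rec = simulate_cell(midpoint_params, proto, tail=100.0)
        assert np.all(rec.site_traces == 0.0)

    def test_dt_refinement_changes_lat_less_than_sampling(self, midpoint_params, cable_grid, short_protocol):
        """Halving dt moves every S1 LAT by less than the sampling interval."""
        lats = []
        for dt in (0.05, 0.025):
            rec = simulate(midpoint_params, cable_grid, short_protocol, dt=dt, tail=300.0)
            obs = build_observation(rec, types=("S1",), noise_sd=1.0)
            lats.append(obs.values)
        assert np.all(np.abs(lats[0] - lats[1]) < rec.sampling_interval)

    def test_conduction_velocity_scales_as_sqrt_diffusivity(self, cable_grid, short_protocol):
        """Monodomain CV ~ sqrt(D): quadrupling D doubles CV within 5%."""

        def cv(D):
            p = TissueParameters(0.3, 7.0, 140.0, 140.0, D)
            rec = simulate(p, cable_grid, short_protocol, tail=300.0)
            obs = build_observation(rec, types=("S1",), noise_sd=1.0)
            x = np.array(rec.sites) * cable_grid.dx
            slope = np.polyfit(obs.values, x, 1)[0]
            return slope

        ratio = cv(0.2) / cv(0.05)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_fused_kernel_matches_split_operators(self, midpoint_params):
        """The JIT time loop equals reaction-then-diffusion composition."""
        grid = GridSpec(dimensionality=1, node_counts=(21,), dx=0.2)
        dt = 0.05
        stim_nodes = (0, 1)
        amp, t_off = 1.0, 2.0
        n_steps = 100
        rec, _ = run_stimuli(
            midpoint_params,
            grid,
            [StimulusWindow(0.0, t_off, stim_nodes, amp)],
            duration=n_steps * dt,
            dt=dt,
            sites=tuple(range(21)),
            sampling_interval=n_steps * dt,
        )
        s = SimulationState.resting(grid)
        stim_field = np.zeros((1, 21))
        stim_field[0, list(stim_nodes)] = amp
        for k in range(n_steps):
            active = (k * dt) < t_off
            s = step_reaction(s, midpoint_params, dt, stim_field if active else 0.0)
            s = apply_diffusion(s, grid, midpoint_params.diffusivity_D, dt)
        assert rec.site_traces[:, -1] == pytest.approx(s.v.ravel(), rel=1e-12, abs=1e-14)


class TestValidation:
    def test_parameter_positivity_enforced(self):
        with pytest.raises(ValueError, match="tau_out"):
            TissueParameters(0.3, -1.0, 140.0, 140.0, 0.2)

    def test_protocol_interval_ordering_enforced(self):
        with pytest.raises(ValueError, match="s1_interval"):
            PacingProtocol(s1_interval=400.0, s2_coupling=500.0)

    def test_stimulus_times_layout(self):
        proto = PacingProtocol()
        assert proto.stimulus_times == (0.0, 800.0, 1600.0, 2100.0)

    def test_grid_stability_bound(self):
        grid = default_cable_grid()
        assert grid.max_stable_dt(0.4) == pytest.approx(0.05)
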