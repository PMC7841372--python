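"""Unit and property tests for the core update rules."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pk_agents import (AgentState, NoiseDraws, SimulationConfig,
                       circular_mean_in_radius, heading_self, heading_update,
                       periodic_distance, position_update, simulate, step,
                       wrap_angle)
from conftest import run_from
from oracle import brute_force_periodic_distance, oracle_step, wrap as oracle_wrap

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

finite_angles = st.floats(-50.0, 50.0, allow_nan=False, allow_infinity=False)


class TestWrapAngle:
    @pytest.mark.parametrize("theta, expected", [
        (0.0, 0.0),
        (3 * math.pi / 2, -math.pi / 2),
        (-math.pi, math.pi),
        (math.pi, math.pi),
        (5 * math.pi, math.pi),
    ])
    def test_examples(self, theta, expected):
        assert wrap_angle(theta) == pytest.approx(expected, abs=1e-12)

    @given(finite_angles)
    def test_range_and_congruence(self, theta):
        w = wrap_angle(theta)
        assert -math.pi < w <= math.pi
        assert math.isclose(math.sin(w - theta), 0.0, abs_tol=1e-9)
        assert wrap_angle(w) == pytest.approx(w)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            wrap_angle(math.inf)


class TestHeadingSelf:
    @pytest.mark.parametrize("theta, xi2, p, expected", [
        (0.3, 0.0, 10.0, 0.3),
        (0.0, 0.5, 10.0, 0.05),
        (math.pi - 0.01, 0.5, 1.0, -(math.pi - 0.49)),
    ])
    def test_examples(self, theta, xi2, p, expected):
        assert heading_self(theta, xi2, p) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_skill_rejected(self):
        with pytest.raises(ValueError):
            heading_self(0.0, 0.1, 0.0)


class TestPeriodicDistance:
    @pytest.mark.parametrize("a, b, L, expected", [
        ((1.0, 1.0), (1.0, 1.0), 5.0, 0.0),
        ((0.1, 0.0), (4.9, 0.0), 5.0, 0.2),
        ((0.0, 0.0), (2.5, 2.5), 5.0, 2.5 * math.sqrt(2)),
    ])
    def test_examples(self, a, b, L, expected):
        assert periodic_distance(a, b, L) == pytest.approx(expected, abs=1e-12)

    @given(st.tuples(st.floats(0, 5, width=32), st.floats(0, 5, width=32)),
           st.tuples(st.floats(0, 5, width=32), st.floats(0, 5, width=32)))
    def test_matches_nine_image_brute_force(self, a, b):
        a = (min(a[0], np.nextafter(5.0, 0)), a[1])
        assert periodic_distance(a, b, 5.0) == pytest.approx(
            brute_force_periodic_distance(a, b, 5.0), abs=1e-9)
        assert periodic_distance(a, b, 5.0) <= 5.0 / math.sqrt(2) + 1e-9


class TestCircularMean:
    def _pair(self, pos_i, pos_j, th_i, th_j):
        return [AgentState(np.array(pos_i), th_i, 10.0),
                AgentState(np.array(pos_j), th_j, 10.0)]

    def test_symmetric_pair(self):
        states = self._pair((1, 1), (1.5, 1), 0.0, math.pi / 2)
        assert circular_mean_in_radius(states, 0, 1.0, 5.0) == pytest.approx(
            math.pi / 4)

    def test_mean_across_branch_cut(self):
        # headings pi-0.1 and -(pi-0.1): mean sine 0, mean cosine -cos(0.1),
        # so the circular mean is pi, not the scalar average 0.
        states = self._pair((1, 1), (1.5, 1), math.pi - 0.1, -math.pi + 0.1)
        assert circular_mean_in_radius(states, 0, 1.0, 5.0) == pytest.approx(
            math.pi)

    def test_out_of_radius_keeps_own_heading(self):
        states = self._pair((0.5, 0.5), (3.0, 3.0), 0.7, -2.0)
        assert circular_mean_in_radius(states, 0, 1.0, 5.0) == 0.7


class TestHeadingUpdate:
    def _draws(self, xi2=0.0, xi3=0.0):
        return NoiseDraws(xi1=np.zeros(2), xi2=xi2, xi3=xi3)

    def test_env_weight_zero_is_self_update(self):
        out = heading_update(0.4, 2.0, self._draws(), p=10.0, alpha=1.0,
                             beta=0.0)
        assert out == pytest.approx(0.4)

    def test_equal_weight_mix(self):
        out = heading_update(0.0, math.pi / 2, self._draws(), p=10.0,
                             alpha=0.5, beta=0.5)
        assert out == pytest.approx(math.pi / 4)

    def test_weighted_affine_form(self):
        # hand computation: 0.95*(0.2 + 0.5/100) + 0.05*(0.6 - 0.5/100)
        out = heading_update(0.2, 0.6, self._draws(xi2=0.5, xi3=-0.5),
                             p=100.0, alpha=0.95, beta=0.05)
        assert out == pytest.approx(0.22450, abs=1e-12)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            heading_update(0.0, 0.0, self._draws(), p=1.0, alpha=0.6, beta=0.5)

    def test_circular_mixing_equal_weights(self):
        out = heading_update(0.0, math.pi / 2, self._draws(), p=10.0,
                             alpha=0.5, beta=0.5, mixing="circular")
        assert out == pytest.approx(math.pi / 4)


class TestPositionUpdate:
    def test_straight_step(self):
        cfg = SimulationConfig()
        s = AgentState(np.zeros(2), 0.0, 10.0)
        assert position_update(s, 0.0, np.zeros(2), cfg) == pytest.approx(
            [0.05, 0.0])

    def test_periodic_wrap(self):
        cfg = SimulationConfig()
        s = AgentState(np.array([4.99, 2.0]), 0.0, 10.0)
        assert position_update(s, 0.0, np.zeros(2), cfg) == pytest.approx(
            [0.04, 2.0])

    def test_noise_divided_by_skill(self):
        cfg = SimulationConfig()
        s = AgentState(np.array([1.0, 1.0]), 0.0, 10.0)
        out = position_update(s, math.pi / 2, np.array([0.5, -0.5]), cfg)
        assert out == pytest.approx([1.05, 1.0], abs=1e-12)


class TestStep:
    def test_noise_free_straight_line(self):
        cfg = SimulationConfig(xi=0.0, n_agents=1, p=(10.0,))
        states = [AgentState(np.array([1.0, 1.0]), 0.7, 10.0)]
        rng = np.random.default_rng(0)
        for _ in range(5):
            states = step(states, cfg, rng)
        assert states[0].heading == 0.7
        expected = np.array([1.0, 1.0]) + 5 * 0.05 * np.array(
            [math.cos(0.7), math.sin(0.7)])
        assert states[0].position == pytest.approx(expected, abs=1e-12)

    def test_alignment_fixed_point(self):
        cfg = SimulationConfig(xi=0.0, n_agents=2, p=(10.0, 10.0),
                               social_enabled=True)
        states = [AgentState(np.array([1.0, 1.0]), 0.0, 10.0),
                  AgentState(np.array([1.5, 1.0]), math.pi / 2, 10.0)]
        new = step(states, cfg, np.random.default_rng(0))
        assert [s.heading for s in new] == pytest.approx(
            [math.pi / 4, math.pi / 4])

    @pytest.mark.parametrize("cfg_kwargs", [
        dict(n_agents=1, p=(5.0,)),
        dict(n_agents=2, p=(5.0, 50.0), social_enabled=True),
        dict(n_agents=2, p=(1.0, 100.0), social_enabled=True,
             env_enabled=True, alpha=0.5, beta=0.5),
        dict(n_agents=2, p=(10.0, 10.0), social_enabled=True,
             env_enabled=True, alpha=0.95, beta=0.05,
             angle_mixing="circular"),
    ])
    def test_matches_scalar_oracle(self, cfg_kwargs):
        """The vectorized stepper reproduces a naive per-agent pure-Python
        loop fed the identical noise draws, over a multi-step rollout."""
        cfg = SimulationConfig(n_steps=40, seed=123, **cfg_kwargs)
        traj = simulate(cfg)
        # replay the generator: init conditions, then the per-run noise block
        rng = np.random.default_rng(cfg.seed)
        rng.uniform(0.0, cfg.L, size=(cfg.n_agents, 2))
        rng.uniform(-math.pi, math.pi, size=cfg.n_agents)
        noise = rng.uniform(-cfg.xi, cfg.xi, size=(cfg.n_steps,
                                                   cfg.n_agents, 4))
        pos = [tuple(xy) for xy in traj.positions[0]]
        head = list(traj.headings[0])
        for t in range(cfg.n_steps):
            pos, head = oracle_step(pos, head, cfg.p, noise[t], cfg)
            assert traj.positions[t + 1] == pytest.approx(np.array(pos),
                                                          abs=1e-10)
            assert traj.headings[t + 1] == pytest.approx(np.array(head),
                                                         abs=1e-10)


class TestSimulate:
    def test_zero_steps_returns_initial_snapshot(self):
        traj = simulate(SimulationConfig(n_steps=0, seed=5))
        assert traj.positions.shape == (1, 1, 2)

    def test_bitwise_deterministic(self, two_agent_cfg):
        a, b = simulate(two_agent_cfg), simulate(two_agent_cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.headings, b.headings)

    def test_step_by_step_replay_matches(self, two_agent_cfg):
        """Pre-drawn noise block == sequential per-step draws from the same
        generator, so driving step() manually reproduces simulate()."""
        traj = simulate(two_agent_cfg)
        rng = np.random.default_rng(two_agent_cfg.seed)
        states = [AgentState(p, h, two_agent_cfg.p[i]) for i, (p, h) in
                  enumerate(zip(traj.positions[0].copy(), traj.headings[0]))]
        # consume the init draws exactly as simulate() does
        rng2 = np.random.default_rng(two_agent_cfg.seed)
        rng2.uniform(0.0, two_agent_cfg.L, size=(2, 2))
        rng2.uniform(-math.pi, math.pi, size=2)
        for t in range(two_agent_cfg.n_steps):
            states = step(states, two_agent_cfg, rng2)
        assert traj.positions[-1] == pytest.approx(
            np.stack([s.position for s in states]), abs=0)

    @pytest.mark.parametrize("cfg_kwargs", [
        dict(n_agents=1, p=(1.0,), xi=5.0),
        dict(n_agents=2, p=(2.0, 80.0), social_enabled=True,
             env_enabled=True, alpha=0.5, beta=0.5, xi=2.5),
    ])
    def test_state_invariants_hold_along_trajectory(self, cfg_kwargs):
        traj = simulate(SimulationConfig(n_steps=300, seed=9, **cfg_kwargs))
        assert np.all(traj.positions >= 0.0)
        assert np.all(traj.positions < traj.config.L)
        assert np.all(traj.headings > -math.pi)
        assert np.all(traj.headings <= math.pi)

    def test_increment_std_matches_uniform_law(self):
        # std of uniform(-xi/p, xi/p) is xi/(p*sqrt(3)); pool >= 1e4 draws
        cfg = SimulationConfig(n_agents=1, p=(100.0,), xi=0.5, n_steps=2500)
        incs = np.concatenate([
            simulate(cfg.replace(seed=s)).heading_increments().ravel()
            for s in range(5)])
        assert incs.size >= 10_000
        expected = 0.5 / (100.0 * math.sqrt(3))
        assert np.std(incs, ddof=1) == pytest.approx(expected, rel=0.05)

    def test_jitter_decreases_with_skill(self):
        stds = []
        for p in (1.0, 10.0, 100.0):
            cfg = SimulationConfig(n_agents=1, p=(p,), xi=0.5, n_steps=500,
                                   seed=11)
            stds.append(float(np.std(simulate(cfg).heading_increments())))
        assert stds[0] > stds[1] > stds[2]


def test_heading_diffusion_law():
    """Self-only headings diffuse: Var[theta(t)-theta(0)] = t*xi^2/(3p^2)."""
    t, xi, p, n_runs = 100, 0.5, 5.0, 400
    cfg = SimulationConfig(n_agents=1, p=(p,), xi=xi, n_steps=t)
    disp = np.array([
        simulate(cfg.replace(seed=s)).heading_increments().sum()
        for s in range(n_runs)])
    expected = t * xi ** 2 / (3 * p ** 2)
    assert disp.var(ddof=1) == pytest.approx(expected, rel=0.10)
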