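"""Sampler tests: Boltzmann statistics, determinism, cross-evaluation and
statistical-inefficiency estimation."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import cgfep as cg
from cgfep.model import AlchemicalState, ThermoConditions
from cgfep.sampler import (
    EnergyMatrix,
    SamplerConfig,
    cross_evaluate,
    decorrelate,
    sample,
    statistical_inefficiency,
    subsample_trajectory,
)


@pytest.fixture(scope="module")
def dimer():
    return cg.make_toy("harmonic_dimer", {"k1": 1.0, "k2": 4.0, "kT": 1.0}, seed=7)


class TestSample:
    def test_zero_temperature_limit_concentrates_at_minimum(self, dimer):
        cold = dataclasses.replace(
            dimer.sampler,
            conditions=ThermoConditions.from_kT(1e-6),
            max_displacement=0.05,
            n_steps=5000,
        )
        traj = sample(dimer.system, dimer.topology, dimer.schedule[0], (), cold)
        x = traj.frames[:, 1, 0]
        # bond r0 = 0: positions collapse onto the minimum
        assert np.abs(x[-100:]).max() < 0.02

    def test_equipartition_variance(self, dimer):
        cfg = dataclasses.replace(dimer.sampler, n_steps=50_000, seed=11)
        traj = sample(dimer.system, dimer.topology, dimer.schedule[0], (), cfg)
        x = traj.frames[:, 1, 0]
        g, idx = decorrelate(x)
        xs = x[idx]
        var = xs.var(ddof=1)
        se = var * np.sqrt(2.0 / (len(xs) - 1))  # SE of a Gaussian variance
        assert abs(var - 1.0) < 3 * se  # kT/k = 1

    def test_boltzmann_distribution_kolmogorov_smirnov(self, dimer):
        cfg = dataclasses.replace(dimer.sampler, n_steps=50_000, seed=13)
        traj = sample(dimer.system, dimer.topology, dimer.schedule[0], (), cfg)
        x = traj.frames[:, 1, 0]
        _, idx = decorrelate(x)
        d, p = stats.kstest(x[idx], "norm", args=(0.0, 1.0))
        assert d < 0.05
        assert p > 1e-4

    def test_same_seed_bitwise_identical(self, dimer):
        t1 = sample(dimer.system, dimer.topology, dimer.schedule[1], (), dimer.sampler)
        t2 = sample(dimer.system, dimer.topology, dimer.schedule[1], (), dimer.sampler)
        assert np.array_equal(t1.frames, t2.frames)
        assert np.array_equal(t1.potentials, t2.potentials)

    def test_acceptance_rate_reported_and_reasonable(self, dimer):
        traj = sample(dimer.system, dimer.topology, dimer.schedule[0], (), dimer.sampler)
        assert 0.2 < traj.acceptance_rate < 0.95

    def test_no_mobile_beads_rejected(self, dimer):
        cfg = dataclasses.replace(dimer.sampler, mobile_set=())
        with pytest.raises(ValueError, match="mobile"):
            sample(dimer.system, dimer.topology, dimer.schedule[0], (), cfg)


class TestCrossEvaluate:
    def test_own_state_row_reproduces_recorded_potentials_exactly(self, dimer):
        cfg = dataclasses.replace(dimer.sampler, n_steps=2000)
        trajs = [
            sample(dimer.system, dimer.topology, s, (), dataclasses.replace(cfg, seed=i))
            for i, s in enumerate(dimer.schedule)
        ]
        m = cross_evaluate(
            dimer.system, dimer.topology, trajs, dimer.schedule, (), dimer.conditions
        )
        for k, t in enumerate(trajs):
            sl = m.state_slice(k)
            assert np.array_equal(m.u_kn[k, sl], t.potentials)

    def test_identical_states_give_identical_rows(self, dimer):
        states = (
            AlchemicalState(0.0, 0.0, 0),
            AlchemicalState(1.0, 1.0, 1),
        )
        # duplicate lambda pair: build two states with the same lambdas
        dup = (states[0], AlchemicalState(0.0, 0.0, 1))
        cfg = dataclasses.replace(dimer.sampler, n_steps=1000)
        traj = sample(dimer.system, dimer.topology, dup[0], (), cfg)
        m = cross_evaluate(
            dimer.system, dimer.topology, [traj], dup, (), dimer.conditions
        )
        assert np.array_equal(m.u_kn[0], m.u_kn[1])

    def test_single_state_matrix_equals_recorded_series(self, dimer):
        # degenerate single-window case
        st = (dimer.schedule[0],)
        cfg = dataclasses.replace(dimer.sampler, n_steps=1000)
        traj = sample(dimer.system, dimer.topology, st[0], (), cfg)
        m = cross_evaluate(dimer.system, dimer.topology, [traj], st, (), dimer.conditions)
        assert np.array_equal(m.u_kn[0], traj.potentials)

    def test_unknown_trajectory_state_rejected(self, dimer):
        cfg = dataclasses.replace(dimer.sampler, n_steps=500)
        traj = sample(
            dimer.system, dimer.topology, AlchemicalState(1.0, 0.25), (), cfg
        )
        with pytest.raises(ValueError, match="not among"):
            cross_evaluate(
                dimer.system, dimer.topology, [traj], dimer.schedule, (),
                dimer.conditions,
            )

    def test_discrete_enumeration_matches_hand_table(self):
        """The exhaustively weighted matrix equals the hand-computed table."""
        fx = cg.make_toy("discrete_two_state")
        m = fx.extras["exhaustive_matrix"]()
        # columns: A-draws (configs 1,2), then B-draws (configs 1,2)
        expect = np.array([[0.0, 1.0, 0.0, 1.0], [2.0, 2.0, 2.0, 2.0]])
        assert np.array_equal(m.u_kn, expect)
        ZA, ZB = fx.reference["Z_A"], fx.reference["Z_B"]
        expect_w = np.array(
            [1 / ZA, np.exp(-1) / ZA, np.exp(-2) / ZB, np.exp(-2) / ZB]
        )
        assert np.allclose(m.weights, expect_w, rtol=1e-14)


class TestDecorrelate:
    def test_white_noise_inefficiency_near_one(self, rng):
        x = rng.standard_normal(100_000)
        g = statistical_inefficiency(x)
        assert g == pytest.approx(1.0, abs=0.1)

    def test_ar1_closed_form(self, rng):
        rho = 0.5
        n = 100_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        g = statistical_inefficiency(x)
        assert g == pytest.approx((1 + rho) / (1 - rho), rel=0.15)

    def test_constant_length_two_series(self):
        with pytest.warns(UserWarning, match="constant"):
            g, idx = decorrelate(np.array([3.0, 3.0]))
        assert g == 1.0
        assert idx.tolist() == [0, 1]

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            statistical_inefficiency(np.array([1.0]))

    def test_subsample_trajectory_strides_frames(self, dimer):
        cfg = dataclasses.replace(dimer.sampler, n_steps=5000)
        traj = sample(dimer.system, dimer.topology, dimer.schedule[0], (), cfg)
        sub = subsample_trajectory(traj)
        assert sub.n_frames <= traj.n_frames
        assert np.array_equal(sub.frames[0], traj.frames[0])


class TestEnergyMatrixContainer:
    def test_counts_must_sum_to_samples(self):
        with pytest.raises(ValueError, match="sum of N_k"):
            EnergyMatrix(u_kn=np.zeros((2, 3)), N_k=np.array([1, 1]))

    def test_nonfinite_rejected(self):
        u = np.zeros((2, 2))
        u[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            EnergyMatrix(u_kn=u, N_k=np.array([1, 1]))
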