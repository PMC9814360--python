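"""Estimator tests against exact oracles: exhaustive partition functions,
Gaussian closed forms, and cross-estimator consistency."""

import dataclasses

import numpy as np
import pytest

import cgfep as cg
from cgfep.estimators import (
    bar,
    bayesian_bootstrap_pmf,
    convergence_series,
    exp_free_energy,
    mbar,
    overlap_matrix,
    ti_free_energy,
    ti_from_matrix,
    wham,
)
from cgfep.sampler import EnergyMatrix, cross_evaluate, sample, subsample_trajectory


@pytest.fixture(scope="module")
def discrete():
    return cg.make_toy("discrete_two_state")


@pytest.fixture(scope="module")
def harmonic_matrix():
    """Sampled energy matrix for the k: 1 -> 4 spring transformation."""
    fx = cg.make_toy("harmonic_dimer", seed=21)
    trajs = []
    for i, st in enumerate(fx.schedule):
        cfg = dataclasses.replace(fx.sampler, n_steps=30_000, seed=100 + i)
        trajs.append(
            subsample_trajectory(sample(fx.system, fx.topology, st, (), cfg))
        )
    m = cross_evaluate(fx.system, fx.topology, trajs, fx.schedule, (), fx.conditions)
    return fx, m


class TestExp:
    def test_zero_differences(self):
        assert exp_free_energy(np.zeros(10)).value == 0.0

    def test_constant_shift(self):
        est = exp_free_energy(np.full(50, 2.5), kT=2.0)
        assert est.value == pytest.approx(5.0)

    def test_gaussian_cumulant_closed_form(self, rng):
        mu, sd = 1.5, 1.0
        du = rng.normal(mu, sd, size=100_000)
        est = exp_free_energy(du)
        # second-order cumulant expansion is exact for a Gaussian
        assert est.value == pytest.approx(mu - sd**2 / 2, abs=3 * max(est.se, 0.01))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            exp_free_energy([])


class TestBar:
    def test_identical_distributions_zero(self, rng):
        du = np.zeros(100)
        est = bar(du, du)
        assert est.value == pytest.approx(0.0, abs=1e-10)

    def test_discrete_exhaustive_weighting_exact(self, discrete):
        uA, uB = discrete.extras["u_A"], discrete.extras["u_B"]
        ZA, ZB = discrete.reference["Z_A"], discrete.reference["Z_B"]
        est = bar(
            uB - uA, uA - uB,
            weights_forward=np.exp(-uA) / ZA,
            weights_reverse=np.exp(-uB) / ZB,
        )
        assert est.value == pytest.approx(discrete.reference["delta_f_kT"], abs=1e-6)

    def test_agrees_with_mbar_on_two_states(self, discrete):
        m = discrete.extras["sampled_matrix"](4000, 3)
        res = mbar(m, tol=1e-12)
        sl0, sl1 = m.state_slice(0), m.state_slice(1)
        est = bar(
            m.u_kn[1, sl0] - m.u_kn[0, sl0],
            m.u_kn[0, sl1] - m.u_kn[1, sl1],
            tol=1e-14,
        )
        # BAR and two-state MBAR solve the same maximum-likelihood equations
        assert est.value == pytest.approx(res.delta_f, abs=1e-8)

    def test_degenerate_overlap_flagged(self):
        est = bar(np.full(10, 1e4), np.full(10, 1e4))
        assert not est.converged


class TestMbar:
    def test_identical_states_give_zero_free_energies(self, rng):
        u = rng.standard_normal(200)
        m = EnergyMatrix(u_kn=np.vstack([u, u, u]), N_k=np.array([100, 50, 50]))
        res = mbar(m)
        assert np.allclose(res.f_k, 0.0, atol=1e-10)

    def test_discrete_two_state_partition_functions(self, discrete):
        """MBAR on exhaustively weighted samples matches ln(Z_A/Z_B) ~ 1.6201."""
        m = discrete.extras["exhaustive_matrix"]()
        res = mbar(m)
        assert res.converged
        assert res.delta_f == pytest.approx(1.6201, abs=1e-4)
        assert res.delta_f == pytest.approx(discrete.reference["delta_f_kT"], abs=1e-6)

    def test_harmonic_spring_ratio(self, harmonic_matrix):
        """Gaussian partition function: delta_f = 0.5 ln(k2/k1) = 0.5 ln 4."""
        fx, m = harmonic_matrix
        res = mbar(m)
        ref = fx.reference["delta_f_kT"]
        assert res.delta_f == pytest.approx(ref, abs=3 * res.delta_f_se())

    def test_row_shift_invariance(self, discrete):
        m = discrete.extras["sampled_matrix"](2000, 5)
        res1 = mbar(m)
        shifted = EnergyMatrix(
            u_kn=m.u_kn + 7.3, N_k=m.N_k, states=m.states
        )
        res2 = mbar(shifted)
        assert res1.delta_f == pytest.approx(res2.delta_f, abs=1e-9)

    def test_nan_energies_rejected(self):
        u = np.zeros((2, 4))
        m = EnergyMatrix(u_kn=u, N_k=np.array([2, 2]))
        m.u_kn[0, 0] = np.nan
        with pytest.raises(ValueError):
            mbar(m)

    def test_single_state_rejected(self):
        m = EnergyMatrix(u_kn=np.zeros((1, 4)), N_k=np.array([4]))
        with pytest.raises(ValueError):
            mbar(m)


class TestTi:
    def test_zero_derivatives(self):
        assert ti_free_energy([0, 0.5, 1], [0, 0, 0]).value == 0.0

    def test_trapezoid_exact_for_linear_integrand(self):
        a, b = 2.0, 6.0
        lam = np.linspace(0, 1, 5)
        dudl = a + (b - a) * lam
        assert ti_free_energy(lam, dudl).value == pytest.approx((a + b) / 2)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            ti_free_energy([0.5], [1.0])

    def test_agrees_with_mbar_on_harmonic_path(self, harmonic_matrix):
        # u is linear in lambda for the interpolated spring, so the
        # central-difference TI derivative is exact per sample
        fx, m = harmonic_matrix
        res = mbar(m)
        est = ti_from_matrix(m)
        tol = 3 * np.hypot(est.se, res.delta_f_se())
        assert est.value == pytest.approx(res.delta_f, abs=max(tol, 0.02))


class TestOverlap:
    def test_rows_sum_to_one(self, harmonic_matrix):
        _, m = harmonic_matrix
        O = overlap_matrix(m)
        assert np.allclose(O.sum(axis=1), 1.0, atol=1e-10)

    def test_identical_states_equal_counts_uniform(self, rng):
        u = rng.standard_normal(300)
        m = EnergyMatrix(u_kn=np.vstack([u, u, u]), N_k=np.array([100, 100, 100]))
        O = overlap_matrix(m)
        assert np.allclose(O, 1.0 / 3.0, atol=1e-10)

    def test_disjoint_states_have_no_overlap(self):
        # state 0 samples have huge energy in state 1 and vice versa
        n = 50
        u0 = np.concatenate([np.zeros(n), np.full(n, 500.0)])
        u1 = np.concatenate([np.full(n, 500.0), np.zeros(n)])
        m = EnergyMatrix(u_kn=np.vstack([u0, u1]), N_k=np.array([n, n]))
        O = overlap_matrix(m)
        assert O[0, 1] < 1e-8 and O[1, 0] < 1e-8


class TestConvergenceSeries:
    def test_full_fraction_equals_full_estimate(self, discrete):
        m = discrete.extras["sampled_matrix"](2000, 9)
        full = mbar(m).delta_f
        rows = convergence_series(m, [0.5, 1.0])
        assert rows[-1]["forward"] == pytest.approx(full, abs=1e-9)
        assert rows[-1]["reverse"] == pytest.approx(full, abs=1e-9)

    def test_stationary_forward_reverse_agreement(self, discrete):
        m = discrete.extras["sampled_matrix"](4000, 11)
        for row in convergence_series(m, [0.5, 0.75, 1.0]):
            assert row["ok"]
            tol = 3 * np.hypot(row["forward_se"], row["reverse_se"])
            assert abs(row["forward"] - row["reverse"]) <= max(tol, 1e-9)

    def test_invalid_fractions_rejected(self, discrete):
        m = discrete.extras["sampled_matrix"](100, 1)
        with pytest.raises(ValueError):
            convergence_series(m, [0.8, 0.2])

    def test_tiny_fraction_flagged(self, discrete):
        m = discrete.extras["sampled_matrix"](100, 1)
        rows = convergence_series(m, [0.001, 1.0])
        assert not rows[0]["ok"] and np.isnan(rows[0]["forward"])


class TestWham:
    KU = 1000.0  # kJ/mol/nm^2 umbrella force constant

    def _harmonic_windows(self, K, x0, kT, rng, n=3000):
        centers = np.arange(0.5, 1.52, 0.02)  # 0.2 Angstrom spacing in nm
        samples = []
        for c in centers:
            ktot = K + self.KU
            mu = (K * x0 + self.KU * c) / ktot
            sd = np.sqrt(kT / ktot)
            samples.append(mu + sd * rng.standard_normal(n))
        return centers, samples

    def test_flat_landscape_recovers_flat_profile(self, rng):
        kT = 1.0
        centers = np.arange(0.5, 1.51, 0.02)
        samples = [
            c + np.sqrt(kT / self.KU) * rng.standard_normal(4000) for c in centers
        ]
        grid = np.arange(0.55, 1.451, 0.02)
        prof = wham(samples, centers, self.KU, grid, kT=kT)
        assert prof.converged
        assert prof.pmf.min() == 0.0
        assert np.nanmax(prof.pmf[np.isfinite(prof.pmf)]) < 0.15

    def test_harmonic_landscape_recovery(self, rng):
        K, x0, kT = 20.0, 1.0, 1.0
        centers, samples = self._harmonic_windows(K, x0, kT, rng)
        grid = np.arange(0.6, 1.401, 0.02)
        prof = wham(samples, centers, self.KU, grid, kT=kT)
        ref = 0.5 * K * (grid - x0) ** 2
        ref -= ref.min()
        well = np.abs(grid - x0) < 0.3
        rms = np.sqrt(np.mean((prof.pmf[well] - ref[well]) ** 2))
        assert rms < 0.1  # kT

    def test_minimum_anchored_to_zero_exactly(self, rng):
        K, x0, kT = 20.0, 1.0, 1.0
        centers, samples = self._harmonic_windows(K, x0, kT, rng, n=500)
        grid = np.arange(0.6, 1.401, 0.02)
        prof = wham(samples, centers, self.KU, grid, kT=kT)
        assert prof.pmf.min() == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            wham([np.array([]), np.ones(5)], [0.0, 1.0], 100.0, np.linspace(0, 1, 5))

    def test_non_overlapping_windows_flagged(self):
        s = [np.full(100, 0.0) + 1e-3, np.full(100, 5.0) - 1e-3]
        with pytest.warns(UserWarning, match="non-overlapping"):
            prof = wham(s, [0.0, 5.0], 1000.0, np.linspace(-0.5, 5.5, 61))
        assert not prof.overlap_ok

    def test_zero_umbrella_reduces_to_histogram_inversion(self, rng):
        # all umbrella constants 0: WHAM must reproduce -kT ln(histogram)
        samples = [rng.normal(1.0, 0.2, 5000), rng.normal(1.0, 0.2, 5000)]
        grid = np.arange(0.5, 1.51, 0.05)
        prof = wham(samples, [0.8, 1.2], 0.0, grid, kT=1.0)
        pooled = np.concatenate(samples)
        dx = 0.05
        edges = np.concatenate([grid - dx / 2, [grid[-1] + dx / 2]])
        hist, _ = np.histogram(pooled, bins=edges)
        with np.errstate(divide="ignore"):
            ref = -np.log(hist / hist.sum())
        ref -= ref[np.isfinite(ref)].min()
        finite = np.isfinite(ref) & np.isfinite(prof.pmf)
        assert np.allclose(prof.pmf[finite], ref[finite], atol=1e-6)


class TestBayesianBootstrap:
    def test_duplicated_windows_give_small_se(self, rng):
        base = rng.normal(1.0, 0.05, 2000)
        samples = [base.copy() for _ in range(6)]
        centers = [1.0] * 6
        grid = np.arange(0.85, 1.151, 0.02)
        se = bayesian_bootstrap_pmf(samples, centers, 100.0, grid, n_rounds=30, seed=4)
        assert np.nanmax(se) < 1e-8  # identical windows: reweighting changes nothing

    def test_seed_reproducibility(self, rng):
        centers = np.arange(0.8, 1.21, 0.05)
        samples = [c + 0.05 * rng.standard_normal(500) for c in centers]
        grid = np.arange(0.85, 1.151, 0.02)
        kw = dict(n_rounds=25, seed=42)
        se1 = bayesian_bootstrap_pmf(samples, centers, 1000.0, grid, **kw)
        se2 = bayesian_bootstrap_pmf(samples, centers, 1000.0, grid, **kw)
        assert np.array_equal(se1, se2)

    def test_single_round_rejected(self, rng):
        with pytest.raises(ValueError):
            bayesian_bootstrap_pmf(
                [np.ones(5), np.ones(5)], [1.0, 1.0], 10.0,
                np.linspace(0, 2, 5), n_rounds=1,
            )
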