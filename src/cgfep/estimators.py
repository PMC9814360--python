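"""Free-energy estimators and diagnostics.

Implements the standard alchemical estimator family on a reduced-energy
matrix ``u_kn``:

* ``exp_free_energy`` — one-sided exponential (Zwanzig) averaging;
* ``bar`` — the Bennett acceptance ratio, the statistically optimal
  two-state estimator, solved self-consistently;
* ``mbar`` — the multistate Bennett acceptance ratio, solved by
  self-consistent iteration of the coupled equations

  ``f_k = -ln sum_n exp(-u_kn) / sum_j N_j exp(f_j - u_jn)``

  with free energies anchored to ``f_0 = 0``;
* ``ti_free_energy`` — thermodynamic integration by trapezoidal quadrature;
* ``overlap_matrix`` and ``convergence_series`` — the usual phase-space
  overlap and forward/reverse time-slicing diagnostics;
* ``wham`` / ``bayesian_bootstrap_pmf`` — the weighted histogram analysis
  method for umbrella-sampling PMFs, with Dirichlet-weighted (Bayesian)
  bootstrap uncertainties.

``exp_free_energy``, ``bar`` and ``mbar`` accept optional per-sample weights
so that discrete toy systems can be fed *exhaustively* Boltzmann-weighted
configurations, in which case the estimators reproduce exact
partition-function ratios (the package's primary correctness oracle).

Uncertainties returned here are asymptotic, per single data set; replica
scatter (SEM across independent repeats) is handled by :mod:`cgfep.cycles`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .sampler import EnergyMatrix

__all__ = [
    "Estimate",
    "FreeEnergyResult",
    "PMFProfile",
    "exp_free_energy",
    "bar",
    "mbar",
    "ti_free_energy",
    "overlap_matrix",
    "convergence_series",
    "wham",
    "bayesian_bootstrap_pmf",
]


@dataclass
class Estimate:
    """A scalar free-energy estimate with its asymptotic standard error."""

    value: float
    se: float
    method: str
    converged: bool = True


@dataclass
class FreeEnergyResult:
    """Per-state reduced free energies from MBAR.

    ``f_k`` are in kT with ``f_k[0] = 0``; ``theta`` is the asymptotic
    covariance of ``f_k`` (gauge-fixed by the pseudo-inverse, so differences
    ``f_k - f_0`` have variance ``theta_kk + theta_00 - 2 theta_k0``).
    """

    f_k: np.ndarray
    theta: np.ndarray
    kT: float
    method: str = "mbar"
    converged: bool = True
    n_iter: int = 0

    @property
    def delta_f(self) -> float:
        """End-to-end reduced free-energy difference f_K-1 - f_0 (kT)."""
        return float(self.f_k[-1] - self.f_k[0])

    def delta_f_se(self, k: int = -1, ref: int = 0) -> float:
        """Asymptotic SE of ``f_k - f_ref`` in kT."""
        t = self.theta
        k = range(len(self.f_k))[k]
        var = t[k, k] + t[ref, ref] - 2.0 * t[k, ref]
        return float(np.sqrt(max(var, 0.0)))

    @property
    def delta_G(self) -> float:
        """End-to-end free-energy difference in energy units (f * kT)."""
        return self.delta_f * self.kT

    @property
    def delta_G_se(self) -> float:
        return self.delta_f_se() * self.kT


@dataclass
class PMFProfile:
    """A one-dimensional potential of mean force on a reaction-coordinate grid.

    The profile is anchored so its minimum is exactly zero.
    """

    grid: np.ndarray  # bin centers, nm
    pmf: np.ndarray  # kJ/mol
    se: np.ndarray | None = None  # bootstrap SE, kJ/mol
    kT: float = 1.0
    converged: bool = True
    overlap_ok: bool = True

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.pmf = np.asarray(self.pmf, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")


# ---------------------------------------------------------------------------
# Scalar estimators
# ---------------------------------------------------------------------------


def _norm_weights(n: int, weights) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be nonnegative with positive sum")
    return w


def exp_free_energy(delta_u, kT: float = 1.0, weights=None) -> Estimate:
    """Exponential (Zwanzig) estimate ``-kT ln < exp(-delta_u) >``.

    ``delta_u`` are forward reduced-energy differences (kT units); the result
    is in the units of ``kT``.  The SE comes from the delta method and
    assumes uncorrelated samples (decorrelate first).
    """
    du = np.asarray(delta_u, dtype=float)
    if du.size == 0:
        raise ValueError("delta_u must be nonempty")
    w = _norm_weights(du.size, weights)
    logmean = logsumexp(-du, b=w) - np.log(w.sum())
    value = -kT * float(logmean)
    x = np.exp(-du - logmean)  # e^{-du} / mean, scale-free
    mean_x = float(np.average(x, weights=w))
    var_x = float(np.average((x - mean_x) ** 2, weights=w))
    n_eff = w.sum() ** 2 / np.sum(w**2)
    se = kT * np.sqrt(var_x / n_eff) / mean_x
    return Estimate(value=value, se=float(se), method="exp")


def bar(
    delta_u_forward,
    delta_u_reverse,
    kT: float = 1.0,
    tol: float = 1e-12,
    weights_forward=None,
    weights_reverse=None,
) -> Estimate:
    """Bennett acceptance-ratio estimate between two states.

    ``delta_u_forward`` holds ``u_1(x) - u_0(x)`` for samples from state 0,
    ``delta_u_reverse`` holds ``u_0(x) - u_1(x)`` for samples from state 1
    (both reduced).  Solves the self-consistent Bennett equation for the
    reduced free-energy difference and reports the standard asymptotic SE.
    Degenerate overlap (no root) is flagged ``converged=False``.
    """
    duF = np.asarray(delta_u_forward, dtype=float)
    duR = np.asarray(delta_u_reverse, dtype=float)
    if duF.size == 0 or duR.size == 0:
        raise ValueError("both directions need at least one sample")
    wF = _norm_weights(duF.size, weights_forward)
    wR = _norm_weights(duR.size, weights_reverse)
    nF, nR = wF.sum(), wR.sum()
    M = np.log(nF / nR)

    def fermi_log(x):
        # log(1/(1+e^x)) computed stably
        return -np.logaddexp(0.0, x)

    def g(df):
        lhs = logsumexp(fermi_log(M + duF - df), b=wF)
        rhs = logsumexp(fermi_log(-M + duR + df), b=wR)
        return lhs - rhs

    lo = min(float(-np.max(duR)), float(np.min(duF))) - 50.0
    hi = max(float(np.max(duF)), float(-np.min(duR))) + 50.0
    try:
        if g(lo) * g(hi) > 0:
            raise ValueError("no bracket")
        df = brentq(g, lo, hi, xtol=tol)
        converged = True
    except ValueError:
        warnings.warn("BAR: degenerate overlap between states; estimate unconverged")
        df = float(-(logsumexp(-duF, b=wF) - np.log(nF)))
        return Estimate(value=kT * df, se=float("inf"), method="bar", converged=False)

    # Standard asymptotic variance (log-space Fermi means for stability).
    log_fF = fermi_log(M + duF - df)
    log_fR = fermi_log(-M + duR + df)
    log_mF = logsumexp(log_fF, b=wF) - np.log(nF)
    log_mR = logsumexp(log_fR, b=wR) - np.log(nR)
    vF = np.exp(logsumexp(2 * log_fF, b=wF) - np.log(nF) - 2 * log_mF) - 1.0
    vR = np.exp(logsumexp(2 * log_fR, b=wR) - np.log(nR) - 2 * log_mR) - 1.0
    var = vF / nF + vR / nR
    # Degenerate overlap: the expected acceptance weight is vanishingly
    # small in either direction, so the root is numerical, not statistical.
    degenerate = (log_mF + np.log(nF) < np.log(1e-6)) or (
        log_mR + np.log(nR) < np.log(1e-6)
    )
    if degenerate or not np.isfinite(var):
        warnings.warn("BAR: degenerate overlap between states; estimate unconverged")
        return Estimate(value=kT * float(df), se=float("inf"), method="bar", converged=False)
    return Estimate(value=kT * float(df), se=kT * float(np.sqrt(max(var, 0.0))), method="bar")


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------


def mbar(
    matrix: EnergyMatrix,
    tol: float = 1e-8,
    max_iter: int = 10000,
    kT: float = 1.0,
    initial_f_k: np.ndarray | None = None,
) -> FreeEnergyResult:
    """Solve the MBAR self-consistent equations on a reduced-energy matrix.

    Per-sample weights on ``matrix.weights`` (if present) generalize the sums
    over samples to weighted sums; feeding exhaustively Boltzmann-weighted
    configurations then recovers exact partition-function ratios.

    Returns free energies anchored to ``f_0 = 0``, their asymptotic
    covariance (pseudo-inverse of the Fisher information of the equivalent
    multinomial-logistic model), and a convergence flag.
    """
    u_kn = matrix.u_kn
    if not np.all(np.isfinite(u_kn)):
        raise ValueError("u_kn contains NaN or infinite energies")
    K, N = u_kn.shape
    if K < 2:
        raise ValueError("MBAR requires at least two states")
    N_k = np.asarray(matrix.N_k, dtype=float)
    if np.sum(N_k > 0) < 2:
        raise ValueError("at least two states must have samples")
    w = _norm_weights(N, matrix.weights)
    log_w = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)

    sampled = N_k > 0
    log_N = np.full(K, -np.inf)
    log_N[sampled] = np.log(N_k[sampled])

    f_k = np.zeros(K) if initial_f_k is None else np.array(initial_f_k, dtype=float)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # log denominator per sample: logsumexp_j [ln N_j + f_j - u_jn]
        log_denom = logsumexp(
            (log_N + f_k)[:, None] - u_kn, axis=0
        )
        f_new = -logsumexp(log_w[None, :] - u_kn - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f_k)))
        f_k = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MBAR did not converge in {max_iter} iterations")

    # Sample-level mixture probabilities p_nk = N_k e^{f_k - u_kn} / denom_n.
    log_denom = logsumexp((log_N + f_k)[:, None] - u_kn, axis=0)
    log_p = (log_N + f_k)[:, None] - u_kn - log_denom[None, :]
    p = np.exp(log_p)  # (K, N), columns sum to 1 over sampled states
    # Fisher information of f (softmax model), weighted by sample weights.
    H = np.einsum("n,kn,jn->kj", w, p, -p)
    H[np.diag_indices(K)] += np.einsum("n,kn->k", w, p)
    theta = np.linalg.pinv(H, hermitian=True)

    return FreeEnergyResult(
        f_k=f_k, theta=theta, kT=kT, method="mbar", converged=converged, n_iter=it
    )


def mbar_sample_weights(matrix: EnergyMatrix, result: FreeEnergyResult) -> np.ndarray:
    """MBAR weight matrix W (N x K): W_nk = e^{f_k - u_kn} / sum_j N_j e^{f_j - u_jn}.

    Each column of W sums to 1 (weighted by sample weights); ``W[:, k]`` are
    the normalized importance weights for computing averages in state k.
    """
    u_kn, N_k, f_k = matrix.u_kn, np.asarray(matrix.N_k, float), result.f_k
    K, N = u_kn.shape
    w = _norm_weights(N, matrix.weights)
    log_N = np.where(N_k > 0, np.log(np.maximum(N_k, 1e-300)), -np.inf)
    log_denom = logsumexp((log_N + f_k)[:, None] - u_kn, axis=0)
    W = np.exp(f_k[None, :] - u_kn.T - log_denom[:, None])
    return W * w[:, None]


def overlap_matrix(matrix: EnergyMatrix, result: FreeEnergyResult | None = None) -> np.ndarray:
    """Row-stochastic phase-space overlap matrix between states.

    ``O_ij = sum_n N_j W_ni W_nj`` with the MBAR weights W; rows sum to 1.
    Large off-diagonal entries mean good overlap between adjacent windows.
    """
    if result is None:
        result = mbar(matrix)
    if not result.converged:
        raise RuntimeError("overlap_matrix requires a converged MBAR solution")
    W = mbar_sample_weights(matrix, result)
    N_k = np.asarray(matrix.N_k, dtype=float)
    return np.einsum("ni,nj,j->ij", W, W, N_k)


def convergence_series(
    matrix: EnergyMatrix,
    fractions: Sequence[float],
    estimator: Callable[[EnergyMatrix], FreeEnergyResult] = mbar,
):
    """Forward/reverse free-energy estimates on growing fractions of the data.

    For each fraction the end-to-end reduced free energy is recomputed on the
    first (forward) and last (reverse) portion of every state's time-ordered
    samples.  Stationary data give forward and reverse series that agree
    within errors; drifting series indicate unequilibrated sampling.

    Returns a list of dicts with keys ``fraction, forward, forward_se,
    reverse, reverse_se, ok``; points where some sampled state would keep
    fewer than 2 samples are flagged ``ok=False`` and carry NaNs.
    """
    fr = list(fractions)
    if not fr or any(not 0 < f <= 1 for f in fr) or any(
        b <= a for a, b in zip(fr, fr[1:])
    ):
        raise ValueError("fractions must be increasing and in (0, 1]")
    N_k = np.asarray(matrix.N_k, dtype=int)
    out = []
    for frac in fr:
        keep = np.ceil(frac * N_k).astype(int)
        if np.any((N_k > 0) & (keep < 2)):
            out.append(
                dict(fraction=frac, forward=np.nan, forward_se=np.nan,
                     reverse=np.nan, reverse_se=np.nan, ok=False)
            )
            continue
        row = {"fraction": frac, "ok": True}
        for tag, take_end in (("forward", False), ("reverse", True)):
            cols = []
            for k in range(matrix.n_states):
                sl = matrix.state_slice(k)
                idx = np.arange(sl.start, sl.stop)
                idx = idx[-keep[k]:] if take_end else idx[: keep[k]]
                cols.append(idx)
            cols = np.concatenate(cols)
            sub = EnergyMatrix(
                u_kn=matrix.u_kn[:, cols],
                N_k=keep * (N_k > 0),
                states=matrix.states,
                weights=None if matrix.weights is None else matrix.weights[cols],
            )
            res = estimator(sub)
            row[tag] = res.delta_f
            row[f"{tag}_se"] = res.delta_f_se()
        out.append(row)
    return out


# ---------------------------------------------------------------------------
# Thermodynamic integration
# ---------------------------------------------------------------------------


def ti_free_energy(
    lambda_values, mean_du_dlambda, kT: float = 1.0, dudl_se=None
) -> Estimate:
    """Thermodynamic integration: trapezoidal quadrature of <du/dlambda>.

    ``mean_du_dlambda`` are window averages of the reduced-potential
    derivative; the result is in the units of ``kT``.
    """
    lam = np.asarray(lambda_values, dtype=float)
    dudl = np.asarray(mean_du_dlambda, dtype=float)
    if lam.size < 2:
        raise ValueError("TI needs at least two lambda windows")
    if lam.shape != dudl.shape:
        raise ValueError("lambda_values and derivatives must have equal length")
    if np.any(np.diff(lam) <= 0):
        raise ValueError("lambda_values must be strictly increasing")
    value = kT * float(np.trapezoid(dudl, lam))
    se = 0.0
    if dudl_se is not None:
        ses = np.asarray(dudl_se, dtype=float)
        wts = np.zeros_like(lam)
        wts[:-1] += 0.5 * np.diff(lam)
        wts[1:] += 0.5 * np.diff(lam)
        se = kT * float(np.sqrt(np.sum((wts * ses) ** 2)))
    return Estimate(value=value, se=se, method="ti")


def ti_from_matrix(matrix: EnergyMatrix, kT: float = 1.0) -> Estimate:
    """TI along the window path using central differences of cross energies.

    The reduced-potential derivative at window k is approximated from the
    neighbouring states' energies evaluated on window k's own samples; this
    is exact when u is linear in the path coordinate between windows (as for
    linearly interpolated charges or bonded terms) and a controlled
    approximation otherwise.
    """
    K = matrix.n_states
    if K < 2:
        raise ValueError("TI needs at least two windows")
    lam = np.linspace(0.0, 1.0, K)
    means, ses = [], []
    for k in range(K):
        sl = matrix.state_slice(k)
        if sl.stop == sl.start:
            raise ValueError(f"window {k} has no samples for TI")
        lo, hi = max(k - 1, 0), min(k + 1, K - 1)
        du = (matrix.u_kn[hi, sl] - matrix.u_kn[lo, sl]) / (lam[hi] - lam[lo])
        means.append(float(np.mean(du)))
        ses.append(float(np.std(du, ddof=1) / np.sqrt(du.size)) if du.size > 1 else 0.0)
    return ti_free_energy(lam, means, kT=kT, dudl_se=ses)


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------


def wham(
    window_samples: Sequence[np.ndarray],
    centers: Sequence[float],
    k_umbrella: float,
    grid: np.ndarray,
    kT: float = 1.0,
    tol: float = 1e-10,
    max_iter: int = 100000,
    window_weights: np.ndarray | None = None,
) -> PMFProfile:
    """Weighted histogram analysis of harmonic umbrella windows.

    ``window_samples[i]`` are reaction-coordinate values collected with the
    bias ``1/2 k_umbrella (xi - centers[i])^2``; ``grid`` are the output bin
    centers (uniform spacing).  The self-consistent WHAM equations are
    iterated to ``tol`` on the window free energies, and the PMF (in the
    energy units of ``kT``) is anchored so its minimum is exactly 0.

    ``window_weights`` rescales each window's sample counts (used by the
    Bayesian bootstrap).  Non-overlapping histograms are flagged via
    ``overlap_ok=False``.
    """
    centers = np.asarray(centers, dtype=float)
    n_win = len(window_samples)
    if n_win < 2:
        raise ValueError("WHAM needs at least two umbrella windows")
    if centers.shape[0] != n_win:
        raise ValueError("need one center per window")
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing bin centers")
    dx = np.diff(grid).mean()
    edges = np.concatenate([grid - dx / 2, [grid[-1] + dx / 2]])

    counts = np.zeros((n_win, grid.size))
    for i, s in enumerate(window_samples):
        s = np.asarray(s, dtype=float)
        if s.size == 0:
            raise ValueError(f"umbrella window {i} has no samples")
        counts[i], _ = np.histogram(s, bins=edges)
    if window_weights is not None:
        counts = counts * np.asarray(window_weights, dtype=float)[:, None]
    N_i = counts.sum(axis=1)

    # Overlap check: consecutive (center-sorted) windows must share occupied bins.
    order = np.argsort(centers)
    occ = counts[order] > 0
    overlap_ok = all(np.any(occ[a] & occ[a + 1]) for a in range(n_win - 1))
    if not overlap_ok:
        warnings.warn("WHAM: non-overlapping umbrella histograms")

    bias = 0.5 * k_umbrella * (grid[None, :] - centers[:, None]) ** 2 / kT
    n_b = counts.sum(axis=0)
    log_nb = np.where(n_b > 0, np.log(np.maximum(n_b, 1e-300)), -np.inf)
    log_Ni = np.where(N_i > 0, np.log(np.maximum(N_i, 1e-300)), -np.inf)

    f_i = np.zeros(n_win)
    converged = False
    for _ in range(max_iter):
        # log P_b = log n_b - logsumexp_i [log N_i + f_i - bias_ib]
        log_P = log_nb - logsumexp(log_Ni[:, None] + f_i[:, None] - bias, axis=0)
        f_new = -logsumexp(log_P[None, :] - bias, axis=1)
        f_new -= f_new[0]
        if float(np.max(np.abs(f_new - f_i))) < tol:
            f_i = f_new
            converged = True
            break
        f_i = f_new
    if not converged:
        warnings.warn(f"WHAM did not converge in {max_iter} iterations")

    log_P = log_nb - logsumexp(log_Ni[:, None] + f_i[:, None] - bias, axis=0)
    pmf = np.where(np.isfinite(log_P), -kT * log_P, np.inf)
    pmf = pmf - np.min(pmf)
    return PMFProfile(
        grid=grid, pmf=pmf, se=None, kT=kT, converged=converged, overlap_ok=overlap_ok
    )


def bayesian_bootstrap_pmf(
    window_samples: Sequence[np.ndarray],
    centers: Sequence[float],
    k_umbrella: float,
    grid: np.ndarray,
    kT: float = 1.0,
    n_rounds: int = 200,
    seed: int = 0,
    tol: float = 1e-8,
) -> np.ndarray:
    """Per-bin PMF standard errors from a Bayesian bootstrap over windows.

    Each round draws Dirichlet(1, ..., 1) weights over the umbrella windows,
    rescales their sample counts, and re-solves WHAM; the SE is the per-bin
    standard deviation across rounds.  Reproducible for a fixed seed.
    """
    if n_rounds < 2:
        raise ValueError("n_rounds must be >= 2")
    rng = np.random.default_rng(seed)
    n_win = len(window_samples)
    profiles = np.empty((n_rounds, np.asarray(grid).size))
    for r in range(n_rounds):
        wts = rng.dirichlet(np.ones(n_win)) * n_win
        prof = wham(
            window_samples, centers, k_umbrella, grid, kT=kT, tol=tol,
            window_weights=wts,
        )
        profiles[r] = prof.pmf
    finite = np.all(np.isfinite(profiles), axis=0)
    se = np.full(profiles.shape[1], np.nan)
    se[finite] = np.std(profiles[:, finite], axis=0, ddof=1)
    return se
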