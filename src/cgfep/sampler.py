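"""Metropolis Monte Carlo sampling of a CGSystem at fixed alchemical state.

The sampler replaces the stochastic-dynamics integrator of a production MD
engine: free-energy estimators only need equilibrium (Boltzmann) samples,
which single-bead Metropolis moves provide without forces or a thermostat.
Each step picks one mobile bead at random, proposes a Gaussian displacement
and accepts it with probability ``min(1, exp(-delta_u))`` where delta_u is
the change in reduced potential.

Cross-evaluation of every saved frame at every lambda window produces the
``u_kn`` reduced-energy matrix that MBAR and its relatives consume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import (
    AlchemicalState,
    AlchemicalTopology,
    CGSystem,
    EnergyModel,
    FlatBottomRestraint,
    SoftCoreParams,
    ThermoConditions,
)
from .constants import DEFAULT_DIELECTRIC

__all__ = [
    "SamplerConfig",
    "Trajectory",
    "EnergyMatrix",
    "sample",
    "cross_evaluate",
    "decorrelate",
    "statistical_inefficiency",
    "subsample_trajectory",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Monte Carlo run settings.

    ``n_steps`` counts attempted single-bead moves.  Frames are saved every
    ``stride`` steps; the first ``equilibration_fraction`` of saved frames is
    discarded.  ``move_dims`` restricts displacements to a subset of the
    Cartesian axes (e.g. ``(0,)`` for a one-dimensional degree of freedom).
    """

    n_steps: int
    max_displacement: float = 0.05  # nm, Gaussian step width
    seed: int = 0
    equilibration_fraction: float = 0.1
    conditions: ThermoConditions = ThermoConditions()
    mobile_set: tuple[int, ...] = ()
    stride: int = 1
    move_dims: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError("n_steps must be > 0")
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be > 0")
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ValueError("equilibration_fraction must be in [0, 1)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class Trajectory:
    """Saved frames (nm) with their reduced potentials at the sampled state."""

    frames: np.ndarray  # (F, N, 3)
    state: AlchemicalState
    potentials: np.ndarray  # (F,) reduced (kT)
    seed: int
    stride: int
    acceptance_rate: float = float("nan")

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.potentials = np.asarray(self.potentials, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (F, N, 3)")
        if self.potentials.shape[0] != self.frames.shape[0]:
            raise ValueError("potential series length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class EnergyMatrix:
    """Reduced energies ``u_kn`` of N pooled samples evaluated in K states.

    Samples are pooled state by state in time order: the first ``N_k[0]``
    columns come from state 0's trajectory, and so on.  ``weights`` optionally
    carries non-uniform sample weights (used by exhaustive discrete fixtures).
    """

    u_kn: np.ndarray  # (K, N)
    N_k: np.ndarray  # (K,)
    states: Sequence[AlchemicalState] = ()
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u_kn = np.asarray(self.u_kn, dtype=float)
        self.N_k = np.asarray(self.N_k)
        if self.u_kn.ndim != 2:
            raise ValueError("u_kn must be 2-D (K states x N samples)")
        if self.N_k.shape[0] != self.u_kn.shape[0]:
            raise ValueError("N_k must have one entry per state")
        if self.weights is None and int(np.sum(self.N_k)) != self.u_kn.shape[1]:
            raise ValueError("sum of N_k must equal the number of samples")
        if not np.all(np.isfinite(self.u_kn)):
            raise ValueError("u_kn contains non-finite entries")

    @property
    def n_states(self) -> int:
        return self.u_kn.shape[0]

    @property
    def n_samples(self) -> int:
        return self.u_kn.shape[1]

    def state_slice(self, k: int) -> slice:
        """Column slice of the samples drawn from state ``k``."""
        starts = np.concatenate([[0], np.cumsum(self.N_k)])
        return slice(int(starts[k]), int(starts[k + 1]))


def sample(
    system: CGSystem,
    topology: AlchemicalTopology,
    state: AlchemicalState,
    restraints: Sequence[FlatBottomRestraint],
    config: SamplerConfig,
    softcore: SoftCoreParams = SoftCoreParams(),
    dielectric: float = DEFAULT_DIELECTRIC,
) -> Trajectory:
    """Run Metropolis MC and return post-equilibration frames.

    Deterministic for a fixed seed: identical inputs give a bitwise-identical
    trajectory.
    """
    mobile = tuple(config.mobile_set)
    if not mobile:
        raise ValueError("mobile_set must contain at least one bead")
    for b in mobile:
        if not 0 <= b < system.n_beads:
            raise ValueError(f"mobile bead index {b} out of range")
    dims = list(config.move_dims)

    model = EnergyModel(
        system, topology, state, restraints, config.conditions, softcore, dielectric
    )
    kT = config.conditions.kT
    rng = np.random.default_rng(config.seed)
    coords = system.positions.copy()

    frames = []
    accepted = 0
    for step in range(config.n_steps):
        bead = mobile[rng.integers(len(mobile))]
        new_pos = coords[bead].copy()
        new_pos[dims] += config.max_displacement * rng.standard_normal(len(dims))
        d_u = model.bead_delta(coords, bead, new_pos) / kT
        if d_u <= 0.0 or rng.random() < math.exp(-d_u):
            coords[bead] = new_pos
            accepted += 1
        if (step + 1) % config.stride == 0:
            frames.append(coords.copy())

    frames = np.array(frames)
    n_equil = int(math.floor(config.equilibration_fraction * len(frames)))
    frames = frames[n_equil:]
    potentials = model.reduced_batch(frames)
    return Trajectory(
        frames=frames,
        state=state,
        potentials=potentials,
        seed=config.seed,
        stride=config.stride,
        acceptance_rate=accepted / config.n_steps,
    )


def cross_evaluate(
    system: CGSystem,
    topology: AlchemicalTopology,
    trajectories: Sequence[Trajectory],
    all_states: Sequence[AlchemicalState],
    restraints: Sequence[FlatBottomRestraint] = (),
    conditions: ThermoConditions = ThermoConditions(),
    softcore: SoftCoreParams = SoftCoreParams(),
    dielectric: float = DEFAULT_DIELECTRIC,
) -> EnergyMatrix:
    """Re-evaluate every trajectory frame in every alchemical state.

    Returns the (K, N) reduced-energy matrix with ``N_k`` giving each state's
    sample count (zero for states never sampled).  For each trajectory the
    row of its own state reproduces the recorded per-frame potentials
    exactly, since the identical energy path is used.
    """
    lam_pairs = [(s.lambda_coul, s.lambda_vdw) for s in all_states]

    def state_pos(s: AlchemicalState) -> int:
        key = (s.lambda_coul, s.lambda_vdw)
        try:
            return lam_pairs.index(key)
        except ValueError:
            raise ValueError(f"trajectory state {key} not among all_states") from None

    n_beads = {t.frames.shape[1] for t in trajectories}
    if len(n_beads) > 1:
        raise ValueError(f"bead-count mismatch between trajectories: {sorted(n_beads)}")

    order = sorted(range(len(trajectories)), key=lambda i: state_pos(trajectories[i].state))
    N_k = np.zeros(len(all_states), dtype=int)
    for t in trajectories:
        N_k[state_pos(t.state)] += t.n_frames

    models = [
        EnergyModel(system, topology, s, restraints, conditions, softcore, dielectric)
        for s in all_states
    ]
    cols = []
    for i in order:
        t = trajectories[i]
        cols.append(np.array([m.reduced_batch(t.frames) for m in models]))
    u_kn = np.concatenate(cols, axis=1) if cols else np.zeros((len(all_states), 0))
    return EnergyMatrix(u_kn=u_kn, N_k=N_k, states=tuple(all_states))


def subsample_trajectory(traj: Trajectory) -> Trajectory:
    """Keep approximately independent frames, stride ceil(g) on the potential series."""
    g, idx = decorrelate(traj.potentials)
    return Trajectory(
        frames=traj.frames[idx],
        state=traj.state,
        potentials=traj.potentials[idx],
        seed=traj.seed,
        stride=traj.stride * int(math.ceil(g)),
        acceptance_rate=traj.acceptance_rate,
    )


def statistical_inefficiency(series: np.ndarray) -> float:
    """Statistical inefficiency g >= 1 of a scalar time series.

    ``g = 1 + 2 sum_t (1 - t/T) C(t)`` with the normalized autocorrelation
    ``C(t)`` summed until it first becomes non-positive.  Independent samples
    give g ~ 1; an AR(1) process with coefficient rho gives
    ``g ~ (1 + rho)/(1 - rho)``.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must have length >= 2")
    x = x - x.mean()
    var = float(np.dot(x, x) / x.size)
    if var == 0.0:
        warnings.warn("constant series: statistical inefficiency defined as 1")
        return 1.0
    n = x.size
    g = 1.0
    for t in range(1, n):
        c = float(np.dot(x[:-t], x[t:]) / ((n - t) * var))
        if c <= 0.0:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(g, 1.0)


def decorrelate(series: np.ndarray) -> tuple[float, np.ndarray]:
    """Statistical inefficiency and equally spaced subsample indices.

    The subsample stride is ``ceil(g)``, following the usual alchemical
    post-processing convention.
    """
    x = np.asarray(series, dtype=float)
    g = statistical_inefficiency(x)
    stride = int(math.ceil(g))
    return g, np.arange(0, x.size, stride)
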