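"""Analytically solvable toy systems.

These fixtures stand in for the channel/membrane systems at desk scale:
every fixture carries a reference free energy that is known in closed form
or by exhaustive enumeration, so estimators can be validated end to end.

* ``harmonic_dimer`` — one bead on a 1-D spring whose force constant is
  transformed k1 -> k2; the Gaussian partition function gives
  ``delta_f = 1/2 ln(k2/k1)`` per transformed degree of freedom.
* ``discrete_two_state`` — two enumerable configurations with prescribed
  reduced energies in two states; ``delta_f = ln(Z_A / Z_B)`` by direct
  partition-function summation.  Provides both an exhaustively weighted
  energy matrix (exact oracle) and categorically sampled matrices.
* ``lj_fluid_box`` — a small periodic Lennard-Jones fluid in which one
  particle is alchemically decoupled through the soft-core path; no analytic
  reference, used for cross-estimator consistency.
* ``toy_receptor_site`` — a frozen charged bead cage (the "binding site")
  plus a mobile charged "lipid" bead, with bound and bulk legs defined so a
  full relative-binding cycle (and its stepwise decomposition) runs end to
  end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

from .model import (
    AlchemicalState,
    AlchemicalTopology,
    BeadType,
    Bond,
    CGSystem,
    FlatBottomRestraint,
    ThermoConditions,
)
from .sampler import EnergyMatrix, SamplerConfig

__all__ = ["ToyFixture", "make_toy", "TOY_NAMES"]

TOY_NAMES = (
    "harmonic_dimer",
    "discrete_two_state",
    "lj_fluid_box",
    "toy_receptor_site",
)


@dataclass
class ToyFixture:
    """A toy system bundled with its reference answer and sampler settings."""

    name: str
    system: CGSystem | None
    topology: AlchemicalTopology | None
    conditions: ThermoConditions
    sampler: SamplerConfig | None
    reference: Mapping[str, float]
    provenance: str
    restraints: tuple[FlatBottomRestraint, ...] = ()
    schedule: tuple[AlchemicalState, ...] = ()
    extras: Mapping[str, Any] = field(default_factory=dict)


def _vdw_leg(n: int) -> tuple[AlchemicalState, ...]:
    """Windows sweeping lambda_vdw only (for bonded/neutral transformations)."""
    return tuple(
        AlchemicalState(lambda_coul=float(lam), lambda_vdw=float(lam), window_index=i)
        for i, lam in enumerate(np.linspace(0.0, 1.0, n))
    )


def make_toy(name: str, params: Mapping[str, Any] | None = None, seed: int = 0) -> ToyFixture:
    """Build one of the named toy fixtures.

    ``params`` overrides the fixture's defaults (see each builder); the same
    name/params/seed always yields an identical fixture.
    """
    builders = {
        "harmonic_dimer": _harmonic_dimer,
        "discrete_two_state": _discrete_two_state,
        "lj_fluid_box": _lj_fluid_box,
        "toy_receptor_site": _toy_receptor_site,
    }
    if name not in builders:
        raise ValueError(f"unknown fixture {name!r}; valid names: {TOY_NAMES}")
    return builders[name](dict(params or {}), seed)


# ---------------------------------------------------------------------------
# harmonic_dimer
# ---------------------------------------------------------------------------


def _harmonic_dimer(p: Mapping[str, Any], seed: int) -> ToyFixture:
    k1 = float(p.get("k1", 1.0))
    k2 = float(p.get("k2", 4.0))
    kT = float(p.get("kT", 1.0))
    n_windows = int(p.get("n_windows", 5))
    conditions = ThermoConditions.from_kT(kT)

    bead = BeadType(name="X", charge=0.0, lj_epsilon=0.0, lj_sigma=0.47)
    system = CGSystem(
        beads=[bead, bead],
        positions=np.array([[0.0, 0.0, 0.0], [0.3, 0.0, 0.0]]),
        box=np.array([50.0, 50.0, 50.0]),
        bonds=[Bond(0, 1, r0=0.0, k=k1)],
        groups={"anchor": (0,), "mobile": (1,)},
    )
    topology = AlchemicalTopology.identity(system)
    topology = replace(topology, bond_perturbations={0: (k1, k2, 0.0, 0.0)})

    # Gaussian proposal width of order the softest-state width keeps the
    # acceptance rate in the productive range.
    sigma_soft = math.sqrt(kT / min(k1, k2))
    sampler = SamplerConfig(
        n_steps=20000,
        max_displacement=1.2 * sigma_soft,
        seed=seed,
        equilibration_fraction=0.1,
        conditions=conditions,
        mobile_set=(1,),
        move_dims=(0,),
    )
    return ToyFixture(
        name="harmonic_dimer",
        system=system,
        topology=topology,
        conditions=conditions,
        sampler=sampler,
        reference={"delta_f_kT": 0.5 * math.log(k2 / k1)},
        provenance="1-D Gaussian partition function: delta_f = (1/2) ln(k2/k1)",
        schedule=_vdw_leg(n_windows),
        extras={"k1": k1, "k2": k2},
    )


# ---------------------------------------------------------------------------
# discrete_two_state
# ---------------------------------------------------------------------------


def _discrete_two_state(p: Mapping[str, Any], seed: int) -> ToyFixture:
    u_A = np.asarray(p.get("u_A", (0.0, 1.0)), dtype=float)
    u_B = np.asarray(p.get("u_B", (2.0, 2.0)), dtype=float)
    if u_A.shape != u_B.shape or u_A.ndim != 1:
        raise ValueError("u_A and u_B must be equal-length 1-D energy tables")
    Z_A = float(np.sum(np.exp(-u_A)))
    Z_B = float(np.sum(np.exp(-u_B)))
    delta_f = math.log(Z_A / Z_B)
    n_cfg = u_A.size
    states = (
        AlchemicalState(0.0, 0.0, window_index=0),
        AlchemicalState(1.0, 1.0, window_index=1),
    )

    def exhaustive_matrix(N_A: float = 1.0, N_B: float = 1.0) -> EnergyMatrix:
        """Every (state, configuration) pair, Boltzmann-weighted exactly."""
        u_kn = np.concatenate(
            [np.vstack([u_A, u_B])] * 2, axis=1
        )  # columns: A-draws over configs, then B-draws
        w = np.concatenate(
            [N_A * np.exp(-u_A) / Z_A, N_B * np.exp(-u_B) / Z_B]
        )
        return EnergyMatrix(
            u_kn=u_kn, N_k=np.array([N_A, N_B]), states=states, weights=w
        )

    def sampled_matrix(n_per_state: int, sample_seed: int) -> EnergyMatrix:
        rng = np.random.default_rng(sample_seed)
        cols = []
        for u in (u_A, u_B):
            prob = np.exp(-u) / np.sum(np.exp(-u))
            draws = rng.choice(n_cfg, size=n_per_state, p=prob)
            cols.append(np.vstack([u_A[draws], u_B[draws]]))
        return EnergyMatrix(
            u_kn=np.concatenate(cols, axis=1),
            N_k=np.array([n_per_state, n_per_state]),
            states=states,
        )

    return ToyFixture(
        name="discrete_two_state",
        system=None,
        topology=None,
        conditions=ThermoConditions.from_kT(1.0),
        sampler=None,
        reference={"delta_f_kT": delta_f, "Z_A": Z_A, "Z_B": Z_B},
        provenance="exhaustive partition-function sums over the configuration table",
        schedule=states,
        extras={
            "u_A": u_A,
            "u_B": u_B,
            "exhaustive_matrix": exhaustive_matrix,
            "sampled_matrix": sampled_matrix,
        },
    )


# ---------------------------------------------------------------------------
# lj_fluid_box
# ---------------------------------------------------------------------------


def _lj_fluid_box(p: Mapping[str, Any], seed: int) -> ToyFixture:
    n = int(p.get("n_particles", 8))
    box_l = float(p.get("box", 2.0))
    eps = float(p.get("eps", 2.0))
    sigma = float(p.get("sigma", 0.47))
    conditions = ThermoConditions(float(p.get("temperature", 323.0)))

    bead = BeadType(name="LJ", charge=0.0, lj_epsilon=eps, lj_sigma=sigma)
    rng = np.random.default_rng(seed)
    # jittered lattice start to avoid overlaps
    per_side = math.ceil(n ** (1 / 3))
    pts = []
    for i in range(per_side):
        for j in range(per_side):
            for k in range(per_side):
                pts.append([i, j, k])
    pos = (np.array(pts[:n], dtype=float) + 0.5) * (box_l / per_side)
    pos += 0.05 * rng.standard_normal(pos.shape)
    system = CGSystem(
        beads=[bead] * n,
        positions=pos,
        box=np.full(3, box_l),
        groups={"solute": (0,), "solvent": tuple(range(1, n))},
    )
    topology = AlchemicalTopology.identity(system).set_dummy_B([0])
    sampler = SamplerConfig(
        n_steps=30000,
        max_displacement=0.12,
        seed=seed,
        conditions=conditions,
        mobile_set=tuple(range(n)),
    )
    return ToyFixture(
        name="lj_fluid_box",
        system=system,
        topology=topology,
        conditions=conditions,
        sampler=sampler,
        reference={},
        provenance="no closed form; validated by cross-estimator consistency "
        "(MBAR vs TI vs BAR) and long-run sampling",
        schedule=_vdw_leg(int(p.get("n_windows", 7))),
    )


# ---------------------------------------------------------------------------
# toy_receptor_site
# ---------------------------------------------------------------------------


def _toy_receptor_site(p: Mapping[str, Any], seed: int) -> ToyFixture:
    box_l = float(p.get("box", 3.0))
    cage_half = float(p.get("cage_half", 0.4))  # nm, half cube side
    q_cage = float(p.get("q_cage", 0.25))
    q_lipid = float(p.get("q_lipid", -2.0))
    eps = float(p.get("eps", 1.0))
    sigma = float(p.get("sigma", 0.47))
    n_solvent = int(p.get("n_solvent", 4))
    conditions = ThermoConditions(float(p.get("temperature", 323.0)))

    center = np.full(3, box_l / 2.0)
    cage_type = BeadType(name="CAGE", charge=q_cage, lj_epsilon=eps, lj_sigma=sigma)
    lipid_type = BeadType(name="LIP", charge=q_lipid, lj_epsilon=eps, lj_sigma=sigma)
    solv_type = BeadType(name="SOL", charge=0.0, lj_epsilon=eps, lj_sigma=sigma)

    # Cage = cube corners plus face centers: the faces close the escape
    # routes so the charged lipid is genuinely enclosed while bound.
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=float,
    )
    faces = np.array(
        [[s * a for a in axis] for axis in np.eye(3) for s in (-1.5, 1.5)]
    )
    cage_pos = np.vstack([center + cage_half * corners, center + cage_half * faces])
    n_cage = cage_pos.shape[0]

    # Bound leg: cage + lipid in the pocket.
    bound_beads = [cage_type] * n_cage + [lipid_type]
    bound_pos = np.vstack([cage_pos, center])
    system_bound = CGSystem(
        beads=bound_beads,
        positions=bound_pos,
        box=np.full(3, box_l),
        groups={"pocket": tuple(range(n_cage)), "lipid": (n_cage,)},
    )

    # Bulk leg: the lipid alone with a few neutral solvent beads.
    rng = np.random.default_rng(seed)
    solv_pos = rng.uniform(0.8, box_l - 0.8, size=(n_solvent, 3))
    # keep solvent clear of the lipid start
    solv_pos += (np.abs(solv_pos - center) < 0.5) * 0.6
    bulk_beads = [lipid_type] + [solv_type] * n_solvent
    bulk_pos = np.vstack([center, solv_pos])
    system_bulk = CGSystem(
        beads=bulk_beads,
        positions=bulk_pos,
        box=np.full(3, box_l),
        groups={"lipid": (0,), "solvent": tuple(range(1, n_solvent + 1))},
    )

    def topology_to_charge(system: CGSystem, lipid_index: int, q_target: float):
        """A -> B leg that only rescales the lipid charge (species step)."""
        t = AlchemicalTopology.identity(system)
        qB = t.charge_B.copy()
        qB[lipid_index] = q_target
        return replace(t, charge_B=qB)

    def topology_to_dummy(system: CGSystem, lipid_index: int):
        return AlchemicalTopology.identity(system).set_dummy_B([lipid_index])

    def system_with_charge(system: CGSystem, lipid_index: int, q: float) -> CGSystem:
        """The same system with the lipid's charge replaced (intermediate species)."""
        beads = list(system.beads)
        b = beads[lipid_index]
        beads[lipid_index] = BeadType(
            name=b.name, charge=q, lj_epsilon=b.lj_epsilon, lj_sigma=b.lj_sigma
        )
        return CGSystem(
            beads=beads,
            positions=system.positions.copy(),
            box=system.box.copy(),
            bonds=system.bonds,
            elastic_network=system.elastic_network,
            groups=system.groups,
        )

    restraint = FlatBottomRestraint(
        group_a=(n_cage,), group_b=tuple(range(n_cage)), flat_radius_d0=0.8, k=1000.0
    )
    sampler = SamplerConfig(
        n_steps=int(p.get("n_steps", 20000)),
        max_displacement=0.15,
        seed=seed,
        conditions=conditions,
        mobile_set=(n_cage,),
    )
    return ToyFixture(
        name="toy_receptor_site",
        system=system_bound,
        topology=topology_to_dummy(system_bound, n_cage),
        conditions=conditions,
        sampler=sampler,
        reference={},
        provenance="relative cycle closure is exact by construction "
        "(stepwise and direct paths share end states); no absolute reference",
        restraints=(restraint,),
        schedule=(),
        extras={
            "system_bound": system_bound,
            "system_bulk": system_bulk,
            "lipid_index_bound": n_cage,
            "lipid_index_bulk": 0,
            "topology_to_charge": topology_to_charge,
            "topology_to_dummy": topology_to_dummy,
            "system_with_charge": system_with_charge,
            "q_lipid": q_lipid,
        },
    )
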