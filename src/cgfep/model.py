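"""Domain types and the alchemical energy function for coarse-grained bead systems.

A :class:`CGSystem` is a set of beads (each with a :class:`BeadType` giving
charge and Lennard-Jones parameters), harmonic bonds, an optional elastic
network, and an orthorhombic periodic box.  An :class:`AlchemicalTopology`
assigns every bead two sets of nonbonded parameters, the A (initial) and the
B (final) end state; an :class:`AlchemicalState` is a point (lambda_coul,
lambda_vdw) on the coupling path between them.

The energy function follows the usual two-leg alchemical convention:

* charges interpolate linearly, ``q(lam) = (1 - lam) * qA + lam * qB``, with
  plain (screened) Coulomb interactions and no soft core;
* Lennard-Jones interactions of perturbed pairs use the Beutler soft-core
  form with effective separation ``r_eff^6 = alpha * sigma_sc^6 *
  (1 - lam)^p + r^6``, which stays finite at r = 0 for any partially
  decoupled pair.

All energies are in kJ/mol, lengths in nm, charges in elementary charges.
Reduced potentials are energies divided by kT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .constants import DEFAULT_DIELECTRIC, KB, KE

__all__ = [
    "BeadType",
    "Bond",
    "ElasticLink",
    "CGSystem",
    "SoftCoreParams",
    "AlchemicalTopology",
    "AlchemicalState",
    "FlatBottomRestraint",
    "ThermoConditions",
    "minimum_image",
    "softcore_pair_energy",
    "scaled_coulomb_energy",
    "flat_bottom_energy",
    "reduced_potential",
    "EnergyModel",
]


@dataclass(frozen=True)
class BeadType:
    """Nonbonded parameters of one bead species.

    Parameters
    ----------
    name : str
        Label, e.g. ``"Qa"`` or ``"PO4"``.
    charge : float
        Partial charge in elementary charges.
    lj_epsilon : float
        Lennard-Jones well depth in kJ/mol (>= 0).
    lj_sigma : float
        Lennard-Jones size parameter in nm (> 0).
    """

    name: str
    charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_sigma: float = 0.47

    def __post_init__(self) -> None:
        if self.lj_epsilon < 0:
            raise ValueError(f"lj_epsilon must be >= 0, got {self.lj_epsilon}")
        if self.lj_sigma <= 0:
            raise ValueError(f"lj_sigma must be > 0, got {self.lj_sigma}")


@dataclass(frozen=True)
class Bond:
    """Harmonic bond ``1/2 k (r - r0)^2`` between beads ``i`` and ``j``."""

    i: int
    j: int
    r0: float  # nm
    k: float  # kJ/mol/nm^2

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("bond must connect two distinct beads")
        if self.k < 0:
            raise ValueError("bond force constant must be >= 0")


@dataclass(frozen=True)
class ElasticLink:
    """Elastic-network spring between backbone beads (same functional form as a bond)."""

    i: int
    j: int
    r0: float
    k: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("elastic link must connect two distinct beads")


@dataclass
class CGSystem:
    """A coarse-grained bead system with periodic boundaries.

    ``groups`` maps a name (e.g. ``"backbone"``, ``"PO4"``, ``"res_67"``)
    to a tuple of 0-based bead indices.
    """

    beads: Sequence[BeadType]
    positions: np.ndarray  # (N, 3) nm
    box: np.ndarray  # (3,) nm
    bonds: Sequence[Bond] = field(default_factory=tuple)
    elastic_network: Sequence[ElasticLink] = field(default_factory=tuple)
    groups: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.beads)
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match {n} beads"
            )
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        for b in tuple(self.bonds) + tuple(self.elastic_network):
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bonded pair ({b.i}, {b.j}) out of range")
        for name, idx in self.groups.items():
            for i in idx:
                if not 0 <= i < n:
                    raise ValueError(f"group {name!r} index {i} out of range")

    @property
    def n_beads(self) -> int:
        return len(self.beads)


@dataclass(frozen=True)
class SoftCoreParams:
    """Beutler soft-core parameters: ``r_eff^6 = alpha sigma_sc^6 (1-lam)^p + r^6``."""

    alpha: float = 0.5
    sigma_sc: float = 0.3  # nm
    power_p: int = 1

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.sigma_sc <= 0:
            raise ValueError("sigma_sc must be > 0")
        if self.power_p < 1:
            raise ValueError("power_p must be a positive integer")


@dataclass(frozen=True)
class AlchemicalState:
    """One lambda window: both components in [0, 1]."""

    lambda_coul: float
    lambda_vdw: float
    window_index: int = 0

    def __post_init__(self) -> None:
        for lam, nm in ((self.lambda_coul, "lambda_coul"), (self.lambda_vdw, "lambda_vdw")):
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1], got {lam}")


@dataclass
class AlchemicalTopology:
    """Per-bead A- and B-end-state nonbonded parameters.

    A *dummy* end state has exactly zero charge and zero epsilon.  Beads whose
    A and B parameters coincide are unperturbed and see plain (non-soft-core)
    interactions at every window.

    ``bond_perturbations`` optionally interpolates harmonic-bond parameters
    linearly in lambda_vdw: ``{bond_index: (kA, kB, r0A, r0B)}``.
    """

    charge_A: np.ndarray
    charge_B: np.ndarray
    eps_A: np.ndarray
    eps_B: np.ndarray
    sigma_A: np.ndarray
    sigma_B: np.ndarray
    bond_perturbations: Mapping[int, tuple[float, float, float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("charge_A", "charge_B", "eps_A", "eps_B", "sigma_A", "sigma_B"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arrays[name])
        n = arrays["charge_A"].shape[0]
        for name, a in arrays.items():
            if a.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if np.any(arrays["eps_A"] < 0) or np.any(arrays["eps_B"] < 0):
            raise ValueError("epsilon values must be >= 0")
        if np.any(arrays["sigma_A"] <= 0) or np.any(arrays["sigma_B"] <= 0):
            raise ValueError("sigma values must be > 0")

    @classmethod
    def identity(cls, system: CGSystem) -> "AlchemicalTopology":
        """Topology whose A and B end states both equal the system's bead types."""
        q = np.array([b.charge for b in system.beads])
        e = np.array([b.lj_epsilon for b in system.beads])
        s = np.array([b.lj_sigma for b in system.beads])
        return cls(q, q.copy(), e, e.copy(), s, s.copy())

    @property
    def n_beads(self) -> int:
        return self.charge_A.shape[0]

    @property
    def perturbed_set(self) -> np.ndarray:
        """Indices of beads whose A and B parameters differ."""
        diff = (
            (self.charge_A != self.charge_B)
            | (self.eps_A != self.eps_B)
            | (self.sigma_A != self.sigma_B)
        )
        return np.flatnonzero(diff)

    def set_dummy_B(self, indices: Sequence[int]) -> "AlchemicalTopology":
        """Return a copy whose B end state makes ``indices`` dummy particles."""
        qB = self.charge_B.copy()
        eB = self.eps_B.copy()
        idx = list(indices)
        qB[idx] = 0.0
        eB[idx] = 0.0
        return replace(self, charge_B=qB, eps_B=eB)

    def end_state(self, which: str) -> "AlchemicalTopology":
        """Collapse to an unperturbed topology at end state ``"A"`` or ``"B"``."""
        if which == "A":
            q, e, s = self.charge_A, self.eps_A, self.sigma_A
            bp = {i: (kA, kA, rA, rA) for i, (kA, _, rA, _) in self.bond_perturbations.items()}
        elif which == "B":
            q, e, s = self.charge_B, self.eps_B, self.sigma_B
            bp = {i: (kB, kB, rB, rB) for i, (_, kB, _, rB) in self.bond_perturbations.items()}
        else:
            raise ValueError("which must be 'A' or 'B'")
        return AlchemicalTopology(
            q.copy(), q.copy(), e.copy(), e.copy(), s.copy(), s.copy(), bp
        )


@dataclass(frozen=True)
class FlatBottomRestraint:
    """Zero inside ``flat_radius_d0``, harmonic ``1/2 k (d - d0)^2`` beyond it.

    The restrained distance is between the centroids of the two bead groups
    (e.g. the lipid PO4 bead and the nearby protein backbone beads).
    """

    group_a: tuple[int, ...]
    group_b: tuple[int, ...]
    flat_radius_d0: float  # nm
    k: float  # kJ/mol/nm^2

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("restraint force constant must be >= 0")
        if self.flat_radius_d0 <= 0:
            raise ValueError("flat_radius_d0 must be > 0")
        if not self.group_a or not self.group_b:
            raise ValueError("restraint groups must be nonempty")


@dataclass(frozen=True)
class ThermoConditions:
    """Temperature and the derived thermal energy kT."""

    temperature: float = 323.0  # K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def kT(self) -> float:
        """Thermal energy in kJ/mol."""
        return KB * self.temperature

    @classmethod
    def from_kT(cls, kT: float) -> "ThermoConditions":
        """Conditions whose thermal energy equals ``kT`` kJ/mol (handy for toys)."""
        return cls(temperature=kT / KB)


# ---------------------------------------------------------------------------
# Pairwise terms
# ---------------------------------------------------------------------------


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    return delta - box * np.round(delta / box)


def _sc_lj(r6: np.ndarray, eps, sigma, soften, sc: SoftCoreParams):
    """4 eps [ (s6)^2 - s6 ] with s6 = sigma^6 / (alpha sigma_sc^6 soften + r^6)."""
    reff6 = sc.alpha * sc.sigma_sc**6 * soften + r6
    s6 = sigma**6 / reff6
    return 4.0 * eps * (s6 * s6 - s6)


def softcore_pair_energy(
    r: float,
    lambda_vdw: float,
    eps: float,
    sigma_lj: float,
    sc: SoftCoreParams = SoftCoreParams(),
) -> float:
    """Soft-core Lennard-Jones energy of a pair coupled at strength ``lambda_vdw``.

    ``lambda_vdw = 1`` gives the plain 12-6 potential; ``lambda_vdw = 0``
    gives zero; for intermediate coupling the energy is finite at any r
    (including r = 0) whenever ``alpha > 0``.
    """
    if r < 0:
        raise ValueError(f"r must be >= 0, got {r}")
    if not 0.0 <= lambda_vdw <= 1.0:
        raise ValueError(f"lambda_vdw must be in [0, 1], got {lambda_vdw}")
    if eps < 0 or sigma_lj <= 0:
        raise ValueError("invalid Lennard-Jones parameters")
    if lambda_vdw == 0.0 or eps == 0.0:
        return 0.0
    soften = (1.0 - lambda_vdw) ** sc.power_p
    if lambda_vdw == 1.0 and r == 0.0:
        raise ValueError("plain LJ (lambda_vdw = 1) diverges at r = 0")
    return float(lambda_vdw * _sc_lj(r**6, eps, sigma_lj, soften, sc))


def scaled_coulomb_energy(
    r: float,
    lambda_coul: float,
    qA_i: float,
    qB_i: float,
    qA_j: float,
    qB_j: float,
    dielectric: float = DEFAULT_DIELECTRIC,
) -> float:
    """Screened Coulomb energy with linearly interpolated charges.

    ``q(lam) = (1 - lam) qA + lam qB`` for each bead; energy is
    ``KE * q_i q_j / (dielectric * r)``.  There is no soft core on charges:
    the two-leg protocol removes charges before vdW cores, so partially
    charged beads always retain a repulsive core.
    """
    if not 0.0 <= lambda_coul <= 1.0:
        raise ValueError(f"lambda_coul must be in [0, 1], got {lambda_coul}")
    qi = (1.0 - lambda_coul) * qA_i + lambda_coul * qB_i
    qj = (1.0 - lambda_coul) * qA_j + lambda_coul * qB_j
    if qi * qj == 0.0:
        return 0.0
    if r <= 0.0:
        raise ValueError("r must be > 0 for charged beads (no soft core on charges)")
    return KE * qi * qj / (dielectric * r)


def flat_bottom_energy(d: float, restraint: FlatBottomRestraint) -> float:
    """Flat-bottom restraint energy at centroid separation ``d``."""
    if d < 0:
        raise ValueError(f"d must be >= 0, got {d}")
    excess = d - restraint.flat_radius_d0
    if excess <= 0:
        return 0.0
    return 0.5 * restraint.k * excess * excess


# ---------------------------------------------------------------------------
# Total potential
# ---------------------------------------------------------------------------


class EnergyModel:
    """Precomputed evaluator of the total potential at one alchemical state.

    Nonbonded pairs exclude bonded and elastic-network pairs.  Pairs in which
    at least one bead is perturbed use interpolated charges and the two-end
    soft-core vdW combination

    ``U_vdw = (1-lam) U_sc(r; A params, soften=lam^p)
            + lam U_sc(r; B params, soften=(1-lam)^p)``

    which reduces to the plain A (B) potential at lambda_vdw = 0 (1).
    Unperturbed pairs use plain LJ + Coulomb throughout.
    """

    def __init__(
        self,
        system: CGSystem,
        topology: AlchemicalTopology,
        state: AlchemicalState,
        restraints: Sequence[FlatBottomRestraint] = (),
        conditions: ThermoConditions = ThermoConditions(),
        softcore: SoftCoreParams = SoftCoreParams(),
        dielectric: float = DEFAULT_DIELECTRIC,
    ):
        if topology.n_beads != system.n_beads:
            raise ValueError(
                f"topology has {topology.n_beads} beads, system has {system.n_beads}"
            )
        self.system = system
        self.topology = topology
        self.state = state
        self.restraints = tuple(restraints)
        self.conditions = conditions
        self.softcore = softcore
        self.dielectric = dielectric

        n = system.n_beads
        excluded = {(min(b.i, b.j), max(b.i, b.j)) for b in system.bonds}
        excluded |= {(min(e.i, e.j), max(e.i, e.j)) for e in system.elastic_network}
        ii, jj = np.triu_indices(n, k=1)
        keep = np.array(
            [(int(a), int(b)) not in excluded for a, b in zip(ii, jj)], dtype=bool
        )
        self.pair_i = ii[keep]
        self.pair_j = jj[keep]

        t = topology
        lc, lv = state.lambda_coul, state.lambda_vdw
        self.q_lam = (1.0 - lc) * t.charge_A + lc * t.charge_B
        # Lorentz-Berthelot combination per end state.
        i, j = self.pair_i, self.pair_j
        self.epsA_ij = np.sqrt(t.eps_A[i] * t.eps_A[j])
        self.epsB_ij = np.sqrt(t.eps_B[i] * t.eps_B[j])
        self.sigA_ij = 0.5 * (t.sigma_A[i] + t.sigma_A[j])
        self.sigB_ij = 0.5 * (t.sigma_B[i] + t.sigma_B[j])
        # Soft-core treatment applies only where the Lennard-Jones end states
        # differ; charge-only perturbations keep their plain repulsive core
        # at every window (no bare-charge overlap at intermediate lambda).
        pert_vdw = (t.eps_A != t.eps_B) | (t.sigma_A != t.sigma_B)
        self.pair_perturbed = pert_vdw[i] | pert_vdw[j]
        self.qq_lam = self.q_lam[i] * self.q_lam[j]

        # Bond parameter interpolation (in lambda_vdw).
        self.bond_i = np.array([b.i for b in system.bonds], dtype=int)
        self.bond_j = np.array([b.j for b in system.bonds], dtype=int)
        bond_k = np.array([b.k for b in system.bonds], dtype=float)
        bond_r0 = np.array([b.r0 for b in system.bonds], dtype=float)
        for bi, (kA, kB, r0A, r0B) in t.bond_perturbations.items():
            bond_k[bi] = (1.0 - lv) * kA + lv * kB
            bond_r0[bi] = (1.0 - lv) * r0A + lv * r0B
        self.bond_k = bond_k
        self.bond_r0 = bond_r0
        self.el_i = np.array([e.i for e in system.elastic_network], dtype=int)
        self.el_j = np.array([e.j for e in system.elastic_network], dtype=int)
        self.el_k = np.array([e.k for e in system.elastic_network], dtype=float)
        self.el_r0 = np.array([e.r0 for e in system.elastic_network], dtype=float)

        # Which pairs carry any interaction at this state (skip zero work).
        self._has_coul = self.qq_lam != 0.0
        self._lv = lv
        sc = softcore
        self._softenA = lv**sc.power_p
        self._softenB = (1.0 - lv) ** sc.power_p

        # Per-bead precomputation for fast single-bead move evaluation:
        # nonbonded pair rows, bonded partners, restraint membership.
        self._bead_rows: list[np.ndarray] = []
        self._bead_partners: list[np.ndarray] = []
        self._bead_bonds: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        self._bead_restraints: list[bool] = []
        restraint_members = set()
        for rs in self.restraints:
            restraint_members |= set(rs.group_a) | set(rs.group_b)
        for b in range(n):
            rows = np.flatnonzero((self.pair_i == b) | (self.pair_j == b))
            self._bead_rows.append(rows)
            self._bead_partners.append(
                np.where(self.pair_i[rows] == b, self.pair_j[rows], self.pair_i[rows])
            )
            bpart, bk, br0 = [], [], []
            for arr_i, arr_j, kk, rr0 in (
                (self.bond_i, self.bond_j, self.bond_k, self.bond_r0),
                (self.el_i, self.el_j, self.el_k, self.el_r0),
            ):
                for ii, jj, kv, rv in zip(arr_i, arr_j, kk, rr0):
                    if ii == b or jj == b:
                        bpart.append(jj if ii == b else ii)
                        bk.append(kv)
                        br0.append(rv)
            self._bead_bonds.append(
                (np.array(bpart, dtype=int), np.array(bk), np.array(br0))
            )
            self._bead_restraints.append(b in restraint_members)

    # -- internals ---------------------------------------------------------

    def _pair_energy(self, r: np.ndarray, rows: np.ndarray | None = None) -> np.ndarray:
        """Nonbonded energy per pair for pair distances ``r`` (kJ/mol).

        ``rows`` optionally restricts evaluation to those pair-list rows, in
        which case ``r`` must be the distances for exactly those rows.
        """
        if rows is None:
            qq = self.qq_lam
            pert = self.pair_perturbed
            epsA, sigA = self.epsA_ij, self.sigA_ij
            epsB, sigB = self.epsB_ij, self.sigB_ij
        else:
            qq = self.qq_lam[rows]
            pert = self.pair_perturbed[rows]
            epsA, sigA = self.epsA_ij[rows], self.sigA_ij[rows]
            epsB, sigB = self.epsB_ij[rows], self.sigB_ij[rows]
        # r may be (P,) for one frame or (F, P) for a batch; masks index the
        # trailing pair axis.
        sc = self.softcore
        lv = self._lv
        e = np.zeros_like(r)
        m = qq != 0.0
        if np.any(m):
            rm = r[..., m]
            if np.any(rm <= 0):
                raise ValueError("zero separation between charged beads")
            e[..., m] += KE * qq[m] / (self.dielectric * rm)
        r6 = r**6
        if np.any(pert):
            if lv < 1.0:
                mA = pert & (epsA > 0)
                if np.any(mA):
                    e[..., mA] += (1.0 - lv) * _sc_lj(
                        r6[..., mA], epsA[mA], sigA[mA], self._softenA, sc
                    )
            if lv > 0.0:
                mB = pert & (epsB > 0)
                if np.any(mB):
                    e[..., mB] += lv * _sc_lj(
                        r6[..., mB], epsB[mB], sigB[mB], self._softenB, sc
                    )
        u = (~pert) & (epsA > 0)
        if np.any(u):
            s6 = sigA[u] ** 6 / r6[..., u]
            e[..., u] += 4.0 * epsA[u] * (s6 * s6 - s6)
        return e

    def _distances(self, coords: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        d = minimum_image(coords[..., i, :] - coords[..., j, :], self.system.box)
        return np.sqrt(np.sum(d * d, axis=-1))

    def _restraint_energy(self, coords: np.ndarray):
        """Restraint energy; supports (N, 3) frames or (F, N, 3) batches."""
        e = 0.0 if coords.ndim == 2 else np.zeros(coords.shape[0])
        for rs in self.restraints:
            ca = coords[..., list(rs.group_a), :].mean(axis=-2)
            cb = coords[..., list(rs.group_b), :].mean(axis=-2)
            d = minimum_image(ca - cb, self.system.box)
            dist = np.sqrt(np.sum(d * d, axis=-1))
            excess = np.maximum(dist - rs.flat_radius_d0, 0.0)
            e = e + 0.5 * rs.k * excess * excess
        return e

    # -- public API --------------------------------------------------------

    def potential(self, coords: np.ndarray) -> float:
        """Total potential energy of one configuration in kJ/mol."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.system.n_beads, 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match system "
                f"({self.system.n_beads} beads)"
            )
        e = 0.0
        if self.pair_i.size:
            r = self._distances(coords, self.pair_i, self.pair_j)
            e += float(np.sum(self._pair_energy(r)))
        if self.bond_i.size:
            r = self._distances(coords, self.bond_i, self.bond_j)
            e += float(np.sum(0.5 * self.bond_k * (r - self.bond_r0) ** 2))
        if self.el_i.size:
            r = self._distances(coords, self.el_i, self.el_j)
            e += float(np.sum(0.5 * self.el_k * (r - self.el_r0) ** 2))
        e += float(self._restraint_energy(coords))
        return e

    def potential_batch(self, frames: np.ndarray) -> np.ndarray:
        """Total potential for every frame of a trajectory, in kJ/mol."""
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1:] != (self.system.n_beads, 3):
            raise ValueError(
                f"frames shape {frames.shape} does not match system "
                f"({self.system.n_beads} beads)"
            )
        e = np.zeros(frames.shape[0])
        if self.pair_i.size:
            r = self._distances(frames, self.pair_i, self.pair_j)
            e += np.sum(self._pair_energy(r), axis=-1)
        if self.bond_i.size:
            r = self._distances(frames, self.bond_i, self.bond_j)
            e += np.sum(0.5 * self.bond_k * (r - self.bond_r0) ** 2, axis=-1)
        if self.el_i.size:
            r = self._distances(frames, self.el_i, self.el_j)
            e += np.sum(0.5 * self.el_k * (r - self.el_r0) ** 2, axis=-1)
        e += self._restraint_energy(frames)
        return e

    def bead_delta(self, coords: np.ndarray, bead: int, new_pos: np.ndarray) -> float:
        """Energy change (kJ/mol) when ``bead`` moves to ``new_pos``."""
        rows = self._bead_rows[bead]
        partners = self._bead_partners[bead]
        bpart, bk, br0 = self._bead_bonds[bead]
        box = self.system.box
        old = coords[bead].copy()

        def local(pos: np.ndarray) -> float:
            e = 0.0
            if rows.size:
                d = minimum_image(pos - coords[partners], box)
                r = np.sqrt(np.sum(d * d, axis=-1))
                e += float(np.sum(self._pair_energy(r, rows)))
            if bpart.size:
                d = minimum_image(pos - coords[bpart], box)
                r = np.sqrt(np.sum(d * d, axis=-1))
                e += float(np.sum(0.5 * bk * (r - br0) ** 2))
            return e

        e = local(np.asarray(new_pos, dtype=float)) - local(old)
        if self._bead_restraints[bead]:
            e -= float(self._restraint_energy(coords))
            coords[bead] = np.asarray(new_pos, dtype=float)
            e += float(self._restraint_energy(coords))
            coords[bead] = old
        return e

    def reduced(self, coords: np.ndarray) -> float:
        """Reduced potential u = U / kT."""
        return self.potential(coords) / self.conditions.kT

    def reduced_batch(self, frames: np.ndarray) -> np.ndarray:
        return self.potential_batch(frames) / self.conditions.kT


def reduced_potential(
    system: CGSystem,
    coords: np.ndarray,
    topology: AlchemicalTopology,
    state: AlchemicalState,
    restraints: Sequence[FlatBottomRestraint] = (),
    conditions: ThermoConditions = ThermoConditions(),
    softcore: SoftCoreParams = SoftCoreParams(),
    dielectric: float = DEFAULT_DIELECTRIC,
) -> float:
    """Reduced potential u = U/kT of one configuration at one alchemical state."""
    model = EnergyModel(
        system, topology, state, restraints, conditions, softcore, dielectric
    )
    return model.reduced(coords)
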