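"""Lambda schedules, transformation specifications and thermodynamic cycles.

The alchemical protocol follows the two-leg convention: Coulombic
interactions are turned off first (lambda_coul swept 0 -> 1 over a linear
grid with the van der Waals interactions untouched), then the Lennard-Jones
interactions are turned off (lambda_vdw swept 0 -> 1 at lambda_coul = 1).
Removing charges before cores prevents bare-charge overlap singularities.

A relative binding free energy is the difference between performing the same
transformation in the bound site (Delta G_2) and in bulk membrane
(Delta G_1):  DDG = Delta G_2 - Delta G_1.  Decomposing a transformation
into steps (e.g. PIP2 -> PI4P -> PI -> PC) and summing the step DDGs must
reproduce the direct DDG; ``closure_check`` quantifies that consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import AlchemicalState

__all__ = [
    "LambdaSchedule",
    "BeadEdit",
    "TransformationSpec",
    "ReplicaSet",
    "ThermodynamicCycle",
    "build_schedule",
    "lipid_transformation",
    "residue_transformation",
    "ddg",
    "closure_check",
    "replica_sem",
    "LIPID_BEADS",
    "RESIDUE_SIDECHAINS",
]


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered lambda windows for a charges-first, then-vdW transformation."""

    states: tuple[AlchemicalState, ...]
    protocol: str = "coul-then-vdw"

    def __post_init__(self) -> None:
        s = self.states
        if not s:
            raise ValueError("schedule must contain at least one state")
        first, last = s[0], s[-1]
        if (first.lambda_coul, first.lambda_vdw) != (0.0, 0.0):
            raise ValueError("schedule must start at (0, 0)")
        if (last.lambda_coul, last.lambda_vdw) != (1.0, 1.0):
            raise ValueError("schedule must end at (1, 1)")
        lc = [st.lambda_coul for st in s]
        lv = [st.lambda_vdw for st in s]
        if any(b < a for a, b in zip(lc, lc[1:])) or any(
            b < a for a, b in zip(lv, lv[1:])
        ):
            raise ValueError("lambda components must be non-decreasing")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)


def build_schedule(n_points_per_leg: int = 11) -> LambdaSchedule:
    """Two-leg linear schedule with the shared (1, 0) midpoint not duplicated.

    The default grid per leg is 0, 0.1, ..., 1.0 (11 points), giving 21
    distinct windows in total.
    """
    if n_points_per_leg < 2:
        raise ValueError("n_points_per_leg must be >= 2")
    grid = np.linspace(0.0, 1.0, n_points_per_leg)
    states = []
    for lc in grid:
        states.append((round(float(lc), 12), 0.0))
    for lv in grid[1:]:  # (1, 0) already present as the leg-1 endpoint
        states.append((1.0, round(float(lv), 12)))
    return LambdaSchedule(
        states=tuple(
            AlchemicalState(lambda_coul=lc, lambda_vdw=lv, window_index=i)
            for i, (lc, lv) in enumerate(states)
        )
    )


# ---------------------------------------------------------------------------
# Transformation specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeadEdit:
    """One bead-level difference between the two end states.

    ``action`` is one of ``"to_dummy"`` (present in A, absent in B),
    ``"from_dummy"`` (absent in A, present in B) or ``"change"`` (bead type
    and/or charge differs).  Parameters are ``(type_name, charge)`` tuples.
    """

    bead: str
    action: str
    params_A: tuple[str, float] | None = None
    params_B: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if self.action not in ("to_dummy", "from_dummy", "change"):
            raise ValueError(f"unknown edit action {self.action!r}")


@dataclass(frozen=True)
class TransformationSpec:
    """An alchemical transformation between two chemical species."""

    kind: str  # "lipid" | "residue"
    from_species: str
    to_species: str
    edits: tuple[BeadEdit, ...]

    @property
    def charge_change(self) -> float:
        """Net end-state charge difference (B minus A) in elementary charges."""
        dq = 0.0
        for e in self.edits:
            qa = e.params_A[1] if e.params_A else 0.0
            qb = e.params_B[1] if e.params_B else 0.0
            dq += qb - qa
        return dq


# Coarse-grained headgroup/tail bead tables.  Each species maps bead label ->
# (bead type, charge).  These are deliberately small, editable tables: just
# enough chemistry for the transformations, not a force-field library.
LIPID_BEADS: Mapping[str, Mapping[str, tuple[str, float]]] = {
    # phosphatidylinositol-4,5-bisphosphate: inositol ring C1-C3, linking
    # phosphate PO4, ring phosphates P4 (4') and P5 (5'), glycerol, two tails
    "PIP2": {
        "C1": ("P1", 0.0), "C2": ("P4", 0.0), "C3": ("P4", 0.0),
        "PO4": ("Qa", -1.0), "P4": ("Qa", -2.0), "P5": ("Qa", -2.0),
        "GL1": ("Na", 0.0), "GL2": ("Na", 0.0),
        "T1A": ("C1", 0.0), "T2A": ("C1", 0.0), "T3A": ("C1", 0.0), "T4A": ("C1", 0.0),
        "T1B": ("C1", 0.0), "T2B": ("C3", 0.0), "T3B": ("C1", 0.0), "T4B": ("C1", 0.0),
    },
    # PI4P: PIP2 without the 5' phosphate
    "PI4P": {
        "C1": ("P1", 0.0), "C2": ("P4", 0.0), "C3": ("P4", 0.0),
        "PO4": ("Qa", -1.0), "P4": ("Qa", -2.0),
        "GL1": ("Na", 0.0), "GL2": ("Na", 0.0),
        "T1A": ("C1", 0.0), "T2A": ("C1", 0.0), "T3A": ("C1", 0.0), "T4A": ("C1", 0.0),
        "T1B": ("C1", 0.0), "T2B": ("C3", 0.0), "T3B": ("C1", 0.0), "T4B": ("C1", 0.0),
    },
    # PI: bare inositol headgroup
    "PI": {
        "C1": ("P1", 0.0), "C2": ("P4", 0.0), "C3": ("P4", 0.0),
        "PO4": ("Qa", -1.0),
        "GL1": ("Na", 0.0), "GL2": ("Na", 0.0),
        "T1A": ("C1", 0.0), "T2A": ("C1", 0.0), "T3A": ("C1", 0.0), "T4A": ("C1", 0.0),
        "T1B": ("C1", 0.0), "T2B": ("C3", 0.0), "T3B": ("C1", 0.0), "T4B": ("C1", 0.0),
    },
    # phosphatidylcholine: choline NC3 + phosphate, no ring
    "PC": {
        "NC3": ("Q0", 1.0), "PO4": ("Qa", -1.0),
        "GL1": ("Na", 0.0), "GL2": ("Na", 0.0),
        "T1A": ("C1", 0.0), "T2A": ("C1", 0.0), "T3A": ("C1", 0.0), "T4A": ("C1", 0.0),
        "T1B": ("C1", 0.0), "T2B": ("C3", 0.0), "T3B": ("C1", 0.0), "T4B": ("C1", 0.0),
    },
    # soluble short-tail analogue: each tail truncated to two beads
    # (one bead ~ four carbons, so two beads ~ eight carbons)
    "PIP2-diC8": {
        "C1": ("P1", 0.0), "C2": ("P4", 0.0), "C3": ("P4", 0.0),
        "PO4": ("Qa", -1.0), "P4": ("Qa", -2.0), "P5": ("Qa", -2.0),
        "GL1": ("Na", 0.0), "GL2": ("Na", 0.0),
        "T1A": ("C1", 0.0), "T2A": ("C1", 0.0),
        "T1B": ("C1", 0.0), "T2B": ("C3", 0.0),
    },
}

# Side-chain bead tables for the coarse-grained amino acids involved in the
# studied substitutions (plus common neighbours).  Backbone beads are shared
# and never edited.
RESIDUE_SIDECHAINS: Mapping[str, Mapping[str, tuple[str, float]]] = {
    "ALA": {},
    "GLY": {},
    "GLU": {"SC1": ("Qa", -1.0)},
    "ASP": {"SC1": ("Qa", -1.0)},
    "LYS": {"SC1": ("C3", 0.0), "SC2": ("Qd", 1.0)},
    "ARG": {"SC1": ("N0", 0.0), "SC2": ("Qd", 1.0)},
    "ASN": {"SC1": ("P5", 0.0)},
    "GLN": {"SC1": ("P4", 0.0)},
    "SER": {"SC1": ("P1", 0.0)},
    "THR": {"SC1": ("P1", 0.0)},
    "CYS": {"SC1": ("C5", 0.0)},
    "HIS": {"SC1": ("SC4", 0.0), "SC2": ("SP1", 0.0), "SC3": ("SP1", 0.0)},
}

_AA_CODES = {
    "A": "ALA", "G": "GLY", "E": "GLU", "D": "ASP", "K": "LYS", "R": "ARG",
    "N": "ASN", "Q": "GLN", "S": "SER", "T": "THR", "C": "CYS", "H": "HIS",
}


def _diff_edits(
    beads_A: Mapping[str, tuple[str, float]],
    beads_B: Mapping[str, tuple[str, float]],
) -> tuple[BeadEdit, ...]:
    """Name-keyed diff of two bead tables into an edit list."""
    edits = []
    for name in beads_A:
        if name not in beads_B:
            edits.append(BeadEdit(name, "to_dummy", params_A=beads_A[name]))
        elif beads_A[name] != beads_B[name]:
            edits.append(
                BeadEdit(name, "change", params_A=beads_A[name], params_B=beads_B[name])
            )
    for name in beads_B:
        if name not in beads_A:
            edits.append(BeadEdit(name, "from_dummy", params_B=beads_B[name]))
    return tuple(edits)


def lipid_transformation(
    from_species: str,
    to_species: str,
    table: Mapping[str, Mapping[str, tuple[str, float]]] | None = None,
) -> TransformationSpec:
    """Bead edit list transforming one lipid species into another.

    PIP2 -> PI4P sends the 5' phosphate bead to a dummy, PI4P -> PI the 4'
    phosphate; PI -> PC exchanges the inositol-ring beads for the choline
    headgroup; PIP2 -> PIP2-diC8 truncates each tail to two beads.  Because
    edits are keyed by bead name, a multi-step decomposition's edits union to
    exactly the direct transformation's edits.
    """
    table = LIPID_BEADS if table is None else table
    for sp in (from_species, to_species):
        if sp not in table:
            raise ValueError(
                f"unsupported lipid species {sp!r}; known: {sorted(table)}"
            )
    return TransformationSpec(
        kind="lipid",
        from_species=from_species,
        to_species=to_species,
        edits=_diff_edits(table[from_species], table[to_species]),
    )


def residue_transformation(
    position: int,
    wt: str,
    mut: str,
    table: Mapping[str, Mapping[str, tuple[str, float]]] | None = None,
) -> TransformationSpec:
    """Side-chain bead edits for a point substitution (e.g. E179K).

    Residues may be given as one-letter or three-letter codes.  E -> K flips
    the side-chain charge from -1 to +1 (net +2 e); K -> N replaces the
    charged bead by a polar one (net -1 e); C -> S is a polar type swap.
    """
    table = RESIDUE_SIDECHAINS if table is None else table

    def canon(code: str) -> str:
        c = code.upper()
        c = _AA_CODES.get(c, c)
        if c not in table:
            raise ValueError(f"unsupported residue {code!r}; known: {sorted(table)}")
        return c

    wt3, mut3 = canon(wt), canon(mut)
    return TransformationSpec(
        kind="residue",
        from_species=f"{wt3}{position}",
        to_species=f"{mut3}{position}",
        edits=_diff_edits(table[wt3], table[mut3]),
    )


# ---------------------------------------------------------------------------
# Replica statistics and cycle arithmetic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReplicaSet:
    """Free-energy values from independent replicas, reported as mean +/- SEM."""

    values: tuple[float, ...]  # kJ/mol

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("replica set must be nonempty")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sem(self) -> float | None:
        """Sample SD / sqrt(n); undefined (None) for a single replica."""
        if self.n < 2:
            return None
        return float(np.std(self.values, ddof=1) / math.sqrt(self.n))


def replica_sem(values: Sequence[float]) -> ReplicaSet:
    """Wrap per-replica Delta G values as mean +/- SEM."""
    return ReplicaSet(values=tuple(float(v) for v in values))


def ddg(bound: ReplicaSet, free: ReplicaSet) -> tuple[float, float]:
    """Relative binding free energy DDG = mean(bound) - mean(free).

    The error combines the two legs' SEMs in quadrature; a missing SEM
    (single replica) contributes zero with the caveat that the combined error
    is then a lower bound.
    """
    value = bound.mean - free.mean
    eb = bound.sem or 0.0
    ef = free.sem or 0.0
    return value, math.hypot(eb, ef)


@dataclass
class ThermodynamicCycle:
    """Legs of the relative binding cycle (all in kJ/mol).

    ``dg_bulk`` (Delta G_1) and ``dg_bound`` (Delta G_2) are alchemical legs;
    ``dg_unbind_A``/``dg_unbind_B`` (Delta G_3 / Delta G_4) are optional
    physical (PMF) legs.  When all four are supplied the cycle must close:
    Delta G_2 - Delta G_1 = Delta G_4 - Delta G_3.
    """

    dg_bulk: ReplicaSet
    dg_bound: ReplicaSet
    dg_unbind_A: ReplicaSet | None = None
    dg_unbind_B: ReplicaSet | None = None
    label: str = ""

    @property
    def ddg(self) -> tuple[float, float]:
        return ddg(self.dg_bound, self.dg_bulk)

    def closure(self) -> tuple[float, float] | None:
        """|(DG2 - DG1) - (DG4 - DG3)| with combined error, if all legs present."""
        if self.dg_unbind_A is None or self.dg_unbind_B is None:
            return None
        alch, e1 = self.ddg
        phys, e2 = ddg(self.dg_unbind_B, self.dg_unbind_A)
        return abs(alch - phys), math.hypot(e1, e2)


def closure_check(
    step_ddgs: Sequence[tuple[float, float]],
    direct_ddg: tuple[float, float],
    multiplier: float = 3.0,
) -> tuple[float, float, bool]:
    """Compare a stepwise-summed DDG against the direct transformation.

    Returns ``(discrepancy, combined_error, passed)`` where the combined
    error adds all step errors and the direct error in quadrature and the
    check passes when ``discrepancy <= multiplier * combined_error``.
    """
    if not step_ddgs:
        raise ValueError("need at least one step")
    total = sum(v for v, _ in step_ddgs)
    err2 = sum(e * e for _, e in step_ddgs) + direct_ddg[1] ** 2
    discrepancy = abs(total - direct_ddg[0])
    combined = math.sqrt(err2)
    return discrepancy, combined, discrepancy <= multiplier * combined
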