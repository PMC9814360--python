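"""File formats: coordinates (GRO/PDB), index groups, trajectories,
reduced-energy matrices and YAML round-trips for systems/topologies.

Conventions
-----------
* GRO: fixed-column format, positions in nm, three-decimal precision.
* PDB: ATOM records with coordinates in Angstrom, converted to nm on read.
* Index files: named groups of 1-based bead indices (``[ name ]`` sections);
  indices are 0-based everywhere inside the package.
* Energy matrices: one plain-text file per sampled state; the header names
  every state's (lambda_coul, lambda_vdw) pair and the sampled state; each
  data row holds the sample's reduced energy in every state at full
  precision.
* Trajectories: a columnar XYZ-per-frame dialect with the frame's reduced
  potential in the frame header.

Malformed records raise :class:`FileFormatError` carrying the offending line
number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .model import (
    AlchemicalState,
    AlchemicalTopology,
    BeadType,
    Bond,
    CGSystem,
    ElasticLink,
)
from .sampler import EnergyMatrix, Trajectory

__all__ = [
    "FileFormatError",
    "read_coordinates",
    "write_coordinates",
    "read_index",
    "write_index",
    "read_energy_matrix",
    "write_energy_matrix",
    "read_trajectory",
    "write_trajectory",
    "system_to_dict",
    "system_from_dict",
    "topology_to_dict",
    "topology_from_dict",
    "save_run_config",
    "load_run_config",
]


class FileFormatError(ValueError):
    """A malformed record, reported with its file and line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------


def write_coordinates(
    system: CGSystem, path, dialect: str = "gro", title: str = "cgfep system"
) -> None:
    """Write bead coordinates in GRO (nm) or PDB (Angstrom) dialect."""
    path = Path(path)
    if dialect == "gro":
        lines = [title, f"{system.n_beads:5d}"]
        for i, (b, pos) in enumerate(zip(system.beads, system.positions), start=1):
            lines.append(
                f"{1:5d}{'TOY':<5s}{b.name[:5]:>5s}{i % 100000:5d}"
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
            )
        lines.append(f"{system.box[0]:10.5f}{system.box[1]:10.5f}{system.box[2]:10.5f}")
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "pdb":
        lines = [
            f"CRYST1{system.box[0]*10:9.3f}{system.box[1]*10:9.3f}"
            f"{system.box[2]*10:9.3f}  90.00  90.00  90.00 P 1           1"
        ]
        for i, (b, pos) in enumerate(zip(system.beads, system.positions), start=1):
            x, y, z = (pos * 10.0).tolist()  # nm -> Angstrom
            lines.append(
                f"ATOM  {i:5d} {b.name[:4]:<4s} TOY A{1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'gro' or 'pdb'")


def read_coordinates(path, dialect: str | None = None) -> CGSystem:
    """Read a CGSystem skeleton (names, positions, box) from GRO or PDB.

    Bead types carry only the name; charges and LJ parameters default to
    zero and must come from a topology.  PDB coordinates are interpreted in
    Angstrom and converted to nm.
    """
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower() or "gro"
    if dialect == "gro":
        return _read_gro(path)
    if dialect == "pdb":
        return _read_pdb(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'gro' or 'pdb'")


def _read_gro(path: Path) -> CGSystem:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise FileFormatError(path, len(lines), "truncated GRO file (need title, count, box)")
    try:
        n = int(lines[1].strip())
    except ValueError:
        raise FileFormatError(path, 2, f"invalid atom count {lines[1]!r}") from None
    if len(lines) < n + 3:
        raise FileFormatError(
            path, len(lines), f"truncated GRO file: expected {n} atom records"
        )
    beads, pos, groups = [], [], {}
    for k in range(n):
        ln = lines[2 + k]
        line_no = 3 + k
        if len(ln) < 44:
            raise FileFormatError(path, line_no, f"GRO record too short: {ln!r}")
        try:
            name = ln[10:15].strip()
            resid = int(ln[0:5])
            xyz = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        except ValueError:
            raise FileFormatError(path, line_no, f"malformed GRO record: {ln!r}") from None
        beads.append(BeadType(name=name or "X"))
        pos.append(xyz)
        groups.setdefault(name, []).append(k)
        groups.setdefault(f"res_{resid}", []).append(k)
    box_line = lines[2 + n]
    try:
        box = [float(v) for v in box_line.split()[:3]]
        if len(box) < 3:
            raise ValueError
    except ValueError:
        raise FileFormatError(path, 3 + n, f"malformed box line: {box_line!r}") from None
    return CGSystem(
        beads=beads,
        positions=np.array(pos),
        box=np.array(box),
        groups={k: tuple(v) for k, v in groups.items()},
    )


def _read_pdb(path: Path) -> CGSystem:
    beads, pos, groups = [], [], {}
    box = np.array([10.0, 10.0, 10.0])
    k = 0
    for line_no, ln in enumerate(path.read_text().splitlines(), start=1):
        rec = ln[:6].strip()
        if rec == "CRYST1":
            try:
                box = np.array([float(ln[6:15]), float(ln[15:24]), float(ln[24:33])]) / 10.0
            except ValueError:
                raise FileFormatError(path, line_no, f"malformed CRYST1: {ln!r}") from None
        elif rec in ("ATOM", "HETATM"):
            if len(ln) < 54:
                raise FileFormatError(path, line_no, f"ATOM record too short: {ln!r}")
            try:
                name = ln[12:16].strip()
                resid = int(ln[22:26])
                xyz = [float(ln[30:38]) / 10.0, float(ln[38:46]) / 10.0, float(ln[46:54]) / 10.0]
            except ValueError:
                raise FileFormatError(path, line_no, f"malformed ATOM record: {ln!r}") from None
            beads.append(BeadType(name=name or "X"))
            pos.append(xyz)
            groups.setdefault(name, []).append(k)
            groups.setdefault(f"res_{resid}", []).append(k)
            k += 1
    if not beads:
        raise FileFormatError(path, 1, "no ATOM records found")
    return CGSystem(
        beads=beads,
        positions=np.array(pos),
        box=box,
        groups={k: tuple(v) for k, v in groups.items()},
    )


# ---------------------------------------------------------------------------
# Index groups
# ---------------------------------------------------------------------------


def write_index(groups: Mapping[str, Sequence[int]], path) -> None:
    """Write named groups as 1-based indices (GROMACS .ndx-style)."""
    lines = []
    for name, idx in groups.items():
        lines.append(f"[ {name} ]")
        one_based = [str(i + 1) for i in idx]
        for start in range(0, len(one_based), 15):
            lines.append(" ".join(one_based[start : start + 15]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_index(path) -> dict[str, tuple[int, ...]]:
    """Read named groups; file indices are 1-based, returned 0-based."""
    groups: dict[str, list[int]] = {}
    current = None
    for line_no, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        s = ln.strip()
        if not s:
            continue
        if s.startswith("[") and s.endswith("]"):
            current = s[1:-1].strip()
            groups[current] = []
        else:
            if current is None:
                raise FileFormatError(path, line_no, "indices before any [ group ] header")
            try:
                vals = [int(v) for v in s.split()]
            except ValueError:
                raise FileFormatError(path, line_no, f"non-integer index in {s!r}") from None
            for v in vals:
                if v < 1:
                    raise FileFormatError(path, line_no, f"index {v} not 1-based positive")
                groups[current].append(v - 1)
    return {k: tuple(v) for k, v in groups.items()}


# ---------------------------------------------------------------------------
# Energy matrices
# ---------------------------------------------------------------------------


def write_energy_matrix(matrix: EnergyMatrix, directory) -> list[Path]:
    """Write one full-precision text file per sampled state.

    Each file repeats the complete state table in its header, so any subset
    of files can be validated for consistency on read.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    states = list(matrix.states)
    if len(states) != matrix.n_states:
        states = [AlchemicalState(0.0, 0.0, window_index=k) for k in range(matrix.n_states)]
    header = ["# cgfep reduced-energy matrix", f"# n_states {matrix.n_states}"]
    for k, s in enumerate(states):
        header.append(f"# state {k} {float(s.lambda_coul)!r} {float(s.lambda_vdw)!r}")
    paths = []
    for k in range(matrix.n_states):
        nk = int(matrix.N_k[k])
        if nk == 0:
            continue
        sl = matrix.state_slice(k)
        block = matrix.u_kn[:, sl]  # (K, nk)
        p = directory / f"state_{k:03d}.u.dat"
        with open(p, "w") as fh:
            fh.write("\n".join(header) + "\n")
            fh.write(f"# sampled_state {k}\n# n_samples {nk}\n")
            for ncol in range(block.shape[1]):
                fh.write(" ".join(repr(float(v)) for v in block[:, ncol]) + "\n")
        paths.append(p)
    return paths


def read_energy_matrix(paths) -> EnergyMatrix:
    """Assemble an EnergyMatrix from per-state files (order-independent).

    ``paths`` may be a directory or an iterable of files.  Files are sorted
    by their sampled-state index; headers must agree across files.
    """
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        paths = sorted(Path(paths).glob("state_*.u.dat"))
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no energy-matrix files given")

    parsed = []
    state_table = None
    for p in paths:
        states, sampled, rows = _parse_energy_file(p)
        if state_table is None:
            state_table = states
        elif states != state_table:
            raise FileFormatError(p, 1, "state header mismatch between files")
        parsed.append((sampled, rows, p))
    parsed.sort(key=lambda t: t[0])

    K = len(state_table)
    N_k = np.zeros(K, dtype=int)
    cols = []
    for sampled, rows, p in parsed:
        if not 0 <= sampled < K:
            raise FileFormatError(p, 1, f"sampled_state {sampled} out of range")
        N_k[sampled] += rows.shape[1]
        cols.append(rows)
    u_kn = np.concatenate(cols, axis=1)
    states = tuple(
        AlchemicalState(lc, lv, window_index=k)
        for k, (lc, lv) in enumerate(state_table)
    )
    return EnergyMatrix(u_kn=u_kn, N_k=N_k, states=states)


def _parse_energy_file(path: Path):
    states: list[tuple[float, float]] = []
    sampled = None
    n_states = None
    data = []
    for line_no, ln in enumerate(path.read_text().splitlines(), start=1):
        s = ln.strip()
        if not s:
            continue
        if s.startswith("#"):
            toks = s[1:].split()
            if toks[:1] == ["n_states"]:
                n_states = int(toks[1])
            elif toks[:1] == ["state"]:
                try:
                    states.append((float(toks[2]), float(toks[3])))
                except (IndexError, ValueError):
                    raise FileFormatError(path, line_no, f"malformed state header: {s!r}") from None
            elif toks[:1] == ["sampled_state"]:
                sampled = int(toks[1])
            continue
        try:
            row = [float(v) for v in s.split()]
        except ValueError:
            raise FileFormatError(path, line_no, f"non-numeric energy row: {s!r}") from None
        if n_states is not None and len(row) != n_states:
            raise FileFormatError(
                path, line_no,
                f"row has {len(row)} columns, expected {n_states} states "
                f"(missing state column)",
            )
        data.append(row)
    if sampled is None or not states:
        raise FileFormatError(path, 1, "missing sampled_state or state table in header")
    return states, sampled, np.array(data).T  # (K, n)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, path) -> None:
    """Columnar XYZ-per-frame text dialect with reduced potentials."""
    with open(Path(path), "w") as fh:
        fh.write("# cgfep trajectory\n")
        fh.write(
            f"# state {float(traj.state.lambda_coul)!r} {float(traj.state.lambda_vdw)!r} "
            f"{traj.state.window_index}\n"
        )
        fh.write(f"# seed {traj.seed} stride {traj.stride} "
                 f"acceptance {float(traj.acceptance_rate)!r}\n")
        fh.write(f"# n_frames {traj.n_frames} n_beads {traj.frames.shape[1]}\n")
        for f in range(traj.n_frames):
            fh.write(f"# frame {f} u {float(traj.potentials[f])!r}\n")
            for pos in traj.frames[f]:
                fh.write(f"{float(pos[0])!r} {float(pos[1])!r} {float(pos[2])!r}\n")


def read_trajectory(path) -> Trajectory:
    state = AlchemicalState(0.0, 0.0)
    seed, stride, acc = 0, 1, float("nan")
    frames, potentials, current = [], [], []
    n_beads = None
    for line_no, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        s = ln.strip()
        if not s:
            continue
        if s.startswith("#"):
            toks = s[1:].split()
            if toks[:1] == ["state"]:
                state = AlchemicalState(float(toks[1]), float(toks[2]), int(toks[3]))
            elif toks[:1] == ["seed"]:
                seed, stride = int(toks[1]), int(toks[3])
                acc = float(toks[5])
            elif toks[:1] == ["n_frames"]:
                n_beads = int(toks[3])
            elif toks[:1] == ["frame"]:
                if current:
                    frames.append(current)
                    current = []
                potentials.append(float(toks[3]))
            continue
        try:
            current.append([float(v) for v in s.split()])
        except ValueError:
            raise FileFormatError(path, line_no, f"malformed coordinate row: {s!r}") from None
    if current:
        frames.append(current)
    if not frames:
        raise FileFormatError(path, 1, "no frames found")
    arr = np.array(frames)
    if n_beads is not None and arr.shape[1] != n_beads:
        raise FileFormatError(path, 1, f"expected {n_beads} beads per frame, got {arr.shape[1]}")
    return Trajectory(
        frames=arr, state=state, potentials=np.array(potentials),
        seed=seed, stride=stride, acceptance_rate=acc,
    )


# ---------------------------------------------------------------------------
# YAML round-trips for systems / topologies / run configs
# ---------------------------------------------------------------------------


def system_to_dict(system: CGSystem) -> dict:
    return {
        "beads": [
            {"name": b.name, "charge": b.charge, "lj_epsilon": b.lj_epsilon,
             "lj_sigma": b.lj_sigma}
            for b in system.beads
        ],
        "positions": np.asarray(system.positions).tolist(),
        "box": np.asarray(system.box).tolist(),
        "bonds": [[b.i, b.j, b.r0, b.k] for b in system.bonds],
        "elastic_network": [[e.i, e.j, e.r0, e.k] for e in system.elastic_network],
        "groups": {k: list(v) for k, v in system.groups.items()},
    }


def system_from_dict(d: Mapping) -> CGSystem:
    return CGSystem(
        beads=[BeadType(**b) for b in d["beads"]],
        positions=np.array(d["positions"], dtype=float),
        box=np.array(d["box"], dtype=float),
        bonds=[Bond(int(i), int(j), float(r0), float(k)) for i, j, r0, k in d.get("bonds", [])],
        elastic_network=[
            ElasticLink(int(i), int(j), float(r0), float(k))
            for i, j, r0, k in d.get("elastic_network", [])
        ],
        groups={k: tuple(v) for k, v in d.get("groups", {}).items()},
    )


def topology_to_dict(t: AlchemicalTopology) -> dict:
    return {
        "charge_A": t.charge_A.tolist(), "charge_B": t.charge_B.tolist(),
        "eps_A": t.eps_A.tolist(), "eps_B": t.eps_B.tolist(),
        "sigma_A": t.sigma_A.tolist(), "sigma_B": t.sigma_B.tolist(),
        "bond_perturbations": {int(k): list(v) for k, v in t.bond_perturbations.items()},
    }


def topology_from_dict(d: Mapping) -> AlchemicalTopology:
    return AlchemicalTopology(
        charge_A=np.array(d["charge_A"]), charge_B=np.array(d["charge_B"]),
        eps_A=np.array(d["eps_A"]), eps_B=np.array(d["eps_B"]),
        sigma_A=np.array(d["sigma_A"]), sigma_B=np.array(d["sigma_B"]),
        bond_perturbations={
            int(k): tuple(float(x) for x in v)
            for k, v in d.get("bond_perturbations", {}).items()
        },
    )


def save_run_config(config: Mapping, path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(config), sort_keys=False))


def load_run_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
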