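"""Binding-site annotation and stability analysis from bead trajectories.

Works on raw frame arrays ``(F, N, 3)`` in nm with an orthorhombic periodic
box, the representation written by :mod:`cgfep.sampler`.  Distances use the
minimum-image convention throughout, so contact calls are invariant to
periodic re-wrapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import minimum_image

__all__ = [
    "ContactProfile",
    "contact_fraction",
    "contact_profile",
    "proximal_residues",
    "min_distance_series",
    "rmsd_series",
    "running_average",
]

#: Default contact cutoff: 6 Angstrom.
DEFAULT_CUTOFF = 0.6  # nm

#: Default proximal-residue threshold: strictly greater than 75 % of frames.
DEFAULT_THRESHOLD = 0.75


@dataclass
class ContactProfile:
    """Per-residue fraction of frames spent within the contact cutoff."""

    fractions: Mapping[str, float]
    cutoff: float
    n_frames: int

    def __post_init__(self) -> None:
        for name, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"contact fraction for {name!r} outside [0, 1]")


def _check_frames(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("need a nonempty (F, N, 3) trajectory")
    return frames


def _min_cross_distance(
    frames: np.ndarray, box: np.ndarray, group_a: Sequence[int], group_b: Sequence[int]
) -> np.ndarray:
    """Per-frame minimum distance over all cross pairs (minimum image)."""
    a = frames[:, list(group_a), :]  # (F, A, 3)
    b = frames[:, list(group_b), :]  # (F, B, 3)
    d = minimum_image(a[:, :, None, :] - b[:, None, :, :], np.asarray(box, float))
    r = np.sqrt(np.sum(d * d, axis=-1))  # (F, A, B)
    return r.reshape(r.shape[0], -1).min(axis=1)


def contact_fraction(
    frames: np.ndarray,
    box: np.ndarray,
    residue_group: Sequence[int],
    lipid_group: Sequence[int],
    cutoff: float = DEFAULT_CUTOFF,
) -> float:
    """Fraction of frames with any residue bead within ``cutoff`` of any lipid bead."""
    frames = _check_frames(frames)
    if not len(residue_group) or not len(lipid_group):
        raise ValueError("groups must be nonempty")
    dmin = _min_cross_distance(frames, box, residue_group, lipid_group)
    return float(np.mean(dmin < cutoff))


def contact_profile(
    frames: np.ndarray,
    box: np.ndarray,
    residue_groups: Mapping[str, Sequence[int]],
    lipid_group: Sequence[int],
    cutoff: float = DEFAULT_CUTOFF,
) -> ContactProfile:
    """Contact fractions for a set of residues against one lipid."""
    frames = _check_frames(frames)
    fr = {
        name: contact_fraction(frames, box, idx, lipid_group, cutoff)
        for name, idx in residue_groups.items()
    }
    return ContactProfile(fractions=fr, cutoff=cutoff, n_frames=frames.shape[0])


def _residue_number(name: str) -> int:
    digits = "".join(c for c in str(name) if c.isdigit())
    return int(digits) if digits else 0


def proximal_residues(
    profile: ContactProfile, threshold: float = DEFAULT_THRESHOLD
) -> list[str]:
    """Residues whose contact fraction is *strictly* greater than ``threshold``.

    The strict inequality follows the ">75 %" (or the variant ">70 %")
    convention; results are sorted by residue number.
    """
    hits = [name for name, f in profile.fractions.items() if f > threshold]
    return sorted(hits, key=lambda n: (_residue_number(n), n))


def min_distance_series(
    frames: np.ndarray,
    box: np.ndarray,
    group_a: Sequence[int],
    group_b: Sequence[int],
) -> np.ndarray:
    """Per-frame minimum distance (nm) between two bead groups."""
    frames = _check_frames(frames)
    if not len(group_a) or not len(group_b):
        raise ValueError("groups must be nonempty")
    return _min_cross_distance(frames, box, group_a, group_b)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation R and centroids aligning P onto Q (both centered)."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cp, cq


def rmsd_series(
    frames: np.ndarray,
    reference: np.ndarray,
    fit_group: Sequence[int],
    measure_group: Sequence[int] | None = None,
) -> np.ndarray:
    """RMSD (Angstrom) of ``measure_group`` after least-squares superposition.

    Each frame is rigid-body superposed onto the reference by the rotation
    and translation minimizing the fit-group RMSD (Kabsch); the RMSD is then
    evaluated over ``measure_group`` (default: the fit group).  Coordinates
    are in nm; the series is reported in Angstrom, the unit convention of
    structural figures.
    """
    frames = _check_frames(frames)
    reference = np.asarray(reference, dtype=float)
    fit = list(fit_group)
    meas = fit if measure_group is None else list(measure_group)
    if len(fit) < 3:
        raise ValueError("need at least 3 fit beads for a rigid superposition")
    ref_fit = reference[fit]
    spread = ref_fit - ref_fit.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-10) < 2:
        raise ValueError("fit beads are collinear; superposition is degenerate")
    out = np.empty(frames.shape[0])
    ref_meas = reference[meas]
    for t, fr in enumerate(frames):
        R, cp, cq = _kabsch(fr[fit], ref_fit)
        moved = (fr[meas] - cp) @ R.T + cq
        out[t] = np.sqrt(np.mean(np.sum((moved - ref_meas) ** 2, axis=-1)))
    return out * 10.0  # nm -> Angstrom


def running_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean with shrinking windows at the edges.

    ``window = 1`` is the identity; even windows extend one point further to
    the left.
    """
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > x.size:
        raise ValueError(f"window {window} exceeds series length {x.size}")
    half_lo = window // 2
    half_hi = (window - 1) // 2
    out = np.empty_like(x)
    for t in range(x.size):
        lo = max(0, t - half_lo)
        hi = min(x.size, t + half_hi + 1)
        out[t] = x[lo:hi].mean()
    return out
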