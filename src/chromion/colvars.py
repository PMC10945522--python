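"""Reaction coordinates: DNA end-to-end distance, unwrapped base pairs,
nucleosome centers/plane normals, inter-nucleosome distance r and plane
angle theta, and the two-start-helix similarity.

Every continuous CV returns ``(value, gradient)`` with the gradient an
exact derivative with respect to all bead positions (finite-difference
testable), so each can drive a harmonic umbrella bias.  The plane normal is
the eigenvector of the wrapped-DNA gyration tensor with the smallest
eigenvalue (the superhelical axis); its derivative follows from first-order
eigenvector perturbation theory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CVValue", "end_to_end", "unwrapped_bp", "nucleosome_geometry",
    "pair_cv", "twostart_similarity", "twostart_reference", "distance_cv",
]


@dataclass
class CVValue:
    name: str
    value: float
    gradient: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# simple distances


def _group_center(positions, idx):
    return positions[np.asarray(idx, int)].mean(axis=0)


def distance_cv(positions: np.ndarray, group_a: Sequence[int],
                group_b: Sequence[int]) -> Tuple[float, np.ndarray]:
    """Distance between the geometric centers of two bead groups, with gradient."""
    ia, ib = np.asarray(group_a, int), np.asarray(group_b, int)
    d = _group_center(positions, ia) - _group_center(positions, ib)
    r = float(np.linalg.norm(d))
    grad = np.zeros_like(positions)
    if r > 1e-12:
        u = d / r
        grad[ia] += u / len(ia)
        grad[ib] -= u / len(ib)
    return r, grad


def end_to_end(positions: np.ndarray, assembly) -> Tuple[float, np.ndarray]:
    """Distance between the two terminal base-pair centers of the duplex."""
    if assembly.n_bp < 2:
        raise ValueError("need at least two base pairs")
    first = assembly.bp_bead_indices[0][:4]    # S/B beads of the terminal bp
    last = assembly.bp_bead_indices[-1][:4]
    return distance_cv(positions, first, last)


# ---------------------------------------------------------------------------
# unwrapping


def unwrapped_bp(positions: np.ndarray, assembly, threshold: Optional[float] = None,
                 margin: float = 10.0) -> int:
    """Number of unwrapped base pairs, counted inward from both DNA ends.

    A wrapped base pair counts as detached when the minimum distance from
    any of its beads to any histone-core bead exceeds ``threshold``
    (default: its build-time native distance plus ``margin`` A).  The count
    is the sum of the two contiguous detached end segments.
    """
    core = np.asarray(assembly.histone_core_beads, int)
    if len(core) == 0:
        return 0
    cpos = positions[core]
    detached = []
    for k, bp in enumerate(assembly.wrapped_bp):
        bpos = positions[assembly.bp_bead_indices[bp]]
        dmin = np.min(np.linalg.norm(cpos[:, None, :] - bpos[None, :, :], axis=2))
        thr = threshold if threshold is not None else assembly.native_bp_core_dist[k] + margin
        detached.append(dmin > thr)
    n = len(detached)
    left = 0
    while left < n and detached[left]:
        left += 1
    right = 0
    while right < n - left and detached[n - 1 - right]:
        right += 1
    return left + right


# ---------------------------------------------------------------------------
# nucleosome plane geometry


def _gyration_axis(positions, idx):
    """Smallest-eigenvalue eigenvector of the gyration tensor of a bead group."""
    x = positions[np.asarray(idx, int)]
    c = x.mean(axis=0)
    d = x - c
    G = d.T @ d / len(x)
    lam, V = np.linalg.eigh(G)       # ascending
    if lam[1] - lam[0] < 1e-8 * max(lam[2], 1e-12):
        raise ValueError("degenerate bead geometry: plane normal undefined "
                         "(smallest two gyration eigenvalues coincide)")
    w = V[:, 0]
    # projector for eigenvector perturbation: sum_m!=0 v_m v_m^T/(lam_0-lam_m)
    P = (np.outer(V[:, 1], V[:, 1]) / (lam[0] - lam[1])
         + np.outer(V[:, 2], V[:, 2]) / (lam[0] - lam[2]))
    return c, w, d, P


def nucleosome_geometry(positions: np.ndarray, assembly=None,
                        bead_indices: Optional[Sequence[int]] = None,
                        orient: Optional[np.ndarray] = None):
    """Geometric center and unit plane normal of a nucleosome.

    The normal is computed from the wrapped-DNA beads and sign-fixed along
    ``orient`` (default: the assembly dyad frame axis, else the first
    non-zero component made positive).
    """
    if bead_indices is None:
        bead_indices = assembly.wrapped_dna_beads()
        if orient is None and assembly is not None:
            orient = assembly.bp_frames.e3[assembly.dyad_bp]
    idx = np.asarray(bead_indices, int)
    center = _group_center(positions, idx)
    _, w, _, _ = _gyration_axis(positions, idx)
    if orient is not None and float(w @ np.asarray(orient, float)) < 0:
        w = -w
    elif orient is None:
        k = int(np.argmax(np.abs(w)))
        if w[k] < 0:
            w = -w
    return center, w


def _axis_dot_gradient(positions, idx, w_self, P_self, d_self, other_axis):
    """Gradient of (w_self . other_axis) wrt the beads defining w_self."""
    idx = np.asarray(idx, int)
    n = len(idx)
    Pw = P_self @ other_axis
    # per bead k: [ (d_k . w) Pw + (d_k . Pw) w ] / n
    dk_w = d_self @ w_self
    dk_Pw = d_self @ Pw
    g = (dk_w[:, None] * Pw[None, :] + dk_Pw[:, None] * w_self[None, :]) / n
    grad = np.zeros_like(positions)
    grad[idx] = g
    return grad


def pair_cv(positions: np.ndarray, assembly1=None, assembly2=None,
            beads1: Optional[Sequence[int]] = None,
            beads2: Optional[Sequence[int]] = None,
            gradients: bool = False):
    """Inter-nucleosome distance r (A) and plane angle theta (deg, in [0, 90]).

    r is the distance between the geometric centers of the two nucleosomes;
    theta = arccos(|w1 . w2|) folds the unsigned plane angle into
    [0, 90] degrees.  With ``gradients=True`` returns
    ``(r, theta, grad_r, grad_theta)``.
    """
    if beads1 is None:
        beads1 = assembly1.nucleosome_beads
    if beads2 is None:
        beads2 = assembly2.nucleosome_beads
    ax1 = assembly1.wrapped_dna_beads() if assembly1 is not None else beads1
    ax2 = assembly2.wrapped_dna_beads() if assembly2 is not None else beads2

    r, grad_r = distance_cv(positions, beads1, beads2)
    _, w1, d1, P1 = _gyration_axis(positions, ax1)
    _, w2, d2, P2 = _gyration_axis(positions, ax2)
    c = float(w1 @ w2)
    theta = float(np.degrees(np.arccos(np.clip(abs(c), 0.0, 1.0))))
    if not gradients:
        return r, theta
    s2 = max(1.0 - c * c, 1e-12)
    pref = -np.sign(c) / np.sqrt(s2) * (180.0 / np.pi)
    grad_theta = pref * (_axis_dot_gradient(positions, ax1, w1, P1, d1, w2)
                         + _axis_dot_gradient(positions, ax2, w2, P2, d2, w1))
    return r, theta, grad_r, grad_theta


# ---------------------------------------------------------------------------
# two-start-helix similarity


def twostart_similarity(positions: np.ndarray, center_groups: List[Sequence[int]],
                        reference_distances: dict, width: float = 10.0,
                        gradients: bool = False):
    """Smooth similarity to a reference two-start helical stack.

    ``Q = (1/N_pairs) sum_ij exp(-(d_ij - d_ij^ref)^2 / (2 width^2))`` over
    the nucleosome-center pairs (i, i+1) and (i, i+2) present in
    ``reference_distances`` (a dict mapping ``(i, j)`` to the reference
    center distance in A).  Q is in (0, 1], equals 1 exactly at the
    reference geometry, and is differentiable everywhere.
    """
    if len(center_groups) < 2:
        raise ValueError("need at least two nucleosomes for the two-start CV")
    if not reference_distances:
        raise ValueError("empty reference pair list")
    centers = np.array([_group_center(positions, g) for g in center_groups])
    q = 0.0
    grad = np.zeros_like(positions) if gradients else None
    for (i, j), dref in reference_distances.items():
        d = centers[i] - centers[j]
        r = float(np.linalg.norm(d))
        g = np.exp(-((r - dref) ** 2) / (2.0 * width ** 2))
        q += g
        if gradients and r > 1e-12:
            coef = -g * (r - dref) / width ** 2
            u = coef * d / r
            gi = np.asarray(center_groups[i], int)
            gj = np.asarray(center_groups[j], int)
            grad[gi] += u / len(gi)
            grad[gj] -= u / len(gj)
    npairs = len(reference_distances)
    q /= npairs
    if gradients:
        return q, grad / npairs
    return q


def twostart_reference(center_positions: np.ndarray) -> dict:
    """Reference (i, i+1)/(i, i+2) center distances from a reference structure."""
    n = len(center_positions)
    if n < 2:
        raise ValueError("reference needs at least two nucleosomes")
    ref = {}
    for i in range(n):
        for j in (i + 1, i + 2):
            if j < n:
                ref[(i, j)] = float(np.linalg.norm(center_positions[i]
                                                   - center_positions[j]))
    return ref
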