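"""Idealized DNA geometry: base-pair frames and site placement.

A duplex is built from a sequence of base-pair *frames*.  Each frame is a
rigid triad (origin, e1, e2, e3) with e3 the local helical axis, plus an
accumulated twist angle about e3.  Straight B-form frames advance 3.4 A and
36 deg per base pair; superhelical frames wrap the same cross-section around
a left-handed superhelix (the nucleosome wrap).  Site coordinates are
obtained by stamping a fixed cross-section template into every frame, which
keeps the builder deterministic and sequence-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RISE", "TWIST_DEG", "BPFrames",
    "straight_frames", "superhelix_frames", "extend_frames",
    "duplex_site_positions", "rotation_matrix",
]

#: helical rise per base pair, A
RISE = 3.4
#: helical twist per base pair, degrees
TWIST_DEG = 36.0

# cross-section template radii (A) and angles (rad)
R_SUGAR = 6.9
R_PHOSPHATE = 8.9
R_BASE = 3.5
GAMMA = np.deg2rad(70.0)          # strand half-separation angle
PHOS_LEAD = np.deg2rad(18.0)      # phosphate sits half-way between sugars
PHOS_DZ = RISE / 2.0


@dataclass
class BPFrames:
    """Per-base-pair rigid frames of a duplex axis."""

    origins: np.ndarray   # (n, 3)
    e1: np.ndarray        # (n, 3)
    e2: np.ndarray        # (n, 3)
    e3: np.ndarray        # (n, 3)
    twist: np.ndarray     # (n,) accumulated twist, rad

    def __len__(self):
        return len(self.origins)


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (non-zero) axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        return np.eye(3)
    x, y, z = axis / n
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def straight_frames(n_bp: int, origin=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0),
                    ref=(1.0, 0.0, 0.0), twist0: float = 0.0) -> BPFrames:
    """Frames of a straight B-form axis starting at ``origin`` along ``axis``."""
    axis = np.asarray(axis, float)
    e3 = axis / np.linalg.norm(axis)
    ref = np.asarray(ref, float)
    e1 = ref - np.dot(ref, e3) * e3
    if np.linalg.norm(e1) < 1e-10:
        ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - np.dot(ref, e3) * e3
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(e3, e1)
    ii = np.arange(n_bp)[:, None]
    origins = np.asarray(origin, float) + ii * RISE * e3
    twist = twist0 + np.arange(n_bp) * np.deg2rad(TWIST_DEG)
    ones = np.ones((n_bp, 1))
    return BPFrames(origins, ones * e1, ones * e2, ones * e3, twist)


def superhelix_frames(n_bp: int, radius: float = 41.8, pitch: float = 25.9,
                      turns: float = 1.65) -> BPFrames:
    """Frames wrapped on a left-handed superhelix (nucleosome geometry).

    ``radius`` and ``pitch`` in A; ``turns`` superhelical turns spread over
    ``n_bp`` base pairs.  The superhelix axis is the global z axis, centered
    at the origin.
    """
    s = np.linspace(0.0, 1.0, n_bp)
    alpha = -2.0 * np.pi * turns * (s - 0.5)   # left-handed
    z = pitch * turns * (s - 0.5)
    origins = np.stack([radius * np.cos(alpha), radius * np.sin(alpha), z], axis=1)
    # tangent of the superhelical curve
    dalpha = alpha[1] - alpha[0] if n_bp > 1 else 1.0
    dz = z[1] - z[0] if n_bp > 1 else 0.0
    t = np.stack([-radius * np.sin(alpha) * dalpha,
                  radius * np.cos(alpha) * dalpha,
                  np.full(n_bp, dz)], axis=1)
    t /= np.linalg.norm(t, axis=1)[:, None]
    # e1 points outward from the superhelix axis, orthogonalized against t
    rad = np.stack([np.cos(alpha), np.sin(alpha), np.zeros(n_bp)], axis=1)
    e1 = rad - np.sum(rad * t, axis=1)[:, None] * t
    e1 /= np.linalg.norm(e1, axis=1)[:, None]
    e2 = np.cross(t, e1)
    twist = np.arange(n_bp) * np.deg2rad(TWIST_DEG)
    return BPFrames(origins, e1, e2, t, twist)


def extend_frames(frames: BPFrames, n_extra: int, prepend: bool = False) -> BPFrames:
    """Continue a frame set tangentially by ``n_extra`` straight base pairs."""
    if n_extra <= 0:
        return frames
    if prepend:
        o, e1, e2, e3 = frames.origins[0], frames.e1[0], frames.e2[0], frames.e3[0]
        tw = frames.twist[0]
        ks = np.arange(n_extra, 0, -1)
        origins = o - ks[:, None] * RISE * e3
        twist = tw - ks * np.deg2rad(TWIST_DEG)
        ones = np.ones((n_extra, 1))
        return BPFrames(
            np.vstack([origins, frames.origins]),
            np.vstack([ones * e1, frames.e1]),
            np.vstack([ones * e2, frames.e2]),
            np.vstack([ones * e3, frames.e3]),
            np.concatenate([twist, frames.twist]),
        )
    o, e1, e2, e3 = frames.origins[-1], frames.e1[-1], frames.e2[-1], frames.e3[-1]
    tw = frames.twist[-1]
    ks = np.arange(1, n_extra + 1)
    origins = o + ks[:, None] * RISE * e3
    twist = tw + ks * np.deg2rad(TWIST_DEG)
    ones = np.ones((n_extra, 1))
    return BPFrames(
        np.vstack([frames.origins, origins]),
        np.vstack([frames.e1, ones * e1]),
        np.vstack([frames.e2, ones * e2]),
        np.vstack([frames.e3, ones * e3]),
        np.concatenate([frames.twist, twist]),
    )


def _site(frames: BPFrames, i: int, radius: float, angle: float, dz: float) -> np.ndarray:
    a = frames.twist[i] + angle
    return (frames.origins[i]
            + radius * np.cos(a) * frames.e1[i]
            + radius * np.sin(a) * frames.e2[i]
            + dz * frames.e3[i])


def duplex_site_positions(n_bp: int, frames: BPFrames):
    """Coordinates of all duplex sites stamped into ``frames``.

    Returns ``(watson, crick)`` where each is a dict with arrays:
    ``sugar`` (n,3), ``base`` (n,3) indexed by that strand's own 5'->3'
    nucleotide order, and ``phosphate`` (n-1,3) where phosphate k joins
    nucleotides k-1 and k of the strand (no 5'-terminal phosphate).
    """
    if len(frames) != n_bp:
        raise ValueError("frame count does not match base-pair count")
    w_s = np.array([_site(frames, i, R_SUGAR, GAMMA, 0.0) for i in range(n_bp)])
    w_b = np.array([_site(frames, i, R_BASE, GAMMA, 0.0) for i in range(n_bp)])
    # Watson phosphate k (k=1..n-1) between sugars k-1, k: stamp near bp k
    w_p = np.array([_site(frames, k, R_PHOSPHATE, GAMMA - PHOS_LEAD, -PHOS_DZ)
                    for k in range(1, n_bp)])
    # Crick nucleotide j corresponds to bp index n-1-j
    c_s = np.array([_site(frames, n_bp - 1 - j, R_SUGAR, -GAMMA, 0.0) for j in range(n_bp)])
    c_b = np.array([_site(frames, n_bp - 1 - j, R_BASE, -GAMMA, 0.0) for j in range(n_bp)])
    # Crick phosphate k joins its nucleotides k-1 (bp n-k) and k (bp n-1-k):
    # stamp at the higher frame, half a rise and half a twist back
    c_p = np.array([_site(frames, n_bp - k, R_PHOSPHATE, -GAMMA - PHOS_LEAD, -PHOS_DZ)
                    for k in range(1, n_bp)]) if n_bp > 1 else np.zeros((0, 3))
    watson = {"sugar": w_s, "base": w_b, "phosphate": w_p}
    crick = {"sugar": c_s, "base": c_b, "phosphate": c_p}
    return watson, crick
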