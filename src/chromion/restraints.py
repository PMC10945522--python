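"""Harmonic umbrella restraints and the DNA-origami-style arc constraint.

All restraints expose ``energy_forces(positions) -> (E, F)`` and use the
convention ``U = k * (value - center)**2`` (so the restoring force on a
unit displacement is ``2k``).  "Constraints" are stiff harmonic penalties,
not holonomic constraints, which keeps umbrella post-processing simple.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Tuple

import numpy as np

__all__ = ["HarmonicCVBias", "PositionRestraint", "ArcRestraint",
           "OrientationRestraint", "apply_arc_constraint"]

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass
class HarmonicCVBias:
    """Umbrella bias on a differentiable collective variable.

    ``cv`` maps positions to ``(value, gradient)`` with gradient shaped like
    the positions array.
    """

    cv: Callable[[np.ndarray], Tuple[float, np.ndarray]]
    k: float
    center: float

    def energy_forces(self, positions):
        v, grad = self.cv(positions)
        dv = v - self.center
        return self.k * dv * dv, -2.0 * self.k * dv * grad


@dataclass
class PositionRestraint:
    """Pin the geometric center of a bead group to a reference point."""

    beads: Sequence[int]
    reference: np.ndarray
    k: float = 1000.0

    def energy_forces(self, positions):
        idx = np.asarray(self.beads, int)
        center = positions[idx].mean(axis=0)
        d = center - np.asarray(self.reference, float)
        F = np.zeros_like(positions)
        F[idx] = -2.0 * self.k * d / len(idx)
        return self.k * float(d @ d), F


@dataclass
class ArcRestraint:
    """Keep a bead group's center on a circular arc of given radius.

    The arc lies in the plane spanned by ``plane`` (default Y-Z) through
    ``origin`` (the device hinge); motion out of the plane and radial
    deviation from ``radius`` are both penalized harmonically with
    stiffness ``k``.
    """

    beads: Sequence[int]
    radius: float                      # A
    plane: Tuple[str, str] = ("y", "z")
    k: float = 1000.0
    origin: Sequence[float] = (0.0, 0.0, 0.0)

    def energy_forces(self, positions):
        idx = np.asarray(self.beads, int)
        center = positions[idx].mean(axis=0) - np.asarray(self.origin, float)
        i1, i2 = _AXIS[self.plane[0]], _AXIS[self.plane[1]]
        i0 = ({0, 1, 2} - {i1, i2}).pop()
        rho = np.hypot(center[i1], center[i2])
        d_off = center[i0]
        d_rad = rho - self.radius
        E = self.k * (d_off * d_off + d_rad * d_rad)
        g = np.zeros(3)
        g[i0] = 2.0 * self.k * d_off
        if rho > 1e-12:
            g[i1] = 2.0 * self.k * d_rad * center[i1] / rho
            g[i2] = 2.0 * self.k * d_rad * center[i2] / rho
        F = np.zeros_like(positions)
        F[idx] = -g / len(idx)
        return float(E), F

    def deviation(self, positions):
        """(off-plane, off-arc) residual deviations in A."""
        idx = np.asarray(self.beads, int)
        center = positions[idx].mean(axis=0) - np.asarray(self.origin, float)
        i1, i2 = _AXIS[self.plane[0]], _AXIS[self.plane[1]]
        i0 = ({0, 1, 2} - {i1, i2}).pop()
        return abs(float(center[i0])), abs(float(np.hypot(center[i1], center[i2]) - self.radius))


@dataclass
class OrientationRestraint:
    """Restrain the plane normal defined by three marker beads.

    The unsigned alignment penalty ``U = k * (1 - (n . n_ref)^2)`` treats the
    nucleosome plane as unoriented (a face flip costs nothing).
    """

    markers: Tuple[int, int, int]
    reference_axis: np.ndarray
    k: float = 1000.0

    def __post_init__(self):
        ref = np.asarray(self.reference_axis, float)
        self.reference_axis = ref / np.linalg.norm(ref)

    def _normal(self, positions):
        a, b, c = (positions[m] for m in self.markers)
        u, v = b - a, c - a
        w = np.cross(u, v)
        return u, v, w, np.linalg.norm(w)

    def energy_forces(self, positions):
        a, b, c = self.markers
        u, v, w, nw = self._normal(positions)
        n = w / nw
        s = float(n @ self.reference_axis)
        E = self.k * (1.0 - s * s)
        # dE/dw through n = w/|w|
        dE_dn = -2.0 * self.k * s * self.reference_axis
        dE_dw = (dE_dn - n * (n @ dE_dn)) / nw
        F = np.zeros_like(positions)
        # w = u x v;  dw/du^T y = v x y,  dw/dv^T y = y x u  (y = dE_dw)
        g_u = np.cross(v, dE_dw)
        g_v = np.cross(dE_dw, u)
        F[b] -= g_u
        F[c] -= g_v
        F[a] += g_u + g_v
        return float(E), F

    def alignment(self, positions) -> float:
        _, _, w, nw = self._normal(positions)
        return abs(float((w / nw) @ self.reference_axis))


def apply_arc_constraint(positions, beads, radius, plane=("y", "z"), k=1000.0):
    """Constraint forces keeping a nucleosome center on an arc (one-shot form)."""
    r = ArcRestraint(beads=beads, radius=radius, plane=plane, k=k)
    return r.energy_forces(positions)
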