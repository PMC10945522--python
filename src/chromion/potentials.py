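"""Energy and force terms of the coarse-grained chromatin model.

Pure pair functions (ion pair potentials, WCA excluded volume, 12-10 native
contacts, Lennard-Jones) live alongside a :class:`ForceField` aggregator
that classifies every bead pair of a topology, applies the packaged
parameter tables, and returns total energies with exact analytic forces.

Nonbonded assignment per pair:

* both beads listed in the charged-pair table (ion-ion, ion-phosphate,
  ion-charged-amino-acid, phosphate-phosphate) -> tabulated ion pair term;
* ion vs neutral particle (sugar, base, neutral amino acid) -> WCA;
* amino acid vs amino acid -> sequence-specific Lennard-Jones with
  Miyazawa-Jernigan depths (native-contact pairs use the structure-based
  12-10 well instead);
* everything else (protein-DNA, non-phosphate DNA-DNA) -> weak non-specific
  Lennard-Jones excluded volume.

Coulomb interactions act between all charged beads on top of the above,
through Ewald summation in periodic boxes or a direct sum in open space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .ewald import EwaldSolver

try:                                   # compiled pair kernels
    from . import _kernels as _kern
except ImportError:                    # pragma: no cover - numba unavailable
    _kern = None
from .parameters import (IonPairParams, WCAParams, interaction_class,
                         load_ion_pair_table, load_mj_matrix, load_wca_table)
from .topology import CGTopology
from .units import COULOMB_K, DIELECTRIC_WATER

__all__ = [
    "ion_pair_energy", "ion_pair_energy_terms", "ion_pair_force",
    "wca_energy", "wca_force", "TabulatedPotential", "tabulate",
    "ForceFieldConfig", "ForceField",
]


# ---------------------------------------------------------------------------
# pure pair functions


def _wca_core(r, eps, sigma):
    """WCA repulsion: LJ truncated at its minimum (r = sigma) and shifted."""
    r = np.asarray(r, dtype=float)
    inside = r < sigma
    sr6 = np.where(inside, (sigma / np.where(inside, r, sigma)) ** 6, 0.0)
    u = np.where(inside, eps * (sr6 * sr6 - 2.0 * sr6) + eps, 0.0)
    # dU/dr = eps * (-12/r) * (sr12 - sr6)
    dudr = np.where(inside, -12.0 * eps / np.where(inside, r, 1.0) * (sr6 * sr6 - sr6), 0.0)
    return u, dudr


def _gauss(r, height, center, width):
    g = height * np.exp(-((r - center) ** 2) / (2.0 * width ** 2))
    return g, -g * (r - center) / width ** 2


def ion_pair_energy_terms(r, params: IonPairParams) -> Dict[str, np.ndarray]:
    """Term-wise decomposition of the short-range ion pair potential.

    ``core``: WCA repulsion from (eps, sigma); ``well``: Gaussian well of
    depth eps at (rm_eps, sigma_eps); ``hydration1``/``hydration2``:
    amplitude-form hydration-shell Gaussians.  Coulomb is handled separately.
    """
    r = np.asarray(r, dtype=float)
    core, _ = _wca_core(r, params.eps, params.sigma)
    well, _ = _gauss(r, -params.eps, params.rm_eps, params.sigma_eps)
    out = {"core": core, "well": well}
    if params.H1 is not None:
        out["hydration1"], _ = _gauss(r, params.H1, params.rm_h1, params.sigma_h1)
    if params.H2 is not None:
        out["hydration2"], _ = _gauss(r, params.H2, params.rm_h2, params.sigma_h2)
    return out


def ion_pair_energy(r, params: IonPairParams):
    """Short-range ion pair energy (kcal/mol); smooth, -> 0 as r -> inf."""
    return sum(ion_pair_energy_terms(r, params).values())


def ion_pair_force(r, params: IonPairParams):
    """-dU/dr of :func:`ion_pair_energy`."""
    r = np.asarray(r, dtype=float)
    _, dudr = _wca_core(r, params.eps, params.sigma)
    total = dudr
    for h, c, w in ((-params.eps, params.rm_eps, params.sigma_eps),
                    (params.H1, params.rm_h1, params.sigma_h1),
                    (params.H2, params.rm_h2, params.sigma_h2)):
        if h is not None:
            _, d = _gauss(r, h, c, w)
            total = total + d
    return -total


def wca_energy(r, params: WCAParams):
    """Purely repulsive WCA energy: eps[(s/r)^12 - 2(s/r)^6] + eps for r < s."""
    u, _ = _wca_core(r, params.eps, params.sigma)
    return u


def wca_force(r, params: WCAParams):
    _, dudr = _wca_core(r, params.eps, params.sigma)
    return -dudr


# ---------------------------------------------------------------------------
# tabulation


@dataclass
class TabulatedPotential:
    """Cubic-spline tabulation of a radial potential, shifted to 0 at cutoff."""

    r: np.ndarray
    energy: np.ndarray
    force: np.ndarray
    cutoff: float
    max_error: float

    def export(self, path, comment: str = ""):
        header = (f"# tabulated potential; units: r [A], E [kcal/mol], F [kcal/mol/A]; "
                  f"cutoff {self.cutoff} A\n")
        with open(path, "w") as fh:
            fh.write(header)
            if comment:
                fh.write(f"# {comment}\n")
            for r, e, f in zip(self.r, self.energy, self.force):
                fh.write(f"{r:.8f}\t{e:.10e}\t{f:.10e}\n")


def tabulate(potential: Callable, r_min: float, r_max: float, n_points: int,
             tolerance: float = 1e-4) -> TabulatedPotential:
    """Tabulate ``potential(r)`` on [r_min, r_max] with interpolation-error control.

    The spline is probed on a 10x finer grid against the analytic values;
    exceeding ``tolerance`` raises with advice to increase ``n_points``.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    r = np.linspace(r_min, r_max, n_points)
    u = np.asarray(potential(r), dtype=float)
    u = u - u[-1]                      # shift energy at cutoff to exactly 0
    spline = CubicSpline(r, u)
    probe = np.linspace(r_min, r_max, 10 * n_points)
    err = float(np.max(np.abs(spline(probe) - (np.asarray(potential(probe)) -
                                               potential(np.array([r_max]))[0]))))
    if err > tolerance:
        raise ValueError(f"interpolation error {err:.3e} exceeds tolerance "
                         f"{tolerance:.3e}; increase n_points")
    force = -spline(r, 1)
    return TabulatedPotential(r=r, energy=u, force=force, cutoff=r_max, max_error=err)


# ---------------------------------------------------------------------------
# force field


@dataclass
class ForceFieldConfig:
    """Tunable constants of the interaction model (kcal/mol, A, radians)."""

    dielectric: float = DIELECTRIC_WATER
    cutoff: float = 30.0               # global short-range cutoff
    ewald_accuracy: float = 1e-4
    k_bond: float = 50.0               # harmonic bond, kcal/mol/A^2
    k_angle: float = 30.0              # harmonic angle, kcal/mol/rad^2
    k_dihedral: float = 2.0            # cosine dihedral amplitude
    eps_native: float = 1.0            # native-contact 12-10 well depth
    mj_scale: Optional[float] = None   # None -> strongest pair ~ 1 kcal/mol
    mj_sigma: float = 6.5              # contact distance of the MJ LJ term
    eps_excluded: float = 0.1          # weak non-specific LJ depth
    lj_cut_factor: float = 2.5         # LJ terms cut (and shifted) at 2.5 sigma
    radii: Optional[Dict[str, float]] = None  # bead radii for excluded volume

    def bead_radius(self, species: str) -> float:
        radii = self.radii or {"AA": 2.5, "P": 2.0, "S": 2.0, "B": 1.8}
        if species in ("P", "S"):
            return radii[species]
        if species.startswith("D"):
            return radii["B"]
        return radii["AA"]


class ForceField:
    """Aggregated energies/forces for a topology in a (possibly periodic) box."""

    def __init__(self, topology: CGTopology, box: Optional[float] = None,
                 config: Optional[ForceFieldConfig] = None):
        self.top = topology
        self.box = box
        self.cfg = config or ForceFieldConfig()
        self._build()

    # -- setup --------------------------------------------------------------

    def _build(self):
        top, cfg = self.top, self.cfg
        n = top.n_beads
        self.charges = top.charges.copy()
        self._ion_table = load_ion_pair_table()
        self._wca_table = load_wca_table()
        self._mj = load_mj_matrix()
        mj_scale = cfg.mj_scale
        if mj_scale is None:
            mj_scale = 1.0 / float(np.abs(self._mj.matrix).max())
        self._mj_scale = mj_scale

        classes = [interaction_class(s, c) for s, c in zip(top.species, top.charges)]
        is_ion = np.array([s in ("NA", "MG", "CL") for s in top.species])
        is_protein = np.array([c in ("AA", "AA+", "AA-") and not ion
                               for c, ion in zip(classes, is_ion)])
        is_dna = np.array([s in ("P", "S", "DA", "DT", "DG", "DC") for s in top.species])

        excluded = self._bonded_exclusions()
        rigid_of = np.full(n, -1)
        for gi, g in enumerate(top.rigid_groups):
            rigid_of[np.asarray(g, dtype=int)] = gi

        native_pairs = {(min(i, j), max(i, j)) for i, j, _ in top.native_contacts}

        ion_i, ion_j, ion_p = [], [], []
        wca_i, wca_j, wca_e, wca_s = [], [], [], []
        mj_i, mj_j, mj_e = [], [], []
        ex_i, ex_j, ex_s = [], [], []
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excluded or (i, j) in native_pairs:
                    continue
                if rigid_of[i] >= 0 and rigid_of[i] == rigid_of[j]:
                    continue
                ci, cj = classes[i], classes[j]
                if (ci, cj) in self._ion_table:
                    ion_i.append(i); ion_j.append(j)
                    ion_p.append(self._ion_table.get(ci, cj))
                elif (is_ion[i] or is_ion[j]) and (ci, cj) in self._wca_table:
                    p = self._wca_table.get(ci, cj)
                    wca_i.append(i); wca_j.append(j)
                    wca_e.append(p.eps); wca_s.append(p.sigma)
                elif is_protein[i] and is_protein[j]:
                    e = abs(self._mj.energy(top.species[i], top.species[j]))
                    mj_i.append(i); mj_j.append(j)
                    mj_e.append(self._mj_scale * e)
                else:
                    ex_i.append(i); ex_j.append(j)
                    ex_s.append(cfg.bead_radius(top.species[i])
                                + cfg.bead_radius(top.species[j]))

        self._pairs = {
            "ion": (np.array(ion_i, int), np.array(ion_j, int), ion_p),
            "wca": (np.array(wca_i, int), np.array(wca_j, int),
                    np.array(wca_e), np.array(wca_s)),
            "mj": (np.array(mj_i, int), np.array(mj_j, int), np.array(mj_e),
                   np.full(len(mj_i), cfg.mj_sigma)),
            "excluded_volume": (np.array(ex_i, int), np.array(ex_j, int),
                                np.full(len(ex_i), cfg.eps_excluded),
                                np.array(ex_s)),
        }
        # pack ion pair parameters into arrays for vectorized evaluation
        if ion_p:
            def col(get, default=0.0):
                return np.array([get(p) if get(p) is not None else default for p in ion_p])
            self._ion_arr = dict(
                eps=col(lambda p: p.eps), sigma=col(lambda p: p.sigma),
                rm=col(lambda p: p.rm_eps), sw=col(lambda p: p.sigma_eps),
                H1=col(lambda p: p.H1), r1=col(lambda p: p.rm_h1),
                s1=col(lambda p: p.sigma_h1, 1.0),
                H2=col(lambda p: p.H2), r2=col(lambda p: p.rm_h2),
                s2=col(lambda p: p.sigma_h2, 1.0))
        else:
            self._ion_arr = None

        self._bonds = (np.array([(i, j) for i, j, _ in top.bonds], int).reshape(-1, 2),
                       np.array([r for _, _, r in top.bonds]))
        self._angles = (np.array([t[:3] for t in top.angles], int).reshape(-1, 3),
                        np.array([t[3] for t in top.angles]))
        self._dihedrals = (np.array([t[:4] for t in top.dihedrals], int).reshape(-1, 4),
                           np.array([t[4] for t in top.dihedrals]))
        self._native = (np.array([(i, j) for i, j, _ in top.native_contacts],
                                 int).reshape(-1, 2),
                        np.array([r for _, _, r in top.native_contacts]))
        # drop bonded terms fully inside one rigid group (their strain is frozen)
        self._bonds = self._filter_rigid(self._bonds, rigid_of)
        self._angles = self._filter_rigid(self._angles, rigid_of)
        self._dihedrals = self._filter_rigid(self._dihedrals, rigid_of)
        self._native = self._filter_rigid(self._native, rigid_of)

        # Coulomb acts on the charged-bead subset only
        self._qidx = np.where(self.charges != 0)[0]
        self._coul_cache = None
        if self.box is None and len(self._qidx) > 1:
            qi = self._qidx
            a, b = np.triu_indices(len(qi), k=1)
            self._coul_cache = (qi[a], qi[b],
                                self.charges[qi[a]] * self.charges[qi[b]])
        # displacement-triggered neighbor culling for short-range pair kinds
        self._nl_skin = 6.0
        self._nl_ref = None
        self._nl_active: Dict[str, np.ndarray] = {}
        self._ewald = None
        if self.box is not None and len(self._qidx):
            self._ewald = EwaldSolver(self.box, accuracy=cfg.ewald_accuracy,
                                      dielectric=cfg.dielectric,
                                      r_cut=min(cfg.cutoff, self.box / 2.0))

    def _filter_rigid(self, term, rigid_of):
        idx, ref = term
        if len(idx) == 0:
            return term
        keep = []
        for k, row in enumerate(idx):
            gs = rigid_of[row]
            if gs[0] >= 0 and np.all(gs == gs[0]):
                continue
            keep.append(k)
        keep = np.array(keep, int)
        return idx[keep].reshape(-1, idx.shape[1]), ref[keep]

    def _bonded_exclusions(self):
        """Pairs within graph distance <= 3 along bonds are excluded from
        short-range nonbonded terms (Coulomb is never excluded)."""
        adj: Dict[int, set] = {}
        for i, j, _ in self.top.bonds:
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
        excluded = set()
        for start in adj:
            frontier = {start}
            seen = {start}
            for _ in range(3):
                frontier = {k for f in frontier for k in adj.get(f, ())} - seen
                seen |= frontier
                for f in frontier:
                    excluded.add((min(start, f), max(start, f)))
        return excluded

    # -- neighbor culling ---------------------------------------------------

    def _pair_cut(self, kind):
        cfg = self.cfg
        if kind == "ion":
            return cfg.cutoff
        if kind == "wca":
            return float(self._pairs["wca"][3].max()) if len(self._pairs["wca"][0]) else 0.0
        if kind == "mj":
            return cfg.lj_cut_factor * cfg.mj_sigma
        sig = self._pairs["excluded_volume"][3]
        return cfg.lj_cut_factor * float(sig.max()) if len(sig) else 0.0

    def _refresh_neighbor_lists(self, x):
        self._nl_sub = {}
        for kind in ("ion", "wca", "mj", "excluded_volume"):
            ii, jj = self._pairs[kind][0], self._pairs[kind][1]
            if len(ii) == 0:
                self._nl_sub[kind] = None
                continue
            d = self._disp(x[ii], x[jj])
            r2 = np.einsum("ij,ij->i", d, d)
            rc = self._pair_cut(kind) + self._nl_skin
            act = np.where(r2 < rc * rc)[0]
            if kind == "ion":
                sub = (ii[act], jj[act],
                       {k: v[act] for k, v in self._ion_arr.items()})
            else:
                sub = (ii[act], jj[act],
                       self._pairs[kind][2][act], self._pairs[kind][3][act])
            self._nl_sub[kind] = sub
        self._nl_ref = x.copy()

    def _active(self, kind, x):
        """Culled pair arrays for pairs currently within cutoff + skin."""
        if self._nl_ref is None or self._nl_ref.shape != x.shape or \
                np.max(np.abs(x - self._nl_ref)) > self._nl_skin / 2.0:
            self._refresh_neighbor_lists(x)
        return self._nl_sub[kind]

    # -- geometry helpers ---------------------------------------------------

    def _disp(self, a, b):
        d = a - b
        if self.box is not None:
            d -= self.box * np.round(d / self.box)
        return d

    # -- evaluation ---------------------------------------------------------

    def energy_terms(self, positions: np.ndarray) -> Dict[str, float]:
        e, _ = self._eval(positions, forces=False)
        return e

    def energy_forces(self, positions: np.ndarray):
        e, f = self._eval(positions, forces=True)
        return sum(e.values()), f

    def protein_energy(self, positions: np.ndarray) -> float:
        """Structure-based protein energy: bonded + native + MJ terms."""
        e = self.energy_terms(positions)
        return (e["bonds"] + e["angles"] + e["dihedrals"]
                + e["native_contacts"] + e["mj"])

    def dna_bonded_energy(self, positions: np.ndarray) -> float:
        e = self.energy_terms(positions)
        return e["bonds"] + e["angles"] + e["dihedrals"]

    def _eval(self, positions, forces=True):
        x = np.asarray(positions, dtype=float)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite coordinates")
        F = np.zeros_like(x)
        E: Dict[str, float] = {}

        E["bonds"] = self._bond_term(x, F)
        E["angles"] = self._angle_term(x, F)
        E["dihedrals"] = self._dihedral_term(x, F)
        E["native_contacts"] = self._native_term(x, F)
        E["ion_pairs"] = self._ion_term(x, F)
        E["wca"] = self._pair_lj_like(x, F, "wca")
        E["mj"] = self._pair_lj_like(x, F, "mj")
        E["excluded_volume"] = self._pair_lj_like(x, F, "excluded_volume")
        E["coulomb"] = self._coulomb_term(x, F)
        return E, F

    # each term accumulates forces into F and returns its energy

    def _pair_setup(self, x, ii, jj):
        d = self._disp(x[ii], x[jj])
        r2 = np.einsum("ij,ij->i", d, d)
        r = np.sqrt(r2)
        if np.any(r < 1e-6):
            k = int(np.argmin(r))
            raise FloatingPointError(
                f"overlapping beads {ii[k]} and {jj[k]} (r={r[k]:.2e} A)")
        return d, r

    @staticmethod
    def _apply_pair_forces(F, ii, jj, d, r, dudr):
        fpair = (-dudr / r)[:, None] * d
        n = len(F)
        for dim in range(3):
            F[:, dim] += np.bincount(ii, weights=fpair[:, dim], minlength=n)
            F[:, dim] -= np.bincount(jj, weights=fpair[:, dim], minlength=n)

    def _bond_term(self, x, F):
        idx, r0 = self._bonds
        if len(idx) == 0:
            return 0.0
        ii, jj = idx[:, 0], idx[:, 1]
        d, r = self._pair_setup(x, ii, jj)
        k = self.cfg.k_bond
        e = float(np.sum(k * (r - r0) ** 2))
        self._apply_pair_forces(F, ii, jj, d, r, 2.0 * k * (r - r0))
        return e

    def _angle_term(self, x, F):
        idx, t0 = self._angles
        if len(idx) == 0:
            return 0.0
        a, b, c = idx[:, 0], idx[:, 1], idx[:, 2]
        u = self._disp(x[a], x[b])
        v = self._disp(x[c], x[b])
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cosv = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cosv)
        k = self.cfg.k_angle
        e = float(np.sum(k * (theta - t0) ** 2))
        dU = 2.0 * k * (theta - t0)
        sin = np.sqrt(np.maximum(1.0 - cosv ** 2, 1e-12))
        # dtheta/du and dtheta/dv
        du = (u * cosv[:, None] / nu[:, None] - v / nv[:, None]) / (sin * nu)[:, None]
        dv = (v * cosv[:, None] / nv[:, None] - u / nu[:, None]) / (sin * nv)[:, None]
        fa = -dU[:, None] * du
        fc = -dU[:, None] * dv
        np.add.at(F, a, fa)
        np.add.at(F, c, fc)
        np.add.at(F, b, -(fa + fc))
        return e

    def _dihedral_term(self, x, F):
        idx, p0 = self._dihedrals
        if len(idx) == 0:
            return 0.0
        a, b, c, d = idx[:, 0], idx[:, 1], idx[:, 2], idx[:, 3]
        b1 = self._disp(x[b], x[a])
        b2 = self._disp(x[c], x[b])
        b3 = self._disp(x[d], x[c])
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        xx = np.einsum("ij,ij->i", n1, n2)
        yy = np.einsum("ij,ij->i", np.cross(n1, n2), b2 / nb2[:, None])
        phi = np.arctan2(yy, xx)
        k = self.cfg.k_dihedral
        dphi = phi - p0
        e = float(np.sum(k * (1.0 - np.cos(dphi))))
        dU = k * np.sin(dphi)
        # analytic dihedral derivatives (van Gunsteren convention)
        n1sq = np.einsum("ij,ij->i", n1, n1)
        n2sq = np.einsum("ij,ij->i", n2, n2)
        dphi_da = -(nb2 / n1sq)[:, None] * n1
        dphi_dd = (nb2 / n2sq)[:, None] * n2
        t12 = (np.einsum("ij,ij->i", b1, b2) / nb2 ** 2)[:, None]
        t32 = (np.einsum("ij,ij->i", b3, b2) / nb2 ** 2)[:, None]
        dphi_db = -(1.0 + t12) * dphi_da + t32 * dphi_dd
        dphi_dc = t12 * dphi_da - (1.0 + t32) * dphi_dd
        np.add.at(F, a, -dU[:, None] * dphi_da)
        np.add.at(F, b, -dU[:, None] * dphi_db)
        np.add.at(F, c, -dU[:, None] * dphi_dc)
        np.add.at(F, d, -dU[:, None] * dphi_dd)
        return e

    def _native_term(self, x, F):
        idx, r0 = self._native
        if len(idx) == 0:
            return 0.0
        ii, jj = idx[:, 0], idx[:, 1]
        d, r = self._pair_setup(x, ii, jj)
        eps = self.cfg.eps_native
        sr = r0 / r
        sr10 = sr ** 10
        sr12 = sr10 * sr * sr
        e = float(np.sum(eps * (5.0 * sr12 - 6.0 * sr10)))
        dudr = eps * (-60.0 * sr12 + 60.0 * sr10) / r
        self._apply_pair_forces(F, ii, jj, d, r, dudr)
        return e

    def _ion_term(self, x, F):
        if len(self._pairs["ion"][0]) == 0:
            return 0.0
        sub = self._active("ion", x)
        if sub is None or len(sub[0]) == 0:
            return 0.0
        ii, jj, p = sub
        if _kern is not None:
            Ft = np.zeros_like(F)
            e = _kern.ion_pair_kernel(
                x, ii, jj, p["eps"], p["sigma"], p["rm"], p["sw"],
                p["H1"], p["r1"], p["s1"], p["H2"], p["r2"], p["s2"],
                self.cfg.cutoff, self.box or 0.0, Ft)
            if np.isfinite(e):
                F += Ft
                return float(e)
        d, r = self._pair_setup(x, ii, jj)
        within = r < self.cfg.cutoff
        u, dudr = _wca_core_arrays(r, p["eps"], p["sigma"])
        for h, c, w in ((-p["eps"], p["rm"], p["sw"]),
                        (p["H1"], p["r1"], p["s1"]),
                        (p["H2"], p["r2"], p["s2"])):
            g = h * np.exp(-((r - c) ** 2) / (2.0 * w ** 2))
            u += g
            dudr += -g * (r - c) / w ** 2
        u = np.where(within, u, 0.0)
        dudr = np.where(within, dudr, 0.0)
        self._apply_pair_forces(F, ii, jj, d, r, dudr)
        return float(np.sum(u))

    def _pair_lj_like(self, x, F, kind):
        if len(self._pairs[kind][0]) == 0:
            return 0.0
        sub = self._active(kind, x)
        if sub is None or len(sub[0]) == 0:
            return 0.0
        ii, jj, eps, sig = sub
        if _kern is not None:
            Ft = np.zeros_like(F)
            if kind == "wca":
                e = _kern.wca_kernel(x, ii, jj, eps, sig, self.box or 0.0, Ft)
            else:
                e = _kern.lj_kernel(x, ii, jj, eps, sig, self.cfg.lj_cut_factor,
                                    self.cfg.cutoff, self.box or 0.0, Ft)
            if np.isfinite(e):
                F += Ft
                return float(e)
        d, r = self._pair_setup(x, ii, jj)
        if kind == "wca":
            u, dudr = _wca_core_arrays(r, eps, sig)
            self._apply_pair_forces(F, ii, jj, d, r, dudr)
            return float(np.sum(u))
        rc = np.minimum(self.cfg.lj_cut_factor * sig, self.cfg.cutoff)
        within = r < rc
        rr = np.where(within, r, rc)
        sr6 = (sig / rr) ** 6
        src6 = (sig / rc) ** 6
        u = np.where(within,
                     eps * (sr6 * sr6 - 2.0 * sr6) - eps * (src6 * src6 - 2.0 * src6),
                     0.0)
        dudr = np.where(within, -12.0 * eps / rr * (sr6 * sr6 - sr6), 0.0)
        self._apply_pair_forces(F, ii, jj, d, r, dudr)
        return float(np.sum(u))

    def _coulomb_term(self, x, F):
        qi = self._qidx
        if len(qi) == 0:
            return 0.0
        if self._ewald is not None:
            e, f = self._ewald.energy_forces(x[qi], self.charges[qi])
            F[qi] += f
            return float(e)
        ii, jj, qq = self._coul_cache
        scale = COULOMB_K / self.cfg.dielectric
        if _kern is not None:
            return float(_kern.coulomb_kernel(x, ii, jj, qq, scale, F))
        d = x[ii] - x[jj]
        r2 = np.einsum("ij,ij->i", d, d)
        inv_r = 1.0 / np.sqrt(r2)
        e = scale * float(qq @ inv_r)
        coef = scale * qq * inv_r / r2
        fpair = coef[:, None] * d
        n = len(F)
        for dim in range(3):
            F[:, dim] += np.bincount(ii, weights=fpair[:, dim], minlength=n)
            F[:, dim] -= np.bincount(jj, weights=fpair[:, dim], minlength=n)
        return e


def _wca_core_arrays(r, eps, sigma):
    inside = r < sigma
    rr = np.where(inside, r, sigma)
    sr6 = (sigma / rr) ** 6
    u = np.where(inside, eps * (sr6 * sr6 - 2.0 * sr6) + eps, 0.0)
    dudr = np.where(inside, -12.0 * eps / rr * (sr6 * sr6 - sr6), 0.0)
    return u, dudr


def total_energy_forces(forcefield: ForceField, positions: np.ndarray):
    """Convenience wrapper: total energy plus exact per-bead forces."""
    return forcefield.energy_forces(positions)
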