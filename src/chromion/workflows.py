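"""Desk-scale study workflows built from the library modules.

These functions reproduce — at fixture scale — the study designs of the
full chromatin simulations: salt-dependent counterion condensation around a
DNA duplex, and restrained-vs-unrestrained umbrella sampling of the binding
free energy between two (toy) nucleosomes.  They are shared by the test
suite, the command-line interface and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .colvars import distance_cv
from .engine import IntegratorSettings, SimulationState, run_nvt
from .geometry import rotation_matrix
from .fixtures import add_ions, make_fixture
from .observables import CondensationReport, condensation_report
from .potentials import ForceField
from .restraints import (ArcRestraint, HarmonicCVBias, OrientationRestraint,
                         PositionRestraint)
from .solvation import IonBoxSpec, count_ions
from .wham import FreeEnergyProfile, UmbrellaWindow, binding_free_energy, wham

__all__ = ["condensation_comparison", "dinucleosome_binding",
           "dinucleosome_binding_comparison", "run_umbrella_windows",
           "CondensationComparison"]


@dataclass
class CondensationComparison:
    nacl: CondensationReport
    mgcl2: CondensationReport

    @property
    def na_bound_fraction(self) -> float:
        return self.nacl.bound_fraction["NA"]

    @property
    def mg_bound_fraction(self) -> float:
        return self.mgcl2.bound_fraction["MG"]


def _solvated_duplex(n_bp: int, box_edge: float, conc_nacl: float,
                     conc_mgcl2: float, seed: int):
    top, state, _ = make_fixture("short_duplex", {"n_bp": n_bp}, seed=seed)
    # center the duplex in the box and freeze it as one rigid body
    top.positions += box_edge / 2.0 - top.positions.mean(axis=0)
    top.rigid_groups = [list(range(top.n_beads))]
    dna_beads = list(range(top.n_beads))
    spec = IonBoxSpec(box_volume_nm3=(box_edge / 10.0) ** 3,
                      conc_nacl=conc_nacl, conc_mgcl2=conc_mgcl2,
                      solute_charge=int(round(top.total_charge)))
    counts = count_ions(spec)
    add_ions(top, counts, box_edge, clearance=6.0, jitter=1.0, seed=seed)
    state = SimulationState(top.positions.copy(), np.zeros_like(top.positions),
                            box=box_edge)
    return top, state, dna_beads, counts


def _condensation_run(conc_nacl: float, conc_mgcl2: float, seed: int,
                      n_bp: int, box_edge: float, n_steps: int,
                      equil_steps: int, report_every: int,
                      cutoff: float) -> CondensationReport:
    top, state, dna_beads, _ = _solvated_duplex(n_bp, box_edge, conc_nacl,
                                                conc_mgcl2, seed)
    ff = ForceField(top, box=box_edge)
    settings = IntegratorSettings(seed=seed)
    traj = run_nvt(state, top, ff, settings, n_steps=equil_steps + n_steps,
                   report_every=report_every)
    n_skip = equil_steps // report_every
    frames = traj.frames[n_skip:]
    return condensation_report(frames, dna_beads, top.species, box=box_edge,
                               cutoff=cutoff)


def condensation_comparison(seed: int = 0, n_bp: int = 20, box_edge: float = 60.0,
                            conc_nacl: float = 0.150, conc_mgcl2: float = 0.001,
                            n_steps: int = 5000, equil_steps: int = 1500,
                            report_every: int = 50,
                            cutoff: float = 10.0) -> CondensationComparison:
    """Mg2+ vs Na+ condensation on a short duplex in matched boxes.

    Runs two explicit-ion simulations of the same rigid ``n_bp`` duplex —
    one in NaCl, one in MgCl2 at the study concentrations (150 mM NaCl vs
    1 mM MgCl2 by default) — and reports the fraction of each cation species
    bound within ``cutoff`` A of the DNA.
    """
    nacl = _condensation_run(conc_nacl, 0.0, seed, n_bp, box_edge,
                             n_steps, equil_steps, report_every, cutoff)
    mg = _condensation_run(0.0, conc_mgcl2, seed + 1, n_bp, box_edge,
                           n_steps, equil_steps, report_every, cutoff)
    return CondensationComparison(nacl=nacl, mgcl2=mg)


# ---------------------------------------------------------------------------
# dinucleosome binding


ARC_RADIUS = 150.0   # A; the origami device arm length (15 nm)


def _place_on_arc(r: float) -> np.ndarray:
    """Center position on the device arc giving center-center distance r
    from a first nucleosome at the origin (hinge at (0, -R, 0))."""
    phi = 2.0 * np.arcsin(min(r / (2.0 * ARC_RADIUS), 1.0))
    hinge = np.array([0.0, -ARC_RADIUS, 0.0])
    return hinge + ARC_RADIUS * np.array([0.0, np.cos(phi), np.sin(phi)])


def run_umbrella_windows(topology, forcefield, cv, centers, k_spring: float,
                         settings: IntegratorSettings, initial_state,
                         retarget=None, extra_restraints=(),
                         n_steps: int = 1600, equil_steps: int = 800,
                         pre_equil_steps: int = 300, force_cap: float = 50.0,
                         first_window_extra_equil: int = 2000,
                         report_every: int = 8) -> List[UmbrellaWindow]:
    """Sequential umbrella scan: windows are visited in the given order and
    each starts from the previous window's final configuration.

    ``retarget(positions, center)`` may rigidly move part of the system
    toward the next window's target CV value; any clashes this constructs
    are resolved by a short force-capped pre-equilibration before the
    (uncapped) equilibration and sampling phases.
    """
    from dataclasses import replace

    windows = []
    state = initial_state
    for w_i, c in enumerate(centers):
        if retarget is not None:
            state.positions = retarget(state.positions, c)
        bias = HarmonicCVBias(cv=cv, k=k_spring, center=c)
        biases = [bias] + list(extra_restraints)
        pre = replace(settings, seed=settings.seed + 1000 * w_i + 500,
                      force_cap=force_cap)
        run_nvt(state, topology, forcefield, pre, biases=biases,
                n_steps=pre_equil_steps, report_every=pre_equil_steps)
        # the first window additionally relaxes the starting construction
        # (e.g. restraint targets far from the built pose)
        equil = equil_steps + (first_window_extra_equil if w_i == 0 else 0)
        wset = replace(settings, seed=settings.seed + 1000 * w_i)
        traj = run_nvt(state, topology, forcefield, wset, biases=biases,
                       n_steps=equil + n_steps, report_every=report_every)
        n_skip = equil // report_every
        samples = np.array([cv(x)[0] for x in traj.frames[n_skip:]])
        windows.append(UmbrellaWindow(cv_names=("r",), k=k_spring, center=c,
                                      samples=samples,
                                      temperature=settings.temperature))
    return windows


def dinucleosome_binding(seed: int = 0, restrained: bool = False,
                         centers: Optional[np.ndarray] = None,
                         k_spring: float = 0.06, n_steps: int = 2800,
                         equil_steps: int = 800, report_every: int = 8,
                         bin_width: float = 3.0
                         ) -> Tuple[FreeEnergyProfile, float, Dict]:
    """Umbrella-sampled binding free energy of the toy dinucleosome.

    With ``restrained=True`` the first nucleosome is pinned at the origin,
    both nucleosome planes are orientation-restrained, and the second
    nucleosome is confined to the Y-Z-plane arc of the origami-style
    device, mimicking the restricted unbinding pathway; otherwise the pair
    is free to reorient.  Windows are sampled sequentially outward from the
    bound configuration, as in a pulling experiment: the stacked start
    defines the bound state and each window inherits the previous one's
    relaxed configuration.  The unrestrained (free 3D relative motion) profile
    carries the standard 2 k_BT ln r Jacobian correction; the restrained
    profile describes 1D motion along the arc and needs none.  Returns
    (profile, binding free energy in k_BT, details).
    """
    if centers is None:
        centers = np.arange(40.0, 93.0, 4.0)
    centers = np.asarray(centers, float)
    order = np.argsort(centers)                # bound -> separated
    r_start = float(centers[order[0]])
    top, state0, extras = make_fixture("toy_dinucleosome",
                                       {"separation": r_start}, seed=seed)
    asm1, asm2 = extras["assembly1"], extras["assembly2"]
    beads1 = asm1.nucleosome_beads
    beads2 = asm2.nucleosome_beads
    idx1 = np.asarray(beads1, int)
    idx2 = np.asarray(beads2, int)
    # nucleosome 1 at the origin
    top.positions -= top.positions[idx1].mean(axis=0)
    c2 = top.positions[idx2].mean(axis=0)
    # rotate nucleosome 2 to the perpendicular (rim-to-face) orientation:
    # the contact-maximizing pose for a free pair, with its polyanionic DNA
    # rim against the first nucleosome's exposed basic face.  The device
    # restraints below forbid exactly this pose.
    R90 = rotation_matrix([1.0, 0.0, 0.0], np.pi / 2.0)
    top.positions[idx2] = (top.positions[idx2] - c2) @ R90.T + c2
    if restrained:
        # the device holds the first nucleosome rim-on as well, with the two
        # planes mutually perpendicular (n1 along x, n2 along y): both the
        # face-contact and coplanar-interlock modes are inaccessible and the
        # rims can only cross
        Ry90 = rotation_matrix([0.0, 1.0, 0.0], np.pi / 2.0)
        top.positions[idx1] = top.positions[idx1] @ Ry90.T
        top.positions[idx2] += _place_on_arc(r_start) - c2

    ff = ForceField(top, box=None)
    settings = IntegratorSettings(seed=seed, rigid_mass_scale=0.005)

    def cv(x):
        return distance_cv(x, beads1, beads2)

    def retarget(x, c):
        x = x.copy()
        c1 = x[idx1].mean(axis=0)
        c2 = x[idx2].mean(axis=0)
        if restrained:
            target = _place_on_arc(c)
        else:
            d = c2 - c1
            target = c1 + d * (c / max(np.linalg.norm(d), 1e-9))
        x[idx2] += target - c2
        return x

    extra = []
    if restrained:
        # both plane normals are held in the arc plane (y), so the
        # face-to-face stacking mode along the approach direction (~z)
        # is inaccessible -- the device dictates a rim-on unbinding path
        markers1 = tuple(asm1.histone_core_beads[:3])
        markers2 = tuple(asm2.histone_core_beads[:3])
        extra = [
            PositionRestraint(beads=beads1, reference=np.zeros(3), k=100.0),
            ArcRestraint(beads=beads2, radius=ARC_RADIUS,
                         origin=(0.0, -ARC_RADIUS, 0.0), k=10.0),
            OrientationRestraint(markers=markers1, reference_axis=(1, 0, 0), k=100.0),
            OrientationRestraint(markers=markers2, reference_axis=(0, 1, 0), k=100.0),
        ]

    state = SimulationState(top.positions.copy(), np.zeros_like(top.positions),
                            box=None)
    seq_windows = run_umbrella_windows(
        top, ff, cv, centers[order], k_spring, settings, state,
        retarget=retarget, extra_restraints=extra, n_steps=n_steps,
        equil_steps=equil_steps, report_every=report_every,
        first_window_extra_equil=2000)
    windows = [seq_windows[list(order).index(i)] for i in range(len(centers))]
    edges = np.arange(centers[0] - 6.0, centers[-1] + 6.0 + bin_width, bin_width)
    # a window whose histogram ended up disconnected (a rare sampling
    # accident on the toy system) contributes nothing WHAM can place;
    # drop it and reconstruct from the remaining windows
    dropped = []
    work = list(windows)
    while True:
        try:
            profile = wham(work, edges, tolerance=1e-7)
            break
        except ValueError as exc:
            msg = str(exc)
            if "shares no" not in msg or len(work) <= 2:
                raise
            k = int(msg.split("window ")[1].split()[0])
            dropped.append(work.pop(k))
    if not restrained:
        # free relative motion in 3D: remove the 4 pi r^2 volume factor
        x_bins = profile.bin_centers[0]
        profile.free_energy += 2.0 * np.log(x_bins / x_bins[-1])
        profile.free_energy -= np.nanmin(profile.free_energy)
    plateau = (centers[-1] - 15.0, centers[-1] + 5.0)
    dF = binding_free_energy(profile, plateau, min_counts=25)
    details = {"windows": windows, "centers": centers, "plateau": plateau,
               "dropped_windows": dropped, "assemblies": (asm1, asm2)}
    return profile, dF, details


def dinucleosome_binding_comparison(seed: int = 0, n_replicas: int = 3,
                                    **kwargs) -> Dict:
    """Restrained-vs-unrestrained binding depths over independent replicas.

    Runs ``n_replicas`` independent umbrella estimates per condition (the
    error protocol used throughout: independent replicas, not bootstrap)
    and compares the medians, which is robust to a single replica whose
    bound state slips or whose profile picks up a sampling artifact.
    Returns a dict with per-replica depths and the median summary.
    """
    unres, res = [], []
    for rep in range(n_replicas):
        _, dF_u, _ = dinucleosome_binding(seed=seed + 101 * rep,
                                          restrained=False, **kwargs)
        _, dF_r, _ = dinucleosome_binding(seed=seed + 101 * rep,
                                          restrained=True, **kwargs)
        unres.append(dF_u)
        res.append(dF_r)
    return {
        "unrestrained_kT": unres,
        "restrained_kT": res,
        "median_unrestrained_kT": float(np.median(unres)),
        "median_restrained_kT": float(np.median(res)),
    }
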