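"""Deterministic desk-scale fixture systems.

These synthetic systems exercise every force term present in full chromatin
setups without requiring any structure download: pure ion boxes, short
B-form duplexes, a folded mini-protein with a disordered tail, and a toy
dinucleosome built from two synthetic wrapped-disk nucleosomes with
flexible, positively charged tails.  All generation is deterministic under
the given seed.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from . import geometry
from .engine import SimulationState
from .solvation import IonCounts, place_ions_grid
from .topology import (CGTopology, NucleosomeAssembly, NucleosomeCoreStructure,
                       ProteinStructure, assemble_nucleosome, coarse_grain_dna,
                       coarse_grain_protein, define_rigid_groups)

__all__ = ["make_fixture", "synthetic_nucleosome_core", "helix_ca_coords",
           "add_ions", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("ion_box", "short_duplex", "mini_protein", "toy_dinucleosome")


def helix_ca_coords(n_res: int, radius: float = 2.3, rise: float = 1.5,
                    turn_deg: float = 100.0) -> np.ndarray:
    """Idealized alpha-helix C-alpha trace."""
    t = np.deg2rad(turn_deg) * np.arange(n_res)
    return np.stack([radius * np.cos(t), radius * np.sin(t), rise * np.arange(n_res)],
                    axis=1)


def add_ions(topology: CGTopology, counts: IonCounts, box_edge: float,
             clearance: float = 5.0, jitter: float = 0.0, seed: int = 0) -> CGTopology:
    """Append grid-placed ions to a topology (optionally jittered)."""
    pos, species = place_ions_grid(counts, box_edge,
                                   solute_positions=topology.positions
                                   if topology.n_beads else None,
                                   clearance=clearance)
    if jitter > 0 and len(pos):
        rng = np.random.default_rng(seed)
        pos = pos + rng.uniform(-jitter, jitter, pos.shape)
    for s in ("NA", "MG", "CL"):
        idx = [k for k, sp in enumerate(species) if sp == s]
        if idx:
            topology.add_chain(f"I{s[0]}", "ion", [s] * len(idx), pos[idx],
                               list(range(1, len(idx) + 1)))
    topology.validate()
    return topology


def synthetic_nucleosome_core(n_bp: int = 28, wrap_radius: float = 15.0,
                              wrap_pitch: float = 6.0, turns: float = 1.0,
                              n_core_ring: int = 16, tail_len: int = 8,
                              tail_stalk: int = 4, tails_per_face: int = 2,
                              sequence: str | None = None) -> NucleosomeCoreStructure:
    """Synthetic stand-in for a nucleosome core structure.

    A toy, not a crystal structure: the "histone core" is two stacked rings
    of arginine beads inside a DNA duplex wrapped on a one-turn superhelix,
    and two lysine-rich disordered tails emerge from opposite faces.  It
    reproduces the charge layout and geometry class of a real core (basic
    protein disk, wrapped polyanionic DNA) at desk scale.
    """
    if sequence is None:
        sequence = ("ATCG" * ((n_bp + 3) // 4))[:n_bp]
    frames = geometry.superhelix_frames(n_bp, radius=wrap_radius,
                                        pitch=wrap_pitch, turns=turns)
    proteins = []
    # two solid disks of ARG beads (the rigid, folded "core"); filled, so
    # nothing can thread through the middle of the particle
    ring_r = max(wrap_radius - 11.0, 3.0)
    for half, z in ((0, -2.5), (1, 2.5)):
        rings = [(1, 0.0), (6, ring_r / 2.0), (n_core_ring - 7, ring_r)]
        pts = []
        for m, rr in rings:
            ang = 2.0 * np.pi * (np.arange(m) + 0.5 * half) / max(m, 1)
            pts.append(np.stack([rr * np.cos(ang), rr * np.sin(ang),
                                 np.full(m, z)], axis=1))
        core_xyz = np.vstack(pts)
        # lysine tail leaving the face axially; its first ``tail_stalk``
        # residues stay folded (a rigid stalk normal to the face), so the
        # flexible segment starts proud of the face surface.  The two
        # faces' tails are rooted on opposite sides of the ring.
        n_outer = n_core_ring - 7
        root_i = 7 + (half * (n_outer // 2)) % n_outer   # on the outer ring
        root = core_xyz[root_i]
        tail_dir = np.array([0.0, 0.0, -1.0 if half == 0 else 1.0])
        tail_xyz = root + tail_dir * 3.8 * np.arange(1, tail_len + 1)[:, None]
        residues = ["ARG"] * n_core_ring + ["LYS"] * tail_len
        coords = np.vstack([core_xyz, tail_xyz])
        proteins.append(ProteinStructure(
            chain_id=f"H{half}", residues=residues, ca_coords=coords,
            flexible_ranges=[(n_core_ring + 1 + tail_stalk,
                              n_core_ring + tail_len)]))
        # additional tails are their own chains, anchored through rigid
        # stalk residues, at the opposite azimuth of the same face
        for extra in range(1, tails_per_face):
            mirror = np.array([-root[0], -root[1], root[2]])
            exy = mirror + tail_dir * 3.8 * np.arange(1, tail_len + 1)[:, None]
            proteins.append(ProteinStructure(
                chain_id=f"T{half}{extra}", residues=["LYS"] * tail_len,
                ca_coords=exy,
                flexible_ranges=[(1 + tail_stalk, tail_len)]))
    return NucleosomeCoreStructure(proteins=proteins, dna_sequence=sequence,
                                   frames=frames)


def _toy_nucleosome(chain_suffix: str, rigid: bool = True) -> NucleosomeAssembly:
    core = synthetic_nucleosome_core()
    asm = assemble_nucleosome(core, linker_bp_each_side=0,
                              chain_ids=(f"W{chain_suffix}", f"C{chain_suffix}"))
    if rigid:
        define_rigid_groups(asm, inner_layer_bp=len(asm.wrapped_bp))
    return asm


def make_fixture(name: str, params: Dict | None = None,
                 seed: int = 0) -> Tuple[CGTopology, SimulationState, Dict]:
    """Build a named fixture; returns (topology, state, extras).

    ``extras`` carries fixture-specific handles (e.g. the two
    :class:`NucleosomeAssembly` objects of the toy dinucleosome).
    """
    params = dict(params or {})
    if name == "ion_box":
        n_na = int(params.pop("n_na", 100))
        n_cl = int(params.pop("n_cl", 100))
        n_mg = int(params.pop("n_mg", 0))
        edge = float(params.pop("edge", 60.0))
        top = CGTopology()
        add_ions(top, IonCounts(n_na, n_mg, n_cl), edge, jitter=1.0, seed=seed)
        state = SimulationState(top.positions.copy(), np.zeros_like(top.positions),
                                box=edge)
        extras = {}
    elif name == "short_duplex":
        n_bp = int(params.pop("n_bp", 20))
        sequence = params.pop("sequence", ("ATCG" * ((n_bp + 3) // 4))[:n_bp])
        top = coarse_grain_dna(sequence)
        state = SimulationState(top.positions.copy(), np.zeros_like(top.positions),
                                box=params.pop("box", None))
        extras = {"sequence": sequence}
    elif name == "mini_protein":
        n_fold = int(params.pop("n_folded", 10))
        n_tail = int(params.pop("n_tail", 4))
        residues = (["LEU", "LYS", "ALA", "GLU", "VAL"] * 4)[:n_fold] \
            + (["LYS", "GLY"] * n_tail)[:n_tail]
        coords = helix_ca_coords(n_fold)
        tail = coords[-1] + np.array([0.0, 0.0, 3.8]) * np.arange(1, n_tail + 1)[:, None]
        struct = ProteinStructure("A", residues, np.vstack([coords, tail]),
                                  flexible_ranges=[(n_fold + 1, n_fold + n_tail)])
        top = coarse_grain_protein(struct)
        state = SimulationState(top.positions.copy(), np.zeros_like(top.positions),
                                box=None)
        extras = {"structure": struct}
    elif name == "toy_dinucleosome":
        separation = float(params.pop("separation", 60.0))
        asm1 = _toy_nucleosome("1")
        asm2 = _toy_nucleosome("2")
        # stack along z (face-to-face start), both centered on the z axis;
        # the second nucleosome is rotated a quarter turn about z so the
        # facing tail stalks interleave instead of meeting head-on
        Rz = geometry.rotation_matrix([0.0, 0.0, 1.0], np.pi / 2.0)
        asm2.topology.positions = asm2.topology.positions @ Rz.T + np.array(
            [0.0, 0.0, separation])
        top = asm1.topology
        off = top.n_beads
        top.merge(asm2.topology)
        _shift_assembly(asm2, off)
        asm2.topology = top
        state = SimulationState(top.positions.copy(), np.zeros_like(top.positions),
                                box=params.pop("box", None))
        extras = {"assembly1": asm1, "assembly2": asm2}
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if params:
        raise ValueError(f"unused fixture parameters: {sorted(params)}")
    top.validate()
    return top, state, extras


def _shift_assembly(asm: NucleosomeAssembly, off: int):
    asm.histone_core_beads = [i + off for i in asm.histone_core_beads]
    asm.tail_beads = [i + off for i in asm.tail_beads]
    asm.bp_bead_indices = [[i + off for i in g] for g in asm.bp_bead_indices]
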