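"""Coarse-grained topologies: one bead per amino acid, three sites per nucleotide.

Proteins are reduced to their C-alpha positions.  Folded regions receive
structure-based bonded terms (bonds, angles, dihedrals) and native contacts;
disordered ranges (histone tails) keep only the chain connectivity.  DNA uses
a three-site-per-nucleotide representation (sugar S, base, phosphate P) with
the 5'-terminal nucleotide of each strand lacking its phosphate, so a strand
of n nucleotides carries 3n-1 beads.  Every phosphate carries a full -1 charge
(explicit ions take over the screening that scaled charges emulate in
implicit-salt models).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import geometry
from .geometry import BPFrames, duplex_site_positions, straight_frames
from .parameters import AA_CHARGE

__all__ = [
    "BeadSpec", "ChainRecord", "CGTopology", "ProteinStructure",
    "NucleosomeCoreStructure", "NucleosomeAssembly",
    "coarse_grain_protein", "coarse_grain_dna", "generate_bdna",
    "assemble_nucleosome", "define_rigid_groups", "complement",
    "base_pair_centers",
]

DNA_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: bead masses in amu
SPECIES_MASS: Dict[str, float] = {
    "ALA": 71.08, "ARG": 156.19, "ASN": 114.10, "ASP": 115.09, "CYS": 103.14,
    "GLN": 128.13, "GLU": 129.12, "GLY": 57.05, "HIS": 137.14, "ILE": 113.16,
    "LEU": 113.16, "LYS": 128.17, "MET": 131.19, "PHE": 147.18, "PRO": 97.12,
    "SER": 87.08, "THR": 101.10, "TRP": 186.21, "TYR": 163.18, "VAL": 99.13,
    "P": 94.97, "S": 83.11,
    "DA": 134.12, "DT": 125.11, "DG": 150.13, "DC": 110.09,
    "NA": 22.99, "MG": 24.31, "CL": 35.45,
}

ION_CHARGE = {"NA": 1.0, "MG": 2.0, "CL": -1.0}


def bead_charge(species: str) -> float:
    """Charge assignment rule: P=-1, Arg/Lys=+1, Asp/Glu=-1, ions by valence."""
    if species == "P":
        return -1.0
    if species in ION_CHARGE:
        return ION_CHARGE[species]
    return AA_CHARGE.get(species, 0.0)


@dataclass
class BeadSpec:
    index: int
    species: str
    charge: float
    mass: float
    chain_id: str
    residue_index: int
    position: np.ndarray


@dataclass
class ChainRecord:
    chain_id: str
    start: int           # first bead index
    stop: int            # one past last bead index
    polymer_type: str    # 'protein' | 'dna' | 'ion'


class CGTopology:
    """Beads plus bonded terms, native contacts, rigid groups and chains."""

    def __init__(self):
        self.species: List[str] = []
        self.charges = np.zeros(0)
        self.masses = np.zeros(0)
        self.chain_ids: List[str] = []
        self.residue_indices: List[int] = []
        self.positions = np.zeros((0, 3))
        self.bonds: List[Tuple[int, int, float]] = []
        self.angles: List[Tuple[int, int, int, float]] = []
        self.dihedrals: List[Tuple[int, int, int, int, float]] = []
        self.native_contacts: List[Tuple[int, int, float]] = []
        self.rigid_groups: List[List[int]] = []
        self.chains: List[ChainRecord] = []

    # -- construction -------------------------------------------------------

    def add_chain(self, chain_id: str, polymer_type: str, species: Sequence[str],
                  positions: np.ndarray, residue_indices: Sequence[int]) -> range:
        start = self.n_beads
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(species), 3):
            raise ValueError("positions shape mismatch")
        self.species.extend(species)
        self.charges = np.concatenate([self.charges, [bead_charge(s) for s in species]])
        self.masses = np.concatenate([self.masses, [SPECIES_MASS[s] for s in species]])
        self.chain_ids.extend([chain_id] * len(species))
        self.residue_indices.extend(residue_indices)
        self.positions = np.vstack([self.positions, positions])
        self.chains.append(ChainRecord(chain_id, start, self.n_beads, polymer_type))
        return range(start, self.n_beads)

    def merge(self, other: "CGTopology") -> "CGTopology":
        """Append ``other``'s beads and terms (index-shifted) onto self."""
        off = self.n_beads
        self.species.extend(other.species)
        self.charges = np.concatenate([self.charges, other.charges])
        self.masses = np.concatenate([self.masses, other.masses])
        self.chain_ids.extend(other.chain_ids)
        self.residue_indices.extend(other.residue_indices)
        self.positions = np.vstack([self.positions, other.positions])
        self.bonds += [(i + off, j + off, r) for i, j, r in other.bonds]
        self.angles += [(i + off, j + off, k + off, t) for i, j, k, t in other.angles]
        self.dihedrals += [(i + off, j + off, k + off, l + off, p)
                           for i, j, k, l, p in other.dihedrals]
        self.native_contacts += [(i + off, j + off, r) for i, j, r in other.native_contacts]
        self.rigid_groups += [[i + off for i in g] for g in other.rigid_groups]
        self.chains += [ChainRecord(c.chain_id, c.start + off, c.stop + off, c.polymer_type)
                        for c in other.chains]
        return self

    # -- queries ------------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.species)

    def bead(self, i: int) -> BeadSpec:
        return BeadSpec(i, self.species[i], float(self.charges[i]), float(self.masses[i]),
                        self.chain_ids[i], self.residue_indices[i], self.positions[i].copy())

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def chain_beads(self, chain_id: str) -> List[int]:
        return [i for c in self.chains if c.chain_id == chain_id
                for i in range(c.start, c.stop)]

    def validate(self):
        n = self.n_beads
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond index out of range: ({i}, {j})")
        for term in self.angles:
            if not all(0 <= t < n for t in term[:3]):
                raise ValueError(f"angle index out of range: {term[:3]}")
        for term in self.dihedrals:
            if not all(0 <= t < n for t in term[:4]):
                raise ValueError(f"dihedral index out of range: {term[:4]}")
        for i, j, _ in self.native_contacts:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"native contact out of range: ({i}, {j})")
        seen = set()
        for g in self.rigid_groups:
            s = set(g)
            if seen & s:
                raise ValueError("rigid groups must be disjoint")
            seen |= s
        # charge bookkeeping: counts by rule must reproduce the stored total
        expected = sum(bead_charge(s) for s in self.species)
        if abs(expected - self.total_charge) > 1e-9:
            raise ValueError("charge bookkeeping violated")
        return True

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "schema": "chromion-topology-1",
            "species": self.species,
            "chain_ids": self.chain_ids,
            "residue_indices": list(map(int, self.residue_indices)),
            "positions": self.positions.tolist(),
            "bonds": [[int(i), int(j), float(r)] for i, j, r in self.bonds],
            "angles": [[int(i), int(j), int(k), float(t)] for i, j, k, t in self.angles],
            "dihedrals": [[int(i), int(j), int(k), int(l), float(p)]
                          for i, j, k, l, p in self.dihedrals],
            "native_contacts": [[int(i), int(j), float(r)] for i, j, r in self.native_contacts],
            "rigid_groups": [[int(i) for i in g] for g in self.rigid_groups],
            "chains": [[c.chain_id, int(c.start), int(c.stop), c.polymer_type]
                       for c in self.chains],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "CGTopology":
        doc = json.loads(text)
        if doc.get("schema") != "chromion-topology-1":
            raise ValueError("unrecognized topology schema")
        top = cls()
        top.species = list(doc["species"])
        top.charges = np.array([bead_charge(s) for s in top.species])
        top.masses = np.array([SPECIES_MASS[s] for s in top.species])
        top.chain_ids = list(doc["chain_ids"])
        top.residue_indices = list(doc["residue_indices"])
        top.positions = np.array(doc["positions"], dtype=float).reshape(-1, 3)
        top.bonds = [tuple(b) for b in doc["bonds"]]
        top.angles = [tuple(a) for a in doc["angles"]]
        top.dihedrals = [tuple(d) for d in doc["dihedrals"]]
        top.native_contacts = [tuple(c) for c in doc["native_contacts"]]
        top.rigid_groups = [list(g) for g in doc["rigid_groups"]]
        top.chains = [ChainRecord(c[0], c[1], c[2], c[3]) for c in doc["chains"]]
        top.validate()
        return top

    def write_pdb(self, path):
        """Coordinate file for visualization (one HETATM per bead)."""
        with open(path, "w") as fh:
            for i in range(self.n_beads):
                name = self.species[i][:3]
                x, y, z = self.positions[i]
                fh.write(
                    f"HETATM{(i + 1) % 100000:5d} {name:<4s}{name:<3s} "
                    f"{self.chain_ids[i][:1]:1s}{self.residue_indices[i] % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n")
            fh.write("END\n")


# ---------------------------------------------------------------------------
# proteins


@dataclass
class ProteinStructure:
    """Minimal per-chain protein record: residue names plus C-alpha coordinates."""

    chain_id: str
    residues: List[str]            # three-letter codes
    ca_coords: np.ndarray          # (n, 3), NaN marks a missing C-alpha
    flexible_ranges: List[Tuple[int, int]] = field(default_factory=list)  # 1-based inclusive


def _check_flexible_ranges(ranges, n_res):
    flags = np.zeros(n_res, dtype=bool)
    for a, b in ranges:
        if a < 1 or b > n_res or a > b:
            raise ValueError(f"flexible range ({a}, {b}) outside chain of {n_res} residues")
        if flags[a - 1:b].any():
            raise ValueError(f"flexible ranges overlap at ({a}, {b})")
        flags[a - 1:b] = True
    return flags


def coarse_grain_protein(structure: ProteinStructure,
                         flexible_ranges: Optional[Sequence[Tuple[int, int]]] = None,
                         contact_cutoff: float = 6.5,
                         contact_scale: float = 1.5,
                         min_seq_sep: int = 4) -> CGTopology:
    """One bead per residue at the C-alpha position.

    Bonds join consecutive residues everywhere; angles, dihedrals and native
    contacts are generated only between residues that all lie outside the
    flexible (disordered-tail) ranges.  Native contacts are C-alpha pairs
    separated by at least ``min_seq_sep`` in sequence and closer than
    ``contact_scale * contact_cutoff`` in the reference structure.
    """
    if flexible_ranges is None:
        flexible_ranges = structure.flexible_ranges
    res = structure.residues
    coords = np.asarray(structure.ca_coords, dtype=float)
    n = len(res)
    if coords.shape != (n, 3):
        raise ValueError("C-alpha coordinate array shape mismatch")
    bad = np.where(~np.isfinite(coords).all(axis=1))[0]
    if len(bad):
        r = bad[0]
        raise ValueError(f"missing C-alpha for residue {r + 1} ({res[r]}) "
                         f"in chain {structure.chain_id}")
    flexible = _check_flexible_ranges(flexible_ranges, n)
    folded = ~flexible

    top = CGTopology()
    top.add_chain(structure.chain_id, "protein", list(res), coords, list(range(1, n + 1)))

    for i in range(n - 1):
        top.bonds.append((i, i + 1, float(np.linalg.norm(coords[i + 1] - coords[i]))))
    for i in range(n - 2):
        if folded[i] and folded[i + 1] and folded[i + 2]:
            top.angles.append((i, i + 1, i + 2,
                               _angle(coords[i], coords[i + 1], coords[i + 2])))
    for i in range(n - 3):
        if folded[i:i + 4].all():
            top.dihedrals.append((i, i + 1, i + 2, i + 3,
                                  _dihedral(coords[i], coords[i + 1],
                                            coords[i + 2], coords[i + 3])))
    cutoff = contact_scale * contact_cutoff
    for i in range(n):
        if not folded[i]:
            continue
        for j in range(i + min_seq_sep, n):
            if not folded[j]:
                continue
            d = float(np.linalg.norm(coords[j] - coords[i]))
            if d <= cutoff:
                top.native_contacts.append((i, j, d))
    top.validate()
    return top


def _angle(a, b, c) -> float:
    u, v = a - b, c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosv, -1.0, 1.0)))


def _dihedral(a, b, c, d) -> float:
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    return float(np.arctan2(y, x))


# ---------------------------------------------------------------------------
# DNA


def complement(sequence: str) -> str:
    """Reverse complement (the complementary strand read 5'->3')."""
    return "".join(DNA_COMPLEMENT[b] for b in reversed(sequence))


def _validate_sequence(sequence: str):
    for pos, b in enumerate(sequence):
        if b not in DNA_COMPLEMENT:
            raise ValueError(f"invalid nucleotide {b!r} at position {pos + 1}")
    if not sequence:
        raise ValueError("empty DNA sequence")


def generate_bdna(sequence: str, frames: Optional[BPFrames] = None):
    """Idealized B-form duplex coordinates for ``sequence`` (Watson strand).

    Returns ``(watson, crick)`` site-coordinate dicts (see
    :func:`chromion.geometry.duplex_site_positions`).  Deterministic: the
    same sequence always yields identical coordinates.
    """
    _validate_sequence(sequence)
    n = len(sequence)
    if frames is None:
        frames = straight_frames(n)
    return duplex_site_positions(n, frames)


def _strand_beads(sequence: str, sites) -> Tuple[List[str], np.ndarray, List[int]]:
    """Bead species/positions for one strand in build order (5'->3').

    Order per nucleotide i: [P_i (absent for i=0), S_i, B_i].
    """
    species: List[str] = []
    pos: List[np.ndarray] = []
    resi: List[int] = []
    for i, base in enumerate(sequence):
        if i > 0:
            species.append("P")
            pos.append(sites["phosphate"][i - 1])
            resi.append(i + 1)
        species.append("S")
        pos.append(sites["sugar"][i])
        resi.append(i + 1)
        species.append("D" + base)
        pos.append(sites["base"][i])
        resi.append(i + 1)
    return species, np.array(pos), resi


def _strand_bonded_terms(top: CGTopology, offset: int, n: int, ref_sites,
                         pair_partners=None):
    """Simplified harmonic bonded terms for one strand, references from
    the idealized straight build of the same length."""
    def P(i):  # bead index of phosphate i (i>=1)
        return offset + 3 * i - 1

    def S(i):
        return offset + 3 * i if i == 0 else offset + 3 * i

    def B(i):
        return offset + 3 * i + 1 if i == 0 else offset + 3 * i + 1

    rs, rb, rp = ref_sites["sugar"], ref_sites["base"], ref_sites["phosphate"]
    for i in range(n):
        top.bonds.append((S(i), B(i), float(np.linalg.norm(rb[i] - rs[i]))))
        if i > 0:
            top.bonds.append((S(i - 1), P(i), float(np.linalg.norm(rp[i - 1] - rs[i - 1]))))
            top.bonds.append((P(i), S(i), float(np.linalg.norm(rs[i] - rp[i - 1]))))
    for i in range(1, n - 1):
        top.angles.append((S(i - 1), P(i), S(i), _angle(rs[i - 1], rp[i - 1], rs[i])))
        top.angles.append((P(i), S(i), P(i + 1), _angle(rp[i - 1], rs[i], rp[i])))
    for i in range(1, n - 2):
        top.dihedrals.append((S(i - 1), P(i), S(i), P(i + 1),
                              _dihedral(rs[i - 1], rp[i - 1], rs[i], rp[i])))
        top.dihedrals.append((P(i), S(i), P(i + 1), S(i + 1),
                              _dihedral(rp[i - 1], rs[i], rp[i], rs[i + 1])))


def coarse_grain_dna(sequence: str, coordinates=None, duplex: bool = True,
                     chain_ids: Tuple[str, str] = ("DW", "DC")) -> CGTopology:
    """Three-site-per-nucleotide DNA topology for ``sequence``.

    ``coordinates`` is an optional ``(watson, crick)`` site dict pair (as
    produced by :func:`generate_bdna`); absent coordinates default to the
    idealized straight B-form.  In duplex mode the complementary strand is
    generated automatically and soft harmonic pairing bonds join paired base
    beads, standing in for the full base-pairing potential of the
    three-site DNA model.
    """
    _validate_sequence(sequence)
    n = len(sequence)
    if coordinates is None:
        coordinates = generate_bdna(sequence)
    watson, crick = coordinates

    # bonded-term reference geometry always comes from the straight build
    ref_w, ref_c = generate_bdna(sequence)

    top = CGTopology()
    sp, pos, resi = _strand_beads(sequence, watson)
    top.add_chain(chain_ids[0], "dna", sp, pos, resi)
    _strand_bonded_terms(top, 0, n, ref_w)
    if duplex:
        cseq = complement(sequence)
        off = top.n_beads
        sp2, pos2, resi2 = _strand_beads(cseq, crick)
        top.add_chain(chain_ids[1], "dna", sp2, pos2, resi2)
        _strand_bonded_terms(top, off, n, ref_c)
        # pairing bonds: Watson base i <-> Crick base n-1-i
        for i in range(n):
            bw = _base_index(0, i)
            bc = _base_index(off, n - 1 - i)
            r0 = float(np.linalg.norm(ref_c["base"][n - 1 - i] - ref_w["base"][i]))
            top.bonds.append((bw, bc, r0))
    top.validate()
    return top


def _base_index(offset: int, i: int) -> int:
    """Bead index of base i within a strand laid out by :func:`_strand_beads`."""
    return offset + (1 if i == 0 else 3 * i + 1)


def _sugar_index(offset: int, i: int) -> int:
    return offset + (0 if i == 0 else 3 * i)


def base_pair_centers(topology: CGTopology, watson_chain: str = "DW",
                      crick_chain: str = "DC",
                      positions: Optional[np.ndarray] = None) -> np.ndarray:
    """Geometric centers of each base pair (mean of both sugar and base beads)."""
    if positions is None:
        positions = topology.positions
    w = next(c for c in topology.chains if c.chain_id == watson_chain)
    c = next(ch for ch in topology.chains if ch.chain_id == crick_chain)
    n = (w.stop - w.start + 1) // 3
    centers = np.empty((n, 3))
    for i in range(n):
        idx = [_sugar_index(w.start, i), _base_index(w.start, i),
               _sugar_index(c.start, n - 1 - i), _base_index(c.start, n - 1 - i)]
        centers[i] = positions[idx].mean(axis=0)
    return centers


# ---------------------------------------------------------------------------
# nucleosome assembly


@dataclass
class NucleosomeCoreStructure:
    """Input record for assembling a nucleosome: histone chains plus the
    wrapped-DNA sequence and its per-base-pair frames."""

    proteins: List[ProteinStructure]
    dna_sequence: str                  # Watson strand of the wrapped DNA
    frames: BPFrames                   # one frame per wrapped base pair


@dataclass
class NucleosomeAssembly:
    topology: CGTopology
    histone_core_beads: List[int]
    tail_beads: List[int]
    wrapped_bp: List[int]              # bp indices of the wrapped core region
    dyad_bp: int
    bp_bead_indices: List[List[int]]   # per bp: indices of its S/B (and P) beads
    bp_frames: BPFrames
    native_bp_core_dist: np.ndarray    # per wrapped bp, build-time min distance to core
    n_bp: int
    watson_chain: str = "DW"
    crick_chain: str = "DC"

    @property
    def nucleosome_beads(self) -> List[int]:
        dna = [i for g in self.bp_bead_indices for i in g]
        return sorted(set(dna) | set(self.histone_core_beads) | set(self.tail_beads))

    def dna_beads(self) -> List[int]:
        return sorted({i for g in self.bp_bead_indices for i in g})

    def wrapped_dna_beads(self) -> List[int]:
        return sorted({i for bp in self.wrapped_bp for i in self.bp_bead_indices[bp]})


def _bp_bead_indices(n: int, w_off: int, c_off: int) -> List[List[int]]:
    out = []
    for i in range(n):
        idx = [_sugar_index(w_off, i), _base_index(w_off, i),
               _sugar_index(c_off, n - 1 - i), _base_index(c_off, n - 1 - i)]
        if i > 0:
            idx.append(w_off + 3 * i - 1)              # Watson phosphate i
        j = n - 1 - i
        if j > 0:
            idx.append(c_off + 3 * j - 1)              # Crick phosphate at this bp
        out.append(idx)
    return out


def assemble_nucleosome(core: NucleosomeCoreStructure,
                        linker_bp_each_side: int = 0,
                        linker_sequence: str = "",
                        chain_ids: Tuple[str, str] = ("DW", "DC")) -> NucleosomeAssembly:
    """Assemble histones + wrapped DNA, appending straight linker DNA tangent
    to the terminal base-pair frames of the wrap."""
    if not core.dna_sequence:
        raise ValueError("core structure lacks DNA")
    if linker_bp_each_side < 0:
        raise ValueError("linker_bp_each_side must be >= 0")
    if linker_bp_each_side and len(linker_sequence) < linker_bp_each_side:
        raise ValueError("linker_sequence shorter than linker_bp_each_side")
    n_core = len(core.dna_sequence)
    if len(core.frames) != n_core:
        raise ValueError("core frames do not match wrapped DNA length")

    lk = linker_sequence[:linker_bp_each_side]
    full_seq = lk + core.dna_sequence + lk
    frames = geometry.extend_frames(core.frames, linker_bp_each_side, prepend=True)
    frames = geometry.extend_frames(frames, linker_bp_each_side, prepend=False)
    coords = duplex_site_positions(len(full_seq), frames)

    top = coarse_grain_dna(full_seq, coordinates=coords, chain_ids=chain_ids)
    w_off = 0
    c_off = next(c for c in top.chains if c.chain_id == chain_ids[1]).start
    n = len(full_seq)
    bp_beads = _bp_bead_indices(n, w_off, c_off)

    core_beads: List[int] = []
    tail_beads: List[int] = []
    for prot in core.proteins:
        off = top.n_beads
        ptop = coarse_grain_protein(prot)
        flexible = _check_flexible_ranges(prot.flexible_ranges, len(prot.residues))
        top.merge(ptop)
        for r in range(len(prot.residues)):
            (tail_beads if flexible[r] else core_beads).append(off + r)

    wrapped = list(range(linker_bp_each_side, linker_bp_each_side + n_core))
    dyad = linker_bp_each_side + n_core // 2
    if core_beads:
        cpos = top.positions[core_beads]
        native = np.array([
            np.min(np.linalg.norm(cpos[:, None, :] - top.positions[bp_beads[bp]][None, :, :],
                                  axis=2))
            for bp in wrapped])
    else:
        native = np.full(len(wrapped), np.inf)

    top.validate()
    return NucleosomeAssembly(
        topology=top, histone_core_beads=core_beads, tail_beads=tail_beads,
        wrapped_bp=wrapped, dyad_bp=dyad, bp_bead_indices=bp_beads,
        bp_frames=frames, native_bp_core_dist=native, n_bp=n,
        watson_chain=chain_ids[0], crick_chain=chain_ids[1])


def define_rigid_groups(assembly: NucleosomeAssembly, inner_layer_bp: int = 73) -> List[int]:
    """One rigid body: folded histone-core beads plus the central
    ``inner_layer_bp`` base pairs of the wrap (centered on the dyad)."""
    if inner_layer_bp < 0 or inner_layer_bp > len(assembly.wrapped_bp):
        raise ValueError(f"inner_layer_bp={inner_layer_bp} exceeds wrapped length "
                         f"{len(assembly.wrapped_bp)}")
    group = set(assembly.histone_core_beads)
    if inner_layer_bp:
        half = inner_layer_bp // 2
        lo = assembly.dyad_bp - half
        hi = lo + inner_layer_bp
        for bp in range(lo, hi):
            group.update(assembly.bp_bead_indices[bp])
    group = sorted(group)
    assembly.topology.rigid_groups = [g for g in assembly.topology.rigid_groups
                                      if not set(g) & set(group)]
    assembly.topology.rigid_groups.append(group)
    assembly.topology.validate()
    return group
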