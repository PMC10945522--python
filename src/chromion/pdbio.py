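"""PDB input for full-scale systems (crystal nucleosome structures).

Standard columns only; the first altloc is kept and hydrogens are ignored.
Desk-scale fixtures never touch this module — it exists so real cores
(e.g. nucleosome crystal structures) can be coarse-grained when available.
"""

from __future__ import annotations

import warnings
from typing import List, Optional

import numpy as np
from Bio.PDB import PDBParser

from .geometry import BPFrames
from .topology import NucleosomeCoreStructure, ProteinStructure

__all__ = ["read_protein_chains", "read_nucleosome_core"]

_DNA_RESNAMES = {"DA", "DT", "DG", "DC", "A", "T", "G", "C"}


def _parse(path):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PDBParser(QUIET=True).get_structure("s", path)


def read_protein_chains(path) -> List[ProteinStructure]:
    """C-alpha traces of every protein chain in a PDB file."""
    structure = _parse(path)
    chains = []
    for chain in structure[0]:
        residues, coords = [], []
        for res in chain:
            if res.id[0] != " " or res.get_resname() in _DNA_RESNAMES:
                continue
            residues.append(res.get_resname())
            coords.append(res["CA"].get_coord() if "CA" in res
                          else np.full(3, np.nan))
        if residues:
            chains.append(ProteinStructure(chain_id=chain.id, residues=residues,
                                           ca_coords=np.asarray(coords, float)))
    return chains


def read_nucleosome_core(path, watson_chain: str, crick_chain: str,
                         flexible_ranges: Optional[dict] = None
                         ) -> NucleosomeCoreStructure:
    """Nucleosome core record from a crystal structure.

    Base-pair frames are estimated from paired C1' midpoints: the frame
    origin is the C1'-C1' midpoint, the local axis comes from consecutive
    origins, and the in-plane reference vector points toward the Watson C1'.
    """
    structure = _parse(path)
    model = structure[0]

    def c1_coords(chain_id):
        out = []
        for res in model[chain_id]:
            if res.get_resname().strip() in _DNA_RESNAMES and "C1'" in res:
                out.append(res["C1'"].get_coord())
        return np.asarray(out, float)

    w = c1_coords(watson_chain)
    c = c1_coords(crick_chain)[::-1]          # align Crick 3'->5' with Watson 5'->3'
    if len(w) == 0 or len(w) != len(c):
        raise ValueError("core lacks a complete DNA duplex")
    n = len(w)
    origins = 0.5 * (w + c)
    e3 = np.gradient(origins, axis=0)
    e3 /= np.linalg.norm(e3, axis=1)[:, None]
    e1 = w - origins
    e1 -= np.sum(e1 * e3, axis=1)[:, None] * e3
    e1 /= np.linalg.norm(e1, axis=1)[:, None]
    e2 = np.cross(e3, e1)
    frames = BPFrames(origins, e1, e2, e3, np.zeros(n))

    # Watson-strand sequence from residue names
    seq = "".join(res.get_resname().strip()[-1] for res in model[watson_chain]
                  if res.get_resname().strip() in _DNA_RESNAMES and "C1'" in res)
    proteins = read_protein_chains(path)
    for p in proteins:
        if flexible_ranges and p.chain_id in flexible_ranges:
            p.flexible_ranges = list(flexible_ranges[p.chain_id])
    return NucleosomeCoreStructure(proteins=proteins, dna_sequence=seq, frames=frames)
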