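"""Trajectory analyses: ion condensation, neutralized charge and bound
fractions, inter-nucleosomal contacts, and the Kirkwood sedimentation
coefficient of an array of nucleosome centers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CondensationReport", "ion_condensation", "condensation_report",
    "internucleosome_contacts", "sedimentation_coefficient",
]

ION_VALENCE = {"NA": 1, "MG": 2, "CL": -1}


def _min_image(d: np.ndarray, box: Optional[float]) -> np.ndarray:
    if box is not None:
        d = d - box * np.round(d / box)
    return d


def _min_dist_to_group(points, group, box):
    """Minimum-image minimum distance from each point to any group bead."""
    out = np.full(len(points), np.inf)
    for s in range(0, len(group), 256):
        d = _min_image(points[:, None, :] - group[None, s:s + 256, :], box)
        out = np.minimum(out, np.sqrt((d ** 2).sum(axis=2)).min(axis=1))
    return out


def ion_condensation(positions: np.ndarray, target_beads: Sequence[int],
                     ion_beads: Sequence[int], box: Optional[float] = None,
                     cutoff: float = 10.0) -> int:
    """Number of the given ions within ``cutoff`` A of any target bead
    (minimum-image convention in periodic boxes)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ions = positions[np.asarray(ion_beads, int)]
    target = positions[np.asarray(target_beads, int)]
    if len(ions) == 0 or len(target) == 0:
        return 0
    return int(np.sum(_min_dist_to_group(ions, target, box) <= cutoff))


@dataclass
class CondensationReport:
    """Time-averaged ion binding to a target group (typically the DNA)."""

    bound_counts: Dict[str, float]        # mean bound ions per species
    bound_std: Dict[str, float]           # frame-to-frame std deviation
    total_counts: Dict[str, int]
    neutralized_charge: float             # e; sum of bound cation charge
    neutralized_std: float
    bound_fraction: Dict[str, float]      # bound / total per species

    def __post_init__(self):
        for s, f in self.bound_fraction.items():
            if not -1e-9 <= f <= 1.0 + 1e-9:
                raise ValueError(f"bound fraction for {s} outside [0, 1]")


def condensation_report(frames: Sequence[np.ndarray], target_beads: Sequence[int],
                        species: Sequence[str], box: Optional[float] = None,
                        cutoff: float = 10.0) -> CondensationReport:
    """Average ion condensation over a trajectory.

    ``species`` gives each bead's species name; all NA/MG/CL beads are
    treated as ions.  Neutralized charge counts bound cations weighted by
    valence (Na+ + 2 Mg2+).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty trajectory")
    ion_idx = {s: [i for i, sp in enumerate(species) if sp == s]
               for s in ("NA", "MG", "CL")}
    per_frame = {s: [] for s in ion_idx}
    neut = []
    for x in frames:
        for s, idx in ion_idx.items():
            per_frame[s].append(
                ion_condensation(x, target_beads, idx, box=box, cutoff=cutoff)
                if idx else 0)
        neut.append(per_frame["NA"][-1] + 2 * per_frame["MG"][-1])
    bound = {s: float(np.mean(v)) for s, v in per_frame.items()}
    std = {s: float(np.std(v)) for s, v in per_frame.items()}
    totals = {s: len(idx) for s, idx in ion_idx.items()}
    frac = {s: (bound[s] / totals[s] if totals[s] else 0.0) for s in bound}
    return CondensationReport(
        bound_counts=bound, bound_std=std, total_counts=totals,
        neutralized_charge=float(np.mean(neut)), neutralized_std=float(np.std(neut)),
        bound_fraction=frac)


def internucleosome_contacts(positions: np.ndarray, assembly1, assembly2,
                             box: Optional[float] = None,
                             cutoff: float = 10.0) -> Tuple[int, int]:
    """Cross-nucleosome (histone-tail, DNA) and (histone-core, DNA) contact counts.

    Counts bead pairs within ``cutoff`` where the protein bead belongs to one
    nucleosome and the DNA bead to the other, summed over both directions.
    """
    def count(prot_idx, dna_idx):
        if not len(prot_idx) or not len(dna_idx):
            return 0
        p = positions[np.asarray(prot_idx, int)]
        d = positions[np.asarray(dna_idx, int)]
        n = 0
        for s in range(0, len(p), 256):
            dd = _min_image(p[s:s + 256, None, :] - d[None, :, :], box)
            n += int(np.sum((dd ** 2).sum(axis=2) <= cutoff ** 2))
        return n

    dna1, dna2 = assembly1.dna_beads(), assembly2.dna_beads()
    tail = (count(assembly1.tail_beads, dna2) + count(assembly2.tail_beads, dna1))
    core = (count(assembly1.histone_core_beads, dna2)
            + count(assembly2.histone_core_beads, dna1))
    return tail, core


def sedimentation_coefficient(centers: np.ndarray, s1: float = 11.1,
                              radius_nm: float = 5.5) -> float:
    """Kirkwood rigid-array sedimentation coefficient in Svedberg.

    ``S = S1 * (1 + (R/N) * sum_{i != j} 1/r_ij)`` over nucleosome centers
    (A), with the mononucleosome coefficient ``s1`` and effective
    hydrodynamic radius ``radius_nm`` (converted to A internally).
    """
    x = np.atleast_2d(np.asarray(centers, float))
    n = len(x)
    if n == 0:
        raise ValueError("need at least one nucleosome center")
    if n == 1:
        return float(s1)
    d = x[:, None, :] - x[None, :, :]
    r = np.sqrt((d ** 2).sum(axis=2))
    off = ~np.eye(n, dtype=bool)
    if np.any(r[off] < 1e-9):
        raise ValueError("coincident nucleosome centers")
    inv_sum = float(np.sum(1.0 / r[off]))
    return float(s1 * (1.0 + (radius_nm * 10.0 / n) * inv_sum))
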