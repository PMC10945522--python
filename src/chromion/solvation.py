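"""Ion counting and grid placement for box solvation.

Bulk ion-pair counts follow ``round(c * V * N_A)`` per salt species; the
excess cations needed to neutralize the (polyanionic) solute are then added
to the policy species: Na+ for mixed/monovalent systems, Mg2+ for
MgCl2-only systems.  The resulting total charge (solute + ions) is exactly
zero by construction.  Ions are placed deterministically on a uniform grid,
skipping points that fall within a clearance distance of any solute bead,
with species interleaved round-robin over the surviving points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .units import N_AVOGADRO

__all__ = ["IonBoxSpec", "IonCounts", "count_ions", "place_ions_grid"]

#: liters per cubic nanometer
NM3_TO_L = 1e-24


@dataclass(frozen=True)
class IonBoxSpec:
    """Target box volume (nm^3), salt concentrations (mol/L), solute charge (e)."""

    box_volume_nm3: float
    conc_nacl: float = 0.0
    conc_mgcl2: float = 0.0
    solute_charge: int = 0
    neutralization_policy: str = "auto"   # 'monovalent' | 'divalent' | 'auto'

    def __post_init__(self):
        if self.box_volume_nm3 <= 0:
            raise ValueError("box volume must be positive")
        if self.conc_nacl < 0 or self.conc_mgcl2 < 0:
            raise ValueError("concentrations must be non-negative")
        if self.solute_charge > 0:
            raise ValueError("only polyanionic solutes are supported")
        if self.neutralization_policy not in ("monovalent", "divalent", "auto"):
            raise ValueError(f"unknown policy {self.neutralization_policy!r}")

    @property
    def policy(self) -> str:
        if self.neutralization_policy != "auto":
            return self.neutralization_policy
        # MgCl2-only systems neutralize with Mg2+, everything else with Na+
        return "divalent" if (self.conc_nacl == 0 and self.conc_mgcl2 > 0) else "monovalent"

    @property
    def box_edge_nm(self) -> float:
        return self.box_volume_nm3 ** (1.0 / 3.0)


@dataclass(frozen=True)
class IonCounts:
    n_na: int
    n_mg: int
    n_cl: int

    def __post_init__(self):
        if min(self.n_na, self.n_mg, self.n_cl) < 0:
            raise ValueError("ion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_na + self.n_mg + self.n_cl

    def net_charge(self) -> int:
        return self.n_na + 2 * self.n_mg - self.n_cl


def _bulk_pairs(conc: float, volume_nm3: float) -> int:
    return int(round(conc * volume_nm3 * NM3_TO_L * N_AVOGADRO))


def count_ions(spec: IonBoxSpec) -> IonCounts:
    """Ion counts achieving the target concentrations and exact neutrality.

    Bulk counts are nearest-integer ``c*V*N_A`` per dissolved salt unit; the
    policy cation species absorbs the neutralization excess
    ``ceil(|solute_charge| / valence)``, with Cl- adjusted only when the
    divalent excess overshoots by one charge (odd solute charge).
    """
    n_nacl = _bulk_pairs(spec.conc_nacl, spec.box_volume_nm3)
    n_mgcl2 = _bulk_pairs(spec.conc_mgcl2, spec.box_volume_nm3)
    q = -spec.solute_charge          # positive charge deficit to fill
    n_na, n_mg = n_nacl, n_mgcl2
    n_cl = n_nacl + 2 * n_mgcl2
    if spec.policy == "monovalent":
        n_na += q
    else:
        extra = -(-q // 2)           # ceil(q / 2)
        n_mg += extra
        n_cl += 2 * extra - q        # 0 for even q, +1 Cl- for odd q
    counts = IonCounts(n_na, n_mg, n_cl)
    if counts.net_charge() + spec.solute_charge != 0:
        raise ValueError("infeasible neutralization for this spec")
    return counts


def place_ions_grid(counts: IonCounts, box_edge: float,
                    solute_positions: Optional[np.ndarray] = None,
                    clearance: float = 5.0):
    """Deterministic uniform-grid placement of ions in a cubic box.

    Returns ``(positions, species)`` with species in {'NA','MG','CL'}
    interleaved round-robin over the surviving grid points.  The grid is
    refined until enough points remain after removing those within
    ``clearance`` (A) of any solute bead.
    """
    total = counts.total
    if total == 0:
        return np.zeros((0, 3)), []
    solute = None
    if solute_positions is not None and len(solute_positions):
        solute = np.asarray(solute_positions, dtype=float)

    m = max(1, int(np.ceil(total ** (1.0 / 3.0))))
    for _ in range(200):
        ticks = (np.arange(m) + 0.5) * (box_edge / m)
        gx, gy, gz = np.meshgrid(ticks, ticks, ticks, indexing="ij")
        grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        if solute is not None:
            # chunked distance scan keeps memory bounded
            keep = np.ones(len(grid), dtype=bool)
            for s in range(0, len(solute), 512):
                d2 = ((grid[:, None, :] - solute[None, s:s + 512, :]) ** 2).sum(axis=2)
                keep &= (d2.min(axis=1) >= clearance ** 2)
            grid = grid[keep]
        if len(grid) >= total:
            break
        m += 1
    else:
        raise ValueError(f"box too small to host {total} ions with clearance "
                         f"{clearance} A; use a larger box")

    # deterministic ordering: lexicographic grid order, species round-robin
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0]))
    grid = grid[order][:total]
    species: list = []
    streams = [s for s, n in (("NA", counts.n_na), ("MG", counts.n_mg), ("CL", counts.n_cl))
               if n > 0]
    remaining = {"NA": counts.n_na, "MG": counts.n_mg, "CL": counts.n_cl}
    k = 0
    while len(species) < total:
        s = streams[k % len(streams)]
        if remaining[s] > 0:
            species.append(s)
            remaining[s] -= 1
        else:
            streams.remove(s)
            continue
        k += 1
    return grid, species
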