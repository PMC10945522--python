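"""Interaction parameter registries.

Three packaged tables drive the nonbonded model:

* ``ion_pairs.tsv`` — pair potentials between ions and charged coarse-grained
  particles (phosphate P, charged amino acids AA+/AA-, and the ions
  themselves).  Each row carries a short-range core (eps, sigma), a Gaussian
  well (rm_eps, sigma_eps) and up to two hydration-shell Gaussians
  (H1/H2 with positions and widths).
* ``wca_pairs.tsv`` — purely repulsive WCA parameters between ions and
  neutral particles (sugar, the four bases, neutral amino acids).
* ``mj_contact_energies.tsv`` — Miyazawa-Jernigan statistical contact
  energies, used as sequence-specific Lennard-Jones depths between amino
  acids after global rescaling.

Registries are loaded from the packaged TSV files and can be re-serialized
digit-for-digit (the raw string cells are retained for that purpose).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Dict, FrozenSet, Optional, Tuple

import numpy as np

__all__ = [
    "IonPairParams",
    "WCAParams",
    "MJMatrix",
    "IonPairTable",
    "WCATable",
    "load_ion_pair_table",
    "load_wca_table",
    "load_mj_matrix",
    "parameter_checksum",
    "AA3_TO_1",
    "AA_ONE_LETTER",
    "interaction_class",
]

# canonical one-letter ordering used by the packaged MJ table
AA_ONE_LETTER = list("CMFILVWYAGTSNQDEHRKP")

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# charged amino acids at neutral pH; His kept neutral
AA_CHARGE = {"ARG": 1.0, "LYS": 1.0, "ASP": -1.0, "GLU": -1.0}


@dataclass(frozen=True)
class IonPairParams:
    """One row of the charged-pair table (energies kcal/mol, lengths A)."""

    pair: str
    eps: float
    sigma: float
    rm_eps: float
    sigma_eps: float
    H1: Optional[float] = None
    rm_h1: Optional[float] = None
    sigma_h1: Optional[float] = None
    H2: Optional[float] = None
    rm_h2: Optional[float] = None
    sigma_h2: Optional[float] = None

    def __post_init__(self):
        if self.eps <= 0 or self.sigma <= 0:
            raise ValueError(f"{self.pair}: eps and sigma must be positive")
        for w in (self.sigma_eps, self.sigma_h1, self.sigma_h2):
            if w is not None and w <= 0:
                raise ValueError(f"{self.pair}: Gaussian widths must be positive")


@dataclass(frozen=True)
class WCAParams:
    """One row of the ion/neutral-particle WCA table."""

    pair: str
    eps: float
    sigma: float


def _species_key(name: str) -> str:
    return name.strip()


class IonPairTable:
    """Symmetric lookup of :class:`IonPairParams` keyed by species-class pair."""

    def __init__(self, rows, raw_lines):
        self._rows: Dict[FrozenSet[str], IonPairParams] = {}
        self.raw_lines = list(raw_lines)
        for row in rows:
            a, b = _split_pair(row.pair)
            key = frozenset((a, b)) if a != b else frozenset((a,))
            if key in self._rows:
                raise ValueError(f"duplicate pair {row.pair}")
            self._rows[key] = row
        if len(self._rows) != 16:
            raise ValueError(f"expected 16 charged-pair rows, got {len(self._rows)}")

    def get(self, a: str, b: str) -> IonPairParams:
        key = frozenset((a, b)) if a != b else frozenset((a,))
        try:
            return self._rows[key]
        except KeyError:
            valid = ", ".join(sorted(r.pair for r in self._rows.values()))
            raise KeyError(f"no charged-pair parameters for ({a}, {b}); valid pairs: {valid}")

    def __contains__(self, ab: Tuple[str, str]) -> bool:
        a, b = ab
        key = frozenset((a, b)) if a != b else frozenset((a,))
        return key in self._rows

    def rows(self):
        return list(self._rows.values())

    def serialize(self) -> str:
        return "\n".join(self.raw_lines) + "\n"


class WCATable:
    """Symmetric lookup of :class:`WCAParams` for ion/neutral pairs."""

    def __init__(self, rows, raw_lines):
        self._rows: Dict[FrozenSet[str], WCAParams] = {}
        self.raw_lines = list(raw_lines)
        for row in rows:
            a, b = _split_pair(row.pair)
            self._rows[frozenset((a, b))] = row
        if len(self._rows) != 18:
            raise ValueError(f"expected 18 WCA rows, got {len(self._rows)}")

    def get(self, a: str, b: str) -> WCAParams:
        try:
            return self._rows[frozenset((a, b))]
        except KeyError:
            valid = ", ".join(sorted(r.pair for r in self._rows.values()))
            raise KeyError(f"no WCA parameters for ({a}, {b}); valid pairs: {valid}")

    def __contains__(self, ab) -> bool:
        return frozenset(ab) in self._rows

    def rows(self):
        return list(self._rows.values())

    def serialize(self) -> str:
        return "\n".join(self.raw_lines) + "\n"


class MJMatrix:
    """Symmetric 20x20 residue contact-energy matrix (attractive entries negative)."""

    def __init__(self, order, matrix):
        self.order = list(order)
        self.matrix = np.asarray(matrix, dtype=float)
        if self.matrix.shape != (20, 20):
            raise ValueError("MJ matrix must be 20x20")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("MJ matrix must be symmetric")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("MJ matrix entries must be finite")
        self._index = {aa: i for i, aa in enumerate(self.order)}

    def energy(self, aa1: str, aa2: str) -> float:
        """Contact energy for a residue pair given one- or three-letter codes."""
        a = AA3_TO_1.get(aa1, aa1)
        b = AA3_TO_1.get(aa2, aa2)
        return float(self.matrix[self._index[a], self._index[b]])


def _split_pair(pair: str) -> Tuple[str, str]:
    # species names may themselves contain '-' (Cl-), so split on the
    # separator that leaves two known tokens
    tokens = ("Na+", "Mg2+", "Cl-", "P", "S", "A", "T", "G", "C", "AA+", "AA-", "AA")
    for i in range(1, len(pair)):
        a, sep, b = pair[:i], pair[i], pair[i + 1:]
        if sep == "-" and a in tokens and b in tokens:
            return a, b
    raise ValueError(f"cannot parse pair name {pair!r}")


def _read_tsv(name: str):
    text = resources.files("chromion.data").joinpath(name).read_text()
    lines = [ln for ln in text.splitlines()]
    body = [ln for ln in lines if ln and not ln.startswith("#")]
    header = body[0].split("\t")
    rows = [dict(zip(header, ln.split("\t"))) for ln in body[1:]]
    return rows, lines


def _opt(value: str) -> Optional[float]:
    return None if value == "-" else float(value)


def load_ion_pair_table() -> IonPairTable:
    rows, raw = _read_tsv("ion_pairs.tsv")
    parsed = [
        IonPairParams(
            pair=r["pair"], eps=float(r["eps"]), sigma=float(r["sigma"]),
            rm_eps=float(r["rm_eps"]), sigma_eps=float(r["sigma_eps"]),
            H1=_opt(r["H1"]), rm_h1=_opt(r["rm_h1"]), sigma_h1=_opt(r["sigma_h1"]),
            H2=_opt(r["H2"]), rm_h2=_opt(r["rm_h2"]), sigma_h2=_opt(r["sigma_h2"]),
        )
        for r in rows
    ]
    return IonPairTable(parsed, raw)


def load_wca_table() -> WCATable:
    rows, raw = _read_tsv("wca_pairs.tsv")
    parsed = [WCAParams(pair=r["pair"], eps=float(r["eps"]), sigma=float(r["sigma"])) for r in rows]
    return WCATable(parsed, raw)


def load_mj_matrix() -> MJMatrix:
    rows, _ = _read_tsv("mj_contact_energies.tsv")
    order = [r["aa"] for r in rows]
    mat = np.array([[float(r[aa]) for aa in order] for r in rows])
    return MJMatrix(order, mat)


def parameter_checksum() -> str:
    """SHA-256 over the packaged parameter tables (logged with every run)."""
    h = hashlib.sha256()
    for name in ("ion_pairs.tsv", "wca_pairs.tsv", "mj_contact_energies.tsv"):
        h.update(resources.files("chromion.data").joinpath(name).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# species -> interaction-class mapping

ION_SPECIES = {"NA": "Na+", "MG": "Mg2+", "CL": "Cl-"}
DNA_BASE_SPECIES = {"DA": "A", "DT": "T", "DG": "G", "DC": "C"}


def interaction_class(species: str, charge: float) -> str:
    """Map a bead species to the class used by the parameter tables.

    Returns one of 'Na+', 'Mg2+', 'Cl-', 'P', 'S', 'A', 'T', 'G', 'C',
    'AA+', 'AA-', 'AA'.
    """
    if species in ION_SPECIES:
        return ION_SPECIES[species]
    if species == "P":
        return "P"
    if species == "S":
        return "S"
    if species in DNA_BASE_SPECIES:
        return DNA_BASE_SPECIES[species]
    # amino acid
    if charge > 0:
        return "AA+"
    if charge < 0:
        return "AA-"
    return "AA"
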