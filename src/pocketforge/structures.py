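"""Core structural containers.

A :class:`ProteinStructure` is the unit every downstream operation works on:
chains of ordered residues with atom coordinates in Å, an optional per-residue
pLDDT (predicted structures store it in the B-factor column), and the ligands
present in the file.  Residue identity is the author identifier — residue
number plus insertion code — scoped by chain; residues are never renumbered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .errors import JoinError

#: water residue names never treated as ligands
WATER_NAMES = frozenset({"HOH", "WAT"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # 3-vector, Å
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")


@dataclass
class Residue:
    chain_id: str
    res_id: str  # author number + insertion code, e.g. "101" or "101A"
    aa: str  # one-letter code, "X" for non-standard
    atoms: list[Atom] = field(default_factory=list)
    plddt: Optional[float] = None

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def ca(self) -> Optional[np.ndarray]:
        for a in self.atoms:
            if a.name == "CA":
                return a.position
        return None

    def center(self) -> np.ndarray:
        """Cα position, or the mean of all atoms when Cα is absent."""
        ca = self.ca
        return ca if ca is not None else self.coords.mean(axis=0)


@dataclass
class LigandInstance:
    ccd_code: str
    chain_id: str
    atoms: list[Atom]
    relevant: bool = False

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


@dataclass
class BindingAnnotation:
    structure_id: str
    chain_id: str
    ligand_ccd: str
    binding_residues: set[str]


@dataclass
class ProteinStructure:
    structure_id: str
    source: str  # "experimental" | "predicted"
    chains: dict[str, list[Residue]]
    ligands: list[LigandInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.source not in ("experimental", "predicted"):
            raise ValueError(f"unknown source {self.source!r}")
        for cid, residues in self.chains.items():
            ids = [r.res_id for r in residues]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate residue ids in chain {cid}")

    # -- residue access -----------------------------------------------------

    def iter_residues(self) -> Iterator[Residue]:
        """Residues in author order, chains in insertion order."""
        for residues in self.chains.values():
            yield from residues

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def residue_keys(self) -> list[tuple[str, str]]:
        return [(r.chain_id, r.res_id) for r in self.iter_residues()]

    def get_residue(self, chain_id: str, res_id: str) -> Residue:
        for r in self.chains.get(chain_id, ()):
            if r.res_id == res_id:
                return r
        raise JoinError(
            f"residue {chain_id}/{res_id} not found in structure {self.structure_id}"
        )

    def has_residue(self, chain_id: str, res_id: str) -> bool:
        return any(r.res_id == res_id for r in self.chains.get(chain_id, ()))

    def sequence(self, chain_id: str) -> str:
        return "".join(r.aa for r in self.chains[chain_id])

    def ca_coords(self) -> np.ndarray:
        """(n_residues, 3) array of residue centers (Cα when present)."""
        return np.array([r.center() for r in self.iter_residues()])

    def relevant_ligands(self) -> list[LigandInstance]:
        return [l for l in self.ligands if l.relevant]
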