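"""Convert raw pocket-finder outputs into a common candidate-pocket record.

Constituent pocket finders emit results in three dialects:

* point clouds describing the predicted pocket space (AutoSite-style) —
  every residue with an atom within 5 Å of any point joins the pocket;
* a single pocket center (LIGSITEcs-style) — every residue with an atom
  within 8 Å of the center joins the pocket;
* per-residue score tracks (PocketMiner-style cryptic-pocket scores) — a
  residue's hotspot score is the mean of its own score and its ten
  spatially nearest neighbors'; every residue whose hotspot score reaches
  0.7 seeds a pocket of exactly that neighborhood (11 residues).

Residue-list outputs (Fpocket/P2Rank/CASTp/CAVITY-style) pass through with
validation only.  Distances use ANY atom of the residue, inclusive at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, EmptyPocketError, JoinError
from .structures import ProteinStructure


@dataclass
class CandidatePocket:
    structure_id: str
    method: str
    residues: set[tuple[str, str]]  # (chain_id, res_id)
    native_score: Optional[float] = None
    native_rank: Optional[int] = None
    model_score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptyPocketError(f"pocket on {self.structure_id}: empty residue set")

    @property
    def size(self) -> int:
        return len(self.residues)

    def center(self, structure: ProteinStructure) -> np.ndarray:
        """Unweighted mean of member residues' Cα coordinates."""
        coords = [
            structure.get_residue(c, r).center() for c, r in sorted(self.residues)
        ]
        return np.mean(coords, axis=0)


@dataclass
class ResidueScoreTrack:
    """Per-residue scalar score in [0, 1] covering one full chain."""

    structure_id: str
    chain_id: str
    scores: dict[str, float] = field(default_factory=dict)  # res_id -> score

    def validate(self, structure: ProteinStructure) -> None:
        chain = structure.chains[self.chain_id]
        missing = [r.res_id for r in chain if r.res_id not in self.scores]
        if missing:
            raise DegenerateInputError(
                f"score track for {self.structure_id}/{self.chain_id} missing "
                f"residues {missing[:5]}"
            )


def _atom_index(structure: ProteinStructure):
    """Flat atom coordinates plus the residue key owning each atom."""
    coords = []
    owners = []
    for res in structure.iter_residues():
        for atom in res.atoms:
            coords.append(atom.position)
            owners.append((res.chain_id, res.res_id))
    return np.array(coords), owners


def pocket_from_points(
    structure: ProteinStructure,
    points: Sequence,
    radius: float = 5.0,
    method: str = "points",
    native_score: Optional[float] = None,
) -> CandidatePocket:
    """Pocket = all residues having any atom within `radius` of any point."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise DegenerateInputError("empty point set")
    coords, owners = _atom_index(structure)
    tree = cKDTree(coords)
    members: set[tuple[str, str]] = set()
    for idx_list in tree.query_ball_point(points, r=radius):
        members.update(owners[i] for i in idx_list)
    if not members:
        raise EmptyPocketError(
            f"no residue of {structure.structure_id} within {radius} Å of any point"
        )
    return CandidatePocket(
        structure_id=structure.structure_id,
        method=method,
        residues=members,
        native_score=native_score,
    )


def pocket_from_center(
    structure: ProteinStructure,
    center,
    radius: float = 8.0,
    method: str = "center",
    native_score: Optional[float] = None,
) -> CandidatePocket:
    """Pocket = all residues with any atom within `radius` of the center."""
    center = np.asarray(center, dtype=float)
    if center.shape != (3,) or not np.all(np.isfinite(center)):
        raise DegenerateInputError("center must be a finite 3-vector")
    return pocket_from_points(
        structure, center[None, :], radius=radius, method=method,
        native_score=native_score,
    )


def _neighborhoods(structure: ProteinStructure, chain_id: str, n_neighbors: int):
    """For each residue of the chain: indices of itself + n spatial neighbors.

    Neighbors by Cα–Cα (residue-center) distance; ties broken by lower
    sequence index.
    """
    chain = structure.chains[chain_id]
    centers = np.array([r.center() for r in chain])
    n = len(chain)
    out = []
    for i in range(n):
        d = np.linalg.norm(centers - centers[i], axis=1)
        # stable sort on (distance, index) => ties to the lower index
        order = np.lexsort((np.arange(n), d))
        out.append(order[: n_neighbors + 1])
    return chain, out


def pockets_from_residue_scores(
    structure: ProteinStructure,
    track: ResidueScoreTrack,
    n_neighbors: int = 10,
    threshold: float = 0.7,
    method: str = "scores",
) -> list[CandidatePocket]:
    """Hotspot conversion of a per-residue cryptic-pocket score track.

    Every residue whose hotspot score (mean over itself and its
    `n_neighbors` nearest residues) reaches `threshold` yields one pocket
    of exactly ``n_neighbors + 1`` members.  Overlapping pockets are kept;
    deduplication happens downstream in clustering.
    """
    chain_res = structure.chains[track.chain_id]
    if len(chain_res) < n_neighbors + 1:
        raise DegenerateInputError(
            f"chain {track.chain_id} has {len(chain_res)} residues; "
            f"need at least {n_neighbors + 1}"
        )
    track.validate(structure)
    chain, hoods = _neighborhoods(structure, track.chain_id, n_neighbors)
    scores = np.array([track.scores[r.res_id] for r in chain])
    pockets = []
    for i, hood in enumerate(hoods):
        hotspot = float(np.mean(scores[hood]))
        if hotspot >= threshold:
            pockets.append(
                CandidatePocket(
                    structure_id=structure.structure_id,
                    method=method,
                    residues={(chain[j].chain_id, chain[j].res_id) for j in hood},
                    native_score=hotspot,
                )
            )
    return pockets


def pocket_from_residue_list(
    structure: ProteinStructure,
    residues: Iterable[tuple[str, str]],
    method: str,
    score: Optional[float] = None,
) -> CandidatePocket:
    """Validated passthrough for residue-list pocket outputs."""
    members = set(residues)
    if not members:
        raise DegenerateInputError("empty residue list")
    for cid, rid in members:
        if not structure.has_residue(cid, rid):
            raise JoinError(
                f"residue {cid}/{rid} not in structure {structure.structure_id}"
            )
    return CandidatePocket(
        structure_id=structure.structure_id,
        method=method,
        residues=members,
        native_score=score,
    )
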