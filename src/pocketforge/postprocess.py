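"""Score/pLDDT filtering and overlap-merge clustering of accepted pockets.

Candidate pockets scoring below the decision threshold t (default 0.4) are
discarded, as are pockets on predicted structures whose member residues
average below 70 pLDDT — the conventional "low confidence" boundary.  In
both filters equality survives.  Surviving pockets that share at least one
residue are merged iteratively until only disjoint "mega-pocket" clusters
remain; a cluster's representative score is the maximum member score and
its center the unweighted mean of member-residue Cα positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataError, ParameterError
from .harmonize import CandidatePocket
from .structures import ProteinStructure

ResidueKey = tuple[str, str]


@dataclass
class PocketCluster:
    members: list[CandidatePocket]
    residues: set[ResidueKey]

    @property
    def representative_score(self) -> float:
        scores = [p.model_score for p in self.members if p.model_score is not None]
        if not scores:
            raise ParameterError("cluster members carry no model scores")
        return max(scores)

    def center(self, structure: ProteinStructure) -> np.ndarray:
        coords = [
            structure.get_residue(c, r).center() for c, r in sorted(self.residues)
        ]
        return np.mean(coords, axis=0)


def filter_by_score(
    pockets: Sequence[CandidatePocket], t: float = 0.4
) -> list[CandidatePocket]:
    """Keep pockets with model score >= t (scores below t are discarded)."""
    out = []
    for p in pockets:
        if p.model_score is None:
            raise ParameterError("pocket lacks a model score")
        if p.model_score >= t:
            out.append(p)
    return out


def filter_by_plddt(
    pockets: Sequence[CandidatePocket],
    structure: ProteinStructure,
    min_mean: float = 70.0,
) -> list[CandidatePocket]:
    """Keep pockets whose member residues average >= min_mean pLDDT.

    No-op for experimental structures, which carry no pLDDT.
    """
    if structure.source != "predicted":
        return list(pockets)
    out = []
    for p in pockets:
        values = []
        for chain_id, res_id in p.residues:
            res = structure.get_residue(chain_id, res_id)
            if res.plddt is None:
                raise DataError(
                    f"residue {chain_id}/{res_id} of predicted structure "
                    f"{structure.structure_id} has no pLDDT"
                )
            values.append(res.plddt)
        if float(np.mean(values)) >= min_mean:
            out.append(p)
    return out


def cluster_pockets(pockets: Sequence[CandidatePocket]) -> list[PocketCluster]:
    """Merge pockets sharing at least one residue into disjoint clusters.

    Connected components of the residue-overlap graph, computed by
    union-find over a residue -> first-seen-pocket index map.  Output order
    is deterministic: by minimum residue key of the merged set.
    """
    n = len(pockets)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    seen: dict[ResidueKey, int] = {}
    for i, p in enumerate(pockets):
        for key in p.residues:
            if key in seen:
                parent[find(i)] = find(seen[key])
            else:
                seen[key] = i

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    clusters = []
    for indices in groups.values():
        members = [pockets[i] for i in indices]
        residues: set[ResidueKey] = set()
        for p in members:
            residues |= p.residues
        clusters.append(PocketCluster(members=members, residues=residues))
    clusters.sort(key=lambda c: min(c.residues))
    return clusters


def rank_clusters(clusters: Sequence[PocketCluster]) -> list[PocketCluster]:
    """Rank by representative score (desc); ties to the larger cluster,
    then by minimum residue id for determinism."""
    return sorted(
        clusters,
        key=lambda c: (-c.representative_score, -len(c.residues), min(c.residues)),
    )


def cluster_center(cluster: PocketCluster, structure: ProteinStructure) -> np.ndarray:
    return cluster.center(structure)
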