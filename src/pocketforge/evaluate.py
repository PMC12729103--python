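"""Per-residue and pocket-level evaluation of pocket predictions.

Per-residue: each residue is labeled 1 when any of its atoms lies within a
radius r (5 or 10 Å by default) of any atom of any biologically relevant
ligand; predicted per-residue scores are compared with ROC/PRC curves,
pooling residues over all evaluated structures.

Pocket-level: the DCA criterion.  For each structure the top-N ranked
pockets (N = N_L, the number of relevant ligands, or N_L + 2) each
contribute the distance from their central coordinate to the nearest atom
of the nearest relevant ligand; precision is the percentage of distances
under a threshold (4 Å, also reported at 8 and 10 Å).  A background
distribution takes the same distances from random surface points, and a
two-sided Kolmogorov–Smirnov test compares the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence
import warnings

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp
from sklearn.metrics import (
    auc as _sk_auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)

from .errors import ParameterError
from .structures import LigandInstance, ProteinStructure

ResidueKey = tuple[str, str]


@dataclass
class EvalLabeling:
    r: float
    labels: dict[ResidueKey, int]

    @property
    def positives(self) -> set[ResidueKey]:
        return {k for k, v in self.labels.items() if v == 1}


def label_residues(
    structure: ProteinStructure,
    relevant_ligands: Optional[Sequence[LigandInstance]] = None,
    r: float = 5.0,
) -> EvalLabeling:
    """Label 1 every residue with an atom within r of a relevant-ligand atom."""
    if relevant_ligands is None:
        relevant_ligands = structure.relevant_ligands()
    if not relevant_ligands:
        raise ParameterError(
            f"structure {structure.structure_id} has no relevant ligands"
        )
    lig_coords = np.vstack([l.coords for l in relevant_ligands])
    tree = cKDTree(lig_coords)
    labels = {}
    for res in structure.iter_residues():
        d = tree.query(res.coords)[0].min()
        labels[(res.chain_id, res.res_id)] = int(d <= r)
    return EvalLabeling(r=r, labels=labels)


def auroc(scores: Sequence[float], labels: Sequence[int]):
    """ROC curve and area (ties counted half, as in the rank estimator)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ParameterError("AUROC needs both classes")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return {"fpr": fpr, "tpr": tpr, "thresholds": thresholds,
            "area": float(_sk_auc(fpr, tpr))}


def auprc(scores: Sequence[float], labels: Sequence[int]):
    """Precision-recall curve and average precision."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.sum() == 0:
        raise ParameterError("AUPRC needs at least one positive")
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    return {"precision": precision, "recall": recall, "thresholds": thresholds,
            "area": float(average_precision_score(labels, scores))}


def pooled_residue_metrics(
    score_maps: Mapping[str, Mapping[ResidueKey, float]],
    labelings: Mapping[str, EvalLabeling],
) -> dict:
    """Pool per-residue scores and labels over structures, then ROC/PRC."""
    scores, labels = [], []
    for sid, labeling in labelings.items():
        smap = score_maps[sid]
        for key, label in labeling.labels.items():
            scores.append(smap.get(key, 0.0))
            labels.append(label)
    return {
        "auroc": auroc(scores, labels)["area"],
        "auprc": auprc(scores, labels)["area"],
        "prevalence": float(np.mean(labels)),
        "n_residues": len(labels),
    }


@dataclass
class DCAResult:
    threshold: float
    top_mode: str  # "NL" | "NL+2"
    distances: list[float] = field(default_factory=list)
    n_structures: int = 0

    @property
    def precision(self) -> float:
        """Percent of contributed distances under the threshold."""
        if not self.distances:
            return float("nan")
        return 100.0 * float(np.mean(np.asarray(self.distances) < self.threshold))


def _nearest_ligand_distance(point: np.ndarray, ligands) -> float:
    coords = np.vstack([l.coords for l in ligands])
    return float(np.linalg.norm(coords - point, axis=1).min())


def dca_precision(
    ranked_centers_by_structure: Mapping[str, Sequence[np.ndarray]],
    structures: Mapping[str, ProteinStructure],
    top_mode: str = "NL",
    threshold: float = 4.0,
) -> DCAResult:
    """DCA precision over structures.

    ``ranked_centers_by_structure`` maps structure_id to pocket central
    coordinates in rank order (best first).  Per structure the top
    N = N_L (or N_L + 2) centers each contribute one distance to the
    nearest relevant-ligand atom; structures with fewer pockets contribute
    what they have, and only contributed distances enter the denominator.
    """
    if top_mode not in ("NL", "NL+2"):
        raise ParameterError(f"unknown top mode {top_mode!r}")
    result = DCAResult(threshold=threshold, top_mode=top_mode)
    for sid, centers in ranked_centers_by_structure.items():
        structure = structures[sid]
        ligands = structure.relevant_ligands()
        if not ligands:
            warnings.warn(f"structure {sid} has no relevant ligands; skipped",
                          stacklevel=2)
            continue
        n = len(ligands) + (2 if top_mode == "NL+2" else 0)
        for center in list(centers)[:n]:
            result.distances.append(
                _nearest_ligand_distance(np.asarray(center, float), ligands)
            )
        result.n_structures += 1
    return result


def surface_residues(
    structure: ProteinStructure,
    neighbor_cutoff: int = 18,
    radius: float = 10.0,
) -> list[ResidueKey]:
    """Exposure proxy: residues whose Cα has < `neighbor_cutoff` Cα
    neighbors within `radius` Å."""
    keys = structure.residue_keys()
    ca = structure.ca_coords()
    tree = cKDTree(ca)
    counts = np.array([len(tree.query_ball_point(c, r=radius)) - 1 for c in ca])
    surf = [keys[i] for i in range(len(keys)) if counts[i] < neighbor_cutoff]
    if not surf:
        warnings.warn(
            f"no surface residues under the exposure proxy on "
            f"{structure.structure_id}; falling back to all residues",
            stacklevel=2,
        )
        return keys
    return surf


def background_distances(
    structure: ProteinStructure,
    relevant_ligands: Optional[Sequence[LigandInstance]] = None,
    n: int = 1,
    seed: int = 0,
    neighbor_cutoff: int = 18,
    radius: float = 10.0,
) -> list[float]:
    """Distances from n random surface-residue Cα points to the nearest
    relevant-ligand atom."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    if relevant_ligands is None:
        relevant_ligands = structure.relevant_ligands()
    if not relevant_ligands:
        raise ParameterError(
            f"structure {structure.structure_id} has no relevant ligands"
        )
    rng = np.random.default_rng(seed)
    surf = surface_residues(structure, neighbor_cutoff, radius)
    picks = rng.integers(len(surf), size=n)
    out = []
    for i in picks:
        cid, rid = surf[i]
        point = structure.get_residue(cid, rid).center()
        out.append(_nearest_ligand_distance(point, relevant_ligands))
    return out


def ks_two_sided(sample_a: Sequence[float], sample_b: Sequence[float]):
    """Two-sample two-sided Kolmogorov–Smirnov test (asymptotic p)."""
    if not len(sample_a) or not len(sample_b):
        raise ParameterError("both samples must be non-empty")
    res = ks_2samp(sample_a, sample_b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
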