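"""Build labeled pocket examples and identity-based data splits.

Positive examples are "pocket spheres": all residues within 5 Å of the Cα
of a randomly sampled annotated binding residue, accepted when the sphere
is dominated by annotated residues (> 50 %) or captures most of the
annotated pocket (> 80 %).  Negative examples are spheres around random
residues containing no annotated residue at all.  Per annotated pocket the
positive quota is 2 / 3 / 4 for pockets of < 10 / 10–24 / ≥ 25 residues and
the negative quota is twice the positive count.  Within each class no two
examples may share 90 % or more of their residues
(overlap = \\|A∩B\\| / min(\\|A\\|, \\|B\\|)).

Structures are partitioned train/val/test (80:10:10) such that no pair of
structures in different splits exceeds 40 % global sequence identity:
structures joined by > 40 % identity form atomic connected components that
are greedily assigned, largest first, to the split with the greatest
remaining deficit.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from .errors import ParameterError
from .structures import BindingAnnotation, ProteinStructure
from .structure_io import join_annotation

ResidueKey = tuple[str, str]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named reproducible RNG substream derived from one run seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class PocketExample:
    structure_id: str
    residues: list[ResidueKey]  # ordered, no duplicates
    label: int  # 0 | 1
    provenance: str  # positive-sphere | negative-sphere | candidate
    center_residue: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ParameterError(f"label must be 0 or 1, got {self.label}")
        if not self.residues:
            raise ParameterError("empty residue list")
        if len(self.residues) != len(set(self.residues)):
            raise ParameterError("duplicate residues in example")

    @property
    def residue_set(self) -> set[ResidueKey]:
        return set(self.residues)


@dataclass
class SplitAssignment:
    assignment: dict[str, str]  # structure_id -> train|val|test
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def split(self, name: str) -> set[str]:
        return {sid for sid, s in self.assignment.items() if s == name}


# -- sequence identity ------------------------------------------------------

def _aligner(match: float = 1.0, mismatch: float = 0.0, gap: float = -1.0) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap
    a.extend_gap_score = gap
    return a


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> float:
    """Global-alignment sequence identity: matches / alignment length."""
    if not seq_a or not seq_b:
        raise ParameterError("sequences must be non-empty")
    alignment = _aligner(match, mismatch, gap).align(seq_a, seq_b)[0]
    identities = alignment.counts().identities
    return identities / alignment.length


def partition_structures(
    sequences: Mapping[str, str],
    max_identity: float = 0.40,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Assign structures to train/val/test respecting the identity bound.

    Structures with pairwise identity > `max_identity` must share a split;
    the connected components of that relation are assigned greedily (largest
    first) to whichever split currently has the greatest deficit relative to
    its target count.  A single component spanning everything degrades to
    an all-in-train assignment with a warning.
    """
    ids = sorted(sequences)
    if len(ids) < 3:
        raise ParameterError("need at least 3 structures to split")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ParameterError("ratios must sum to 1")

    # union-find over the >max_identity relation
    parent = {sid: sid for sid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if pairwise_identity(sequences[a], sequences[b]) > max_identity:
                parent[find(a)] = find(b)

    components: dict[str, list[str]] = {}
    for sid in ids:
        components.setdefault(find(sid), []).append(sid)
    comps = sorted(components.values(), key=lambda c: (-len(c), c[0]))

    if len(comps) == 1:
        warnings.warn(
            "all structures form one identity component; assigning everything "
            "to the training split",
            stacklevel=2,
        )
        return SplitAssignment(
            assignment={sid: "train" for sid in ids}, ratios=ratios
        )

    rng = substream(seed, "split")
    # seeded shuffle among equal-size components, then stable largest-first
    order = rng.permutation(len(comps))
    comps = [comps[i] for i in order]
    comps.sort(key=len, reverse=True)

    splits = ("train", "val", "test")
    target = {s: r * len(ids) for s, r in zip(splits, ratios)}
    count = {s: 0 for s in splits}
    assignment: dict[str, str] = {}
    for comp in comps:
        deficit = {s: target[s] - count[s] for s in splits}
        best = max(splits, key=lambda s: deficit[s])  # ties: train > val > test
        for sid in comp:
            assignment[sid] = best
        count[best] += len(comp)
    return SplitAssignment(assignment=assignment, ratios=ratios)


# -- example generation -----------------------------------------------------

def positive_quota(annotated_pocket_size: int) -> int:
    """Number of positive examples to draw for an annotated pocket."""
    if annotated_pocket_size < 1:
        raise ParameterError("pocket size must be >= 1")
    if annotated_pocket_size < 10:
        return 2
    if annotated_pocket_size <= 24:
        return 3
    return 4


def _sphere(
    structure: ProteinStructure,
    center: np.ndarray,
    radius: float,
    tree: cKDTree,
    owners: list[ResidueKey],
) -> list[ResidueKey]:
    """Residues with >=1 atom within radius of center, in author order."""
    hit = {owners[i] for i in tree.query_ball_point(center, r=radius)}
    return [key for key in structure.residue_keys() if key in hit]


def _atom_tree(structure: ProteinStructure) -> tuple[cKDTree, list[ResidueKey]]:
    coords, owners = [], []
    for res in structure.iter_residues():
        for atom in res.atoms:
            coords.append(atom.position)
            owners.append((res.chain_id, res.res_id))
    return cKDTree(np.array(coords)), owners


def overlap_fraction(a: set, b: set) -> float:
    """|A∩B| / min(|A|,|B|) — the strictest symmetric overlap measure."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def generate_positive_examples(
    structure: ProteinStructure,
    annotation: BindingAnnotation,
    radius: float = 5.0,
    seed: int = 0,
    quota: Optional[int] = None,
    max_overlap: float = 0.9,
) -> list[PocketExample]:
    """Sample accepted pocket spheres around annotated residues.

    May return fewer than the quota when geometry exhausts the annotated
    residues before enough acceptable, non-redundant spheres are found.
    """
    annotated = join_annotation(annotation, structure)
    if not annotated:
        return []
    if quota is None:
        quota = positive_quota(len(annotated))
    rng = substream(seed, "positives")
    tree, owners = _atom_tree(structure)

    order = sorted(annotated)
    rng.shuffle(order)
    accepted: list[PocketExample] = []
    for chain_id, res_id in order:
        if len(accepted) >= quota:
            break
        center = structure.get_residue(chain_id, res_id).center()
        sphere = _sphere(structure, center, radius, tree, owners)
        if not sphere:
            continue
        sphere_set = set(sphere)
        inter = len(sphere_set & annotated)
        ok = (inter / len(sphere_set) > 0.5) or (inter / len(annotated) > 0.8)
        if not ok:
            continue
        if any(
            overlap_fraction(sphere_set, e.residue_set) >= max_overlap
            for e in accepted
        ):
            continue
        accepted.append(
            PocketExample(
                structure_id=structure.structure_id,
                residues=sphere,
                label=1,
                provenance="positive-sphere",
                center_residue=res_id,
            )
        )
    return accepted


def generate_negative_examples(
    structure: ProteinStructure,
    annotation: Optional[BindingAnnotation],
    n_required: int,
    radius: float = 5.0,
    seed: int = 0,
    max_attempts: Optional[int] = None,
    max_overlap: float = 0.9,
    annotated_union: Optional[set[ResidueKey]] = None,
) -> list[PocketExample]:
    """Sample spheres fully disjoint from the annotated binding residues.

    `annotated_union` may supply the union over several annotations of one
    structure; otherwise the single annotation (or nothing) defines it.
    """
    if n_required < 0:
        raise ParameterError("n_required must be >= 0")
    if n_required == 0:
        return []
    if annotated_union is None:
        annotated_union = (
            join_annotation(annotation, structure) if annotation is not None else set()
        )
    if max_attempts is None:
        max_attempts = 50 * n_required
    rng = substream(seed, "negatives")
    tree, owners = _atom_tree(structure)
    keys = structure.residue_keys()

    accepted: list[PocketExample] = []
    for _ in range(max_attempts):
        if len(accepted) >= n_required:
            break
        chain_id, res_id = keys[rng.integers(len(keys))]
        center = structure.get_residue(chain_id, res_id).center()
        sphere = _sphere(structure, center, radius, tree, owners)
        if not sphere:
            continue
        sphere_set = set(sphere)
        if sphere_set & annotated_union:
            continue
        if any(
            overlap_fraction(sphere_set, e.residue_set) >= max_overlap
            for e in accepted
        ):
            continue
        accepted.append(
            PocketExample(
                structure_id=structure.structure_id,
                residues=sphere,
                label=0,
                provenance="negative-sphere",
                center_residue=res_id,
            )
        )
    return accepted


def build_examples(
    structure: ProteinStructure,
    annotations: Sequence[BindingAnnotation],
    radius: float = 5.0,
    seed: int = 0,
    negatives_per_positive: int = 2,
) -> list[PocketExample]:
    """Positives per annotated pocket plus twice as many negatives.

    Negatives avoid the union of all annotated residues on the structure.
    """
    union: set[ResidueKey] = set()
    for ann in annotations:
        union |= join_annotation(ann, structure)
    out: list[PocketExample] = []
    n_pos_total = 0
    for i, ann in enumerate(annotations):
        pos = generate_positive_examples(
            structure, ann, radius=radius, seed=seed + i
        )
        out.extend(pos)
        n_pos_total += len(pos)
    out.extend(
        generate_negative_examples(
            structure,
            None,
            n_required=negatives_per_positive * n_pos_total,
            radius=radius,
            seed=seed,
            annotated_union=union,
        )
    )
    return out
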