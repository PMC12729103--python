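"""Synthetic structures, ligands, method predictions, and embeddings.

Everything the pipeline consumes can be generated offline with controlled
signal so each stage is testable without external downloads:

* Cα-trace "proteins": seeded self-avoiding 3-D walks with 3.8 Å steps and
  a compactness bias toward the running centroid, so the chains stay
  globular and "surface" is meaningful;
* planted ligands: small atom clusters placed just outside a surface
  residue; the ground-truth annotation is every residue within 5 Å of any
  ligand atom — the same rule the evaluator uses;
* simulated pocket-finder outputs in all four raw dialects (point cloud,
  single center, per-residue score track, residue list), parameterized by
  a per-method sensitivity ``p_hit`` and decoy rate ``p_fp``;
* a signal embedder whose binding-residue embeddings are mean-shifted by a
  controllable amount σ along a fixed seeded direction, with everything
  else standard normal.  σ = 0 means no signal at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .dataset import substream
from .errors import ParameterError, PocketforgeError
from .evaluate import surface_residues
from .features import EmbeddingTable
from .harmonize import (
    CandidatePocket,
    ResidueScoreTrack,
    pocket_from_center,
    pocket_from_points,
    pocket_from_residue_list,
    pockets_from_residue_scores,
)
from .structures import (
    Atom,
    BindingAnnotation,
    LigandInstance,
    ProteinStructure,
    Residue,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Cα–Cα virtual bond length, Å
STEP_LENGTH = 3.8
#: non-adjacent residues may not come closer than this, Å
SELF_AVOID_RADIUS = 3.0


@dataclass
class MethodProfile:
    dialect: str  # points | center | scores | residues
    p_hit: float = 0.9
    p_fp: float = 0.1
    n_decoy_slots: int = 5

    def __post_init__(self) -> None:
        if self.dialect not in ("points", "center", "scores", "residues"):
            raise ParameterError(f"unknown dialect {self.dialect!r}")
        if not (0 <= self.p_hit <= 1 and 0 <= self.p_fp <= 1):
            raise ParameterError("probabilities must lie in [0, 1]")


def default_method_profiles() -> dict[str, MethodProfile]:
    """Seven simulated constituent methods spanning all raw dialects."""
    return {
        "pointsA": MethodProfile("points"),
        "centerA": MethodProfile("center"),
        "scoresA": MethodProfile("scores"),
        "listA": MethodProfile("residues"),
        "listB": MethodProfile("residues", p_hit=0.8, p_fp=0.15),
        "pointsB": MethodProfile("points", p_hit=0.8, p_fp=0.15),
        "centerB": MethodProfile("center", p_hit=0.8, p_fp=0.15),
    }


@dataclass
class SyntheticConfig:
    n_residues: int = 150
    n_ligands: int = 1
    method_profiles: dict[str, MethodProfile] = field(
        default_factory=default_method_profiles
    )
    embed_dim: int = 64
    embed_signal: float = 2.0  # σ: mean shift for binding residues
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_signal < 0:
            raise ParameterError("embed_signal must be >= 0")


# -- structure generation ---------------------------------------------------


def generate_structure(
    n_residues: int,
    seed: int = 0,
    structure_id: Optional[str] = None,
    source: str = "experimental",
    compactness: float = 0.45,
    plddt_tail: int = 0,
    max_retries: int = 20,
) -> ProteinStructure:
    """Seeded self-avoiding compact Cα walk of `n_residues` residues.

    ``plddt_tail`` > 0 (with ``source="predicted"``) marks that many
    residues at each terminus as low-confidence (pLDDT around 50) while the
    core sits around 90, mimicking disordered tails of predicted models.
    """
    if n_residues < 12:
        raise ParameterError("need at least 12 residues")
    rng = substream(seed, "structure")
    coords = _self_avoiding_walk(n_residues, rng, compactness, max_retries)
    sid = structure_id or f"synth{seed}"
    residues = []
    for i in range(n_residues):
        plddt = None
        if source == "predicted":
            if i < plddt_tail or i >= n_residues - plddt_tail:
                plddt = float(np.clip(rng.normal(50, 5), 0, 100))
            else:
                plddt = float(np.clip(rng.normal(90, 3), 0, 100))
        aa = AA_ALPHABET[rng.integers(len(AA_ALPHABET))]
        residues.append(
            Residue(
                chain_id="A",
                res_id=str(i + 1),
                aa=aa,
                atoms=[Atom(name="CA", element="C", position=coords[i],
                            bfactor=plddt or 0.0)],
                plddt=plddt,
            )
        )
    return ProteinStructure(
        structure_id=sid, source=source, chains={"A": residues}
    )


def _self_avoiding_walk(
    n: int, rng: np.random.Generator, compactness: float, max_retries: int
) -> np.ndarray:
    for _ in range(max_retries):
        coords = [np.zeros(3)]
        ok = True
        for _i in range(1, n):
            centroid = np.mean(coords, axis=0)
            placed = False
            for _try in range(60):
                direction = rng.standard_normal(3)
                pull = centroid - coords[-1]
                norm = np.linalg.norm(pull)
                if norm > 1e-9:
                    direction = direction + compactness * pull / norm * np.linalg.norm(direction)
                direction /= np.linalg.norm(direction)
                cand = coords[-1] + STEP_LENGTH * direction
                if len(coords) > 1:
                    d = np.linalg.norm(np.array(coords[:-1]) - cand, axis=1)
                    if d.min() < SELF_AVOID_RADIUS:
                        continue
                coords.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(coords)
    raise PocketforgeError(f"self-avoiding walk failed after {max_retries} retries")


# -- ligand planting --------------------------------------------------------


def plant_ligand(
    structure: ProteinStructure,
    seed: int = 0,
    ccd_code: str = "LIG",
    n_contacts: int = 7,
    offset: float = 3.0,
    avoid: Optional[np.ndarray] = None,
    min_separation: float = 25.0,
) -> tuple[LigandInstance, BindingAnnotation]:
    """Place a small ligand next to a seeded surface residue.

    The annotation lists every residue with an atom within 5 Å of any
    ligand atom (the evaluator's labeling rule at r = 5).  ``avoid`` can
    hold existing ligand coordinates; the site is then chosen at least
    ``min_separation`` Å away so multiple planted sites stay disjoint.
    """
    rng = substream(seed, f"ligand-{ccd_code}")
    surf = surface_residues(structure)
    ca_all = structure.ca_coords()
    centroid = ca_all.mean(axis=0)
    order = rng.permutation(len(surf))
    site = None
    for i in order:
        cid, rid = surf[i]
        ca = structure.get_residue(cid, rid).center()
        if avoid is not None and len(avoid):
            if np.linalg.norm(np.asarray(avoid) - ca, axis=1).min() < min_separation:
                continue
        site = (cid, rid, ca)
        break
    if site is None:
        raise PocketforgeError("no surface residue far enough from existing ligands")
    _cid, _rid, ca = site
    outward = ca - centroid
    norm = np.linalg.norm(outward)
    outward = outward / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
    # one atom nestled against each of the site's nearest residues, so the
    # ligand contacts a realistic number of residues (annotated pockets in
    # curated databases typically span ~5-20 residues)
    d_site = np.linalg.norm(ca_all - ca, axis=1)
    contact_idx = np.argsort(d_site)[:n_contacts]
    keys = structure.residue_keys()
    atoms = []
    for j, idx in enumerate(contact_idx):
        ccid, crid = keys[idx]
        cca = structure.get_residue(ccid, crid).center()
        pos = cca + offset * outward + rng.normal(0, 0.4, size=3)
        atoms.append(Atom(name=f"C{j+1}", element="C", position=pos))
    ligand = LigandInstance(ccd_code=ccd_code, chain_id="A", atoms=atoms,
                            relevant=True)
    structure.ligands.append(ligand)

    lig_tree = cKDTree(ligand.coords)
    binding = set()
    for res in structure.iter_residues():
        if lig_tree.query(res.coords)[0].min() <= 5.0:
            binding.add(res.res_id)
    annotation = BindingAnnotation(
        structure_id=structure.structure_id,
        chain_id="A",
        ligand_ccd=ccd_code,
        binding_residues=binding,
    )
    return ligand, annotation


# -- simulated method outputs -----------------------------------------------


@dataclass
class RawPrediction:
    """A simulated pocket-finder output in one of the raw dialects."""

    method: str
    dialect: str
    points: list[np.ndarray] = field(default_factory=list)  # point clouds
    centers: list[np.ndarray] = field(default_factory=list)
    track: Optional[ResidueScoreTrack] = None
    residue_lists: list[list[tuple[str, str]]] = field(default_factory=list)


def simulate_method_predictions(
    structure: ProteinStructure,
    annotation: BindingAnnotation,
    profile: MethodProfile,
    seed: int = 0,
    method: str = "sim",
) -> RawPrediction:
    """Emit the true pocket with probability ``p_hit`` plus decoys.

    Decoys appear independently with probability ``p_fp`` at each of
    ``n_decoy_slots`` random non-annotated surface locations, in the same
    dialect as the true-site output.
    """
    rng = substream(seed, f"method-{method}")
    annotated = {(annotation.chain_id, rid) for rid in annotation.binding_residues}
    ann_centers = np.array(
        [structure.get_residue(c, r).center() for c, r in sorted(annotated)]
    )
    surf = [k for k in surface_residues(structure) if k not in annotated]

    hit = rng.random() < profile.p_hit
    decoy_sites = []
    for _slot in range(profile.n_decoy_slots):
        if rng.random() < profile.p_fp and surf:
            cid, rid = surf[rng.integers(len(surf))]
            decoy_sites.append(structure.get_residue(cid, rid).center())

    raw = RawPrediction(method=method, dialect=profile.dialect)
    if profile.dialect == "points":
        if hit:
            jitter = rng.normal(0, 0.8, size=ann_centers.shape)
            raw.points.append(ann_centers + jitter)
        for site in decoy_sites:
            raw.points.append(site + rng.normal(0, 1.5, size=(4, 3)))
    elif profile.dialect == "center":
        if hit:
            raw.centers.append(ann_centers.mean(axis=0) + rng.normal(0, 1.0, 3))
        for site in decoy_sites:
            raw.centers.append(site + rng.normal(0, 1.0, 3))
    elif profile.dialect == "scores":
        chain = structure.chains[annotation.chain_id]
        centers = np.array([r.center() for r in chain])
        scores = {r.res_id: float(rng.uniform(0.0, 0.3)) for r in chain}

        def _boost(site: np.ndarray, n_boost: int = 12) -> None:
            # lift a full spatial neighborhood so 11-residue hotspot means
            # clear the 0.7 conversion threshold
            d = np.linalg.norm(centers - site, axis=1)
            for j in np.argsort(d)[:n_boost]:
                scores[chain[j].res_id] = float(rng.uniform(0.85, 1.0))

        if hit:
            _boost(ann_centers.mean(axis=0))
            for _cid, rid in annotated:
                scores[rid] = float(rng.uniform(0.85, 1.0))
        for site in decoy_sites:
            _boost(site)
        raw.track = ResidueScoreTrack(
            structure_id=structure.structure_id,
            chain_id=annotation.chain_id,
            scores=scores,
        )
    else:  # residues
        if hit:
            raw.residue_lists.append(sorted(annotated))
        tree = cKDTree(structure.ca_coords())
        keys = structure.residue_keys()
        for site in decoy_sites:
            members = [keys[i] for i in tree.query_ball_point(site, r=6.0)]
            if members:
                raw.residue_lists.append(sorted(set(members)))
    return raw


def harmonize_raw(
    structure: ProteinStructure, raw: RawPrediction,
    n_neighbors: int = 10, score_threshold: float = 0.7,
) -> list[CandidatePocket]:
    """Run the dialect-appropriate harmonization on a raw prediction."""
    pockets: list[CandidatePocket] = []
    if raw.dialect == "points":
        for cloud in raw.points:
            pockets.append(
                pocket_from_points(structure, cloud, method=raw.method)
            )
    elif raw.dialect == "center":
        for center in raw.centers:
            pockets.append(
                pocket_from_center(structure, center, method=raw.method)
            )
    elif raw.dialect == "scores":
        if raw.track is not None:
            pockets.extend(
                pockets_from_residue_scores(
                    structure, raw.track, n_neighbors=n_neighbors,
                    threshold=score_threshold, method=raw.method,
                )
            )
    else:
        for residues in raw.residue_lists:
            pockets.append(
                pocket_from_residue_list(structure, residues, method=raw.method)
            )
    return pockets


# -- embeddings -------------------------------------------------------------


class SignalEmbedder:
    """Synthetic per-residue embedder with a controllable class signal.

    Non-binding residues draw i.i.d. standard normal coordinates; binding
    residues are additionally shifted by σ along a fixed unit direction
    seeded once per embedder.  At σ = 0 the two classes are
    indistinguishable by construction.
    """

    def __init__(self, width: int = 64, sigma: float = 2.0, seed: int = 0):
        if width < 2:
            raise ParameterError("width must be >= 2")
        self.width = width
        self.sigma = sigma
        self.seed = seed
        self.embedder_id = f"signal-{width}-{sigma}-{seed}"
        rng = substream(seed, "embed-direction")
        direction = rng.standard_normal(width)
        self.direction = direction / np.linalg.norm(direction)

    def embed_structure(
        self,
        structure: ProteinStructure,
        binding_residues: set[tuple[str, str]],
        chain_id: str = "A",
    ) -> EmbeddingTable:
        chain = structure.chains[chain_id]
        rng = substream(self.seed, f"embed-{structure.structure_id}-{chain_id}")
        vectors = {}
        for res in chain:
            v = rng.standard_normal(self.width)
            if (chain_id, res.res_id) in binding_residues:
                v = v + self.sigma * self.direction
            vectors[res.res_id] = v
        return EmbeddingTable(
            structure_id=structure.structure_id,
            chain_id=chain_id,
            embedder_id=self.embedder_id,
            vectors=vectors,
        )


def synthetic_embedder(
    structure: ProteinStructure,
    annotation: Optional[BindingAnnotation],
    width: int = 64,
    sigma: float = 2.0,
    seed: int = 0,
    chain_id: str = "A",
) -> EmbeddingTable:
    """Convenience wrapper over :class:`SignalEmbedder` for one chain."""
    binding: set[tuple[str, str]] = set()
    if annotation is not None:
        binding = {(annotation.chain_id, rid) for rid in annotation.binding_residues}
    return SignalEmbedder(width=width, sigma=sigma, seed=seed).embed_structure(
        structure, binding, chain_id=chain_id
    )
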