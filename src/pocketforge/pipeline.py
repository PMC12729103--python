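"""End-to-end pipeline: simulate/load inputs, harmonize, build the dataset,
train and apply the scorer, filter, cluster, and evaluate.

The synthetic mode (no input paths in the config) exercises every stage on
generated structures, which is how the pipeline is validated offline.  Per
stage the manifest records counts in and out, the seeds used, and a hash
of the configuration, so a rerun with the same config reproduces every
deterministic output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import structure_io
from .config import RunConfig
from .dataset import build_examples, partition_structures, substream
from .ensemble import aggregate_residue_scores, consensus_hotspots, vote_counts
from .errors import PocketforgeError
from .evaluate import (
    background_distances,
    dca_precision,
    ks_two_sided,
    label_residues,
    pooled_residue_metrics,
)
from .features import featurize_pocket
from .dataset import PocketExample
from .models import (
    PRESET_NN_B,
    TrainedScorer,
    save_scorer,
    score_pockets,
    select_threshold,
    train_scorer,
)
from .postprocess import (
    cluster_pockets,
    filter_by_plddt,
    filter_by_score,
    rank_clusters,
)
from .synthetic import (
    SignalEmbedder,
    SyntheticConfig,
    harmonize_raw,
    generate_structure,
    plant_ligand,
    simulate_method_predictions,
)

logger = logging.getLogger("pocketforge")


def build_example_corpus(
    n_structures: int = 60,
    sigma: float = 2.0,
    seed: int = 0,
    embed_dim: int = 64,
    n_residues: int = 150,
    n_permutations: int = 10,
    n_rows: int = 15,
):
    """Labeled, featurized pocket examples from synthetic structures.

    Structures are generated and annotated, pocket-sphere examples built,
    structures partitioned by sequence identity (80:10:10), and training
    examples augmented with up to `n_permutations` residue orderings.
    Embeddings come from the signal embedder at mean shift `sigma`, so the
    corpus carries a known, controllable amount of signal.

    Returns (train_matrices, val_matrices, test_matrices).
    """
    from .features import augment_examples

    embedder = SignalEmbedder(width=embed_dim, sigma=sigma, seed=seed)
    per_structure: dict[str, list] = {}
    tables = {}
    sequences = {}
    for i in range(n_structures):
        seed_i = seed * 100_003 + i
        structure = generate_structure(
            n_residues, seed=seed_i, structure_id=f"corpus{i:03d}"
        )
        _, ann = plant_ligand(structure, seed=seed_i)
        examples = build_examples(structure, [ann], seed=seed_i)
        binding = {(ann.chain_id, rid) for rid in ann.binding_residues}
        tables[structure.structure_id] = {
            "A": embedder.embed_structure(structure, binding)
        }
        sequences[structure.structure_id] = structure.sequence("A")
        per_structure[structure.structure_id] = examples

    split = partition_structures(sequences, seed=seed)

    def matrices(split_name: str, augment: bool):
        out = []
        for sid in sorted(split.split(split_name)):
            for j, ex in enumerate(per_structure[sid]):
                variants = (
                    augment_examples(ex, n_permutations, seed=seed + j)
                    if augment
                    else [ex]
                )
                for k, v in enumerate(variants):
                    out.append(
                        featurize_pocket(
                            v, "B", embeddings=tables[sid],
                            n_rows=n_rows, seed=seed + 31 * j + k,
                        )
                    )
        return out

    return (
        matrices("train", augment=True),
        matrices("val", augment=True),
        matrices("test", augment=False),
    )


def parameter_recovery_experiment(
    sigma: float,
    n_structures: int = 60,
    seed: int = 0,
    epochs: int = 50,
    embed_dim: int = 64,
) -> dict:
    """Train the published NN configuration on a synthetic corpus with
    embedding signal `sigma` and report the best validation AUROC."""
    train_m, val_m, _ = build_example_corpus(
        n_structures=n_structures, sigma=sigma, seed=seed, embed_dim=embed_dim
    )
    scorer, history = train_scorer(
        train_m, val_m, PRESET_NN_B, epochs=epochs, seed=seed
    )
    t = select_threshold(scorer, val_m)
    return {
        "sigma": sigma,
        "n_train": len(train_m),
        "n_val": len(val_m),
        "best_val_auroc": max(history.val_auroc),
        "threshold_t": t,
    }


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def simulate_inputs(config: RunConfig):
    """Generate structures, planted ligands/annotations, raw predictions,
    and per-chain embeddings for a synthetic run."""
    syn = SyntheticConfig(
        n_residues=config.n_residues,
        n_ligands=config.n_ligands,
        embed_dim=config.embed_dim,
        embed_signal=config.embed_signal,
        seed=config.seed,
    )
    embedder = SignalEmbedder(
        width=syn.embed_dim, sigma=syn.embed_signal, seed=config.seed
    )
    structures, annotations, raw_by_structure, embeddings = {}, {}, {}, {}
    for i in range(config.n_structures):
        seed_i = config.seed * 100_003 + i
        structure = generate_structure(
            syn.n_residues, seed=seed_i, structure_id=f"synth{i:03d}"
        )
        anns = []
        avoid = None
        for j in range(syn.n_ligands):
            _lig, ann = plant_ligand(
                structure, seed=seed_i + j, ccd_code=f"LG{j}", avoid=avoid
            )
            anns.append(ann)
            avoid = np.vstack([l.coords for l in structure.ligands])
        annotations[structure.structure_id] = anns
        raws = {}
        for m, (method, profile) in enumerate(
            sorted(syn.method_profiles.items())
        ):
            raws[method] = simulate_method_predictions(
                structure, anns[0], profile, seed=seed_i + 31 * m, method=method
            )
        raw_by_structure[structure.structure_id] = raws
        binding = {
            (ann.chain_id, rid) for ann in anns for rid in ann.binding_residues
        }
        embeddings[structure.structure_id] = {
            "A": embedder.embed_structure(structure, binding, chain_id="A")
        }
        structures[structure.structure_id] = structure
    return structures, annotations, raw_by_structure, embeddings


def harmonize_all(structures, raw_by_structure, config: RunConfig):
    """Raw dialect outputs -> candidate pockets, per structure and method."""
    pockets = {}
    for sid, raws in raw_by_structure.items():
        per_method = {}
        for method, raw in raws.items():
            per_method[method] = harmonize_raw(
                structures[sid], raw,
                n_neighbors=config.n_neighbors,
                score_threshold=config.score_track_threshold,
            )
        pockets[sid] = per_method
    return pockets


def _method_channels(per_method_pockets) -> dict:
    channels: dict[str, dict] = {}
    for method, pockets in per_method_pockets.items():
        chan: dict = {}
        for p in pockets:
            for key in p.residues:
                chan[key] = 1
        channels[method] = chan
    return channels


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full workflow and write all stage outputs.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    stage = manifest["stages"]

    try:
        # --- inputs ---------------------------------------------------
        if config.structures_dir:
            raise PocketforgeError(
                "file-based runs chain the dedicated subcommands; run_pipeline "
                "currently drives the synthetic workflow"
            )
        structures, annotations, raws, embeddings = simulate_inputs(config)
        stage["simulate"] = {"n_structures": len(structures)}
        logger.info("simulated %d structures", len(structures))

        # --- harmonize ------------------------------------------------
        pockets = harmonize_all(structures, raws, config)
        n_pockets = sum(
            len(ps) for per in pockets.values() for ps in per.values()
        )
        stage["harmonize"] = {"n_candidate_pockets": n_pockets}

        # --- consensus report -----------------------------------------
        consensus_rows = []
        for sid, per_method in pockets.items():
            votes = vote_counts(per_method, structures[sid])
            for k in range(1, votes.n_methods + 1):
                res = consensus_hotspots(votes, k)
                consensus_rows.append(
                    {"structure_id": sid, "k": k,
                     "n_hotspot_residues": len(res.hotspot_residues)}
                )
        pd.DataFrame(consensus_rows).to_csv(
            out / "consensus.tsv", sep="\t", index=False
        )
        stage["consensus"] = {"rows": len(consensus_rows)}

        # --- dataset --------------------------------------------------
        examples = {}
        for sid, structure in structures.items():
            examples[sid] = build_examples(
                structure, annotations[sid], radius=config.sphere_radius,
                seed=config.seed,
            )
        split = partition_structures(
            {sid: s.sequence("A") for sid, s in structures.items()},
            max_identity=config.max_identity,
            ratios=config.split_ratios,
            seed=config.seed,
        )
        n_pos = sum(e.label == 1 for ex in examples.values() for e in ex)
        n_neg = sum(e.label == 0 for ex in examples.values() for e in ex)
        stage["dataset"] = {
            "n_positives": n_pos, "n_negatives": n_neg,
            "split_sizes": {s: len(split.split(s)) for s in ("train", "val", "test")},
        }

        # --- featurize + train ----------------------------------------
        def matrices_for(split_name):
            out_m = []
            for sid in sorted(split.split(split_name)):
                chans = _method_channels(pockets[sid])
                for j, ex in enumerate(examples[sid]):
                    out_m.append(
                        featurize_pocket(
                            ex, config.feature_set,
                            method_channels=chans,
                            embeddings=embeddings[sid],
                            n_rows=config.n_rows,
                            seed=config.seed + j,
                        )
                    )
            return out_m

        train_m = matrices_for("train")
        val_m = matrices_for("val")
        scorer, history = train_scorer(
            train_m, val_m, PRESET_NN_B, epochs=config.epochs, seed=config.seed
        )
        t = select_threshold(scorer, val_m)
        save_scorer(scorer, out / "model")
        stage["train"] = {
            "n_train": len(train_m), "n_val": len(val_m),
            "best_val_auroc": max(history.val_auroc), "threshold_t": t,
        }

        # --- score + filter + cluster ---------------------------------
        scored_rows = []
        clusters_by_structure = {}
        residue_scores = {}
        for sid, per_method in pockets.items():
            structure = structures[sid]
            chans = _method_channels(per_method)
            flat = [p for ps in per_method.values() for p in ps]
            if not flat:
                clusters_by_structure[sid] = []
                residue_scores[sid] = {}
                continue
            mats = []
            for p in flat:
                ex = PocketExample(
                    structure_id=sid,
                    residues=sorted(p.residues),
                    label=0,  # placeholder; scoring ignores labels
                    provenance="candidate",
                )
                mats.append(
                    featurize_pocket(
                        ex, config.feature_set, method_channels=chans,
                        embeddings=embeddings[sid], n_rows=config.n_rows,
                        seed=config.seed,
                    )
                )
            scores = score_pockets(scorer, mats)
            for p, s in zip(flat, scores):
                p.model_score = float(s)
            residue_scores[sid] = aggregate_residue_scores(
                flat, structure, score_source="model"
            )
            kept = filter_by_score(flat, t=config.score_threshold)
            kept = filter_by_plddt(kept, structure, min_mean=config.min_plddt)
            clusters = rank_clusters(cluster_pockets(kept)) if kept else []
            clusters_by_structure[sid] = clusters
            for rank, c in enumerate(clusters):
                scored_rows.append(
                    {"structure_id": sid, "rank": rank,
                     "score": c.representative_score,
                     "n_residues": len(c.residues),
                     "residues": ",".join(f"{a}:{b}" for a, b in sorted(c.residues))}
                )
        pd.DataFrame(
            scored_rows,
            columns=["structure_id", "rank", "score", "n_residues", "residues"],
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        stage["postprocess"] = {
            "n_clusters": sum(len(c) for c in clusters_by_structure.values())
        }

        # --- evaluate -------------------------------------------------
        metrics = {}
        for r in config.eval_radii:
            labelings = {
                sid: label_residues(s, r=r) for sid, s in structures.items()
            }
            metrics[f"residue_r{r:g}"] = pooled_residue_metrics(
                residue_scores, labelings
            )
        centers = {
            sid: [c.center(structures[sid]) for c in clusters]
            for sid, clusters in clusters_by_structure.items()
        }
        for mode in config.top_modes:
            for thr in config.dca_thresholds:
                res = dca_precision(centers, structures, top_mode=mode,
                                    threshold=thr)
                metrics[f"dca_{mode}_{thr:g}A"] = {
                    "precision": res.precision,
                    "n_distances": len(res.distances),
                }
        bg = []
        fg = []
        rng = substream(config.seed, "background")
        for sid, structure in structures.items():
            n_l = len(structure.relevant_ligands())
            bg.extend(
                background_distances(
                    structure, n=n_l, seed=int(rng.integers(2**31))
                )
            )
            res = dca_precision({sid: centers[sid]}, structures, top_mode="NL")
            fg.extend(res.distances)
        if fg and bg:
            stat, p = ks_two_sided(fg, bg)
            metrics["ks_vs_background"] = {"statistic": stat, "p_value": p}
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=1, default=float)
        stage["evaluate"] = {"metrics": sorted(metrics)}

    except PocketforgeError as exc:
        raise PocketforgeError(
            f"pipeline failed at stage {len(stage)}: {exc}"
        ) from exc

    manifest["metrics_path"] = str(out / "metrics.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return manifest
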