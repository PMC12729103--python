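"""Run configuration: one serializable object holding every stage default.

Defaults follow the published workflow: 5 Å point-cloud rule, 8 Å center
rule, 10-neighbor / 0.7 hotspot conversion, N = 15 feature rows, up to 10
permutations for augmentation, 50 training epochs (500 iterations for the
linear model), decision threshold 0.4, pLDDT floor 70, evaluation radii
5/10 Å, DCA thresholds 4/8/10 Å, 40 % identity bound with 80:10:10 splits,
positive quotas 2/3/4, twice as many negatives, 90 % overlap cap, and the
>50 % / >80 % sphere acceptance rules.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    # paths (empty -> fully synthetic run)
    structures_dir: str = ""
    annotations_path: str = ""
    raw_outputs_dir: str = ""
    embeddings_dir: str = ""

    # harmonization
    point_radius: float = 5.0
    center_radius: float = 8.0
    n_neighbors: int = 10
    score_track_threshold: float = 0.7

    # consensus
    consensus_k: int = 4

    # dataset construction
    sphere_radius: float = 5.0
    max_identity: float = 0.40
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    quota_small: int = 2  # pockets of < 10 residues
    quota_medium: int = 3  # 10-24 residues
    quota_large: int = 4  # >= 25 residues
    negatives_per_positive: int = 2
    max_overlap: float = 0.9
    accept_majority: float = 0.5  # > 50% of sphere annotated
    accept_coverage: float = 0.8  # > 80% of annotation captured

    # features / models
    n_rows: int = 15
    feature_set: str = "B"
    n_permutations_max: int = 10
    order_mode: str = "n_to_c"
    epochs: int = 50
    lr_max_iter: int = 500
    embed_dim: int = 64
    embed_signal: float = 2.0

    # postprocessing
    score_threshold: float = 0.4
    min_plddt: float = 70.0

    # evaluation
    eval_radii: tuple[float, float] = (5.0, 10.0)
    dca_thresholds: tuple[float, float, float] = (4.0, 8.0, 10.0)
    top_modes: tuple[str, str] = ("NL", "NL+2")

    # synthetic inputs
    n_structures: int = 30
    n_residues: int = 150
    n_ligands: int = 1

    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("split_ratios", "eval_radii", "dca_thresholds", "top_modes"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
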