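"""Naive consensus over constituent methods and per-residue aggregation.

The k-of-M consensus calls a residue a hotspot when at least k of the M
constituent methods place it in any pocket.  A method contributes at most
one vote per residue regardless of how many of its pockets contain it, so
counts are bounded by M.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import ConfigError, ParameterError
from .harmonize import CandidatePocket
from .structures import ProteinStructure

ResidueKey = tuple[str, str]


@dataclass
class ResidueVoteMap:
    counts: dict[ResidueKey, int]
    method_set: frozenset[str]

    @property
    def n_methods(self) -> int:
        return len(self.method_set)


@dataclass
class ConsensusResult:
    k: int
    hotspot_residues: set[ResidueKey]


def vote_counts(
    pockets_by_method: Mapping[str, Sequence[CandidatePocket]],
    structure: ProteinStructure,
) -> ResidueVoteMap:
    """Count, per residue, how many methods predict it in at least one pocket."""
    counts: dict[ResidueKey, int] = {key: 0 for key in structure.residue_keys()}
    for method, pockets in pockets_by_method.items():
        covered: set[ResidueKey] = set()
        for p in pockets:
            covered.update(p.residues)
        for key in covered:
            if key in counts:
                counts[key] += 1
    return ResidueVoteMap(counts=counts, method_set=frozenset(pockets_by_method))


def consensus_hotspots(votes: ResidueVoteMap, k: int) -> ConsensusResult:
    """Residues predicted by at least k of the M methods."""
    m = votes.n_methods
    if not 1 <= k <= m:
        raise ParameterError(f"k={k} outside [1, {m}]")
    hotspots = {key for key, c in votes.counts.items() if c >= k}
    return ConsensusResult(k=k, hotspot_residues=hotspots)


@dataclass
class SimpleFilterConfig:
    """Configurable low-confidence pocket filter.

    ``min_size`` applies to every method; per-method overrides and native
    score floors are optional.  Score thresholds default to off.
    """

    enabled: bool = True
    min_size: int = 5
    min_size_by_method: dict[str, int] = field(default_factory=dict)
    min_native_score_by_method: dict[str, float] = field(default_factory=dict)

    def validate(self, known_methods: Optional[set[str]] = None) -> None:
        if known_methods is not None:
            unknown = (
                set(self.min_size_by_method) | set(self.min_native_score_by_method)
            ) - known_methods
            if unknown:
                raise ConfigError(f"unknown method tags in filter config: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "enabled": self.enabled,
            "min_size": self.min_size,
            "min_size_by_method": dict(self.min_size_by_method),
            "min_native_score_by_method": dict(self.min_native_score_by_method),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimpleFilterConfig":
        return cls(**d)


def simple_filter(
    pockets: Sequence[CandidatePocket], config: SimpleFilterConfig
) -> list[CandidatePocket]:
    """Drop pockets failing any enabled rule; input order preserved."""
    if not config.enabled:
        return list(pockets)
    known = {p.method for p in pockets}
    config.validate(known_methods=known | set(config.min_size_by_method)
                    | set(config.min_native_score_by_method))
    out = []
    for p in pockets:
        min_size = config.min_size_by_method.get(p.method, config.min_size)
        if p.size < min_size:
            continue
        floor = config.min_native_score_by_method.get(p.method)
        if floor is not None and (p.native_score is None or p.native_score < floor):
            continue
        out.append(p)
    return out


def aggregate_residue_scores(
    pockets: Sequence[CandidatePocket],
    structure: ProteinStructure,
    score_source: str = "native",
) -> dict[ResidueKey, float]:
    """Per-residue score = max over containing pockets.

    With ``score_source="native"`` all pockets must come from one method:
    scoring methods use their native score, unscored methods contribute a
    binary 1 for any covered residue.  With ``score_source="model"`` the
    attached model scores are used and pockets may mix methods.
    """
    if score_source not in ("native", "model"):
        raise ParameterError(f"unknown score_source {score_source!r}")
    if score_source == "native":
        methods = {p.method for p in pockets}
        if len(methods) > 1:
            raise ParameterError(
                f"native aggregation must be called per method; got {sorted(methods)}"
            )
    out: dict[ResidueKey, float] = {key: 0.0 for key in structure.residue_keys()}
    for p in pockets:
        if score_source == "model":
            if p.model_score is None:
                raise ParameterError("pocket lacks a model score")
            s = p.model_score
        else:
            s = 1.0 if p.native_score is None else p.native_score
        for key in p.residues:
            if key in out and s > out[key]:
                out[key] = s
    return out
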