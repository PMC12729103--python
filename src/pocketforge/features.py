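"""Fixed-size feature matrices for pocket examples.

A pocket example becomes an N×D matrix (N = 15 residues by default).
Feature Set A uses one binary channel per constituent method (D = M),
Feature Set B the per-residue embedding (D = E), and Feature Set C their
concatenation (D = M + E; 2567 with 7 methods and the 2560-wide reference
embedder).  Pockets smaller than N are zero-padded; larger pockets are
truncated to a seeded uniform subset of N residues.  Method channels are
laid out in a frozen alphabetical order that must travel with any trained
model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .dataset import PocketExample, substream
from .errors import FeaturizationError, ParameterError

ResidueKey = tuple[str, str]


@dataclass
class EmbeddingTable:
    """Per-residue numeric vectors of constant width E for one chain."""

    structure_id: str
    chain_id: str
    embedder_id: str
    vectors: dict[str, np.ndarray]  # res_id -> (E,)

    @property
    def width(self) -> int:
        return next(iter(self.vectors.values())).shape[0]

    def get(self, res_id: str) -> np.ndarray:
        if res_id not in self.vectors:
            raise FeaturizationError(
                f"no embedding for residue {self.chain_id}/{res_id} "
                f"({self.embedder_id})"
            )
        return self.vectors[res_id]


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (N, D)
    feature_set: str  # A | B | C
    n_rows: int
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.values.shape[0] != self.n_rows:
            raise FeaturizationError(
                f"expected {self.n_rows} rows, got {self.values.shape[0]}"
            )

    @property
    def flat(self) -> np.ndarray:
        return self.values.reshape(-1)


def canonical_method_order(methods) -> list[str]:
    """Frozen channel layout: alphabetical by method tag."""
    return sorted(methods)


def featurize_pocket(
    example: PocketExample,
    feature_set: str,
    method_channels: Optional[Mapping[str, Mapping[ResidueKey, int]]] = None,
    embeddings: Optional[Mapping[str, EmbeddingTable]] = None,
    n_rows: int = 15,
    order_mode: str = "n_to_c",
    seed: int = 0,
) -> FeatureMatrix:
    """Build the N×D matrix for one pocket example.

    ``method_channels`` maps method tag -> {(chain, res_id): 0/1}; membership
    defaults to 0 for unlisted residues.  ``embeddings`` maps chain_id ->
    :class:`EmbeddingTable`.  ``order_mode`` is ``n_to_c`` (chain order as
    stored in the example) or ``shuffled`` (seeded permutation).
    """
    if feature_set not in ("A", "B", "C"):
        raise ParameterError(f"unknown feature set {feature_set!r}")
    if feature_set in ("A", "C") and method_channels is None:
        raise ParameterError(f"feature set {feature_set} requires method channels")
    if feature_set in ("B", "C") and embeddings is None:
        raise ParameterError(f"feature set {feature_set} requires embeddings")
    if not example.residues:
        raise ParameterError("empty example")

    rng = substream(seed, "featurize")
    residues = list(example.residues)
    if order_mode == "shuffled":
        rng.shuffle(residues)
    elif order_mode != "n_to_c":
        raise ParameterError(f"unknown order mode {order_mode!r}")
    if len(residues) > n_rows:
        keep = sorted(rng.choice(len(residues), size=n_rows, replace=False))
        residues = [residues[i] for i in keep]

    rows = []
    for key in residues:
        parts = []
        if feature_set in ("A", "C"):
            order = canonical_method_order(method_channels)
            parts.append(
                np.array(
                    [float(method_channels[m].get(key, 0)) for m in order]
                )
            )
        if feature_set in ("B", "C"):
            chain_id, res_id = key
            if chain_id not in embeddings:
                raise FeaturizationError(f"no embedding table for chain {chain_id}")
            parts.append(np.asarray(embeddings[chain_id].get(res_id), dtype=float))
        rows.append(np.concatenate(parts))

    d = rows[0].shape[0]
    values = np.zeros((n_rows, d))
    values[: len(rows)] = rows
    return FeatureMatrix(
        values=values, feature_set=feature_set, n_rows=n_rows, label=example.label
    )


def augment_examples(
    example: PocketExample, n_permutations_max: int = 10, seed: int = 0
) -> list[PocketExample]:
    """Up to `n_permutations_max` distinct residue orderings of one pocket."""
    if n_permutations_max < 1:
        raise ParameterError("n_permutations_max must be >= 1")
    rng = substream(seed, "augment")
    n = len(example.residues)
    # small pockets: enumerate all permutations and sample without replacement
    if n <= 6:
        perms = list(permutations(range(n)))
        k = min(n_permutations_max, len(perms))
        chosen = [perms[i] for i in rng.choice(len(perms), size=k, replace=False)]
    else:
        seen: set[tuple[int, ...]] = set()
        chosen = []
        while len(chosen) < n_permutations_max:
            p = tuple(rng.permutation(n))
            if p not in seen:
                seen.add(p)
                chosen.append(p)
    return [
        PocketExample(
            structure_id=example.structure_id,
            residues=[example.residues[i] for i in perm],
            label=example.label,
            provenance=example.provenance,
            center_residue=example.center_residue,
        )
        for perm in chosen
    ]


class Embedder(Protocol):
    """Contract for per-residue sequence embedders.

    Deterministic per (embedder_id, sequence); fixed output width.
    """

    embedder_id: str
    width: int

    def __call__(self, sequence: str) -> np.ndarray:  # (len(sequence), E)
        ...


def embed_sequence(
    sequence: str, embedder: Embedder, structure_id: str = "", chain_id: str = "",
    res_ids: Optional[Sequence[str]] = None,
) -> EmbeddingTable:
    """Run an embedder over a sequence and package the result."""
    if not sequence:
        raise ParameterError("empty sequence")
    try:
        matrix = np.asarray(embedder(sequence), dtype=float)
    except Exception as exc:
        raise FeaturizationError(
            f"embedder {getattr(embedder, 'embedder_id', '?')} failed on "
            f"{structure_id}/{chain_id}: {exc}"
        ) from exc
    if matrix.shape != (len(sequence), embedder.width):
        raise FeaturizationError(
            f"embedder returned shape {matrix.shape}, expected "
            f"({len(sequence)}, {embedder.width})"
        )
    if res_ids is None:
        res_ids = [str(i + 1) for i in range(len(sequence))]
    return EmbeddingTable(
        structure_id=structure_id,
        chain_id=chain_id,
        embedder_id=embedder.embedder_id,
        vectors={rid: matrix[i] for i, rid in enumerate(res_ids)},
    )


class HashEmbedder:
    """Deterministic content-hash embedder (no learned signal).

    Each residue's vector is drawn from an RNG keyed on the sequence and
    position, so identical sequences always embed identically.
    """

    def __init__(self, width: int = 64, embedder_id: str = "hash-64"):
        self.width = width
        self.embedder_id = embedder_id

    def __call__(self, sequence: str) -> np.ndarray:
        import zlib

        out = np.empty((len(sequence), self.width))
        for i, _aa in enumerate(sequence):
            key = zlib.crc32(f"{self.embedder_id}|{sequence}|{i}".encode())
            out[i] = np.random.default_rng(key).standard_normal(self.width)
        return out


# -- embedding table I/O ----------------------------------------------------

def write_embedding_table(table: EmbeddingTable, path) -> None:
    rows = []
    for rid, vec in table.vectors.items():
        rows.append([table.chain_id, rid] + [f"{v:.9g}" for v in vec])
    cols = ["chain_id", "res_id"] + [f"v{i+1}" for i in range(table.width)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_embedding_table(
    path, structure_id: str = "", embedder_id: str = "file"
) -> EmbeddingTable:
    df = pd.read_csv(path, sep="\t", dtype={"chain_id": str, "res_id": str})
    chain_id = str(df["chain_id"].iloc[0])
    vcols = [c for c in df.columns if c.startswith("v")]
    vectors = {
        str(row["res_id"]): row[vcols].to_numpy(dtype=float)
        for _, row in df.iterrows()
    }
    return EmbeddingTable(
        structure_id=structure_id,
        chain_id=chain_id,
        embedder_id=embedder_id,
        vectors=vectors,
    )
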