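# Methods

This note documents the models and procedures implemented in pocketforge,
the defaults they ship with, the design choices made where the protocol
was genuinely open, and what the synthetic benchmark does and does not
demonstrate.

## Harmonization rules

Three raw pocket-finder dialects are converted to residue sets:

| dialect | rule | default |
|---|---|---|
| point cloud | residue joins if any atom is within the radius of any point | 5 Å |
| single center | residue joins if any atom is within the radius of the center | 8 Å |
| score track | hotspot = mean of own + n nearest residues' scores; each residue with hotspot ≥ threshold seeds a pocket of itself + those neighbors | n = 10, threshold 0.7 |

Distances use **any atom** of the residue, inclusive at the boundary. The
source protocols do not name the atom set for the 5/8 Å rules; any-atom is
the inclusive reading, and the radius is configurable. "Nearest" in the
score-track rule is spatial (residue-center distance, Cα when present),
ties broken toward the lower sequence index, so every emitted pocket has
exactly n + 1 = 11 residues. Redundant overlapping pockets from the track
are kept; deduplication is clustering's job downstream.

## Consensus and per-residue aggregation

A residue's vote count is the number of methods with at least one pocket
containing it — a method predicting a residue in many pockets still
contributes one vote, so counts are bounded by the number of methods M. A
k-of-M hotspot set is monotone non-increasing in k. For residue-level
scoring, a residue's score is the maximum over the scores of pockets
containing it; methods without native scores contribute binary membership
(1 in any pocket, else 0).

The pre-model "simple filter" is configurable (minimum pocket size,
default 5, plus optional per-method size and native-score floors) and
serializable; its published exact rules are not specified in the available
text, so no fixed variant is hard-coded.

## Example construction

Positive pocket spheres are sampled in seeded random order over the
annotated residues; the sphere is all residues with an atom within 5 Å of
the sampled residue's **Cα** (center atom unspecified in the protocol; Cα
is the deterministic choice). Acceptance: > 50 % of the sphere annotated,
or the sphere covers > 80 % of the annotation. Quotas per annotated
pocket: 2 (< 10 residues), 3 (10–24), 4 (≥ 25); negatives (annotation-free
spheres) target twice the positive count, with a default attempt budget of
50 × the requested count to guarantee termination. Within each class,
overlap — defined here as |A∩B| / min(|A|,|B|), the strictest symmetric
choice since the protocol names no denominator — must stay below 0.9.

Splitting uses global pairwise sequence identity (Biopython global
alignment, match +1, mismatch 0, gap open/extend −1; identity = matches /
alignment length — the scoring scheme is a documented, configurable
choice). Structures joined by > 40 % identity form atomic components
assigned greedily, largest first, to the split (80:10:10) with the
greatest remaining deficit; a single all-spanning component degrades to
all-in-train with a warning.

## Feature matrices and scorers

Examples become N×D matrices with N = 15 rows (configurable; the
protocol's own ablation found N insensitive). Oversized pockets are
truncated to a seeded uniform subset; undersized ones zero-padded. Method
channels are laid out alphabetically by tag — the layout is arbitrary but
must be frozen and serialized with any trained model, which the model
bundle does. Up to 10 seeded permutations of residue order augment the
training set.

Three scorer families: logistic regression (scikit-learn, to convergence
or 500 iterations, penalties none/L1/L2/elastic-net), a feedforward NN on
the flattened N·D vector, and a CNN on the 1-channel N×D image. The
NN/CNN backend is a compact in-repo numpy implementation — explicit
forward/backward passes with minibatch SGD/Adam/AdamW, inverted dropout,
Glorot initialization, and binary cross-entropy (implied by the
probability output; the exact loss is unstated in the protocol). Returned
parameters are those of the best-validation-AUROC epoch over 50 epochs.
Hidden width defaults to 256 (unstated upstream; configurable). Published
final configurations ship as presets: embedding-only NN = {1 hidden layer,
batch 32, dropout 0.5, lr 0.001, AdamW}; combined-features NN = {1 hidden
layer, batch 64, dropout 0.4, lr 0.01, Adam}. Grid search trains each
configuration with the same seed triple and ranks by mean best validation
AUROC, ties to the earlier grid entry. No class weighting is applied (the
2:1 negative:positive imbalance is mild).

The decision threshold t is the validation score maximizing TPR − FPR
(Youden's J), ties to the smallest candidate; a non-positive maximum
raises a warning rather than an error.

## Filtering and clustering

Score filter keeps pockets with score ≥ t (default 0.4) and, on predicted
structures, mean member pLDDT ≥ 70 — both boundaries inclusive, following
the literal "less than" phrasing of the thresholds. The two filters
commute. Clustering is connected components of the residue-overlap graph
(union-find); a cluster's representative score is the max member score
(mirroring the per-residue max rule), its center the unweighted mean of
member Cα positions (all-atom centroid available as an option). Ranking:
score descending, ties to the larger cluster, then minimum residue id.

## Evaluation

Per-residue labels: 1 iff any residue atom is within r of any
relevant-ligand atom (r = 5 and 10 Å). ROC/PRC pool residues over all
evaluated structures; AUPRC is average precision. DCA: per structure the
top-N ranked pocket centers (N = N_L or N_L + 2) each contribute the
distance to the nearest relevant-ligand atom; precision is the percentage
below the threshold (4, also 8/10 Å). Structures with fewer than N pockets
contribute what they have and only contributed distances enter the
denominator — renormalizing rather than counting misses, a documented
choice where the protocol is silent. The background distribution samples
surface residues' Cα positions; "surface" uses an exposure proxy (< 18 Cα
neighbors within 10 Å) since no surface definition is stated, and the
proxy parameters are configurable. Foreground and background are compared
with the asymptotic two-sided two-sample Kolmogorov–Smirnov test.

## Synthetic benchmark

The generator emulates the statistical structure the pipeline assumes:

- **Structures**: seeded self-avoiding 3-D Cα walks, 3.8 Å steps, ≥ 3 Å
  non-adjacent separation, with a centroid-attraction bias keeping chains
  globular so surface and pockets are meaningful. Optional predicted-mode
  pLDDT with low-confidence termini.
- **Ligands**: a small carbon cluster placed ~3 Å outside a surface
  residue, one atom nestled against each of the site's ~7 nearest
  residues so annotations span a realistic 5–15 residues; ground truth is
  the same 5 Å any-atom rule the evaluator uses, making planted
  annotations and evaluation labels consistent by construction.
- **Method predictions**: per method, the true site is emitted with
  probability p_hit (0.8–0.9 by default) in the method's dialect, and
  decoys appear at rate p_fp (0.1–0.15) at random non-annotated surface
  sites. Seven default profiles cover all four dialects.
- **Embeddings**: standard normal per coordinate; binding residues
  mean-shifted by σ along a fixed seeded direction (default width 64 for
  speed — the contract is width-agnostic; σ = 2 by default, σ = 0 yields
  provably indistinguishable classes).

What passing synthetic tests shows: the plumbing, protocol rules, and
learning machinery are correct, and the scorer recovers a planted signal
of known strength (validation AUROC ≥ 0.9 at σ = 2 on ~4,000 examples;
chance at σ = 0). What it does not show: performance on real proteins —
real embeddings encode far richer, non-Gaussian structure, real pockets
are concave side-chain environments rather than Cα neighborhoods, and
real pocket finders have correlated, structured errors rather than
independent Bernoulli hits.

## Problem sizes and numerics

Default synthetic runs use 30 structures of 150 residues; the parameter
recovery experiment uses 70 structures (~4,000 examples after
augmentation). All randomness flows from one run seed through named
substreams (split, positives, negatives, featurization, training), so
reruns with the same configuration reproduce outputs exactly within one
environment; network reproducibility is per (numpy version, seed). Scores
are computed in float64; batched and single scoring agree to 1e-6, and
serialized models reload to identical scores. Degenerate inputs (empty
point sets, all-padding matrices, single-class validation sets) raise
typed errors or are documented legal cases (an all-zero matrix scores in
[0, 1]).

## Known limitations

- Cα-only synthetic traces cannot exercise any-atom vs Cα distance
  differences; those paths are covered by hand-built multi-atom fixtures.
- The self-avoiding walk becomes unreliable above ~500 residues at the
  default compactness; the benchmark targets 100–150-residue chains.
- `run_pipeline` drives the synthetic workflow; real-data runs chain the
  file-based CLI subcommands (`harmonize`, `make-dataset`, `filter`,
  `cluster`, `evaluate`) instead.
- The identity splitter computes all pairwise alignments (O(n²)); it is
  intended for hundreds, not tens of thousands, of chains.
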