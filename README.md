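# pocketforge

A toolkit for **ensemble ligand binding pocket prediction**: it harmonizes
the heterogeneous outputs of multiple pocket-finding programs into a common
representation, builds labeled pocket examples from binding-site
annotations, trains an embedding-based neural scorer to separate real
pockets from spurious ones, filters and clusters the surviving candidates
into disjoint "mega-pockets", and evaluates predictions at both the residue
and the pocket level.

It is aimed at structural bioinformaticians who run several pocket finders
(geometry-, energy- and ML-based) over many structures and need a single,
consistent, scored pocket set — plus a fully synthetic benchmark so every
stage can be developed and validated offline.

## The method

**Harmonization.** Constituent pocket finders emit three raw dialects, each
converted to a residue set on the structure:

- *point clouds* (predicted pocket space): a pocket contains every residue
  with an atom within 5 Å of any point;
- *single centers*: every residue with an atom within 8 Å of the center;
- *per-residue cryptic-pocket score tracks*: a residue's hotspot score is
  the mean of its own score and its 10 spatially nearest neighbors'; each
  residue with hotspot score ≥ 0.7 seeds an 11-residue pocket (itself plus
  its 10 neighbors). Residue-list outputs pass through with validation.

**Consensus.** A residue is a k-of-M hotspot when at least k of the M
methods place it in any pocket (each method votes at most once per
residue).

**Training data.** For each annotated binding pocket, *positive* examples
are "pocket spheres" — all residues within 5 Å of a randomly sampled
annotated residue's Cα — accepted when > 50 % of the sphere is annotated or
the sphere captures > 80 % of the annotation; 2/3/4 positives are drawn for
pockets of < 10, 10–24 and ≥ 25 residues, and twice as many *negatives*
(spheres containing no annotated residue). No two same-class examples may
share ≥ 90 % of their residues. Structures are split 80:10:10 such that no
cross-split pair exceeds 40 % global sequence identity.

**Scoring model.** A pocket example becomes an N×D matrix (N = 15 rows;
zero-padded or randomly truncated). Feature Set A holds one binary channel
per method (D = M), Set B the per-residue embedding (D = E), Set C both
(D = M + E, e.g. 2567 for 7 methods and a 2560-wide embedder). Logistic
regression, a feedforward NN and a CNN are supported; networks train under
binary cross-entropy for 50 epochs and keep the best-validation-AUROC
epoch. The decision threshold t maximizes TPR − FPR on validation scores.

**Filtering and clustering.** Candidates scoring below t = 0.4 are
discarded, as are pockets on predicted structures averaging < 70 pLDDT;
survivors sharing at least one residue merge into disjoint clusters ranked
by their best member score.

**Evaluation.** Per-residue: residues within r (5/10 Å) of a relevant
ligand are positives; scores are pooled over structures into ROC/PRC
curves. Pocket-level: the DCA criterion — the percentage of top-N ranked
pocket centers (N = N_L relevant ligands, or N_L + 2) lying within 4 Å
(also 8/10 Å) of the nearest relevant-ligand atom — compared against
distances from random surface points by a two-sided Kolmogorov–Smirnov
test.

## Worked example

Run the full synthetic pipeline (30 generated structures with planted
ligands, 7 simulated pocket finders, signal embeddings):

```python
from pocketforge.config import RunConfig
from pocketforge.pipeline import run_pipeline

manifest = run_pipeline(RunConfig(seed=7), "out/")
print(manifest["stages"]["train"])
```

which prints (numbers from an actual run):

```
{'n_train': 162, 'n_val': 18, 'best_val_auroc': 0.806,
 'threshold_t': 0.417}
```

and writes `out/metrics.json` containing, among others:

```
"residue_r5":  {"auroc": 0.966, "auprc": 0.614, "prevalence": 0.056, "n_residues": 4500}
"dca_NL_4A":   {"precision": 56.7, "n_distances": 30}
"dca_NL_8A":   {"precision": 90.0, "n_distances": 30}
"ks_vs_background": {"statistic": 0.60, "p_value": 1.1e-05}
```

Reading: pooling all 4500 residues, the trained scorer separates binding
from non-binding residues with AUROC 0.97 at the 5 Å labeling radius
(chance = 0.5; chance AUPRC = the 0.056 prevalence). 90 % of top-N_L
cluster centers land within 8 Å of a planted ligand, and the
pocket-to-ligand distance distribution differs from the random-surface
background (KS p ≈ 10⁻⁵).

The same workflow is scriptable from the shell:

```bash
pocketforge run --seed 7 --out out/
pocketforge simulate --n-structures 4 --seed 1 --out sim/
pocketforge harmonize --structure sim/structures/synth000.pdb \
    --method centerA --dialect center \
    --input sim/raw/synth000.centerA.centers --out pockets.tsv
```

## Layout

- `pocketforge.structure_io` — legacy PDB read/write, annotation TSV,
  pocket tables
- `pocketforge.harmonize` — raw dialects → candidate pockets
- `pocketforge.ensemble` — k-of-M consensus, simple filter, per-residue
  max aggregation
- `pocketforge.dataset` — pocket-sphere examples, quotas, identity splits
- `pocketforge.features` — N×D matrices, permutation augmentation,
  embedder contract
- `pocketforge.models` — LR/NN/CNN scorers, grid search, threshold
  selection
- `pocketforge.postprocess` — score/pLDDT filters, overlap-merge
  clustering
- `pocketforge.evaluate` — ROC/PRC, DCA precision, background distances,
  KS test
- `pocketforge.synthetic` — structures, ligands, simulated predictions,
  signal embeddings
- `pocketforge.cli` / `pocketforge.pipeline` — the `pocketforge`
  command and the end-to-end runner

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
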