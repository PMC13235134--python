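# biodrp

Biologically-constrained neural network for cancer drug-response
classification from multi-omics cell-line profiles and drug fingerprints.

## The problem

Cancer cell lines with the same diagnosis respond very differently to the
same compound. Large screening panels measure the half-maximal inhibitory
concentration (IC50) of hundreds of drugs across hundreds of cell lines,
alongside the lines' molecular profiles; predicting sensitivity from those
profiles supports drug prioritisation and biomarker discovery. Dense neural
networks predict well but are black boxes. `biodrp` is for computational
biologists who want both: a classifier whose hidden layers *are* biological
entities — protein complexes, pathways, drugs — so a prediction can be
traced back to the genes, complexes and pathways that drove it.

## The model

A (cell line, drug) pair is labelled sensitive when

```
R(c, d) = 1  iff  exp(ln IC50(c, d)) ≤ max_conc(d)
```

with `max_conc(d)` the drug's maximum screening concentration. Cell-line
features are four min-max-scaled omics layers (gene expression, copy-number
variation, mutation VAF, protein expression) merged by availability-weighted
averaging: `F(c, g) = (1/|M_g|) Σ_{M ∋ g} M(c, g)`.

The network wires features through a gene → protein-complex → pathway →
drug hierarchy. Each layer carries a binary mask `M^(l)` built from
annotation edge lists (PPI scores, pathway memberships with enrichment
p-values, drug-target indicators), applied elementwise to the weights in
every forward pass:

```
y^(l) = ReLU((M^(l) ∗ W^(l))ᵀ x^(l−1) + b^(l))
```

so only biologically annotated connections carry signal — and, because the
loss reaches a weight only through `M ∗ W`, masked weights receive exactly
zero gradient and never move during training. The drug-layer output is
concatenated with the sample's 1024-bit Morgan (ECFP4) fingerprint and read
by a single sigmoid unit; training is mini-batch Adam (batch 64, 50 epochs,
lr 0.001) on binary cross-entropy. Hierarchies are pruned to a fixed point
so every retained node lies on a complete gene→drug path.

Interpretation operates at four levels: input genes are scored by gradient,
activation, variance and permutation importance (plus their min-max
combined average); complexes, pathways and drugs by mean absolute
activation of their layer nodes; and rankings are stabilised by aggregating
top-k membership over independently seeded training runs.

A built-in synthetic generator emulates every input table with a planted
response mechanism (designated driver genes wired onto guaranteed
gene→drug paths), so the full pipeline — including importance recovery —
is testable without any download.

## Worked example

```python
from biodrp import SyntheticSpec, TrainConfig, generate_dataset
from biodrp.evaluation import run_experiment, split_lodo, split_pair_kfold, summarize

spec = SyntheticSpec(n_cells=150, signal_strength=4.0, noise_sd=0.3,
                     edge_density_pk=0.6, edge_density_kd=1.0,
                     fingerprint_bits=128, seed=1)
ds = generate_dataset(spec)
cfg = TrainConfig(epochs=50, seed=1)

for plan in (split_pair_kfold(ds.bundle.responses, k=5, seed=1),
             split_lodo(ds.bundle.responses)):
    metrics = run_experiment(ds.bundle, plan, cfg)
    row = summarize(metrics).iloc[0]
    print(f"{plan.strategy:11s} {row['n_folds']:3d} folds  "
          f"AUC {row['auc_mean']:.4f} +/- {row['auc_sd']:.4f}  "
          f"AUPR {row['aupr_mean']:.4f}")
```

prints

```
pair_kfold    5 folds  AUC 0.8322 +/- 0.0341  AUPR 0.7249
lodo          8 folds  AUC 0.8444 +/- 0.0420  AUPR 0.7111
```

AUC is the probability that a sensitive pair outranks a resistant one
(0.5 = chance); AUPR weights the sensitive minority class. `pair_kfold`
holds out random (cell, drug) pairs; `lodo` (leave-one-drug-out) retrains
once per drug with that drug entirely unseen — the harder, drug-discovery
reading of generalisation. Leave-one-cell-line-out and
leave-one-cancer-type-out splits work the same way
(`split_loclo`, `split_loco`).

The `examples/` directory holds one short script per capability:
benchmark simulation, hierarchy building/pruning from annotation tables,
training + evaluation, omics ablation, and driver-gene recovery with the
importance suite. A thin CLI wraps the same functions:

```
biodrp simulate --out data/ --seed 1
biodrp evaluate --data data/ --strategy lodo --out results/
biodrp interpret --data data/ --runs 10 --top-k 20 --out interp/
```

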