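# Methods

## The model

`biodrp` predicts whether a cancer cell line is *sensitive* or *resistant*
to a drug. A screening experiment reports the half-maximal inhibitory
concentration on the natural-log scale; the pair is labelled sensitive when

    R(c, d) = 1  iff  exp(ln IC50(c, d)) <= max_conc(d),

where `max_conc(d)` is the drug's maximum screening concentration (boundary
inclusive). Both quantities must be on the same concentration scale; the
loaders convert log10 inputs when asked but perform no unit conversion.

The classifier is a feedforward network whose structure is a biological
hierarchy rather than a dense architecture. Four levels — genes,
protein complexes, pathways, drugs — are connected by annotation-derived
edges (protein-protein interaction scores for gene→complex, pathway
membership with enrichment p-values for complex→pathway, target indicators
for pathway→drug). Each adjacent pair of levels contributes a binary mask
`M` the same shape as the layer's weight matrix `W`, and every forward pass
computes

    y_l = ReLU((M_l ∗ W_l)^T x_{l-1} + b_l),     l = 1..3,

with `∗` the Hadamard product. Because the loss reaches a weight only
through `M ∗ W`, the gradient at a masked-out position is identically zero:
masked weights never move under any number of Adam steps, which the test
suite asserts exactly (not to a tolerance). The drug-layer output is
concatenated with the sample's 1024-bit Morgan fingerprint (radius 2, the
ECFP4 convention) and mapped through a single sigmoid unit; training
minimises mean binary cross-entropy with mini-batch Adam (defaults:
batch 64, 50 epochs, learning rate 0.001, seeded Glorot-uniform
initialisation on unmasked positions).

One source ambiguity is worth recording: descriptions of this architecture
class sometimes give the output stage as `n_drugs × 1` and elsewhere as a
concatenation of the drug layer with the fingerprint. We implement the
concatenated reading (output weight vector of length
`n_drugs + n_fingerprint_bits`); the non-concatenated variant would ignore
the drug's structure entirely at prediction time.

The implementation is plain NumPy in float64 with hand-derived
backpropagation. This keeps per-sample input gradients (needed by the
importance suite) first-class, makes finite-difference checks at 1e-4
comfortable, and removes any framework nondeterminism.

### An important structural property

The network is **additive in (cell, drug)**: cell features pass through the
masked layers without ever seeing which drug is being queried, and the
sigmoid reads a *linear* combination of drug-layer activations and
fingerprint bits. The model class is therefore
`σ(f(cell) + g(drug))` — it cannot represent cell × drug interactions.
This matters when interpreting both real-data and synthetic results: any
component of the response that depends jointly on the cell's state and the
drug's identity (beyond an additive shift) is invisible to the model. The
learnability and ablation benchmarks below are constructed so their planted
signal lies inside this class.

## Preprocessing and integration

Per omics layer (gene expression GE, copy-number variation CNV, mutation
variant-allele fraction MUT, protein expression PROT), in order:

1. **Variance filter** (optional, two stages): drop the fraction of
   lowest-variance features, then keep only the top fraction by variance of
   the remainder. Ties break lexicographically by feature ID so the result
   is deterministic.
2. **Zero-fraction filter** (optional): drop features whose fraction of
   exact zeros *strictly* exceeds the threshold (default 0.05; a feature at
   exactly the threshold is retained).
3. **Min-max scaling** into [0, 1] per feature. Constant features map to 0
   (they carry no information; zero keeps them inert).

Integration merges the layers into one cells × features matrix. For a
feature present in `|M_g|` of the layers,

    F(c, g) = (1/|M_g|) Σ_{layers M containing g} M(c, g).

The divisor is the *availability count* by default — a feature measured by
one omics keeps its value — because dividing by the constant number of
layers would systematically shrink single-omics features; the constant
divisor is available as `integrate_omics(..., divisor="constant")`.
Duplicate (cell, feature) entries within one table are mean-aggregated at
load time. Gene and protein IDs are matched verbatim; no symbol mapping is
attempted.

A consequence worth knowing: availability-averaging reduces the variance of
multi-omics features relative to single-omics ones (the mean of four
scaled columns has a narrower range than any one of them). Undertrained or
data-poor models may therefore underuse exactly the features measured
everywhere; see the ablation sizing note below.

## Hierarchy processing

* `filter_significant_pathways` keeps pathways with enrichment p ≤ α
  (default 0.05, boundary inclusive). Combined enrichment scores are kept
  as protein→pathway edge attributes; they never gate connectivity, but an
  optional initialisation mode (`init_scheme="glorot_enrichment"`) scales
  the corresponding initial weights by the edge score normalised to unit
  mean. Where that weight should enter the model is genuinely open; keeping
  it out of the default path avoids guessing.
* `prune_hierarchy` removes genes without complex edges, complexes without
  pathway edges, pathways without drug targets, drugs without pathways, and
  then iterates backward sweeps to a fixed point, so every surviving node
  lies on a complete gene→complex→pathway→drug path. Termination is
  guaranteed (the node set strictly shrinks); the operation is idempotent,
  and the test suite checks the survivor set against an independent
  breadth-first-search oracle. A hierarchy pruned to emptiness raises
  rather than returning a degenerate model.
* `overrepresentation_pvalue` is a hypergeometric upper tail
  (P[X ≥ overlap]) — a desk stand-in for running an external enrichment
  service when annotation tables lack p-values.

## The synthetic benchmark

The generator emulates the full input surface — hierarchy edge tables with
scores and p-values, four omics matrices, a drug table (SMILES, max_conc),
responses, a cell→cancer-type map — with a planted mechanism:

* **Drivers.** The first `n_driver_genes` genes are drivers; random wiring
  at the configured densities is repaired so every driver lies on at least
  one full gene→drug path (verified against the BFS oracle). Pathways on
  driver paths receive strongly significant p-values (U(0, 0.01)) so the
  default α = 0.05 filter never severs the mechanism; others draw
  U(0, 0.2).
* **Omics.** GE ~ N(0,1) over all genes; CNV ∈ {0,…,4}/4 over drivers plus
  even-indexed genes; MUT ~ Beta(2,5) (VAF-like) over drivers plus every
  third gene; PROT ~ N(0,1) over drivers plus another third, keyed by gene
  ID (interpreted as product abundance). Drivers thus appear in all four
  layers — the planted signal is spread across omics — while some genes
  appear in exactly one, so integration averaging is always exercised.
* **Responses.** Per (cell, drug): the planted score is
  `signal_strength × mean_z(driver values over drivers reaching the drug)`
  plus a drug-level fingerprint term, standardised over all pairs, plus
  N(0, noise_sd) noise, minus Φ⁻¹(2/3) ≈ 0.431 so the sensitive fraction
  sits near 1/3 (a roughly 2:1 resistant:sensitive class balance, the ratio
  typical of large screening panels). `ln IC50 = ln(max_conc) − score`, so
  binarisation against the stored max_conc reproduces `score ≥ 0` exactly,
  and rescaling max_conc moves the sensitive fraction monotonically.
* **Determinism.** Everything is a pure function of (spec, seed); one seed
  feeds named independent substreams (hierarchy / omics / drugs /
  responses / cancer types), so adding a generator never perturbs others.
* **SMILES.** Drugs get random linear heteroatom chains over {C, N, O, S}
  — always parseable, chemically trivial, but with distinct Morgan
  neighbourhoods. Nothing about real chemical space is claimed.

What the generator does **not** emulate: realistic covariance between
genes, platform effects, dose–response curve fitting, chemical similarity
structure, or the label noise of real screens. Passing tests on this
benchmark demonstrate that the machinery is correct and that planted
signal of the stated form is recovered — not that any particular real-data
accuracy would be achieved.

## Benchmark configurations and problem sizes

Defaults (`SyntheticSpec()`): 120 cells, 60 genes, 24 complexes, 10
pathways, 8 drugs, 6 drivers, densities 0.12/0.30/0.35, signal 3.0, noise
0.5, 1024 fingerprint bits. Tests and the acceptance script use desk-scale
variants (≤ 250 cells, ≤ 2000 pairs) so the whole suite runs in minutes on
one CPU; these sizes are the package's own choice of benchmark scale.

Two derived configurations deserve explanation:

* **Learnability ("easy") benchmark** — signal 6.0, noise 0, and
  `edge_density_kd = 1.0`, `edge_density_pk = 0.6`. With every pathway
  wired to every drug, all drivers reach all drugs, so the planted score
  decomposes as cell effect + drug effect — inside the model's additive
  class (held-out AUC ≈ 0.95). At sparse pathway→drug wiring the planted
  score contains a cell × drug interaction the architecture cannot
  represent, and no amount of training recovers it (AUC plateaus near
  0.74); that is a property of the model class, not a defect of the
  optimiser.
* **Ablation benchmark** — same dense wiring, 200 cells, 50 epochs,
  signal 4.0, noise 0.3. The claim under test is that the all-omics model
  is at least as good as the best single-omics model when signal is spread
  across layers. Information-wise this is guaranteed by construction, but
  exploiting it requires enough data and training: availability-averaging
  shrinks the dynamic range of multi-omics features, and at 150 cells / 30
  epochs the ordering held or flipped depending on the seed. At 200 cells /
  50 epochs it holds with a clear margin on every seed probed.

Driver-recovery tests deliberately keep the **default sparse wiring** — the
importance machinery should find drivers even when the model can only
partially fit the response.

## Importance scores

On a held-out test set of N samples, per input gene i:

* gradient: `S_grad(i) = (1/N) Σ_j |∂L(f(x_j), y_j)/∂x_ji|` (per-sample
  loss, exact backprop; checked against central differences at 1e-4);
* activation: `S_act(i) = (1/N) Σ_j |x_ji|` (model-independent);
* variance: unbiased sample variance of the column (model-independent);
* permutation: mean over repeats of the increase in test BCE when column i
  is shuffled (seeded), clipped at 0 after averaging (clipping each repeat
  would bias pure noise upward).

The combined score averages the four after min-max normalisation across
genes — their raw scales are incommensurable and variance would otherwise
dominate; raw-scale averaging is behind `normalize=False`. Fingerprint
bits are excluded throughout: importance is reported for biological
entities only. Protein/pathway/drug nodes are scored by mean absolute
activation of their layer. Cross-run aggregation takes each run's top-k
(ties by entity ID), counts membership frequency across runs, and ranks by
frequency, then mean score, then ID.

Caveat: because activation and variance ignore the model, the combined
ranking is conservative — on the synthetic benchmark it favours
single-omics genes (whose integrated columns keep full dynamic range)
relative to drivers, while the permutation and gradient components rank
drivers sharply. Both views are useful; the examples print both.

## Evaluation protocols

* random pair k-fold (default k = 5, seeded, unstratified by default);
* leave-one-drug-out (LODO): one fold per drug;
* leave-one-cell-line-out (LOCLO): one fold per cell line;
* leave-one-cancer-type-out (LOCO): one fold per type.

Every fold retrains from scratch with identical hyperparameters. Folds
whose test set is single-class are reported with NaN metrics rather than
silently dropped. AUC is the Mann–Whitney concordance probability (average
ranks, ties = 1/2); AUPR is the step-wise non-interpolated
precision–recall area; both are cross-checked in the tests against
brute-force loops and against scikit-learn. Summaries report mean ±
sample (ddof = 1) standard deviation across folds.

## Numerical choices

* probabilities clipped to [1e-7, 1 − 1e-7] inside the loss only;
* constant features scale to 0 under min-max (0/0 guarded);
* variance-filter and top-k ties break by ID, making every ranking
  deterministic;
* sigmoid evaluated in the numerically stable two-branch form;
* predictions are bit-reproducible for a fixed batch; across different
  batch partitions BLAS reassociation can perturb the last bits (≤ 1e-12
  relative), which the contracts state explicitly.

## Known limitations

* The additive (cell, drug) structure bounds achievable accuracy whenever
  the response contains genuine interactions (see above).
* Protein complexes are opaque IDs from the annotation tables; no complex
  inference from interaction data is attempted.
* No regularisation, early stopping, or hyperparameter search: the sparse
  masks are the intended capacity control.
* The hypergeometric over-representation test assumes exchangeable
  membership; it is a stand-in, not a replacement for a proper enrichment
  analysis with curated gene sets.
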