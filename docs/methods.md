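# Methods

## Problem setting

A labeled reference $D_{ref} = \{(x_i, y_i)\}$ of single-cell expression
profiles ($x_i \in \mathbb{R}^p$, $y_i \in \mathcal{Y} = \{c_1,\dots,c_K\}$)
and an unlabeled query sharing the same gene space. Two failure modes make
naive label transfer unreliable: query cells of types absent from
$\mathcal{Y}$ (out-of-distribution, OOD), and miscalibrated classifier
scores that overstate confidence. Both are addressed with split (inductive)
conformal inference: the reference is partitioned — 10% internal test, 15%
of the remainder validation, then 40% of what is left calibration, the rest
proper training — stratified by cell type so every class reaches the
training and calibration pools. All guarantees are finite-sample and
distribution-free, conditional only on exchangeability of calibration and
query cells.

## OOD detection

A symmetric autoencoder (defaults: p → 128 → 32 → 128 → p, ReLU, Adam,
lr 1e-3, at most 300 epochs, patience 15 on validation MSE) is trained on
the proper training cells only — which must be clean of outliers, hence the
removal of held-out types upstream in evaluation. Gene-wise standardization
(fitted on training cells) is applied internally for optimization; anomaly
scores are reported as the per-cell mean squared reconstruction error in
the original log-expression units. The conformal p-value of a new score
uses the (n+1)-denominator form

p = (1 + #{calibration scores ≥ s}) / (n_cal + 1),

with ties counted in the conservative direction; this form is bounded in
(0, 1] and makes P(p ≤ t) ≤ t exact for any t. Flagging p ≤ α_o therefore
bounds the expected false positive rate by α_o regardless of the
autoencoder's quality — the network affects only power. The decision
threshold α_o can be fixed (default 0.15, the small-sample fallback) or
chosen automatically by an excess-mass heuristic: over a grid of candidate
thresholds t, estimate e(t) = max(0, F̂(t) − t), the p-value mass exceeding
the uniform baseline, and return the largest t at which e(t)/F̂(t) ≥ 0.5 —
i.e. flag only where at least half of the flagged mass is genuinely
anomalous. This selector is a documented substitute for an unpublished
procedure; it is deliberately simple, and the fixed mode is always
available.

The same p-values serve as an exchangeability diagnostic (KS statistic
against U[0,1], histogram, maximal excess mass): batch effects or disease
states that shift the query distribution show up as low-p enrichment even
when no new cell type is present.

## Conformal annotation

Any model that outputs a point on the K-simplex per cell can be plugged in.
Included: a feed-forward MLP (two hidden layers 256/64, ReLU, Adam lr 1e-3,
batch 256, ≤ 200 epochs, patience 10 on validation cross-entropy, L2 weight
decay 1e-4 — weight decay substitutes for dropout because the
implementation rides on scikit-learn's MLP, which has none) and two fast
baselines (multinomial logistic regression; nearest-centroid softmax). The
class order is fixed as sorted label strings everywhere.

Non-conformity scores from the softmax row f̂(x):

* THR: 1 − f̂_y(x).
* APS: Σ of f̂ over classes ranked strictly above y (descending score,
  ties broken stably by class index) + u · f̂_y(x), u ~ U[0,1].
* RAPS: APS + η · (rank(y) − κ)₊ with 1-based rank; defaults η = 0.01,
  κ = 1. η = 0 reduces exactly to APS.

One u is drawn per calibration cell at calibration time and one per query
cell at prediction time, shared across that cell's candidate classes
(seeded; `randomized=False` replaces u by 1, the conservative deterministic
variant). Calibration computes each cell's score at its true label only;
query scores are recomputed per hypothesized label. The p-value of
candidate class c_k ranks the hypothesized score among the calibration
scores of c_k's group, with the same (1+count)/(n+1) form, and the set is
C(x) = {c_k : p_k ≥ α} (the weak inequality follows the displayed set
definition; sets are nested in α by construction). Empty sets are
rejections and are reported as such; `force_label` collapses a set to the
top-p class (ties: higher softmax, then class order).

Taxonomies:

* standard — one pooled calibration group; marginal coverage ≥ 1 − α.
* classwise (Mondrian) — one group per class; coverage ≥ 1 − α for every
  class. Requires ≥ 2 calibration cells per class (error) and warns below
  20 (default `min_class_cal`), where the guarantee still holds in
  expectation but single-run coverage is coarse (p-values take only
  n_k + 1 values).
* cluster — classes with ≥ `min_class_cal` calibration scores are embedded
  as their score quantiles at (0.5, 0.6, 0.7, 0.8, 0.9) and grouped by
  seeded k-means (default cluster count: one per four embeddable classes);
  classes below the threshold fall into a null cluster calibrated
  marginally over all calibration scores. One cluster reproduces the
  standard taxonomy exactly.

## Preprocessing

Order: QC → rare-type filter → CPM/log2 → HVG selection → optional batch
integration. QC removes cells whose mitochondrial (> 0.10), ribosomal
(> 0.60) or hemoglobin (> 0.60) count fractions strictly exceed their
thresholds; gene families are matched by configurable name prefixes
("MT-"/"mt-", "RPS"/"RPL", "HB" minus "HBP") since no canonical gene lists
are assumed. Cell types with fewer than 60 reference observations are
dropped before splitting. Normalization scales each cell to one million
counts then applies log2(x+1); a layer-state flag prevents double
normalization. Highly-variable genes are chosen on the reference only
(never the query) by the binned-dispersion method: dispersion =
variance/mean per gene, 20 equal-width bins of mean expression, z-scored
dispersion within bins, top 2000 genes, ties broken by gene index. Batch
integration is an external hook (`harmonypy` when installed); the algorithm
is deliberately not reimplemented, and `method="none"` is the default.

## Synthetic worlds

All testable guarantees are exercised on negative-binomial count data with
known truth. Counts for a cell of class c are NB with mean
`baseline_mean` (1.0) boosted by `signature_fold` on the class's signature
genes and a single global dispersion θ = 2 (var = μ + μ²/θ); an optional
per-gene log-normal factor shifts query means to emulate batch effects.
Three canned worlds:

* exchangeable (`default_config`): 5 classes, disjoint 20-gene signatures,
  fold 5, 300 genes, 600 reference / 400 query cells per class — uniform
  proportions make reference and query exchangeable by construction; used
  for the marginal-coverage and detector-FPR checks.
* LOCO (`loco_config`): same but with broad 40-gene signatures and one or
  more classes held out of the reference — a held-out type distinct enough
  for reconstruction error to reach high power, the premise of the
  power and coverage-vs-power checks.
* imbalanced (`make_imbalanced_fixture`): reference sizes
  (2000, 1500, 1000, 300, 80) plus a query-only OOD class. The 80-cell
  minority carries a weaker (fold 2.5) signature half-shared with a major
  class, reflecting that rare types are typically also the subtler ones;
  this is what makes a single marginal calibration pool undercover the
  minority while classwise calibration holds it — the fixture for the
  class-conditional checks.

What the generator does **not** emulate: zero-inflation beyond NB sampling,
ambient RNA, doublets, gene-gene correlation within a class, realistic
library-size variation. A green test therefore establishes the
distribution-free logic of the pipeline (which holds for any
exchangeable data), not robustness to every real scRNA-seq artifact.
One observed consequence: an OOD class whose signature inflates its library
size can evade MSE-based detection after CPM normalization equalizes
totals — worth knowing when interpreting detector power on real data.

## Numerical choices and conventions

* All p-values exact rationals of the form k/(n+1) computed by binary
  search on sorted score arrays; a brute-force loop implementation is kept
  in the test suite as the oracle.
* QC inequalities strict; conformal set inclusion weak (p ≥ α).
* Degenerate cases: empty query → empty score/probability arrays, not
  errors; zero-total cells are a normalization error naming the cell;
  flag thresholds α_o = 0 flag nothing (p > 0 always).
* Determinism: every stochastic component (splits, minibatch order, weight
  init, APS u draws, k-means) is seeded; identical configuration and seed
  reproduce outputs bit-for-bit.
* Evaluation convention: detector-flagged cells receive no prediction set
  and leave the coverage/size denominators; OOD cells that evade the
  detector count as uncovered (their label is outside the label space).

## Known limitations

* The neural components use scikit-learn MLPs (CPU, full-batch epochs via
  `partial_fit`); at atlas scale (10⁵+ cells) a GPU deep-learning backend
  behind the same `SoftmaxModel` contract would be preferable.
* Classwise calibration with very rare classes yields coarse p-values and
  unstable single-run class coverage (warned at < 20 calibration cells).
* The cluster taxonomy degenerates for extreme nominal levels (α close to
  1), where sets become uninformative.
* Calibration-conditional (1−δ) p-value variants and per-cell adaptive α
  are out of scope; the marginal guarantees are exactly what is promised.
* Gene matching is by exact identifier string; no Ensembl/symbol mapping.
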