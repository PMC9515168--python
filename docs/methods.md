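# Methods

`pathdrp` predicts drug sensitivity in tumors and patient-derived
xenografts (PDX) by transferring a network pre-trained on large cell-line
drug screens, with all genomic information mapped to molecular-pathway
features. This note describes the models and procedures the package
implements, the parameters that matter, and what the synthetic validation
does and does not establish.

## Feature construction

**Harmonization.** Expression matrices from different sources (cell lines,
tumor compendia) are made comparable in three steps, each dataset treated
as a batch: (1) restriction to the common gene set; (2) gene-wise
standardization of the pooled matrix to mean 0, sd 1 (sample sd, ddof=1;
zero-variance genes dropped with a warning); (3) parametric empirical-Bayes
location/scale batch adjustment in the style of Johnson, Li & Rabinovic
(2007). For batch *b* and gene *g*, the per-batch additive effect
γ̂<sub>bg</sub> (batch mean) and multiplicative effect δ̂²<sub>bg</sub>
(batch variance) are shrunk toward method-of-moments hyperpriors — normal
for γ, inverse-gamma for δ² — by the standard iterated conditional
estimates, to a convergence tolerance of 1e-4. The adjusted value is
(z − γ*)/√δ*, mapped back to the original scale through the stored pooled
mean/sd. Standardization is computed on the pooled (all-batch) matrix
before EB estimation; covariates such as cancer type are deliberately not
modelled (batch-only correction). When the hyperprior is degenerate (a
single gene, or zero spread of the per-gene estimates) the batch falls back
to the unshrunken estimates; this makes tiny inputs well-defined at the
cost of shrinkage.

**Pathway activities (EXP).** Per-sample pathway scores use single-sample
GSEA: genes are ranked descending within the sample (ties broken by a
seeded shuffle so scoring is deterministic but order-unbiased); walking the
ranked list, the in-set cumulative fraction — weighted by the
rank-normalized value raised to the exponent α — is compared with the
uniform out-of-set fraction, and the score is the *integral* (sum) of the
running difference. α defaults to 0.25; at α=0 the score is a pure rank
statistic (asserted by a monotone-transform invariance test). Pathways
overlapping the universe by fewer than `min_overlap` (default 5) genes are
dropped. An optional membership-permutation test (`n_perm ≥ 100`) gives
p = (1 + #{null ≥ observed})/(1 + n_perm); because membership permutations
at fixed set size are sample-independent, the null is computed once per set
size. An optional `normalize` flag divides the score matrix by its value
range; the pipeline enables it so the EXP block is on a comparable scale
with the other feature blocks when fed to the network. Raw scores (not
permutation-filtered) are used as features.

**Drug features.** CHEM is a 256-bit folded Morgan (circular) fingerprint
of the drug's SMILES, radius 2 (ECFP4-equivalent; only the bit length is
fixed by the protocol, the radius is the community default). DGNet
quantifies propagated target influence: a random walk with restart from the
drug's target genes over the protein–protein interaction graph,
p = r·e + (1−r)·M·p with column-stochastic M, uniform restart vector e over
the targets, restart probability r = 0.5 (exposed in config), solved by
power iteration to L1 tolerance 1e-8 (a direct linear solve is available
and is used internally where a factorization can be reused). Each
pathway's raw score is the mean stationary probability over its member
genes; a z-score is formed against `n_perm` random target sets of equal
size drawn uniformly from the graph (a degree-matched null is available as
an option). Drugs with no target in the graph get an all-zero, flagged
DGNet vector rather than being dropped; pathways absent from the graph are
imputed to 0 with a warning.

## The sensitivity network

A feed-forward regressor/classifier with reference hidden widths
1000/800/500/100, ELU activations, neuron-level dropout (10%), and a task
head: linear output for continuous sensitivity (1−AUC of the dose-response
curve, in [0,1]) or sigmoid for responder classification. Training uses
Adamax (default learning rate 4e-4), RMSE loss for pre-training, BCE or MSE
for fine-tuning; weight values are clipped to [−5, 5] after every update
(a hard invariant, tested); early stopping monitors a held-out validation
split (10% of the training fold, stratified by drug, and by label for
dichotomous tasks) with patience 30 and restores the best-validation
weights. Initialization is a seeded uniform fan-in scheme; training is
CPU-only, bit-reproducible from the seed.

The implementation is plain numpy with hand-written backpropagation.
Widths are configurable down to toy scale: the packaged pipeline and tests
use 64/32/16/8 so that a full 5×5 cross-validated two-arm comparison runs
in minutes on one CPU. At that scale the reference learning rate of 4e-4
under-trains badly (diagnosed against a ridge-regression oracle on the
noiseless problem), so pipeline runs default to 3e-3; the 4e-4 default is
kept on `TrainConfig` for full-width use.

**Transfer.** `transfer_build` copies the first `n_transfer_layers` hidden
layers from the pre-trained network into the target model, marks them
pretrained and (optionally) frozen, and freshly seeds any new hidden layers
plus the task head. Frozen layers are excluded from optimizer updates and
are bitwise identical after any number of epochs (tested). Heavily
imbalanced dichotomous panels are rebalanced per drug by keeping every
responder and subsampling non-responders without replacement to a
responder:non-responder ratio of 1:3 (drugs with zero responders are
dropped with a warning). Hyperparameters (optimizer, activation, batch
size, dropout, learning rate, new-layer widths and count, transfer depth,
retrain flag) can be searched with a sequential model-based optimizer:
Gaussian-process surrogate (Matérn 5/2) with expected improvement over a
finite grid, deterministic under seed; the recommended objective is a mean
inner 3-fold validation metric to avoid test leakage.

## Evaluation

AUROC is computed in its rank-sum form (probability a positive outranks a
negative, ties ½) and is tested against exhaustive pairwise enumeration.
Cross-validation is 5-fold repeated 5 times (25 fold scores), stratified by
(drug, label) for classification; every fold trains from scratch. Results
are reported as mean ± SD over folds. Per-drug/per-cancer breakdowns use
pooled out-of-fold predictions (per-fold AUROC is undefined for small
groups) and exclude groups with fewer than 5 samples; groups are averaged
separately by membership in the source panel. Arms are compared with the
two-sided Mann–Whitney U test over fold scores (exact for ≤ 8 per side
without ties, asymptotic with tie correction otherwise).

## Explanation

Shapley values are estimated by permutation sampling against a baseline
set: per draw, features flip from a baseline row to the explained row in
random order and each feature is credited its marginal output change.
Summing over features telescopes to f(x) − f(b), and baselines are cycled
so the estimate satisfies efficiency against the full baseline-set mean
exactly (up to float); with ≤ 12 features exact subset enumeration is used
instead. Linearity, symmetry, dummy and efficiency are asserted directly
in tests. Importance is the mean |Shapley value| across samples, computed
per drug when requested. For dichotomous tasks, responders/non-responders
are defined as the classifier's true positives/true negatives at threshold
0.5, and per-pathway ssGSEA enrichment is compared between the two groups
by two-sided Mann–Whitney U with Benjamini–Hochberg FDR control at 0.05.
(The compared quantity is the enrichment score; comparing Shapley values
instead is a defensible alternative the package does not default to.)

## Synthetic cohorts

The generator produces the statistical structure the pipeline assumes, so
every stage is testable without external downloads. Pathways tile the gene
universe with overlap; each sample has a latent activity a_p ~ N(0,1) per
pathway and member genes read baseline + a_p + N(0, noise_sd). Batches
apply gene-wise distortions — shift ~ N(0, batch_shift_sd), scale ~
U(batch_scale_range) — exactly the location/scale family the EB adjustment
removes. The PPI graph is dense within pathways (p=0.3) and sparse across
(p=0.01). Each drug acts through a few signal pathways with signed weights
scaled by `effect_size`; its targets are drawn from those pathways;
continuous sensitivity is logistic(Σ w_p·a_p + intercept) + N(0, noise_sd)
clipped to [0,1], and dichotomous labels split at the per-drug median.
Cell-line and tumor samples share the generative law — the regime in which
transfer should help — with a small tumor cohort (default 80 samples vs
2000 cell samples, 5 drugs, effect size 1.5, noise sd 0.5, two cell-line
batches plus a tumor batch).

What this does *not* emulate: real expression marginals and gene-gene
correlation beyond pathway co-membership, dose-response curve shapes (AUC
is generated directly), drug-set chemistry diversity (SMILES come from a
small scaffold pool), inter-batch differences beyond location/scale, and
covariate confounding between batch and biology. Passing tests therefore
demonstrate that the machinery recovers planted structure under its own
assumptions, not performance on real tumor data.

## Numerical choices and degenerate inputs

- ComBat iteration tolerance 1e-4; δ* floored at 1e-12; degenerate
  hyperpriors fall back to unshrunken estimates.
- ssGSEA ties broken by a seeded shuffle; gene sets equal to the whole
  universe are rejected (degenerate complement).
- RWR dangling nodes (zero-degree columns) restart uniformly; non-
  convergence after `max_iter` raises with the residual.
- DGNet z-scores with null sd < 1e-300 are set to 0.
- Mann–Whitney p-values switch from exact to asymptotic in the presence of
  ties; identical inputs give p = 1.
- RMSE loss gradients guard against division by zero at perfect fit.
- Folds that lose a class are re-drawn (up to 10 attempts, logged).

## Problem sizes used in packaged runs

The pipeline's packaged configurations use 120–200 genes, 12–20 pathways,
1000–2000 cell samples, 60–80 tumor samples, 3–5 drugs, and hidden widths
64/32/16/8 — large enough for the planted signal to dominate sampling noise
in every asserted comparison, small enough for interactive iteration. The
`demo` subcommand is the smallest such configuration.
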