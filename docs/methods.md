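# Methods

This note documents the models behind each stage, the parameters that matter,
the synthetic-data assumptions, and the numerical choices made where the
design was genuinely open. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Differential expression and consensus signatures

Counts are transformed to `log2(x + 1)`; log-scale input is used as-is. Each
gene gets a Welch two-sample *t* statistic (unequal variances), a two-sided p,
and a Benjamini–Hochberg adjusted p (via statsmodels). A gene is flagged
up/down only when it clears **both** thresholds — |log2FC| above the cutoff
and adjusted p below alpha. Defaults follow the analysis conventions: 1.5 /
0.05 for cell-population contrasts, 0.5 / 0.05 for bulk glioma contrasts.
Zero-variance genes with equal means get p = 1 (no evidence), not NaN.

This package deliberately uses one DE engine for both data scales rather than
a count-model GLM: the downstream method consumes only the flag lists, and
the thresholds — not the engine — define them. No empirical-Bayes variance
moderation is applied (a documented non-goal).

Consensus: a gene enters the consensus for a contrast group when flagged with
the same direction in at least `min_support` datasets (2 for MicT/MacT, 3 for
MicT/MicN). A gene flagged up in one dataset and down in another is *excluded*
and reported separately — exclusion, not majority vote, because a
direction-conflicted seed would poison both propagation runs.

## Cox models

All Cox fits maximize the Breslow partial likelihood (tied event times see
the full risk set) by Newton iteration with step halving, so the likelihood
never decreases. Wald tests give per-covariate p-values. A covariate is
classified risk when HR > 1 and p < 0.01, protective when HR < 1 and
p < 0.01; since HR is always positive, "absolute HR > 1" is read as the sign
of log HR plus significance. Breslow was chosen because the tie method is
otherwise unspecified; the suite cross-checks the joint fit against lifelines
on tie-free fixtures, where Breslow and Efron coincide.

Degenerate inputs: zero events raise a dedicated error; constant covariates
are rejected (or skipped with a warning in the per-gene screen); rank-deficient
covariate matrices raise a collinearity error naming the offending columns.

## Network propagation (RWR)

The walk `P_{t+1} = (1−r) W P_t + r P_0` uses the column-normalized **binary**
adjacency of the evidence-filtered network (edge weights are ignored beyond
the ≥ 2 evidence filter), restart `r = 0.7`, and `P_0` uniform over the seeds
present in the network (absent seeds are dropped with a warning). Iteration
stops when `||P_{t+1} − P_t||_1 < 1e-6`; the L1 norm was chosen because it is
scale-free in network size and makes the geometric convergence factor exactly
`(1 − r)`. Restricting to the largest connected component removes dangling
columns, so `W` is column-stochastic and `sum(P_t) = 1` holds at every
iteration — an invariant the tests assert directly. `max_iterations` defaults
to 10000; exceeding it raises an error carrying the last iterate. The
iterative fixed point is validated against the direct solve
`P = r (I − (1−r) W)^{-1} P_0` to 1e-8 (L∞) on random connected graphs.

## Subpathway scores and permutation significance

`Score = mean(score_up) − mean(score_down)` over the covered members; members
absent from the network are ignored and counted in a coverage report, and a
subpathway with no covered member is skipped with a warning.

The permutation null redraws `member_count` genes without replacement from
all scored genes, carrying each gene's actual (up, down) score pair — gene
resampling rather than score shuffling, to preserve the dependence between a
gene's two scores. Significance is two-sided on the magnitude:
`p = #(|Score_random| > |Score_observed|) / n_perm`. This form is exactly
uniform under the null regardless of the score distribution's shape (the
calibration tests verify the 5% level within [0.03, 0.07]) and treats up- and
down-regulated subpathways symmetrically; a one-sided upper-tail count would
never flag down-regulated subpathways, and a sign-conditional one-sided count
doubles the null rejection rate. The direction label is the sign of the
observed score. Defaults: 5000 permutations, selection at p < 0.001 with no
multiplicity correction (the raw cutoff is the method's convention); p = 0 is
printed as `< 1/n_perm` and stored as 0.0.

Crosstalk: an edge joins two selected subpathways when they share strictly
more than 7 member genes (≥ 8). Nodes carry (group, direction); a subpathway
significant in both contrasts appears once per contrast.

## ssGSEA activity

Per sample, genes are ranked by expression (average ranks on ties; only the
ordering matters, so any monotone transform of expression gives the same
score). Walking down the ranked list, the score is the sum of the difference
between the weighted in-set cumulative distribution — weights
`|rank|^exponent`, exponent 0.25 — and the unweighted out-of-set cumulative
distribution. The exponent and the matrix-wide `(max − min)` NES
normalization follow the method's common defaults; the normalization choice
is recorded in the activity metadata because NES values are comparable only
within one normalization scheme. Sets with no expressed member are dropped
with a warning; a set leaving fewer than two genes outside the universe, or a
constant sample, is rejected.

## Batch merging

Studies are intersected to a common gene space on the log2 scale and adjusted
with parametric empirical-Bayes ComBat (scanpy's implementation of the same
scheme as the R `sva` package), one batch per study. A single study is
returned unadjusted. On a planted pure +2 location shift (50 genes, 2×20
samples) the residual per-gene batch mean difference after adjustment is
≈ 0.09 — identical to what `sva::ComBat` itself leaves on the same fixture,
reflecting sampling noise partially re-injected by shrinkage — so the tests
assert a > 90% reduction of the shift rather than an arbitrary small constant.

## Lasso Cox signature

Objective: `−(1/n)·Breslow partial log-likelihood + λ‖β‖₁` on activities
standardized to unit variance (coefficients are reported on the original
scale). Solved by iteratively reweighted least squares with cyclic coordinate
descent on the quadratic surrogate — active-set cycling with a full sweep to
admit new coordinates — warm-started along a decreasing λ grid of 100 points.
The grid spans four decades below `λ_max` (the largest absolute score
gradient of the null model, on the 1/n scale) when n > p, two decades when
p ≥ n where the unpenalized end of the path is unbounded; the path also stops
early if the model approaches saturation (> 99.9% of null deviance). These
are the glmnet conventions. The outer loop stops on the subgradient KKT
conditions (1e-8); a step-halving safeguard keeps the true penalized
objective non-increasing across outer sweeps, which the tests assert.

λ is selected as the minimizer of the mean cross-validated partial-likelihood
deviance in the Verweij–van Houwelingen form, `−2[ll_all(β_{−k}) −
ll_{−k}(β_{−k})]`, with 10 folds by default (deviance rather than C-index, a
recorded choice in the model metadata). An all-zero model at the selected λ
is returned with a warning rather than an error.

In the full pipeline the signature is fit on the activities of the
*permutation-selected* subpathways — the analysis's own flow — which also
keeps the fit in the well-posed n > p regime at the package's default problem
sizes.

Risk score = Σ coefficient × NES per sample; cohorts split at the training
median (applied unchanged to test cohorts). A constant score vector flags the
split as degenerate. KM curves and the two-group log-rank test come from
lifelines; the log-rank p is validated against a 100000-draw label-permutation
oracle in the tests.

## Drug–subpathway network

Per drug, lines at or below the median IC50 form the low (sensitive) group —
ties go low — with at least two lines required per group. Per omics layer,
high vs low groups are compared per gene (Welch *t* for expression, Wilcoxon
rank-sum for methylation and copy number; the rank-sum test is exact by
enumeration for pooled size ≤ 12 without ties, otherwise a tie-corrected
continuity-corrected normal approximation), BH-adjusted within the layer, and
thresholded at adjusted p < 0.05. Layer gene sets are linked to subpathways
by the hypergeometric upper tail over that layer's gene universe at raw
p < 0.05 (raw, per the method's convention), requiring a non-empty overlap.
Edge width = number of linking layers; BH is applied within each layer but
not across drugs, matching the per-drug procedure the edges represent.

## Synthetic data: what it emulates, and what it does not

* **Network** — preferential attachment (Barabási–Albert, attachment 2), so
  degrees are heavy-tailed like curated protein-interaction networks; RWR
  behavior depends on that heterogeneity. Edges carry evidence counts in
  {1,2,3} with P(≥2) = `evidence_rate` (default 0.85).
* **Counts** — negative binomial with log-normal gene means (meanlog 4,
  sdlog 1), dispersion 0.1 (variance = μ + 0.1μ²); planted genes shift by
  ±`effect_log2fc` (default 2.0) in the first-named group.
* **Survival** — exponential proportional hazards with rate
  `h₀·exp(Σβ·activity)` (h₀ = 0.1) and independent Uniform(0, c_max)
  censoring, with c_max calibrated by root-finding to a target censoring rate
  (default 0.3). The simplest model under which lasso recovery is well posed.
* **Tumor cohorts** — members of each signal subpathway share a per-sample
  latent log2 factor, so ssGSEA activity tracks the factor and survival can
  be generated from true coefficients over real activities.
* **Drug screen** — driven drugs: log IC50 = 1 + effect × (mean expression of
  the driver subpathway's members) + noise; driver members share a per-line
  latent factor so they individually separate the IC50 groups. Methylation is
  logit-normal in (0,1) and copy number integer in {−2..2}; both are noise
  layers in the generator (neither is specified by the study design).
* **Default problem sizes** — 1200 genes, 150 subpathways of 6–30 members
  (5 carrying signal, unit coefficients of alternating sign), 2 + 3 studies
  of 10 vs 10 samples, 100 training / 80 test tumor samples, 20 drugs × 40
  lines with 8 driven. These are the package's desk-scale defaults; the
  generators accept the full-scale values (e.g. 1773 subpathways) unchanged.

The generators do **not** emulate platform-specific microarray artifacts,
real accession structure, tumor purity gradients, or cross-species mapping;
passing tests demonstrate the statistical machinery recovers planted
structure under the stated models, not performance on any real cohort.

## Known limitations

* Propagation is unweighted and undirected; no multi-network fusion.
* No elastic-net mixing, time-dependent covariates, or dose–response fitting.
* Enrichment is against user-supplied GMT collections; no ontology traversal.
* The DE engine is Welch-t based; strongly dispersed low-count data would
  warrant a count GLM upstream of the same thresholds.
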