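# subpathnet

Microglia-specific subpathway analysis by network propagation.

Tumor-associated microglia (brain-resident immune cells) are easily confounded
with infiltrating macrophages, and cell-population signatures alone say little
about which *functional* pathway regions they dysregulate. `subpathnet`
implements the full analysis chain for resolving this at the subpathway level
(a subpathway is a connected region of a curated pathway, treated as its own
gene set of at least three members):

1. **Consensus differential signatures.** Per dataset, genes are tested on the
   log2 scale (Welch *t*, Benjamini–Hochberg); a gene is called only when
   |log2FC| > 1.5 **and** FDR < 0.05. Genes flagged with the same direction in
   enough datasets — two for tumor-microglia vs tumor-macrophage (MicT/MacT),
   three for tumor vs normal microglia (MicT/MicN) — become consensus seeds;
   conflicting genes are excluded and reported.
2. **Random walk with restart (RWR).** On the high-confidence interaction
   network (edges supported by ≥ 2 resources, largest connected component),
   the walk `P_{t+1} = (1−r) W P_t + r P_0` with column-normalized binary
   adjacency `W`, restart `r = 0.7` and uniform seed vector `P_0` is iterated
   until the L1 difference falls below 1e-6. Four walks (up/down seeds × two
   contrasts) give each gene a `score_up` and `score_down` per contrast.
3. **Subpathway scoring.** `Score = mean(score_up) − mean(score_down)` over a
   subpathway's network-covered members. Significance comes from 5000
   permutations that redraw same-sized gene sets from all scored genes;
   subpathways with p < 0.001 are selected, and pairs sharing more than seven
   member genes form a crosstalk network.
4. **Activity and prognosis.** Per-sample subpathway activity is a
   single-sample GSEA (ssGSEA) normalized enrichment score. On a
   ComBat-merged training cohort, an l1-penalized (lasso) Cox model over the
   selected subpathway activities — fit by cyclic coordinate descent with
   cross-validated penalty selection — yields a sparse prognostic signature;
   cohorts split at the training-median risk score are compared by
   Kaplan–Meier curves and the log-rank test.
5. **Drug–subpathway network.** Per drug, cell lines split at the median IC50;
   drug-related genes are called per omics layer (Welch *t* on expression,
   rank-sum on methylation and copy number, BH within layer) and linked to
   signature subpathways by the hypergeometric test
   `P = 1 − Σ_{x<r} C(t,x)C(m−t,n−x)/C(m,n)`. Edge width counts the
   supporting layers (1–3).

A first-class synthetic-data module generates every input with planted ground
truth (consistent DE signatures, a scale-free interaction network, gene sets,
activity-driven exponential survival, expression-driven IC50), so the whole
chain runs and is tested without any external download.

## Worked example

```python
import subpathnet as sp
from subpathnet.synthetic_data import simulate_all

bundle = simulate_all(seed=7)  # 1200 genes, 150 subpathways, 5 planted

contrast = {"SIM_MM": ("MicT", "MacT"), "SIM_MN": ("MicT", "MicN")}
de = {sid: sp.differential_expression(study, contrast[sid[:6]])
      for sid, study in bundle.studies.items()}
mm = sp.consensus_signatures({k: v for k, v in de.items() if "MM" in k}, 2, "MicT/MacT")
mn = sp.consensus_signatures({k: v for k, v in de.items() if "MN" in k}, 3, "MicT/MicN")

net = sp.build_high_quality_network(bundle.network, min_evidence=2)
scores = sp.score_all_groups(net, {
    "MicT/MacT": {"up": mm.genes("up"), "down": mm.genes("down")},
    "MicT/MicN": {"up": mn.genes("up"), "down": mn.genes("down")}})

results = sp.score_collection(bundle.collection, scores, n_perm=5000, seed=7)
selected = sp.select_significant(results, alpha=0.001)
```

Continuing through the signature fit and drug network (as in
`scripts/acceptance.py`), the run prints:

```
consensus seeds: 51 up / 29 down (MicT/MacT), 56 up / 4 down (MicT/MicN)
significant subpathways: 6 (planted recovered: 5/5); crosstalk edges: 1
signature: 6 subpathways at lambda=0.0260; test-cohort log-rank chi2=16.7, p=4.29e-05
drug network: 31 edges over 20 drugs
```

Reading: the consensus seeds recover the planted signatures; propagation plus
permutation scoring finds all five subpathways that actually carry signal
(one extra set overlaps them heavily); the lasso signature fitted on the
training cohort separates high- from low-risk samples in the held-out test
cohort decisively; and the driven drugs connect to their driver subpathways.

## Command line

Every stage is also a subcommand of the `subpathnet` CLI — `simulate`, `de`,
`consensus`, `risk-screen`, `rwr`, `subpath-score`, `enrich`, `ssgsea`,
`correlate`, `merge`, `fit-signature`, `score`, `evaluate`, `drugnet` — reading
and writing plain-text formats (TSV matrices, SIF networks, GMT gene sets,
CSV survival tables, JSON models). `subpathnet <cmd> --help` documents each.

## Layout

```
src/subpathnet/
  synthetic_data.py   seeded generators + ground truth
  diffexpr.py         DE, BH, consensus signatures, univariate Cox screens
  netprop.py          network assembly, RWR propagation
  subpathway.py       subpathway scores, permutation p-values, crosstalk
  enrichment.py       hypergeometric tests, ssGSEA, marker correlations
  prognosis.py        ComBat merge, lasso Cox signature, KM/log-rank
  drugnet.py          multi-omic drug-subpathway association network
  io.py, cli.py       plain-text formats and the CLI
docs/methods.md       model assumptions, parameters, numerical choices
```
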