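"""Differential expression, consensus signatures across datasets, and
survival-based risk-gene screens.

Per dataset, genes are tested on the log2 scale (counts get a pseudocount)
with a Welch two-sample t statistic and Benjamini-Hochberg adjustment; a gene
is called up/down only when it passes BOTH the fold-change cutoff and the
adjusted-p cutoff (defaults |log2FC| > 1.5, FDR < 0.05 for the cell-population
contrasts; 0.5 / 0.05 is the convention for bulk glioma contrasts). Consensus
signatures keep genes flagged with the same direction in at least
``min_support`` datasets; genes flagged in opposite directions anywhere are
excluded and reported separately. The risk-gene screen runs a univariate Cox
model per gene (p < 0.01; hazard ratio above/below 1 marks risk/protective).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._cox import cox_newton
from .errors import (
    AlignmentError,
    InsufficientReplicatesError,
    InvalidArgumentError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "ConsensusSignature",
    "ConsensusResult",
    "CoxResult",
    "differential_expression",
    "benjamini_hochberg",
    "consensus_signatures",
    "univariate_cox",
    "risk_gene_screen",
]


@dataclass
class DEResult:
    gene: str
    log2fc: float
    p_value: float
    adjusted_p: float
    direction: str  # up / down / none


@dataclass(frozen=True)
class ConsensusSignature:
    gene: str
    direction: str
    support: int
    group: str


@dataclass
class ConsensusResult:
    """Consensus gene list plus the genes excluded for conflicting directions."""

    signatures: list[ConsensusSignature]
    conflicting: dict[str, dict[str, int]]  # gene -> {direction: support}

    def genes(self, direction: str | None = None) -> set:
        return {
            s.gene for s in self.signatures if direction is None or s.direction == direction
        }


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values, clipped at 1, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    study,
    contrast: tuple[str, str],
    lfc_cutoff: float = 1.5,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> list[DEResult]:
    """Welch-t differential expression of group A versus group B.

    ``study`` is a GeneExpressionStudy; ``contrast`` names two annotation
    groups (e.g. ("MicT", "MacT")). log2FC is mean(A) - mean(B) on the log2
    scale, so "up" means higher in A.
    """
    if lfc_cutoff < 0:
        raise InvalidArgumentError("lfc_cutoff must be >= 0")
    labels = study.group_labels()
    a_samples = labels.index[labels == contrast[0]]
    b_samples = labels.index[labels == contrast[1]]
    for name, samples in zip(contrast, (a_samples, b_samples)):
        if len(samples) < 2:
            raise InsufficientReplicatesError(
                f"group {name!r} has {len(samples)} samples; >= 2 required"
            )
    log_expr = study.log_values(pseudocount=pseudocount)
    a = log_expr[a_samples].to_numpy()
    b = log_expr[b_samples].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # zero-variance genes with equal means: no evidence against the null
    p = np.where(np.isnan(p), 1.0, p)
    adj = benjamini_hochberg(p)
    results = []
    for gene, fc, pv, ap in zip(log_expr.index, log2fc, p, adj):
        if abs(fc) > lfc_cutoff and ap < alpha:
            direction = "up" if fc > 0 else "down"
        else:
            direction = "none"
        results.append(DEResult(gene=gene, log2fc=float(fc), p_value=float(pv),
                                adjusted_p=float(ap), direction=direction))
    return results


def de_results_to_frame(results: Iterable[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": r.gene, "log2fc": r.log2fc, "p_value": r.p_value,
             "adjusted_p": r.adjusted_p, "direction": r.direction}
            for r in results
        ]
    )


def consensus_signatures(
    results: Mapping[str, Iterable[DEResult]],
    min_support: int,
    group: str,
) -> ConsensusResult:
    """Genes flagged with one direction in at least ``min_support`` datasets.

    A gene flagged up in some datasets and down in others is excluded from the
    consensus and returned in ``conflicting`` with its per-direction support.
    """
    if min_support < 1:
        raise InvalidArgumentError("min_support must be >= 1")
    if not results:
        raise InvalidArgumentError("empty result map")
    if len(results) < min_support:
        raise InvalidArgumentError(
            f"min_support {min_support} exceeds the {len(results)} supplied datasets"
        )
    support: dict[str, dict[str, int]] = {}
    for dataset_id, res in results.items():
        for r in res:
            if r.direction in ("up", "down"):
                support.setdefault(r.gene, {"up": 0, "down": 0})[r.direction] += 1
    signatures = []
    conflicting = {}
    for gene in sorted(support):
        counts = support[gene]
        if counts["up"] > 0 and counts["down"] > 0:
            conflicting[gene] = dict(counts)
            continue
        direction = "up" if counts["up"] > 0 else "down"
        if counts[direction] >= min_support:
            signatures.append(
                ConsensusSignature(gene=gene, direction=direction,
                                   support=counts[direction], group=group)
            )
    if conflicting:
        logger.warning("%d genes flagged in opposite directions were excluded: %s",
                       len(conflicting), sorted(conflicting)[:10])
    return ConsensusResult(signatures=signatures, conflicting=conflicting)


@dataclass
class CoxResult:
    covariate: str
    log_hr: float
    hr: float
    p_value: float
    classification: str  # risk / protective / none
    se: float = float("nan")


def _classify(hr: float, p: float, p_threshold: float) -> str:
    if p < p_threshold and hr > 1:
        return "risk"
    if p < p_threshold and hr < 1:
        return "protective"
    return "none"


def univariate_cox(
    cohort,
    covariate,
    p_threshold: float = 0.01,
    name: str = "covariate",
) -> CoxResult:
    """Single-covariate Cox proportional-hazards fit (Breslow ties, Newton).

    Classification: significant with HR > 1 -> risk, HR < 1 -> protective.
    """
    x = np.asarray(covariate, dtype=float)
    if np.all(x == x[0]):
        raise InvalidArgumentError(f"covariate {name!r} is constant")
    time = cohort.time.to_numpy(dtype=float)
    event = cohort.event.to_numpy(dtype=float)
    if len(x) != len(time):
        raise AlignmentError("covariate length does not match the cohort")
    fit = cox_newton(x[:, None], time, event)
    log_hr = float(fit.beta[0])
    se = float(fit.se[0])
    z = log_hr / se if se > 0 else np.inf * np.sign(log_hr)
    p = float(2 * stats.norm.sf(abs(z)))
    hr = float(np.exp(log_hr))
    return CoxResult(covariate=name, log_hr=log_hr, hr=hr, p_value=p,
                     classification=_classify(hr, p, p_threshold), se=se)


def risk_gene_screen(
    expr,
    cohort,
    p_threshold: float = 0.01,
) -> dict[str, CoxResult]:
    """Univariate Cox model per gene; constant genes are skipped with a warning.

    Sample ids must match between the expression study and the cohort. The
    risk/protective gene lists feed the subpathway association tests
    downstream.
    """
    log_expr = expr.log_values()
    cohort_samples = list(cohort.samples)
    if set(log_expr.columns) != set(cohort_samples):
        missing = set(cohort_samples) ^ set(log_expr.columns)
        raise AlignmentError(f"sample ids do not align between expression and cohort: {sorted(missing)[:5]}")
    mat = log_expr[cohort_samples]
    out: dict[str, CoxResult] = {}
    skipped = []
    for gene in mat.index:
        x = mat.loc[gene]
        if np.all(x.to_numpy() == x.iloc[0]):
            skipped.append(gene)
            continue
        out[gene] = univariate_cox(cohort, x, p_threshold=p_threshold, name=gene)
    if skipped:
        logger.warning("%d constant genes skipped in the risk screen", len(skipped))
    return out


def risk_gene_sets(screen: Mapping[str, CoxResult]) -> dict[str, set]:
    """Split a risk screen into {'risk': genes, 'protective': genes}."""
    return {
        "risk": {g for g, r in screen.items() if r.classification == "risk"},
        "protective": {g for g, r in screen.items() if r.classification == "protective"},
    }
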