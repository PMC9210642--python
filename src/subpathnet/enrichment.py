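"""Hypergeometric association tests, single-sample gene-set activity (ssGSEA)
and marker-set correlation analyses.

The hypergeometric test reports the upper tail

    P = 1 - sum_{x=0}^{r-1} C(t, x) C(m - t, n - x) / C(m, n)

for an overlap of ``r`` genes between a query of size ``n`` and a reference
set of size ``t`` drawn from a universe of ``m`` genes (for human whole-genome
universes m is conventionally ~20000).

ssGSEA scores one gene set in one sample as the sum, down the expression-ranked
gene list, of the difference between the weighted in-set cumulative
distribution (weights = rank statistic to the power ``exponent``) and the
unweighted out-of-set cumulative distribution. Scores are normalized across
the whole subpathway x sample matrix by its (max - min) range, giving NES
values comparable within one matrix.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, UndefinedCorrelationError
from .subpathway import SubpathwayCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "ActivityMatrix",
    "hypergeometric_test",
    "associate_gene_sets",
    "ssgsea_scores",
    "marker_correlation",
    "default_marker_sets",
]

DEFAULT_UNIVERSE_SIZE = 20000
DEFAULT_SSGSEA_EXPONENT = 0.25


def hypergeometric_test(m: int, t: int, n: int, r: int) -> float:
    """Upper-tail overlap probability P(X >= r), X ~ Hypergeom(m, t, n).

    m: universe size; t: reference-set size; n: query size; r: observed overlap.
    """
    if not (0 <= r <= n <= m):
        raise InvalidArgumentError(f"need 0 <= r <= n <= m, got r={r}, n={n}, m={m}")
    if not (0 <= t <= m):
        raise InvalidArgumentError(f"need 0 <= t <= m, got t={t}, m={m}")
    if r == 0:
        return 1.0
    # survival function P(X > r-1) = P(X >= r); stable in log space internally
    return float(stats.hypergeom.sf(r - 1, m, t, n))


@dataclass
class EnrichmentResult:
    query_set_id: str
    reference_set_id: str
    m: int
    t: int
    n: int
    r: int
    p_value: float
    overlap_genes: frozenset
    significant: bool = False


def associate_gene_sets(
    query_sets: Mapping[str, Iterable],
    reference_sets: Mapping[str, Iterable],
    universe: Iterable,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric overlap test for every (query, reference) pair.

    All sets are intersected with the universe before testing; ``significant``
    flags raw P < alpha (no multiplicity correction, matching the convention
    for these association screens).
    """
    universe = set(universe)
    if not universe:
        raise InvalidArgumentError("universe must be non-empty")
    m = len(universe)
    results = []
    for q_id, q_genes in query_sets.items():
        q = set(q_genes) & universe
        for ref_id, ref_genes in reference_sets.items():
            ref = set(ref_genes) & universe
            overlap = q & ref
            p = hypergeometric_test(m, len(ref), len(q), len(overlap))
            results.append(
                EnrichmentResult(
                    query_set_id=q_id,
                    reference_set_id=ref_id,
                    m=m,
                    t=len(ref),
                    n=len(q),
                    r=len(overlap),
                    p_value=p,
                    overlap_genes=frozenset(overlap),
                    significant=p < alpha,
                )
            )
    return results


def enrichment_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_set_id": e.query_set_id,
                "reference_set_id": e.reference_set_id,
                "m": e.m,
                "t": e.t,
                "n": e.n,
                "r": e.r,
                "p_value": e.p_value,
                "significant": e.significant,
                "overlap_genes": ",".join(sorted(e.overlap_genes)),
            }
            for e in results
        ]
    )


@dataclass
class ActivityMatrix:
    """Subpathway x sample NES matrix plus the scoring metadata that produced it."""

    values: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def subpathways(self) -> list:
        return list(self.values.index)

    def row(self, subpathway_id) -> pd.Series:
        return self.values.loc[subpathway_id]


def _single_sample_es(expr: np.ndarray, in_set: np.ndarray, exponent: float) -> float:
    """Running-sum enrichment score of one set in one sample.

    expr: expression values over the gene universe; in_set: boolean mask.
    Genes are ordered by decreasing expression; the rank statistic is the
    average rank (highest expression -> rank N), so the score depends on the
    expression only through its ordering.
    """
    n = len(expr)
    n_in = int(in_set.sum())
    n_out = n - n_in
    # average ranks, largest expression -> rank n; ties share their mean rank
    ranks = stats.rankdata(expr, method="average")
    order = np.argsort(-expr, kind="stable")
    in_ordered = in_set[order]
    weights = np.abs(ranks[order]) ** exponent
    w_in = np.where(in_ordered, weights, 0.0)
    denom_in = w_in.sum()
    cdf_in = np.cumsum(w_in) / denom_in
    cdf_out = np.cumsum(~in_ordered) / n_out
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_scores(
    expr,
    collection: SubpathwayCollection | Mapping[str, Iterable],
    exponent: float = DEFAULT_SSGSEA_EXPONENT,
) -> ActivityMatrix:
    """Single-sample enrichment (NES) of each subpathway in each sample.

    ``expr`` is a genes x samples DataFrame (or a study object with ``.values``);
    log-scale input is assumed but only the within-sample ordering matters.
    Sets with no expressed member are dropped with a warning. NES = raw score
    divided by the (max - min) range over the whole score matrix.
    """
    frame = expr.log_values() if hasattr(expr, "log_values") else expr
    if not isinstance(frame, pd.DataFrame):
        frame = pd.DataFrame(frame)
    gene_sets = (
        collection.gene_sets() if isinstance(collection, SubpathwayCollection) else
        {k: set(v) for k, v in collection.items()}
    )
    genes = frame.index
    gene_pos = {g: i for i, g in enumerate(genes)}
    masks = {}
    for set_id, members in gene_sets.items():
        idx = [gene_pos[g] for g in members if g in gene_pos]
        if not idx:
            logger.warning("gene set %s has no expressed member; dropped", set_id)
            continue
        mask = np.zeros(len(genes), dtype=bool)
        mask[idx] = True
        if (~mask).sum() < 2:
            raise InvalidArgumentError(
                f"gene set {set_id} leaves fewer than 2 genes outside the set"
            )
        masks[set_id] = mask
    if not masks:
        raise InvalidArgumentError("no gene set has any expressed member")

    mat = frame.to_numpy(dtype=float)
    set_ids = list(masks)
    mask_matrix = np.stack([masks[s] for s in set_ids])  # sets x genes
    n_out = (~mask_matrix).sum(axis=1).astype(float)
    scores = np.empty((len(set_ids), frame.shape[1]))
    for j in range(frame.shape[1]):
        col = mat[:, j]
        if np.all(col == col[0]):
            raise InvalidArgumentError(
                f"sample {frame.columns[j]!r} has constant expression; cannot rank"
            )
        ranks = stats.rankdata(col, method="average")
        order = np.argsort(-col, kind="stable")
        weights = np.abs(ranks[order]) ** exponent
        ordered = mask_matrix[:, order]
        w_in = np.where(ordered, weights, 0.0)
        cdf_in = np.cumsum(w_in, axis=1) / w_in.sum(axis=1, keepdims=True)
        cdf_out = np.cumsum(~ordered, axis=1) / n_out[:, None]
        scores[:, j] = (cdf_in - cdf_out).sum(axis=1)

    span = scores.max() - scores.min()
    nes = scores / span if span > 0 else scores
    return ActivityMatrix(
        values=pd.DataFrame(nes, index=set_ids, columns=frame.columns),
        metadata={
            "method": "ssgsea",
            "exponent": exponent,
            "normalization": "matrix_minmax",
            "raw_range": float(span),
        },
    )


def marker_correlation(
    activity_row: pd.Series,
    marker_sets: Mapping[str, Iterable],
    expr,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate a subpathway activity profile with marker-set activities.

    Each marker set is scored per sample by ssGSEA on the supplied expression,
    then rank (spearman) or linear (pearson) correlated with ``activity_row``
    over the shared samples. Returns a frame (marker_set, correlation, p_value,
    adjusted_p) with BH adjustment across marker sets. Also suits activity-vs-
    covariate screens (e.g. tumor purity) by passing the covariate as a
    one-row "marker activity" via :func:`correlate_vectors`.
    """
    if method not in ("spearman", "pearson"):
        raise InvalidArgumentError(f"method must be spearman or pearson, got {method!r}")
    marker_activity = ssgsea_scores(expr, dict(marker_sets), exponent=DEFAULT_SSGSEA_EXPONENT)
    shared = [s for s in marker_activity.samples if s in activity_row.index]
    if len(shared) < 3:
        raise InvalidArgumentError("need >= 3 paired samples for correlation")
    rows = []
    for name in marker_activity.subpathways:
        rho, p = correlate_vectors(
            activity_row.loc[shared], marker_activity.row(name).loc[shared], method
        )
        rows.append({"marker_set": name, "correlation": rho, "p_value": p})
    out = pd.DataFrame(rows)
    from .diffexpr import benjamini_hochberg

    out["adjusted_p"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


def correlate_vectors(x: pd.Series, y: pd.Series, method: str = "spearman"):
    """Correlation between two aligned sample vectors; errors on constant input."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise UndefinedCorrelationError("correlation against a constant vector is undefined")
    if method == "spearman":
        rho, p = stats.spearmanr(xv, yv)
    else:
        rho, p = stats.pearsonr(xv, yv)
    return float(rho), float(p)


def default_marker_sets() -> dict[str, set]:
    """Packaged microglia/macrophage polarization marker sets.

    Homeostatic microglia, pro-inflammatory (M1) and alternatively activated
    (M2) marker genes, shipped as a GMT resource.
    """
    from .io import parse_gmt

    text = (
        importlib.resources.files("subpathnet") / "data" / "markers.gmt"
    ).read_text()
    return {k: set(v) for k, (_, v) in parse_gmt(text).items()}
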