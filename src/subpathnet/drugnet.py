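"""Drug-subpathway association network from a multi-omic drug screen.

For every drug, cell lines are split at the median IC50 (ties go to the
low-IC50, i.e. sensitive, group). Drug-related genes are then called per
omics level — Welch t-test on expression, Wilcoxon rank-sum on methylation
beta values and copy-number calls — with Benjamini-Hochberg adjustment within
each level (adjusted p < 0.05). Each level's gene set is linked to signature
subpathways by the hypergeometric overlap test over the omics gene universe
(raw p < 0.05); a drug-subpathway edge exists when at least one level links,
and its width is the number of linking levels (1-3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg
from .enrichment import hypergeometric_test
from .errors import InsufficientLinesError, InvalidArgumentError
from .subpathway import SubpathwayCollection

logger = logging.getLogger(__name__)

__all__ = [
    "DrugScreen",
    "DrugSubpathwayNetwork",
    "median_ic50_split",
    "wilcoxon_rank_sum",
    "drug_related_genes",
    "build_drug_network",
]

OMICS_LEVELS = ("expression", "methylation", "cnv")


@dataclass
class DrugScreen:
    """IC50 matrix (drug x cell line) plus per-line expression, methylation
    and copy-number matrices (gene x cell line)."""

    ic50: pd.DataFrame
    expression: pd.DataFrame
    methylation: pd.DataFrame
    cnv: pd.DataFrame

    def __post_init__(self):
        lines = set(self.ic50.columns)
        for level in OMICS_LEVELS:
            cols = set(getattr(self, level).columns)
            if cols != lines:
                raise InvalidArgumentError(
                    f"{level} cell lines do not match the IC50 matrix"
                )
        finite = self.ic50.to_numpy(dtype=float)
        if np.any(finite[~np.isnan(finite)] <= 0):
            raise InvalidArgumentError("IC50 values must be positive")

    @property
    def drugs(self) -> list:
        return list(self.ic50.index)

    @property
    def lines(self) -> list:
        return list(self.ic50.columns)

    def omics(self, level: str) -> pd.DataFrame:
        if level not in OMICS_LEVELS:
            raise InvalidArgumentError(f"unknown omics level {level!r}")
        return getattr(self, level)


def median_ic50_split(ic50_row: pd.Series) -> tuple[set, set]:
    """Split cell lines at the median IC50: (low/sensitive, high/resistant).

    Lines at or below the median go to the low group; missing values are
    excluded. Raises :class:`InsufficientLinesError` when either group ends up
    with fewer than two lines.
    """
    row = pd.Series(ic50_row).dropna()
    if len(row) < 4:
        raise InsufficientLinesError(
            f"need >= 4 lines with IC50 values, got {len(row)}"
        )
    median = float(row.median())
    low = set(row.index[row <= median])
    high = set(row.index[row > median])
    if len(low) < 2 or len(high) < 2:
        raise InsufficientLinesError(
            f"median split left groups of sizes {len(low)}/{len(high)}; >= 2 each required"
        )
    return low, high


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the pooled size is <= 12 with no ties, otherwise a
    normal approximation with tie-corrected variance and continuity
    correction. Returns (rank-sum statistic of sample a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidArgumentError("each sample needs >= 2 observations")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    # rank-sum of a = U_a + n_a(n_a+1)/2
    w = float(res.statistic + len(a) * (len(a) + 1) / 2)
    return w, float(min(res.pvalue, 1.0))


def _level_test(level: str, high_vals: np.ndarray, low_vals: np.ndarray) -> np.ndarray:
    """Per-gene two-sided p-values, high-IC50 vs low-IC50 lines."""
    if level == "expression":
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(high_vals, low_vals, axis=1, equal_var=False)
        return np.where(np.isnan(p), 1.0, p)
    pooled = np.concatenate([high_vals, low_vals], axis=1)
    constant = np.all(pooled == pooled[:, :1], axis=1)
    small = pooled.shape[1] <= 12
    p = np.ones(high_vals.shape[0])
    if small:
        # exact branch possible per gene; delegate to the scalar test
        for i in np.flatnonzero(~constant):
            _, p[i] = wilcoxon_rank_sum(high_vals[i], low_vals[i])
        return p
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(high_vals, low_vals, axis=1,
                                 alternative="two-sided", method="asymptotic",
                                 use_continuity=True)
    p[~constant] = res.pvalue[~constant]
    return np.where(np.isnan(p), 1.0, p)


def drug_related_genes(
    screen: DrugScreen, drug, alpha: float = 0.05
) -> dict[str, set]:
    """Genes separating high- from low-IC50 lines, per omics level.

    Expression uses Welch's t; methylation and CNV use the rank-sum test. BH
    adjustment is applied within each level; genes with adjusted p < alpha are
    returned.
    """
    low, high = median_ic50_split(screen.ic50.loc[drug])
    out: dict[str, set] = {}
    for level in OMICS_LEVELS:
        mat = screen.omics(level)
        high_vals = mat[sorted(high & set(mat.columns))].to_numpy(dtype=float)
        low_vals = mat[sorted(low & set(mat.columns))].to_numpy(dtype=float)
        if np.all(mat.to_numpy() == mat.to_numpy()[0:1, 0:1]):
            logger.warning("%s layer is constant; empty gene set for drug %s", level, drug)
            out[level] = set()
            continue
        p = _level_test(level, high_vals, low_vals)
        adj = benjamini_hochberg(p)
        out[level] = set(mat.index[adj < alpha])
    return out


@dataclass
class DrugSubpathwayNetwork:
    """Bipartite drug/subpathway graph; edge width counts the significant levels."""

    graph: nx.Graph
    edge_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def edges(self) -> list[tuple]:
        return list(self.graph.edges(data=True))


def build_drug_network(
    screen: DrugScreen,
    collection: SubpathwayCollection,
    alpha_gene: float = 0.05,
    alpha_assoc: float = 0.05,
    drug_classes: Mapping | None = None,
    subpathway_flags: Mapping | None = None,
) -> DrugSubpathwayNetwork:
    """Drug-subpathway network across the three omics levels.

    For each (drug, level), the level's drug-related gene set is tested for
    hypergeometric overlap against every subpathway (universe = that level's
    gene space); the association flags at raw p < ``alpha_assoc`` and requires
    a non-empty overlap. An edge joins a drug and a subpathway when any level
    flags; edge width = number of flagged levels. ``drug_classes`` and
    ``subpathway_flags`` (risk/protective from the signature model) become
    node attributes when given.
    """
    for level in OMICS_LEVELS:
        if screen.omics(level).index.empty:
            raise InvalidArgumentError(f"{level} gene universe is empty")
    g = nx.Graph()
    rows = []
    for sid in collection.ids():
        g.add_node(("subpathway", sid), kind="subpathway",
                   flag=(subpathway_flags or {}).get(sid, "none"))
    for drug in screen.drugs:
        g.add_node(("drug", drug), kind="drug",
                   drug_class=(drug_classes or {}).get(drug, "unknown"))
        try:
            gene_sets = drug_related_genes(screen, drug, alpha=alpha_gene)
        except InsufficientLinesError as exc:
            logger.warning("drug %s skipped: %s", drug, exc)
            continue
        for entry in collection:
            flags = {}
            for level in OMICS_LEVELS:
                universe = set(screen.omics(level).index)
                members = set(entry.members) & universe
                query = gene_sets[level] & universe
                overlap = query & members
                if not query or not members:
                    flags[level] = False
                    continue
                p = hypergeometric_test(len(universe), len(members), len(query), len(overlap))
                flags[level] = bool(len(overlap) > 0 and p < alpha_assoc)
            width = sum(flags.values())
            if width >= 1:
                g.add_edge(("drug", drug), ("subpathway", entry.subpathway_id),
                           width=width, **{f"{lv}_flag": flags[lv] for lv in OMICS_LEVELS})
                rows.append({"drug": drug, "subpathway_id": entry.subpathway_id,
                             "width": width, **{lv: flags[lv] for lv in OMICS_LEVELS}})
    table = pd.DataFrame(rows, columns=["drug", "subpathway_id", "width", *OMICS_LEVELS])
    logger.info("drug network: %d drugs, %d subpathways, %d edges",
                len(screen.drugs), len(collection), len(rows))
    return DrugSubpathwayNetwork(graph=g, edge_table=table)
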