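"""Subpathway scoring, permutation significance and the crosstalk network.

A subpathway is a small (>= 3 gene) connected region of a curated pathway,
treated as its own gene set. Its activity contrast is summarized from the
propagation scores as

    score = mean(score_up over covered members) - mean(score_down over covered members)

where "covered" means present in the interaction network. Significance is
assessed by drawing, for each subpathway, random gene sets of the same covered
size from all scored genes (each sampled gene carries its actual paired
up/down scores) and counting how often the random score's magnitude exceeds
the observed one's. Subpathways passing the significance cutoff
(default p < 0.001 at 5000 permutations) form the nodes of a crosstalk network
whose edges join pairs sharing strictly more than a threshold number of member
genes (default 7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UncoveredSubpathwayError
from .netprop import RWRScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "Subpathway",
    "SubpathwayCollection",
    "SubpathwayResult",
    "subpathway_score",
    "permutation_pvalue",
    "score_collection",
    "select_significant",
    "crosstalk_network",
]

DEFAULT_N_PERMUTATIONS = 5000
DEFAULT_ALPHA = 0.001
DEFAULT_OVERLAP_THRESHOLD = 7


@dataclass(frozen=True)
class Subpathway:
    subpathway_id: str
    parent_pathway_id: str
    class_label: str
    members: frozenset

    def __post_init__(self):
        if len(self.members) < 3:
            raise InvalidArgumentError(
                f"subpathway {self.subpathway_id} has {len(self.members)} members; >= 3 required"
            )


@dataclass
class SubpathwayCollection:
    """Named gene sets with parent-pathway and class annotations; ids unique."""

    entries: list[Subpathway]

    def __post_init__(self):
        ids = [e.subpathway_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise InvalidArgumentError("duplicate subpathway ids in collection")
        self._by_id = {e.subpathway_id: e for e in self.entries}

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, subpathway_id):
        return subpathway_id in self._by_id

    def __getitem__(self, subpathway_id) -> Subpathway:
        try:
            return self._by_id[subpathway_id]
        except KeyError:
            raise InvalidArgumentError(f"unknown subpathway id {subpathway_id!r}") from None

    def ids(self) -> list[str]:
        return [e.subpathway_id for e in self.entries]

    def gene_sets(self) -> dict[str, frozenset]:
        return {e.subpathway_id: e.members for e in self.entries}


@dataclass
class SubpathwayResult:
    """Observed score and permutation p-value of one subpathway in one contrast."""

    subpathway_id: str
    group: str
    score: float
    p_value: float
    direction: str  # "up" if score >= 0 else "down"
    n_permutations: int
    n_members_covered: int = 0

    def formatted_p(self) -> str:
        """p = 0 is reported as an upper bound set by the permutation count."""
        if self.p_value == 0.0:
            return f"< {1.0 / self.n_permutations:g}"
        return f"{self.p_value:g}"


def _covered_members(members: Iterable, frame: pd.DataFrame) -> list:
    return [g for g in members if g in frame.index]


def subpathway_score(
    members: Iterable, scores: RWRScoreTable, group: str
) -> tuple[float, int]:
    """Mean up-score minus mean down-score over the covered members.

    Returns (score, number of covered members); members absent from the
    network are ignored. Raises :class:`UncoveredSubpathwayError` when no
    member is scored.
    """
    frame = scores.frame(group)
    covered = _covered_members(members, frame)
    if not covered:
        raise UncoveredSubpathwayError(f"no member of the subpathway is scored in group {group!r}")
    sub = frame.loc[covered]
    return float(sub["score_up"].mean() - sub["score_down"].mean()), len(covered)


def _sample_without_replacement(rng, n_perm, k, n_pool, chunk=2000):
    """(n_perm, k) index matrix, each row a uniform draw of k of n_pool without
    replacement; generated in chunks to bound memory."""
    out = np.empty((n_perm, k), dtype=np.intp)
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        keys = rng.random((stop - start, n_pool))
        out[start:stop] = np.argpartition(keys, k - 1, axis=1)[:, :k]
    return out


def permutation_pvalue(
    true_score: float,
    member_count: int,
    scores: RWRScoreTable,
    group: str,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    subpathway_id: str = "",
) -> SubpathwayResult:
    """Permutation p-value of an observed subpathway score.

    Each permutation draws ``member_count`` genes uniformly without replacement
    from all scored genes and recomputes the score from their actual
    (score_up, score_down) pairs. Significance is two-sided on the magnitude,
    p = #(|random| > |observed|)/n_perm, which is exactly uniform under the
    null whatever the shape of the score distribution and treats up- and
    down-regulated subpathways symmetrically; the direction is the sign of
    the observed score.
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    frame = scores.frame(group)
    n_pool = len(frame)
    if member_count > n_pool:
        raise InvalidArgumentError(
            f"member_count {member_count} exceeds the {n_pool} scored genes"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # the score is the mean of per-gene (up - down) over the sampled members
    diff = (frame["score_up"] - frame["score_down"]).to_numpy()
    idx = _sample_without_replacement(rng, n_perm, member_count, n_pool)
    random_scores = diff[idx].mean(axis=1)
    exceed = int(np.sum(np.abs(random_scores) > abs(true_score)))
    return SubpathwayResult(
        subpathway_id=subpathway_id,
        group=group,
        score=float(true_score),
        p_value=exceed / n_perm,
        direction="up" if true_score >= 0 else "down",
        n_permutations=n_perm,
        n_members_covered=member_count,
    )


def score_collection(
    collection: SubpathwayCollection,
    scores: RWRScoreTable,
    groups: Sequence[str] | None = None,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> list[SubpathwayResult]:
    """Score every subpathway in every contrast and attach permutation p-values.

    Subpathways with no scored member are skipped with a warning (they cannot
    be assessed on this network). Permutations are drawn per (subpathway,
    group) from a generator seeded once, so results are reproducible given
    (collection order, seed).
    """
    groups = list(groups) if groups is not None else scores.groups()
    rng = np.random.default_rng(seed)
    results: list[SubpathwayResult] = []
    skipped = 0
    for group in groups:
        for entry in collection:
            try:
                score, covered = subpathway_score(entry.members, scores, group)
            except UncoveredSubpathwayError:
                skipped += 1
                continue
            res = permutation_pvalue(
                score, covered, scores, group, n_perm=n_perm, seed=rng,
                subpathway_id=entry.subpathway_id,
            )
            results.append(res)
    if skipped:
        logger.warning("%d (subpathway, group) pairs had no scored member and were skipped", skipped)
    return results


def select_significant(
    results: Iterable[SubpathwayResult], alpha: float = DEFAULT_ALPHA
) -> list[SubpathwayResult]:
    """Strict p < alpha filter, preserving input order; no multiplicity correction."""
    return [r for r in results if r.p_value < alpha]


@dataclass
class CrosstalkNetwork:
    """Graph over significant subpathways; edges mark large membership overlap."""

    graph: nx.Graph

    def hub_report(self) -> pd.DataFrame:
        degrees = sorted(self.graph.degree, key=lambda kv: kv[1], reverse=True)
        return pd.DataFrame(degrees, columns=["subpathway_id", "degree"])


def crosstalk_network(
    selected: Iterable[SubpathwayResult],
    collection: SubpathwayCollection,
    overlap_threshold: int = DEFAULT_OVERLAP_THRESHOLD,
) -> CrosstalkNetwork:
    """Join two significant subpathways iff they share strictly more than
    ``overlap_threshold`` member genes (default: an edge needs >= 8 shared genes).

    Node attributes carry each result's group and direction. A subpathway
    significant in both contrasts contributes one node per (id, group).
    """
    if overlap_threshold < 0:
        raise InvalidArgumentError("overlap_threshold must be >= 0")
    selected = list(selected)
    g = nx.Graph()
    for res in selected:
        if res.subpathway_id not in collection:
            raise InvalidArgumentError(
                f"selected subpathway {res.subpathway_id!r} missing from the collection"
            )
        node = (res.subpathway_id, res.group)
        g.add_node(node, subpathway_id=res.subpathway_id, group=res.group,
                   direction=res.direction, score=res.score, p_value=res.p_value)
    nodes = list(g.nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            shared = len(
                collection[nodes[i][0]].members & collection[nodes[j][0]].members
            )
            if shared > overlap_threshold:
                g.add_edge(nodes[i], nodes[j], shared_gene_count=shared)
    net = CrosstalkNetwork(g)
    if g.number_of_nodes():
        top = net.hub_report().head(5).to_dict("records")
        logger.info("crosstalk network: %d nodes, %d edges; top hubs %s",
                    g.number_of_nodes(), g.number_of_edges(), top)
    return net


def results_to_frame(results: Iterable[SubpathwayResult]) -> pd.DataFrame:
    rows = [
        {
            "subpathway_id": r.subpathway_id,
            "group": r.group,
            "score": r.score,
            "p_value": r.p_value,
            "direction": r.direction,
            "n_permutations": r.n_permutations,
            "n_members_covered": r.n_members_covered,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
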