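"""Protein-interaction network assembly and random walk with restart (RWR).

The propagation model is the standard restart walk

    P[t+1] = (1 - r) * W @ P[t] + r * P0

with ``W`` the column-normalized binary adjacency matrix of the network, ``P0``
uniform over the seed genes, and restart probability ``r`` (default 0.7).
Iteration stops when the L1 difference between successive vectors falls below
the tolerance (default 1e-6), at which point ``P`` approximates the steady
state ``P∞ = r (I - (1-r) W)^{-1} P0``. Because the network is restricted to
its largest connected component before propagation, ``W`` is column stochastic
and probability mass is conserved exactly at every step.

Four walks are run per analysis: up- and down-regulated consensus seeds for
each of the two contrasts (tumor microglia vs tumor macrophage, and tumor
microglia vs normal microglia), yielding a per-gene ``score_up`` and
``score_down`` for each contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConvergenceError, EmptyNetworkError, InvalidArgumentError, InvalidSeedsError

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "FilterReport",
    "RWRConfig",
    "RWRScoreTable",
    "build_high_quality_network",
    "random_walk_restart",
    "score_all_groups",
]

#: the two contrasts scored in a full analysis
GROUPS = ("MicT/MacT", "MicT/MicN")


@dataclass
class FilterReport:
    """What evidence filtering and the largest-component restriction removed."""

    dropped_edges: int
    dropped_nodes: list


@dataclass
class InteractionNetwork:
    """Undirected gene interaction graph; each edge carries an evidence count >= 1."""

    graph: nx.Graph
    filter_report: FilterReport | None = None

    def __post_init__(self):
        if any(u == v for u, v in self.graph.edges):
            raise InvalidArgumentError("interaction network must not contain self-loops")
        for u, v, data in self.graph.edges(data=True):
            if data.get("evidence_count", 1) < 1:
                raise InvalidArgumentError(f"edge {u}-{v} has evidence_count < 1")

    @property
    def genes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple]) -> "InteractionNetwork":
        """Build from (gene_a, gene_b, evidence_count) triples, merging duplicates
        by keeping the larger evidence count and dropping self-loops."""
        g = nx.Graph()
        for a, b, count in edges:
            if a == b:
                continue
            count = int(count)
            if g.has_edge(a, b):
                g[a][b]["evidence_count"] = max(g[a][b]["evidence_count"], count)
            else:
                g.add_edge(a, b, evidence_count=count)
        return cls(g)

    def edge_triples(self) -> list[tuple]:
        return [(u, v, d["evidence_count"]) for u, v, d in self.graph.edges(data=True)]


def build_high_quality_network(
    network: InteractionNetwork | Iterable[tuple], min_evidence: int = 2
) -> InteractionNetwork:
    """Keep edges supported by at least ``min_evidence`` resources and restrict to
    the largest connected component.

    The dropped node/edge counts are attached to the result as ``filter_report``.
    """
    if min_evidence < 1:
        raise InvalidArgumentError(f"min_evidence must be >= 1, got {min_evidence}")
    if not isinstance(network, InteractionNetwork):
        network = InteractionNetwork.from_edges(network)
    g = network.graph
    kept = nx.Graph()
    kept.add_nodes_from(g.nodes)
    for u, v, data in g.edges(data=True):
        if data["evidence_count"] >= min_evidence:
            kept.add_edge(u, v, **data)
    kept.remove_nodes_from(list(nx.isolates(kept)))
    if kept.number_of_edges() == 0:
        raise EmptyNetworkError(
            f"no edge has evidence_count >= {min_evidence}; the filtered network is empty"
        )
    components = sorted(nx.connected_components(kept), key=len, reverse=True)
    giant = kept.subgraph(components[0]).copy()
    report = FilterReport(
        dropped_edges=g.number_of_edges() - giant.number_of_edges(),
        dropped_nodes=sorted(set(g.nodes) - set(giant.nodes)),
    )
    if report.dropped_nodes:
        logger.info(
            "evidence filter (>= %d) dropped %d nodes and %d edges",
            min_evidence,
            len(report.dropped_nodes),
            report.dropped_edges,
        )
    return InteractionNetwork(giant, filter_report=report)


@dataclass
class RWRConfig:
    """Restart-walk parameters: restart probability, L1 stopping tolerance, budget."""

    restart: float = 0.7
    tolerance: float = 1e-6
    max_iterations: int = 10000

    def __post_init__(self):
        if not (0 < self.restart <= 1):
            raise InvalidArgumentError(f"restart must be in (0, 1], got {self.restart}")
        if self.tolerance <= 0:
            raise InvalidArgumentError("tolerance must be positive")


def _column_normalized_adjacency(graph: nx.Graph, nodes: Sequence) -> sp.csr_matrix:
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight=None, format="csc", dtype=float)
    colsum = np.asarray(adj.sum(axis=0)).ravel()
    if np.any(colsum == 0):
        raise InvalidArgumentError("network has isolated nodes; restrict to a connected component")
    inv = sp.diags(1.0 / colsum)
    return (adj @ inv).tocsr()


def random_walk_restart(
    network: InteractionNetwork, seeds: Iterable, config: RWRConfig | None = None
) -> pd.Series:
    """Steady-state visiting probabilities of a restart walk from ``seeds``.

    Seeds absent from the network are dropped (with a warning) before the
    initial vector is normalized. Returns a probability vector over all network
    genes (sums to 1).
    """
    config = config or RWRConfig()
    nodes = list(network.graph.nodes)
    if not nx.is_connected(network.graph):
        raise InvalidArgumentError(
            "RWR requires a connected network; apply build_high_quality_network first"
        )
    seeds = set(seeds)
    effective = seeds & set(nodes)
    if not effective:
        raise InvalidSeedsError("no seed gene is present in the network")
    if len(effective) < len(seeds):
        logger.warning("%d seed genes absent from the network were dropped", len(seeds) - len(effective))

    index = {g: i for i, g in enumerate(nodes)}
    p0 = np.zeros(len(nodes))
    p0[[index[s] for s in effective]] = 1.0 / len(effective)

    w = _column_normalized_adjacency(network.graph, nodes)
    r = config.restart
    p = p0.copy()
    for _ in range(config.max_iterations):
        p_next = (1.0 - r) * (w @ p) + r * p0
        if np.abs(p_next - p).sum() < config.tolerance:
            return pd.Series(p_next, index=nodes, name="rwr_score")
        p = p_next
    raise ConvergenceError(
        f"RWR did not reach tolerance {config.tolerance} in {config.max_iterations} iterations",
        last_iterate=pd.Series(p, index=nodes),
    )


def rwr_steady_state_direct(
    network: InteractionNetwork, seeds: Iterable, restart: float = 0.7
) -> pd.Series:
    """Closed-form steady state ``r (I - (1-r)W)^{-1} P0`` by dense linear solve.

    Exact counterpart of :func:`random_walk_restart`; O(n^3), intended for
    validation on small networks.
    """
    nodes = list(network.graph.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    effective = set(seeds) & set(nodes)
    if not effective:
        raise InvalidSeedsError("no seed gene is present in the network")
    p0 = np.zeros(len(nodes))
    p0[[index[s] for s in effective]] = 1.0 / len(effective)
    w = _column_normalized_adjacency(network.graph, nodes).toarray()
    mat = np.eye(len(nodes)) - (1.0 - restart) * w
    p = restart * np.linalg.solve(mat, p0)
    return pd.Series(p, index=nodes, name="rwr_score")


@dataclass
class RWRScoreTable:
    """Per-gene propagation scores, one (score_up, score_down) pair per contrast.

    ``frames`` maps a contrast label to a DataFrame indexed by gene with
    columns ``score_up`` and ``score_down``; each column sums to 1.
    """

    frames: dict[str, pd.DataFrame]
    metadata: dict = field(default_factory=dict)

    def groups(self) -> list[str]:
        return list(self.frames)

    def frame(self, group: str) -> pd.DataFrame:
        if group not in self.frames:
            raise InvalidArgumentError(f"no scores for group {group!r}; have {list(self.frames)}")
        return self.frames[group]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gene, group, score_up, score_down."""
        parts = []
        for group, frame in self.frames.items():
            part = frame.reset_index(names="gene")
            part.insert(1, "group", group)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


def score_all_groups(
    network: InteractionNetwork,
    seed_sets: Mapping[str, Mapping[str, Iterable]],
    config: RWRConfig | None = None,
) -> RWRScoreTable:
    """Run the four restart walks (up/down seeds for each contrast).

    ``seed_sets`` maps group label -> {"up": genes, "down": genes}. Raises
    :class:`InvalidSeedsError` naming any seed set with no gene in the network.
    """
    config = config or RWRConfig()
    frames: dict[str, pd.DataFrame] = {}
    meta: dict[str, dict] = {}
    node_set = set(network.graph.nodes)
    for group, directions in seed_sets.items():
        cols = {}
        meta[group] = {}
        for direction in ("up", "down"):
            seeds = set(directions.get(direction, ()))
            effective = seeds & node_set
            if not effective:
                raise InvalidSeedsError(
                    f"seed set ({group}, {direction}) has no gene in the network"
                )
            cols[f"score_{direction}"] = random_walk_restart(network, effective, config)
            meta[group][direction] = {"n_seeds": len(seeds), "n_effective": len(effective)}
        frames[group] = pd.DataFrame(cols)
        logger.info("RWR scores for %s: seeds %s", group, meta[group])
    return RWRScoreTable(frames=frames, metadata=meta)
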