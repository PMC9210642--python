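import numpy as np
import pandas as pd
import pytest

from subpathnet.netprop import InteractionNetwork, RWRScoreTable


def make_score_table(n_genes: int, seed: int = 0, groups=("MicT/MacT",)) -> RWRScoreTable:
    """Synthetic propagation-score table with i.i.d. uniform scores, each
    column normalized to sum to 1 (the RWR invariant)."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    frames = {}
    for g in groups:
        up = rng.random(n_genes)
        down = rng.random(n_genes)
        frames[g] = pd.DataFrame(
            {"score_up": up / up.sum(), "score_down": down / down.sum()}, index=genes
        )
    return RWRScoreTable(frames=frames)


@pytest.fixture
def score_table():
    return make_score_table(500, seed=11)


@pytest.fixture
def path_network():
    """Tiny connected network A-B-C with full-evidence edges."""
    return InteractionNetwork.from_edges([("A", "B", 2), ("B", "C", 3)])


def random_connected_network(n, rng):
    """Random preferential-attachment graph (always connected) as an
    InteractionNetwork with evidence 2 everywhere."""
    import networkx as nx

    g = nx.barabasi_albert_graph(n, 2, seed=int(rng.integers(2**31)))
    return InteractionNetwork.from_edges([(f"N{u}", f"N{v}", 2) for u, v in g.edges])
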