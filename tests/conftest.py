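"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math
from collections import Counter

import networkx as nx
import pytest

from iacd.graph_io import Network
from iacd.synthetic import figure1_fixture

# ---------------------------------------------------------------------------
# frozen reference rows of the 16-node worked example (nodes 1..16)

EXAMPLE_DEG = (5, 4, 4, 5, 3, 4, 4, 2, 5, 4, 5, 4, 4, 2, 2, 3)
EXAMPLE_KSCORE = (3, 3, 3, 3, 3, 3, 3, 2, 3, 3, 3, 3, 2, 2, 2, 2)
EXAMPLE_IF = (15, 12, 12, 15, 9, 12, 12, 4, 15, 12, 15, 12, 8, 4, 4, 6)
EXAMPLE_GIF_2DP = (1.0, 0.8, 0.8, 1.0, 0.6, 0.8, 0.8, 0.27,
                   1.0, 0.8, 1.0, 0.8, 0.53, 0.27, 0.27, 0.4)
EXAMPLE_PAIRS = (4, 1, 1, 1, 1, 9, 9, 9, 6, 9, 10, 11, 16, 13, 13, 13)
EXAMPLE_COMMUNITIES = (
    frozenset({"1", "2", "3", "4", "5"}),
    frozenset({"6", "7", "8", "9", "10", "11", "12"}),
    frozenset({"13", "14", "15", "16"}),
)
EXAMPLE_NODE1_ATTR = {"2": 0.64, "3": 0.64, "4": 0.8, "5": 0.36,
                      "6": 0.08, "9": 0.1, "10": 0.08, "11": 0.4}
EXAMPLE_NODE1_SL = {"2": 1, "3": 1, "4": 1, "5": 1, "6": 2,
                    "9": 2, "10": 2, "11": 1, "12": 2}


@pytest.fixture(scope="session")
def example():
    """The validated 16-node worked-example benchmark instance."""
    return figure1_fixture()


@pytest.fixture(scope="session")
def example_net(example):
    return example.network


def random_network(n: int, p: float, seed: int) -> Network:
    return Network(nx.gnp_random_graph(n, p, seed=seed))


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_core_numbers(net: Network) -> dict[str, int]:
    """k-core index by literal iterative pruning, independent of networkx."""
    scores = {v: 0 for v in net.nodes}
    k = 1
    alive = set(net.nodes)
    adj = {v: net.neighbors(v) for v in net.nodes}
    while alive:
        # peel all nodes of degree < k within the surviving subgraph
        while True:
            doomed = {v for v in alive
                      if sum(1 for u in adj[v] if u in alive) < k}
            if not doomed:
                break
            alive -= doomed
        for v in alive:
            scores[v] = k
        k += 1
    return scores


def pair_counting_ari(labels_a: dict, labels_b: dict) -> float:
    """Adjusted Rand index by exhaustive enumeration of node pairs."""
    nodes = sorted(labels_a)
    together_a = together_b = together_both = 0
    n_pairs = 0
    for u, v in itertools.combinations(nodes, 2):
        n_pairs += 1
        sa = labels_a[u] == labels_a[v]
        sb = labels_b[u] == labels_b[v]
        together_a += sa
        together_b += sb
        together_both += sa and sb
    expected = together_a * together_b / n_pairs if n_pairs else 0.0
    max_index = (together_a + together_b) / 2.0
    if max_index == expected:
        return 1.0
    return (together_both - expected) / (max_index - expected)


def contingency_nmi(labels_a: dict, labels_b: dict) -> float:
    """NMI with arithmetic normalisation, from raw label lists."""
    nodes = sorted(labels_a)
    n = len(nodes)
    ca = Counter(labels_a[v] for v in nodes)
    cb = Counter(labels_b[v] for v in nodes)
    joint = Counter((labels_a[v], labels_b[v]) for v in nodes)
    ha = -sum(c / n * math.log(c / n) for c in ca.values())
    hb = -sum(c / n * math.log(c / n) for c in cb.values())
    if ha + hb == 0.0:
        return 1.0
    mi = sum(
        c / n * math.log(n * c / (ca[a] * cb[b]))
        for (a, b), c in joint.items()
    )
    return 2.0 * mi / (ha + hb)


def plurality_purity(labels_pred: dict, labels_true: dict) -> float:
    """Purity by direct per-community plurality counting."""
    groups: dict = {}
    for v, c in labels_pred.items():
        groups.setdefault(c, []).append(v)
    correct = sum(
        Counter(labels_true[v] for v in members).most_common(1)[0][1]
        for members in groups.values()
    )
    return correct / len(labels_pred)


def random_labelings(n: int, seed: int) -> tuple[dict, dict]:
    """A random pair of labelings of n nodes (for metric cross-checks)."""
    import random as _random

    rng = _random.Random(seed)
    nodes = [str(i) for i in range(n)]
    ka = rng.randint(1, n)
    kb = rng.randint(1, n)
    a = {v: str(rng.randrange(ka)) for v in nodes}
    b = {v: str(rng.randrange(kb)) for v in nodes}
    return a, b
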