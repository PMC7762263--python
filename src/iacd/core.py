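"""Community detection by internode attraction (IACD).

The method is parameter-free and runs in three stages:

1. **Influence.**  Every node gets an influence score
   ``IF(v) = Deg(v) * KScore(v)`` combining its local connectivity with its
   global position from k-core decomposition, normalised to
   ``GIF(v) = IF(v) / MAX_IF`` in [0, 1].

2. **Attraction and pairing.**  For each node ``v`` and each candidate ``m``
   in its (closed) second-order neighborhood, a gravity-style attraction

       Attr(v, m) = P(v, m) * GIF(v) * GIF(m) / SL(v, m)^2

   is computed, where ``P(v, m) = (Triangle(v, m) + 1) / Deg(v)`` counts
   shared triangles and ``SL`` is the shortest path length (1 or 2 within
   the candidate set).  Each node is paired with its strongest attractor
   (maximal ``Attr``, ties to the smaller ``SL``, remaining ties by policy).

3. **Merging.**  The pairs ``{v, MAX_Strong(v)}`` are treated as edges of an
   auxiliary graph; its connected components (computed with union-find, so
   the result is independent of pair order) are the output communities.

All arithmetic is exact rational-over-float at full precision; rounding to
two decimals happens only for display.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Literal, Mapping

import networkx as nx
from networkx.utils.union_find import UnionFind

from .graph_io import Network, Partition, label_sort_key

__all__ = [
    "DegenerateNetworkError",
    "InfluenceTable",
    "AttractionRecord",
    "PairTable",
    "TiePolicy",
    "kcore_scores",
    "influence_table",
    "triangle_count",
    "candidate_set",
    "shortest_level",
    "attraction",
    "max_strong",
    "build_pair_table",
    "merge_communities",
    "detect",
]

TiePolicy = Literal["lowest-label", "random"]


class DegenerateNetworkError(ValueError):
    """Raised when influence is undefined (edgeless network: MAX_IF = 0)."""


# ---------------------------------------------------------------------------
# Stage 1: node influence


def kcore_scores(net: Network) -> dict[str, int]:
    """k-core (k-shell) index of every node; isolated nodes score 0.

    The score of ``v`` is the largest ``k`` such that ``v`` survives the
    iterative removal of all nodes of degree < ``k``.
    """
    return dict(nx.core_number(net.graph))


@dataclass(frozen=True)
class InfluenceTable:
    """Per-node Deg, KScore, IF = Deg*KScore and GIF = IF/MAX_IF."""

    deg: Mapping[str, int]
    kscore: Mapping[str, int]
    influence: Mapping[str, int]
    gif: Mapping[str, float]
    max_if: float

    def row(self, v: str) -> tuple[int, int, int, float]:
        return (self.deg[v], self.kscore[v], self.influence[v], self.gif[v])


def influence_table(net: Network) -> InfluenceTable:
    """Compute influence and normalised (global) influence for all nodes.

    Raises :class:`DegenerateNetworkError` on an edgeless network, where
    the normaliser MAX_IF would be zero.
    """
    if net.n_edges == 0:
        raise DegenerateNetworkError("edgeless network: MAX_IF = 0")
    kscore = kcore_scores(net)
    deg = {v: net.degree(v) for v in net.nodes}
    inf = {v: deg[v] * kscore[v] for v in net.nodes}
    max_if = max(inf.values())
    gif = {v: inf[v] / max_if for v in net.nodes}
    return InfluenceTable(deg=deg, kscore=kscore, influence=inf, gif=gif, max_if=max_if)


# ---------------------------------------------------------------------------
# Stage 2: attraction and strongest-attractor pairing


def triangle_count(net: Network, v: str, m: str) -> int:
    """Number of triangles through the pair: ``|N(v) ∩ N(m)|``."""
    if v == m:
        raise ValueError("triangle_count requires two distinct nodes")
    return len(net.neighbors(v) & net.neighbors(m))


def candidate_set(net: Network, v: str) -> set[str]:
    """All nodes within distance 2 of ``v`` reachable through its neighbors.

    This is ``N(v) ∪ ⋃_{n∈N(v)} N(n)`` minus ``v`` itself: the strict
    second-order neighborhood closed over the direct neighbors, so that a
    pendant neighbor sharing no triangle with ``v`` still qualifies.
    """
    first = net.neighbors(v)
    out = set(first)
    for n in first:
        out |= net.neighbors(n)
    out.discard(v)
    return out


def shortest_level(net: Network, v: str, m: str) -> int:
    """Shortest path length within the candidate neighborhood: 1 if
    adjacent, else 2 (candidates are within distance 2 by construction)."""
    return 1 if net.has_edge(v, m) else 2


@dataclass(frozen=True)
class AttractionRecord:
    """Directional attraction of ``target`` on ``source``."""

    source: str
    target: str
    triangles: int
    p: float
    sl: int
    attr: float


def attraction(net: Network, inf: InfluenceTable, v: str, m: str) -> AttractionRecord:
    """Attraction of ``m`` on ``v``; ``m`` must lie in ``candidate_set(v)``."""
    if m not in candidate_set(net, v):
        raise ValueError(f"{m!r} is not in the candidate neighborhood of {v!r}")
    tri = triangle_count(net, v, m)
    p = (tri + 1) / inf.deg[v]
    sl = shortest_level(net, v, m)
    attr = p * inf.gif[v] * inf.gif[m] / sl**2
    return AttractionRecord(source=v, target=m, triangles=tri, p=p, sl=sl, attr=attr)


def max_strong(
    net: Network,
    inf: InfluenceTable,
    v: str,
    tie_policy: TiePolicy = "lowest-label",
    rng: random.Random | None = None,
) -> str | None:
    """The candidate exerting maximal attraction on ``v``.

    Selection: maximal ``Attr``; among those, minimal ``SL``; remaining
    ties broken by the smallest label (default) or a seeded random draw.
    Returns ``None`` when the candidate set is empty (isolated node).
    Attraction values are compared exactly — they are short rational
    expressions, and an epsilon would silently change tie semantics.
    """
    candidates = candidate_set(net, v)
    if not candidates:
        return None
    records = [attraction(net, inf, v, m) for m in candidates]
    best_attr = max(r.attr for r in records)
    best = [r for r in records if r.attr == best_attr]
    min_sl = min(r.sl for r in best)
    best = [r for r in best if r.sl == min_sl]
    if len(best) == 1:
        return best[0].target
    if tie_policy == "lowest-label":
        return min((r.target for r in best), key=label_sort_key)
    if tie_policy == "random":
        if rng is None:
            raise ValueError("tie_policy='random' requires a seeded rng")
        return rng.choice(sorted((r.target for r in best), key=label_sort_key))
    raise ValueError(f"unknown tie policy {tie_policy!r}")


@dataclass(frozen=True)
class PairTable:
    """One (node, strongest attractor) record per non-isolated node, in
    stable label order; isolated nodes listed separately."""

    records: tuple[tuple[str, str], ...]
    isolated: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, str]:
        return dict(self.records)


def build_pair_table(
    net: Network,
    inf: InfluenceTable | None = None,
    tie_policy: TiePolicy = "lowest-label",
    seed: int | None = None,
) -> PairTable:
    """Pair every non-isolated node with its strongest attractor."""
    if inf is None:
        inf = influence_table(net)
    rng = random.Random(seed) if tie_policy == "random" else None
    if tie_policy == "random" and seed is None:
        raise ValueError("tie_policy='random' requires a seed")
    if tie_policy not in ("lowest-label", "random"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    # Precomputed adjacency fast path; arithmetic is kept expression-for-
    # expression identical to attraction()/max_strong() so both routes give
    # bit-identical scores and therefore identical tie behavior.
    g = net.graph
    adj = {v: set(g[v]) for v in g}
    gif = inf.gif
    deg = inf.deg
    records: list[tuple[str, str]] = []
    isolated: list[str] = []
    for v in net.nodes:
        nbrs = adj[v]
        if not nbrs:
            isolated.append(v)
            continue
        cand = set(nbrs)
        for n_ in nbrs:
            cand |= adj[n_]
        cand.discard(v)
        gif_v = gif[v]
        deg_v = deg[v]
        best_key: tuple[float, int] | None = None
        best_targets: list[str] = []
        for m in cand:
            tri = len(nbrs & adj[m])
            p = (tri + 1) / deg_v
            sl = 1 if m in nbrs else 2
            attr = p * gif_v * gif[m] / sl**2
            key = (attr, -sl)
            if best_key is None or key > best_key:
                best_key, best_targets = key, [m]
            elif key == best_key:
                best_targets.append(m)
        if len(best_targets) == 1:
            target = best_targets[0]
        elif tie_policy == "lowest-label":
            target = min(best_targets, key=label_sort_key)
        else:
            target = rng.choice(sorted(best_targets, key=label_sort_key))
        records.append((v, target))
    return PairTable(records=tuple(records), isolated=tuple(isolated))


# ---------------------------------------------------------------------------
# Stage 3: community merging


def merge_communities(pairs: PairTable, all_nodes: set[str] | list[str]) -> Partition:
    """Union the pair endpoints into communities.

    Equivalent to connected components of the undirected graph whose edges
    are ``{v, MAX_Strong(v)}`` — union-find semantics, so the result does
    not depend on the order of the pair records.  Nodes absent from the
    table (isolated) become singleton communities.
    """
    all_nodes = {str(v) for v in all_nodes}
    for v, m in pairs.records:
        if v not in all_nodes or m not in all_nodes:
            raise ValueError(f"pair ({v!r}, {m!r}) references a node outside the network")
    uf = UnionFind(all_nodes)
    for v, m in pairs.records:
        uf.union(v, m)
    return Partition.from_communities(uf.to_sets())


def detect(
    net: Network,
    tie_policy: TiePolicy = "lowest-label",
    seed: int | None = None,
) -> Partition:
    """Run the full pipeline: influence -> pairing -> merge.

    Deterministic under the default tie policy; a multi-node edgeless
    network yields all-singleton communities instead of an error.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot detect communities in an empty network")
    if net.n_edges == 0:
        return Partition.from_communities([{v} for v in net.nodes])
    inf = influence_table(net)
    pairs = build_pair_table(net, inf, tie_policy=tie_policy, seed=seed)
    return merge_communities(pairs, set(net.nodes))
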