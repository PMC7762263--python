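"""Graph and partition data model plus file readers/writers.

The attraction-based detector operates on undirected, unweighted simple
graphs.  Node labels are kept as opaque strings externally; all ordering
(table rows, tie-breaks, canonical community identifiers) uses a natural
sort key so that integer-labelled inputs behave the way a human reading
the tables expects ("2" before "10").

Supported formats:

* edge list — two whitespace-separated labels per line, ``#`` comments;
* GML (undirected) via :mod:`networkx`;
* community/partition files — one ``node<TAB>label`` record per line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Network",
    "Partition",
    "GroundTruth",
    "GraphFormatError",
    "EdgeListParseError",
    "label_sort_key",
    "read_edge_list",
    "read_gml",
    "write_gml",
    "read_communities",
    "write_partition",
]


class GraphFormatError(ValueError):
    """Raised for malformed or unsupported graph / community files."""


class EdgeListParseError(GraphFormatError):
    """Raised when an edge-list line cannot be parsed; carries the line number."""

    def __init__(self, message: str, lineno: int):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def label_sort_key(label: str) -> tuple[int, int | str]:
    """Natural ordering for node labels: numeric labels sort numerically,
    everything else lexicographically after them."""
    s = str(label)
    if s.isdigit():
        return (0, int(s))
    return (1, s)


class Network:
    """Undirected, unweighted simple graph with stable node ordering.

    Thin wrapper over :class:`networkx.Graph` that enforces simplicity
    (no self-loops, no parallel edges) and string node labels.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._g = nx.Graph()
        if graph is not None:
            for v in graph.nodes:
                self._g.add_node(str(v))
            for u, v in graph.edges:
                u, v = str(u), str(v)
                if u != v:
                    self._g.add_edge(u, v)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        warn: bool = True,
    ) -> "Network":
        """Build a network, collapsing duplicate edges and dropping self-loops.

        ``nodes`` may add isolated nodes not mentioned by any edge.
        """
        net = cls()
        g = net._g
        n_dup = n_loop = 0
        for node in nodes:
            g.add_node(str(node))
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                n_loop += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
        if warn and n_loop:
            warnings.warn(f"dropped {n_loop} self-loop(s)", stacklevel=2)
        if warn and n_dup:
            warnings.warn(f"collapsed {n_dup} duplicate edge(s)", stacklevel=2)
        return net

    # -- basic accessors -------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The backing networkx graph (treat as read-only)."""
        return self._g

    @property
    def nodes(self) -> list[str]:
        return sorted(self._g.nodes, key=label_sort_key)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self._g.edges}

    def neighbors(self, v: str) -> set[str]:
        if v not in self._g:
            raise KeyError(f"unknown node {v!r}")
        return set(self._g[v])

    def degree(self, v: str) -> int:
        if v not in self._g:
            raise KeyError(f"unknown node {v!r}")
        return self._g.degree[v]

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def __contains__(self, v: str) -> bool:
        return v in self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Network(n={self.n_nodes}, e={self.n_edges})"


@dataclass(frozen=True)
class Partition:
    """Disjoint cover of a node set: node -> community identifier."""

    assignment: Mapping[str, str]

    def __post_init__(self):
        if any(v is None for v in self.assignment.values()):
            raise ValueError("community identifier may not be None")

    @classmethod
    def from_communities(cls, communities: Iterable[Iterable[str]]) -> "Partition":
        """Build from member sets; the canonical identifier of each community
        is its smallest member label."""
        assignment: dict[str, str] = {}
        for members in communities:
            members = [str(m) for m in members]
            if not members:
                raise ValueError("empty community")
            cid = min(members, key=label_sort_key)
            for m in members:
                if m in assignment:
                    raise ValueError(f"node {m!r} assigned to two communities")
                assignment[m] = cid
        return cls(assignment=dict(assignment))

    @property
    def communities(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return out

    @property
    def nodes(self) -> set[str]:
        return set(self.assignment)

    def __len__(self) -> int:
        return len(set(self.assignment.values()))

    def community_sets(self) -> list[set[str]]:
        """Member sets in canonical (smallest-member) order."""
        comms = self.communities
        return [comms[c] for c in sorted(comms, key=label_sort_key)]

    def relabeled_canonical(self) -> "Partition":
        """Same partition with every identifier replaced by the smallest
        member label of its community."""
        return Partition.from_communities(self.communities.values())


@dataclass(frozen=True)
class GroundTruth:
    """Reference classification: node -> class label."""

    assignment: Mapping[str, str]

    @property
    def nodes(self) -> set[str]:
        return set(self.assignment)

    @property
    def classes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for node, label in self.assignment.items():
            out.setdefault(label, set()).add(node)
        return out

    def as_partition(self) -> Partition:
        return Partition(assignment=dict(self.assignment))


# -- readers / writers ----------------------------------------------------


def read_edge_list(path: str | Path, node_list: str | Path | None = None) -> Network:
    """Read a whitespace-delimited edge list (two labels per line).

    Duplicate edges are collapsed and self-loops dropped, each with a
    warning.  Lines starting with ``#`` are ignored.  ``node_list`` may
    name a sidecar file of one label per line to add isolated nodes.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"expected two node labels, got {line!r}", lineno
                )
            edges.append((tokens[0], tokens[1]))
    if not edges:
        raise GraphFormatError(f"{path}: no edges found (empty network)")
    extra_nodes: list[str] = []
    if node_list is not None:
        with Path(node_list).open() as fh:
            extra_nodes = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    return Network.from_edges(edges, nodes=extra_nodes)


def read_gml(path: str | Path) -> Network:
    """Read an undirected GML graph; directed graphs are rejected."""
    g = nx.read_gml(str(path), label="label")
    if g.is_directed():
        raise GraphFormatError(f"{path}: directed graphs are unsupported")
    return Network(g)


def write_gml(net: Network, path: str | Path) -> None:
    if net.n_nodes == 0:
        raise GraphFormatError("refusing to write an empty (zero-node) graph")
    nx.write_gml(net.graph, str(path))


def read_communities(path: str | Path) -> GroundTruth:
    """Read a ``node<TAB>label`` file (any whitespace accepted as separator)."""
    assignment: dict[str, str] = {}
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split(None, 1)
            if len(tokens) != 2:
                raise EdgeListParseError(
                    f"expected 'node<TAB>label', got {line!r}", lineno
                )
            node, label = tokens[0], tokens[1].strip()
            if node in assignment and assignment[node] != label:
                raise GraphFormatError(
                    f"{path}: node {node!r} listed with conflicting labels "
                    f"{assignment[node]!r} and {label!r}"
                )
            assignment[node] = label
    return GroundTruth(assignment=assignment)


def write_partition(p: Partition | GroundTruth, path: str | Path) -> None:
    """Write one ``node<TAB>community`` record per line, in label order."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for node in sorted(p.assignment, key=label_sort_key):
            fh.write(f"{node}\t{p.assignment[node]}\n")
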