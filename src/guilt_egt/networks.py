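"""Interaction topologies: complete graph, periodic lattice, scale-free bank.

Graphs are plain :class:`networkx.Graph` objects with integer node ids
``0..N-1``, no self-loops and no parallel edges; the interaction network
doubles as the imitation network.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "NetworkStats",
    "network_stats",
    "validate_graph",
    "complete_graph",
    "periodic_lattice",
    "barabasi_albert",
    "preseed_networks",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    mean_degree: float
    min_degree: int
    max_degree: int
    degree_histogram: tuple[int, ...]


def network_stats(graph: nx.Graph) -> NetworkStats:
    degrees = [d for _, d in graph.degree()]
    return NetworkStats(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        mean_degree=2.0 * graph.number_of_edges() / graph.number_of_nodes(),
        min_degree=min(degrees),
        max_degree=max(degrees),
        degree_histogram=tuple(nx.degree_histogram(graph)),
    )


def validate_graph(graph: nx.Graph, require_connected: bool = True) -> None:
    """Check the package's graph invariants, raising ValueError on failure."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("graph has no nodes")
    if sorted(graph.nodes()) != list(range(n)):
        raise ValueError("node ids must be 0..N-1")
    if any(u == v for u, v in graph.edges()):
        raise ValueError("graph contains a self-loop")
    if require_connected and not nx.is_connected(graph):
        raise ValueError("graph is not connected")


def complete_graph(n: int) -> nx.Graph:
    """Well-mixed topology: all N(N-1)/2 pairs interact."""
    if n < 2:
        raise ValueError("complete graph needs N >= 2")
    return nx.complete_graph(n)


def periodic_lattice(rows: int, cols: int) -> nx.Graph:
    """Square lattice with von Neumann neighbourhood and periodic boundaries.

    Every node has degree exactly 4 and the graph has 2 * rows * cols
    edges.  Dimensions below 3 would wrap onto duplicate edges and are
    rejected.
    """
    if rows < 3 or cols < 3:
        raise ValueError("periodic lattice requires rows >= 3 and cols >= 3")
    g = nx.Graph()
    g.add_nodes_from(range(rows * cols))
    for r in range(rows):
        for c in range(cols):
            u = r * cols + c
            g.add_edge(u, ((r + 1) % rows) * cols + c)
            g.add_edge(u, r * cols + (c + 1) % cols)
    return g


def barabasi_albert(n: int, m: int, m0: int | None = None, seed: int | None = None) -> nx.Graph:
    """Scale-free graph by growth and preferential attachment.

    Starts from ``m0`` fully interconnected seed nodes (default ``m + 1``,
    so every seed node has nonzero degree and attachment probabilities are
    well defined without an initial-attractiveness constant); each arriving
    node links to ``m`` distinct existing nodes chosen with probability
    proportional to current degree.  Mean degree approaches ``2 m``.
    """
    if m0 is None:
        m0 = m + 1
    if not (m >= 1 and m0 >= m and n >= m0):
        raise ValueError("require N >= m0 >= m >= 1")
    if n == m0:
        return nx.complete_graph(n)
    return nx.barabasi_albert_graph(n, m, seed=seed, initial_graph=nx.complete_graph(m0))


def preseed_networks(
    count: int, n: int = 1000, m: int = 2, base_seed: int = 0
) -> list[nx.Graph]:
    """Deterministic bank of scale-free graphs derived from one base seed."""
    if count < 1:
        raise ValueError("count must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(count) % (2**31)
    return [barabasi_albert(n, m, seed=int(s)) for s in seeds]


def write_edge_list(graph: nx.Graph, path: str | os.PathLike) -> None:
    """Write 'u v' pairs, one edge per line, 0-based ids."""
    with open(path, "w") as fh:
        fh.write(f"# nodes: {graph.number_of_nodes()}\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u} {v}\n")


def read_edge_list(path: str | os.PathLike) -> nx.Graph:
    """Read an undirected edge list; rejects malformed lines with a location.

    Lines are whitespace-separated integer pairs; '#' starts a comment.
    Self-loops, duplicate edges and non-integer tokens are parse errors.
    Node count is inferred as max id + 1.
    """
    g = nx.Graph()
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tokens, got {len(tokens)}")
            try:
                u, v = int(tokens[0]), int(tokens[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer node id in {line!r}")
            if u < 0 or v < 0:
                raise ValueError(f"{path}:{lineno}: negative node id")
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u}-{v}")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise ValueError(f"{path}:{lineno}: duplicate edge {u}-{v}")
            seen.add(key)
            g.add_edge(u, v)
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: no edges found")
    g.add_nodes_from(range(max(g.nodes()) + 1))
    return g
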