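"""Synthetic networks: random-graph generators and named toy fixtures.

ER graphs give a homogeneous degree regime, BA graphs a heavy-tailed
one; the toy registry holds small hand-checkable graphs whose attribute
values can be verified by hand.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

__all__ = ["generate_er", "generate_ba", "toy_graph", "TOY_NAMES"]


def generate_er(n: int, p: float, rng_seed: int) -> nx.Graph:
    """Erdos-Renyi G(n, p): each pair is an edge independently with prob p."""
    if n < 1:
        raise ValueError("generate_er: n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"generate_er: p must be in [0, 1], got {p}")
    return nx.gnp_random_graph(n, p, seed=rng_seed)


def generate_ba(n: int, m: int, rng_seed: int) -> nx.Graph:
    """Barabasi-Albert preferential attachment.

    Starts from a complete graph on m+1 nodes; each subsequent node
    attaches to m distinct existing nodes chosen with probability
    proportional to degree, giving exactly m(n-m-1) + C(m+1, 2) edges.
    """
    if not 1 <= m < n:
        raise ValueError(f"generate_ba: need 1 <= m < n, got m={m}, n={n}")
    rng = np.random.default_rng(rng_seed)
    g = nx.complete_graph(m + 1)
    # degree-proportional sampling via a repeated-nodes urn
    urn = [x for e in g.edges() for x in e]
    for new in range(m + 1, n):
        targets = set()
        while len(targets) < m:
            targets.add(urn[rng.integers(len(urn))])
        for t in targets:
            g.add_edge(new, t)
            urn.extend((new, t))
    return g


def _edges(*pairs):
    def build():
        g = nx.Graph()
        g.add_edges_from(pairs)
        return g

    return build


_TOYS = {
    "triangle": lambda: nx.complete_graph([1, 2, 3]),
    "k4": lambda: nx.complete_graph(4),
    "k5": lambda: nx.complete_graph(5),
    "c5": lambda: nx.cycle_graph([1, 2, 3, 4, 5]),
    "p3": lambda: nx.path_graph([1, 2, 3]),
    "p5": lambda: nx.path_graph([1, 2, 3, 4, 5]),
    "star5": lambda: nx.star_graph(5),
    "star20": lambda: nx.star_graph(20),
    "triangle_tail": _edges((1, 2), (1, 3), (2, 3), (3, 4), (4, 5)),
    "two_triangles": _edges((1, 2), (1, 3), (2, 3), (4, 5), (4, 6), (5, 6)),
}

TOY_NAMES = tuple(sorted(_TOYS))


def toy_graph(name: str) -> nx.Graph:
    """A fixed, hand-auditable labeled graph from the fixture registry."""
    try:
        return _TOYS[name]()
    except KeyError:
        raise KeyError(f"unknown toy graph {name!r}; known: {', '.join(TOY_NAMES)}") from None
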