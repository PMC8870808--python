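"""Shared fixtures and independent oracles.

The oracles re-derive quantities by a different route than the package
(distance matrices, exhaustive geodesic enumeration, straight-from-the-
formula numpy evaluation) so agreement is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np
import networkx as nx
import pytest

from lwcent import toy_graph
from lwcent.generators import TOY_NAMES


@pytest.fixture
def triangle_tail():
    return toy_graph("triangle_tail")


@pytest.fixture(params=TOY_NAMES)
def any_toy(request):
    return toy_graph(request.param)


def small_toys(max_nodes=8):
    return [n for n in TOY_NAMES if toy_graph(n).number_of_nodes() <= max_nodes]


# ---------------------------------------------------------------- oracles


def two_hop_degree_oracle(g: nx.Graph) -> dict:
    """Count nodes at shortest-path distance 1 or 2, via full APSP."""
    dist = dict(nx.all_pairs_shortest_path_length(g))
    return {
        v: sum(1 for u, d in dist[v].items() if 1 <= d <= 2) for v in g.nodes()
    }


def betweenness_oracle(g: nx.Graph) -> dict:
    """Brute-force enumeration of all geodesics of all unordered pairs."""
    b = {v: 0.0 for v in g.nodes()}
    for j, s in itertools.combinations(g.nodes(), 2):
        if not nx.has_path(g, j, s):
            continue
        paths = list(nx.all_shortest_paths(g, j, s))
        for v in g.nodes():
            if v in (j, s):
                continue
            through = sum(1 for p in paths if v in p)
            b[v] += through / len(paths)
    return b


def lwc_oracle(g: nx.Graph) -> dict:
    """Direct evaluation of the six pipeline steps with plain numpy.

    Attributes are recomputed from scratch (degree, neighbor-edge counts,
    distance-2 balls) without using any lwcent intermediate type.
    """
    nodes = sorted(g.nodes(), key=lambda v: (str(type(v).__name__), v) if not isinstance(v, str) else ("str", v))
    n = len(nodes)
    k = np.array([g.degree(v) for v in nodes], dtype=float)

    def clc_of(v):
        nbrs = list(g[v])
        kk = len(nbrs)
        if kk <= 1:
            return 0.0
        e = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
        return 2.0 * e / (kk * (kk - 1))

    clc = np.array([clc_of(v) for v in nodes])
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=2))
    thk = np.array(
        [sum(1 for u, d in dist[v].items() if 1 <= d <= 2) for v in nodes], dtype=float
    )
    thclc = np.array([sum(clc_of(u) for u in g[v]) for v in nodes])

    P = np.column_stack([k, thk, clc, thclc])
    R = np.zeros_like(P)
    for j in range(4):
        col = P[:, j]
        if col.max() > 0:
            d = col / col.max()
            R[:, j] = d / d.sum()
    E = np.zeros(4)
    for j in range(4):
        r = R[:, j]
        mask = r > 0
        E[j] = -(r[mask] * np.log(r[mask])).sum() / np.log(n)
    one_minus = 1.0 - E
    one_minus[~np.any(R > 0, axis=0)] = 0.0
    if one_minus.sum() < 1e-12:
        live = np.any(R > 0, axis=0)
        w = np.zeros(4)
        if live.any():
            w[live] = 1.0 / live.sum()
        else:
            w[:] = 0.25
    else:
        w = one_minus / one_minus.sum()
    scores = R @ w
    return dict(zip(nodes, scores))


def kendall_tau_a_oracle(x, y) -> float:
    """Literal pairwise sign sum over i < j."""
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            s += np.sign((x[i] - x[j]) * (y[i] - y[j]))
    return s / (0.5 * n * (n - 1))
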