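"""The four local attributes feeding the weighted centrality.

Node influence is split into a *direct* part, exerted on one-hop
neighbors, and an *indirect* part reaching two hops out:

* degree ``k``                        (direct)
* clustering coefficient ``clc``      (direct)
* two-hop degree ``thk``              (indirect) — the number of distinct
  nodes within graph distance <= 2 of a node, excluding the node itself;
  overlapping neighborhoods are counted once
* two-hop clustering coefficient ``thclc`` (indirect) — the sum of the
  clustering coefficients of a node's one-hop neighbors

All vectors are returned as :class:`pandas.Series` indexed by node label
in the package's canonical (sorted) node order.
"""

from __future__ import annotations

import pandas as pd
import networkx as nx

from .graphio import node_order

__all__ = [
    "ATTRIBUTES",
    "degree_vector",
    "clustering_vector",
    "two_hop_degree_vector",
    "two_hop_clustering_vector",
]

#: fixed attribute (column) order of the decision matrix
ATTRIBUTES = ("k", "thk", "clc", "thclc")


def degree_vector(net: nx.Graph) -> pd.Series:
    """Degree k_i of every node."""
    order = node_order(net)
    return pd.Series([net.degree(v) for v in order], index=order, name="k", dtype=float)


def clustering_vector(net: nx.Graph) -> pd.Series:
    """Clustering coefficient clc_i = 2 e_i / (k_i (k_i - 1)).

    ``e_i`` counts edges among i's neighbors; nodes with degree <= 1 get 0.
    """
    order = node_order(net)
    clc = nx.clustering(net)
    return pd.Series([clc[v] for v in order], index=order, name="clc", dtype=float)


def two_hop_degree_vector(net: nx.Graph) -> pd.Series:
    """Two-hop degree thk_i: distinct nodes within distance <= 2, minus i."""
    order = node_order(net)
    values = []
    for v in order:
        reach = set(net[v])
        for u in list(reach):
            reach.update(net[u])
        reach.discard(v)
        values.append(len(reach))
    return pd.Series(values, index=order, name="thk", dtype=float)


def two_hop_clustering_vector(net: nx.Graph) -> pd.Series:
    """Two-hop clustering coefficient thclc_i = sum of clc_j over neighbors j."""
    order = node_order(net)
    clc = nx.clustering(net)
    values = [sum(clc[u] for u in net[v]) for v in order]
    return pd.Series(values, index=order, name="thclc", dtype=float)
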