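"""Baseline centrality measures used for comparison with LWC.

* betweenness — fraction of shortest paths through a node, summed over
  unordered pairs, endpoints excluded, unnormalized (Brandes algorithm).
* closeness — reciprocal of the sum of distances on connected graphs;
  on graphs with unreachable pairs the harmonic form sum_j 1/d_ij with
  1/inf = 0 is used instead, the two conventions coinciding in spirit
  (a node close to many others scores high) while keeping values finite.
* local centrality — two-level aggregation of two-hop neighborhood
  sizes: N(w) = #nodes within two hops of w, Q(u) = sum of N over u's
  neighbors, CL(v) = sum of Q over v's neighbors.
* clustered local degree — (1 + clc_i) * sum of the degrees of i's
  neighbors, rewarding nodes whose neighborhood is both large and
  cohesive.
"""

from __future__ import annotations

import pandas as pd
import networkx as nx

from .attributes import clustering_vector, degree_vector, two_hop_degree_vector
from .graphio import node_order

__all__ = [
    "betweenness",
    "closeness",
    "local_centrality",
    "clustered_local_degree",
]


def betweenness(net: nx.Graph) -> pd.Series:
    """Unnormalized shortest-path betweenness b_i (Brandes accumulation)."""
    order = node_order(net)
    bc = nx.betweenness_centrality(net, normalized=False)
    return pd.Series([bc[v] for v in order], index=order, name="bc", dtype=float)


def closeness(net: nx.Graph) -> pd.Series:
    """Closeness centrality with the dual connected/harmonic convention."""
    order = node_order(net)
    n = net.number_of_nodes()
    if n == 1:
        return pd.Series([0.0], index=order, name="cc")
    if nx.is_connected(net):
        values = []
        for v in order:
            total = sum(nx.single_source_shortest_path_length(net, v).values())
            values.append(1.0 / total)
    else:
        values = []
        for v in order:
            dist = nx.single_source_shortest_path_length(net, v)
            values.append(sum(1.0 / d for u, d in dist.items() if u != v))
    return pd.Series(values, index=order, name="cc", dtype=float)


def local_centrality(net: nx.Graph) -> pd.Series:
    """Local centrality CL(v) = sum_{u in N(v)} sum_{w in N(u)} thk(w)."""
    order = node_order(net)
    thk = two_hop_degree_vector(net)
    q = {v: sum(thk[u] for u in net[v]) for v in order}
    cl = [sum(q[u] for u in net[v]) for v in order]
    return pd.Series(cl, index=order, name="localc", dtype=float)


def clustered_local_degree(net: nx.Graph) -> pd.Series:
    """Clustered local degree cld_i = (1 + clc_i) * sum of neighbor degrees."""
    order = node_order(net)
    clc = clustering_vector(net)
    k = degree_vector(net)
    values = [(1.0 + clc[v]) * sum(k[u] for u in net[v]) for v in order]
    return pd.Series(values, index=order, name="cld", dtype=float)
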