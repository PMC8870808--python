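"""Registry mapping method names to per-node score vectors."""

from __future__ import annotations

import pandas as pd
import networkx as nx

from .attributes import clustering_vector, degree_vector
from .baselines import betweenness, clustered_local_degree, closeness, local_centrality
from .ranking import Ranking, lwc_ranking, rank_nodes

__all__ = ["METHOD_NAMES", "method_scores", "method_ranking"]

_SCORERS = {
    "degree": degree_vector,
    "bc": betweenness,
    "cc": closeness,
    "localc": local_centrality,
    "cld": clustered_local_degree,
    "clc": clustering_vector,
    "lwc": None,  # handled via the full pipeline
}

METHOD_NAMES = tuple(_SCORERS)


def method_scores(net: nx.Graph, name: str) -> pd.Series:
    """Raw score vector of a named centrality method."""
    if name not in _SCORERS:
        raise KeyError(f"unknown method {name!r}; known: {', '.join(METHOD_NAMES)}")
    if name == "lwc":
        from .ranking import build_attribute_matrix, entropy_weights, lwc_scores, normalize_matrix

        R = normalize_matrix(build_attribute_matrix(net))
        return lwc_scores(R, entropy_weights(R))
    return _SCORERS[name](net)


def method_ranking(net: nx.Graph, name: str, decimals: int = 10) -> Ranking:
    """Tie-aware ranking produced by a named method."""
    return rank_nodes(method_scores(net, name), decimals=decimals)
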