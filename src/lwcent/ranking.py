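"""The multiple-local-attributes-weighted centrality (LWC) pipeline.

The algorithm treats every node as a decision alternative and its four
local attributes (k, thk, clc, thclc) as criteria of a multi-attribute
decision problem:

1. build the n x 4 decision matrix P of raw attribute values;
2. normalize each column: divide by the column maximum, then by the sum
   of those ratios, so each column is a probability distribution;
3. compute the Shannon entropy E_j of each column (natural log, scaled
   by 1/ln n so E_j is in [0, 1]);
4. weight each attribute by its *discriminating power* 1 - E_j,
   renormalized to sum to one — an attribute that varies little across
   nodes (high entropy of its normalized column ... note the column is a
   distribution over nodes, so a near-uniform column means the attribute
   does not separate nodes) receives a small weight;
5. score each node by the weighted row sum LWC_i = sum_j w_j r_ij;
6. rank nodes by descending score, ties sharing a rank.

Degenerate inputs are handled explicitly: an all-zero attribute column
(e.g. clustering on a tree) carries no information and its weight is
forced to 0; if every informative column is constant the weights fall
back to uniform (any weighting gives the same total-tie ranking).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import networkx as nx

from .attributes import (
    ATTRIBUTES,
    clustering_vector,
    degree_vector,
    two_hop_clustering_vector,
    two_hop_degree_vector,
)

__all__ = [
    "WeightVector",
    "Ranking",
    "build_attribute_matrix",
    "normalize_matrix",
    "entropy_weights",
    "lwc_scores",
    "rank_nodes",
    "lwc_ranking",
]


@dataclass(frozen=True)
class WeightVector:
    """Entropy-derived attribute weights.

    ``weights`` and ``entropies`` are Series over the four attribute
    names; weights are nonnegative and sum to 1.
    """

    weights: pd.Series
    entropies: pd.Series

    def to_dict(self) -> dict:
        return {
            "weights": {a: float(self.weights[a]) for a in ATTRIBUTES},
            "entropies": {a: float(self.entropies[a]) for a in ATTRIBUTES},
        }


@dataclass(frozen=True)
class Ranking:
    """An ordered ranking list with tie-aware dense ranks.

    Nodes are ordered by descending score; nodes whose scores are equal
    (after rounding to ``decimals``) share a rank, and ranks run 1, 2, ...
    over distinct score values.  Tied nodes are listed in label order, so
    the list is fully deterministic.
    """

    nodes: tuple
    scores: np.ndarray
    ranks: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "ranks", np.asarray(self.ranks, dtype=int))

    def __len__(self) -> int:
        return len(self.nodes)

    def top(self, t: int) -> list:
        """The first ``t`` nodes of the list (deterministic under ties)."""
        if not 1 <= t <= len(self):
            raise ValueError(f"top-{t} requested from a list of {len(self)}")
        return list(self.nodes[:t])

    def rank_of(self) -> dict:
        return dict(zip(self.nodes, self.ranks.tolist()))

    def score_of(self) -> dict:
        return dict(zip(self.nodes, self.scores.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": list(self.nodes), "score": self.scores, "rank": self.ranks}
        )


def build_attribute_matrix(net: nx.Graph) -> pd.DataFrame:
    """Decision matrix P: one row per node, columns (k, thk, clc, thclc)."""
    if net.number_of_nodes() == 0:
        raise ValueError("build_attribute_matrix: empty graph")
    cols = {
        "k": degree_vector(net),
        "thk": two_hop_degree_vector(net),
        "clc": clustering_vector(net),
        "thclc": two_hop_clustering_vector(net),
    }
    return pd.DataFrame(cols, columns=list(ATTRIBUTES))


def normalize_matrix(P: pd.DataFrame) -> pd.DataFrame:
    """Column-wise max-then-sum normalization of the decision matrix.

    Each column is divided by its maximum and then by the sum of those
    ratios, turning it into a distribution over nodes.  An all-zero
    column stays all-zero.
    """
    R = pd.DataFrame(index=P.index, columns=P.columns, dtype=float)
    for col in P.columns:
        x = P[col].to_numpy(dtype=float)
        m = x.max(initial=0.0)
        if m <= 0.0:
            R[col] = 0.0
            continue
        d = x / m
        R[col] = d / d.sum()
    return R


def entropy_weights(R: pd.DataFrame) -> WeightVector:
    """Attribute entropies and entropy weights from the normalized matrix.

    E_j = -(1/ln n) * sum_i r_ij ln r_ij   (0 ln 0 := 0)
    w_j = (1 - E_j) / sum_j (1 - E_j)

    An all-zero column gets weight 0 before renormalization; if every
    remaining column has entropy 1 (all columns constant), weights fall
    back to uniform over those columns — or over all four when no column
    is informative at all.
    """
    n = len(R)
    if n < 2:
        raise ValueError("entropy_weights: need at least 2 nodes (ln n = 0)")
    ent = {}
    degenerate = {}
    for col in R.columns:
        r = R[col].to_numpy(dtype=float)
        degenerate[col] = not np.any(r > 0)
        terms = np.where(r > 0, r * np.log(np.where(r > 0, r, 1.0)), 0.0)
        ent[col] = float(-terms.sum() / np.log(n))
    entropies = pd.Series(ent, index=list(R.columns))

    one_minus = (1.0 - entropies).clip(lower=0.0)
    for col, is_zero in degenerate.items():
        if is_zero:
            one_minus[col] = 0.0
    total = float(one_minus.sum())
    if total < 1e-12:
        live = [c for c, z in degenerate.items() if not z] or list(R.columns)
        weights = pd.Series(0.0, index=list(R.columns))
        weights[live] = 1.0 / len(live)
    else:
        weights = one_minus / total
    return WeightVector(weights=weights, entropies=entropies)


def lwc_scores(R: pd.DataFrame, w: WeightVector) -> pd.Series:
    """Per-node LWC score: the weighted row sum of the normalized matrix."""
    if list(R.columns) != list(w.weights.index):
        raise ValueError("lwc_scores: attribute columns and weights disagree")
    scores = R.to_numpy(dtype=float) @ w.weights.to_numpy(dtype=float)
    return pd.Series(scores, index=R.index, name="lwc")


def rank_nodes(scores: Mapping | pd.Series, decimals: int = 10) -> Ranking:
    """Tie-aware descending ranking of a score mapping.

    Scores are rounded to ``decimals`` places before grouping so float
    ties are detected deterministically; tied nodes are ordered by label.
    """
    if not isinstance(scores, pd.Series):
        scores = pd.Series(dict(scores))
    from .graphio import _sort_key

    items = sorted(
        scores.items(), key=lambda kv: (-round(float(kv[1]), decimals), _sort_key(kv[0]))
    )
    nodes, raw = zip(*items) if items else ((), ())
    rounded = [round(float(s), decimals) for s in raw]
    ranks = []
    current = 0
    prev = None
    for r in rounded:
        if prev is None or r != prev:
            current += 1
            prev = r
        ranks.append(current)
    return Ranking(nodes=tuple(nodes), scores=np.array(raw, dtype=float), ranks=np.array(ranks))


def lwc_ranking(net: nx.Graph, decimals: int = 10) -> tuple[Ranking, WeightVector]:
    """Full pipeline: decision matrix -> weights -> scores -> ranking."""
    P = build_attribute_matrix(net)
    R = normalize_matrix(P)
    w = entropy_weights(R)
    scores = lwc_scores(R, w)
    return rank_nodes(scores, decimals=decimals), w
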