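"""Ranking-quality metrics.

Discrimination: *monotonicity* M(S) in [0, 1] penalizes ties — with
|V|_s nodes sharing rank s,

    M(S) = [ 1 - sum_s |V|_s (|V|_s - 1) / (|V| (|V| - 1)) ]^2

and M = 1 iff every node has a unique rank; the *CCDF* of scores shows
the same information as a curve (a slower decay = more distinct ranks).

Accuracy against the SIR ground truth sigma: *Kendall's tau* (the tau-a
variant, exactly the printed pairwise-sign sum with no tie correction),
the *imprecision function* eps(p) = 1 - M(p)/M_eff(p) comparing the mean
true spreading power of a method's top p-fraction with the best
possible, and the *Jaccard coefficient* of top-T node sets.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .ranking import Ranking
from .sir import InfluenceTable

__all__ = [
    "monotonicity",
    "ccdf_curve",
    "kendall_tau",
    "imprecision",
    "jaccard_topk",
]


def monotonicity(ranking: Ranking) -> float:
    """Squared tie penalty M(S); 1 = all ranks distinct, 0 = all tied."""
    n = len(ranking)
    if n < 2:
        raise ValueError("monotonicity: need at least 2 ranked nodes")
    _, counts = np.unique(ranking.ranks, return_counts=True)
    tie_mass = float((counts * (counts - 1)).sum())
    return (1.0 - tie_mass / (n * (n - 1))) ** 2


def ccdf_curve(ranking: Ranking) -> pd.Series:
    """Fraction of nodes scoring >= s, over distinct scores s (descending)."""
    scores = np.sort(np.unique(np.round(ranking.scores, 10)))[::-1]
    n = len(ranking)
    fracs = [float(np.sum(np.round(ranking.scores, 10) >= s)) / n for s in scores]
    return pd.Series(fracs, index=scores, name="ccdf")


def _aligned_ranks(truth: Ranking, method: Ranking) -> tuple[np.ndarray, np.ndarray]:
    if set(truth.nodes) != set(method.nodes):
        raise ValueError("rankings cover different node sets")
    t = truth.rank_of()
    m = method.rank_of()
    nodes = list(truth.nodes)
    x = np.array([t[v] for v in nodes], dtype=float)
    y = np.array([m[v] for v in nodes], dtype=float)
    return x, y


def kendall_tau(truth: Ranking, method: Ranking) -> float:
    """Kendall tau-a between two rank lists over the same node set.

    tau = sum_{i<j} sgn[(x_i - x_j)(y_i - y_j)] / (N(N-1)/2); tied pairs
    contribute zero and no tie correction is applied.
    """
    x, y = _aligned_ranks(truth, method)
    n = len(x)
    if n < 2:
        raise ValueError("kendall_tau: need at least 2 nodes")
    total = 0.0
    block = 512  # ordered pairs summed blockwise; each unordered pair twice
    for start in range(0, n, block):
        xs = np.sign(x[start : start + block, None] - x[None, :])
        ys = np.sign(y[start : start + block, None] - y[None, :])
        total += float((xs * ys).sum())
    return total / (n * (n - 1))


def imprecision(influence: InfluenceTable, method: Ranking, p: float) -> float:
    """Imprecision eps(p) = 1 - M(p) / M_eff(p) for the top ceil(pN) nodes.

    M(p) is the mean true spreading influence of the method's top nodes,
    M_eff(p) the same for the ground-truth ranking.  The value may be
    slightly negative under Monte-Carlo noise; it is reported unclamped.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    n = len(influence.means)
    t = math.ceil(p * n)
    truth = influence.ranking()
    top_true = truth.top(t)
    top_method = method.top(t)
    m_eff = float(influence.means.loc[top_true].mean())
    m_p = float(influence.means.loc[top_method].mean())
    return 1.0 - m_p / m_eff


def jaccard_topk(truth: Ranking, method: Ranking, T: int) -> float:
    """Jaccard similarity of the two top-T node sets."""
    n = len(truth)
    if not 1 <= T <= n:
        raise ValueError(f"T must be in [1, {n}], got {T}")
    a = set(truth.top(T))
    b = set(method.top(T))
    return len(a & b) / len(a | b)
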