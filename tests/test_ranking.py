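"""The entropy-weighted pipeline: normalization, weights, scores, ranks."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lwcent import (
    build_attribute_matrix,
    entropy_weights,
    lwc_ranking,
    lwc_scores,
    normalize_matrix,
    rank_nodes,
    toy_graph,
)
from lwcent.attributes import ATTRIBUTES
from conftest import lwc_oracle


def frame(cols):
    return pd.DataFrame(dict(zip(ATTRIBUTES, cols)), columns=list(ATTRIBUTES))


def test_attribute_matrix_rows(triangle_tail):
    P = build_attribute_matrix(triangle_tail)
    assert list(P.columns) == ["k", "thk", "clc", "thclc"]
    assert P["k"].tolist() == [2, 2, 3, 2, 1]
    K4 = build_attribute_matrix(toy_graph("k4"))
    assert (K4.to_numpy() == np.array([3, 3, 1, 3])).all()
    edge = build_attribute_matrix(toy_graph("p3").subgraph([1, 2]))
    assert (edge.to_numpy() == np.array([1, 1, 0, 0])).all()


def test_normalize_matrix_hand_case():
    R = normalize_matrix(frame([[2, 2, 3, 2, 1]] * 4))
    assert np.allclose(R["k"], [0.2, 0.2, 0.3, 0.2, 0.1], atol=1e-12)


def test_normalize_matrix_constant_and_zero_columns():
    R = normalize_matrix(frame([[3, 3, 3], [0, 0, 0], [1, 2, 3], [5, 5, 5]]))
    assert np.allclose(R["k"], 1 / 3)
    assert (R["thk"] == 0).all()
    assert np.allclose(R["thclc"], 1 / 3)
    sums = R.sum(axis=0)
    assert np.allclose(sums[["k", "clc", "thclc"]], 1.0, atol=1e-9)


def test_entropy_hand_value_and_limits():
    R = normalize_matrix(frame([[2, 2, 3, 2, 1]] * 4))
    w = entropy_weights(R)
    expected = -(3 * 0.2 * math.log(0.2) + 0.3 * math.log(0.3) + 0.1 * math.log(0.1)) / math.log(5)
    assert w.entropies["k"] == pytest.approx(expected, abs=1e-12)
    assert w.entropies["k"] == pytest.approx(0.9675, abs=5e-5)

    uniform = pd.DataFrame({a: [0.25] * 4 for a in ATTRIBUTES})
    assert np.allclose(entropy_weights(uniform).entropies, 1.0, atol=1e-12)

    onehot = pd.DataFrame({a: [1.0, 0.0, 0.0] for a in ATTRIBUTES})
    assert np.allclose(entropy_weights(onehot).entropies, 0.0, atol=1e-12)


def test_weights_follow_one_minus_entropy():
    # entropies (1, 1, 0.5, 1) must force all weight onto the third column
    R = pd.DataFrame(
        {
            "k": [0.25] * 4,
            "thk": [0.25] * 4,
            "clc": [0.97, 0.01, 0.01, 0.01],
            "thclc": [0.25] * 4,
        }
    )
    w = entropy_weights(R)
    assert w.weights["clc"] == pytest.approx(1.0)
    assert w.weights[["k", "thk", "thclc"]].abs().sum() == pytest.approx(0.0)


def test_zero_column_gets_zero_weight():
    P = frame([[1, 2, 3], [2, 3, 5], [0, 0, 0], [0, 0, 0]])
    R = normalize_matrix(P)
    w = entropy_weights(R)
    assert w.weights["clc"] == 0.0 and w.weights["thclc"] == 0.0
    assert w.weights.sum() == pytest.approx(1.0)


def test_all_constant_graph_falls_back_to_equal_weights():
    _, w = lwc_ranking(toy_graph("k4"))
    assert np.allclose(w.weights, 0.25)


def test_entropy_requires_two_rows():
    with pytest.raises(ValueError):
        entropy_weights(pd.DataFrame({a: [1.0] for a in ATTRIBUTES}))


def test_scores_are_weighted_row_sums_and_sum_to_one(triangle_tail):
    P = build_attribute_matrix(triangle_tail)
    R = normalize_matrix(P)
    w = entropy_weights(R)
    s = lwc_scores(R, w)
    assert s.sum() == pytest.approx(1.0, abs=1e-9)
    assert (s >= 0).all()


def test_scale_invariance_of_pipeline(triangle_tail):
    P = build_attribute_matrix(triangle_tail)
    scaled = P.copy()
    scaled["thk"] *= 17.0
    scaled["clc"] *= 0.003
    a = lwc_scores(normalize_matrix(P), entropy_weights(normalize_matrix(P)))
    b = lwc_scores(normalize_matrix(scaled), entropy_weights(normalize_matrix(scaled)))
    assert np.allclose(a, b, atol=1e-12)


@pytest.mark.parametrize("toy", ["k4", "k5", "c5", "triangle"])
def test_vertex_transitive_graph_all_rank_one(toy):
    ranking, _ = lwc_ranking(toy_graph(toy))
    assert (ranking.ranks == 1).all()
    assert np.allclose(ranking.scores, 1.0 / len(ranking))


def test_pipeline_matches_direct_formula_oracle(any_toy):
    ranking, _ = lwc_ranking(any_toy)
    oracle = lwc_oracle(any_toy)
    got = ranking.score_of()
    for node, expect in oracle.items():
        assert got[node] == pytest.approx(expect, abs=1e-12)


def test_triangle_tail_ranking_order(triangle_tail):
    # entropy weighting favors the clustering column on this fixture, so
    # the two triangle corners (1, 2) tie on top and the hub 3 is second
    ranking, w = lwc_ranking(triangle_tail)
    ranks = ranking.rank_of()
    assert ranks[1] == ranks[2] == 1
    assert ranks[3] == 2
    assert ranks[5] == max(ranks.values())
    assert w.weights["clc"] > w.weights["k"]


def test_rank_nodes_tie_grouping_and_order():
    r = rank_nodes({"a": 0.5, "b": 0.3, "c": 0.3, "d": 0.1})
    assert list(r.nodes) == ["a", "b", "c", "d"]
    assert r.ranks.tolist() == [1, 2, 2, 3]

    tied = rank_nodes({"x": 1.0, "y": 1.0 + 1e-14})
    assert tied.ranks.tolist() == [1, 1]

    all_equal = rank_nodes({i: 2.0 for i in range(5)})
    assert (all_equal.ranks == 1).all()


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=0, max_value=10, allow_nan=False), min_size=2, max_size=30)
)
def test_rank_nodes_properties(scores):
    r = rank_nodes({i: s for i, s in enumerate(scores)})
    assert sorted(r.nodes) == list(range(len(scores)))
    assert (np.diff(r.scores.round(10)) <= 0).all()
    assert r.ranks[0] == 1
    assert (np.diff(r.ranks) >= 0).all() and (np.diff(r.ranks) <= 1).all()
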