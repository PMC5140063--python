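"""Entropy scoring, stage assignment, quantile normalization, transience."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adipoepi.expression import ExpressionMatrix
from adipoepi.stage_specificity import (
    entropy_score,
    entropy_score_vector,
    entropy_scores,
    quantile_normalize,
    select_bmp7_transient,
    select_stage_specific,
    select_stage_specific_mirna,
)

STAGES = ["d-3", "d0", "6h", "d2", "d7"]


def brute_entropy(e):
    """Direct formula evaluation, independently coded."""
    total = sum(e)
    if total == 0:
        return float("nan")
    h = 0.0
    for x in e:
        r = x / total
        if r > 0:
            h -= r * math.log2(r)
    return h


def expr_matrix(values, feature_class="coding", unit="FPKM"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    df = pd.DataFrame(
        values, index=[f"f{i}" for i in range(values.shape[0])], columns=STAGES
    )
    return ExpressionMatrix(df, feature_class=feature_class, unit=unit)


# ---------------------------------------------------------------------------
# entropy


def test_entropy_known_values():
    assert entropy_score_vector([10, 0, 0, 0, 0]) == 0.0
    assert entropy_score_vector([5, 5, 5, 5, 5]) == pytest.approx(
        math.log2(5), abs=1e-12
    )
    assert entropy_score_vector([8, 2, 0, 0, 0]) == pytest.approx(
        0.721928, abs=1e-6
    )


def test_entropy_matches_brute_force_on_random_vectors(rng):
    for _ in range(1000):
        v = rng.random(5) * rng.choice([0.1, 1, 100])
        assert entropy_score_vector(v) == pytest.approx(
            brute_entropy(list(v)), abs=1e-10
        )


def test_entropy_zero_total_is_nan_and_negative_rejected():
    assert math.isnan(entropy_score_vector([0, 0, 0, 0, 0]))
    with pytest.raises(ValueError):
        entropy_score_vector([1, -1, 0, 0, 0])


@given(
    st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=8).filter(
        lambda v: sum(v) > 0
    ),
    st.floats(1e-3, 1e3),
)
@settings(max_examples=200, derandomize=True)
def test_entropy_scale_invariant(v, c):
    h1 = entropy_score_vector(np.array(v))
    h2 = entropy_score_vector(np.array(v) * c)
    assert h2 == pytest.approx(h1, abs=1e-8)


@given(st.permutations(list(range(5))))
@settings(max_examples=50, derandomize=True)
def test_entropy_permutation_invariant(perm):
    v = np.array([8.0, 2.0, 1.0, 0.0, 5.0])
    assert entropy_score_vector(v[perm]) == pytest.approx(
        entropy_score_vector(v), abs=1e-12
    )
    s = entropy_score("f", v[perm])
    np.testing.assert_allclose(sorted(s.relative), sorted(v / v.sum()))


def test_entropy_scores_matrix_range():
    m = expr_matrix([[10, 0, 0, 0, 0], [5, 5, 5, 5, 5], [0, 0, 0, 0, 0]])
    h = entropy_scores(m)
    assert h.iloc[0] == 0.0
    assert h.iloc[1] == pytest.approx(math.log2(5), abs=1e-12)
    assert math.isnan(h.iloc[2])


# ---------------------------------------------------------------------------
# stage assignment


def test_select_stage_specific_examples():
    m = expr_matrix(
        [
            [50, 0.1, 0.1, 0.1, 0.1],  # stage 1 only
            [6, 6, 6, 6, 6],  # uniform: fails entropy and breadth
            [50, 8, 0.1, 0.1, 0.1],  # stages 1 and 2
        ]
    )
    out = {a.feature_id: a.stages for a in select_stage_specific(m)}
    assert out == {"f0": ["d-3"], "f2": ["d-3", "d0"]}


def brute_select(values, stages, entropy_max, expr_min, max_additional):
    out = {}
    for i, row in enumerate(values):
        h = brute_entropy(list(row))
        if not (h < entropy_max):
            continue
        assigned = []
        for j, s in enumerate(stages):
            others = sum(1 for k in range(len(stages)) if k != j and row[k] > expr_min)
            if row[j] > expr_min and others <= max_additional:
                assigned.append(s)
        if assigned:
            out[f"f{i}"] = assigned
    return out


def test_select_stage_specific_equals_brute_force(rng):
    # mixture of flat, spiky and intermediate profiles around the cutoffs
    n = 4000
    base = rng.random((n, 5)) * 12
    spikes = rng.integers(0, 5, n)
    base[np.arange(n), spikes] *= rng.choice([0.1, 1, 10, 40], n)
    m = expr_matrix(base)
    got = {a.feature_id: a.stages for a in select_stage_specific(m)}
    want = brute_select(base, STAGES, 2.0, 5.0, 3)
    assert got == want


def test_select_lncrna_threshold():
    m = expr_matrix([[2.0, 0.1, 0.1, 0.1, 0.1]], feature_class="lncRNA")
    out = select_stage_specific(m)
    assert out[0].stages == ["d-3"]  # 0.5 FPKM cutoff engages


def test_select_requires_known_class_threshold():
    m = expr_matrix([[1, 1, 1, 1, 1]], feature_class="miRNA", unit="array_signal")
    with pytest.raises(ValueError, match="cutoff"):
        select_stage_specific(m)


# ---------------------------------------------------------------------------
# quantile normalization + miRNA selection


def test_quantile_normalize_hand_example():
    df = pd.DataFrame({"a": [1.0, 2, 3], "b": [4.0, 5, 6]}, index=["x", "y", "z"])
    m = ExpressionMatrix(df, feature_class="miRNA", unit="array_signal")
    out = quantile_normalize(m).data
    np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
    np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])


def test_quantile_normalize_fixed_point_and_column_means(rng):
    v = rng.random((30, 5)) * 100
    m = ExpressionMatrix(
        pd.DataFrame(v, columns=STAGES), feature_class="miRNA", unit="array_signal"
    )
    out = quantile_normalize(m).data
    means = out.mean(axis=0)
    np.testing.assert_allclose(means, means.iloc[0])
    same = ExpressionMatrix(
        pd.DataFrame(np.tile(v[:, :1], (1, 5)), columns=STAGES),
        feature_class="miRNA",
        unit="array_signal",
    )
    np.testing.assert_allclose(quantile_normalize(same).data.values, same.data.values)


def test_quantile_normalize_tie_handling():
    df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
    m = ExpressionMatrix(df, feature_class="miRNA", unit="array_signal")
    out = quantile_normalize(m).data
    # rank means are [mean(1,2), mean(1,4), mean(5,6)] = [1.5, 2.5, 5.5];
    # the tie spans ranks 1-2 and receives their mean
    assert out["a"].iloc[0] == out["a"].iloc[1] == pytest.approx((1.5 + 2.5) / 2)


def test_quantile_normalize_rejects_non_mirna():
    m = expr_matrix([[1, 2, 3, 4, 5]])
    with pytest.raises(ValueError):
        quantile_normalize(m)


def test_mirna_selection_fold_rule():
    m = expr_matrix(
        [
            [10, 10, 10, 10, 10],  # flat: out
            [30, 10, 10, 10, 10],  # fold 3: stage 1
            [20, 10, 10, 10, 10],  # fold exactly 2: out (strictly more than)
        ],
        feature_class="miRNA",
        unit="array_signal",
    )
    out = {a.feature_id: a.stages for a in select_stage_specific_mirna(m)}
    assert out == {"f1": ["d-3"]}


def test_mirna_argmax_tie_flagged():
    m = expr_matrix(
        [[30, 30, 1, 1, 1]], feature_class="miRNA", unit="array_signal"
    )
    (a,) = select_stage_specific_mirna(m)
    assert a.stages == ["d-3"] and a.tie_broken


def test_mirna_floor_prevents_unbounded_folds():
    m = expr_matrix(
        [[1.5, 0.0, 0.0, 0.0, 0.0]], feature_class="miRNA", unit="array_signal"
    )
    # fold = 1.5 / max(0, floor=1) = 1.5 < 2 -> not selected
    assert select_stage_specific_mirna(m) == []


# ---------------------------------------------------------------------------
# transient induction


def test_bmp7_transient_selection():
    m = expr_matrix(
        [
            [1, 10, 1, 1, 1],  # robust transient induction
            [1, 2, 4, 8, 16],  # monotone rise: not transient
            [1, 1, 1, 1, 1],  # flat
            [1, 10, 8, 1, 1],  # induced but not falling 2-fold by 6h
        ]
    )
    assert select_bmp7_transient(m) == ["f0"]


def test_bmp7_requires_stages():
    df = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"], index=["f0"])
    m = ExpressionMatrix(df)
    with pytest.raises(ValueError, match="stage"):
        select_bmp7_transient(m)
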