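"""Fisher exact tests, clinical comparison tables, logistic odds ratios."""

from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import proteoclust as pc
from conftest import make_log2_matrix


def _fisher_2x2_oracle(a, b, c, d):
    """Two-sided probability-mass rule by direct enumeration."""
    r1, r2 = a + b, c + d
    n1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, n1 - x) / comb(n, n1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, n1 - r2), min(r1, n1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def test_balanced_table_is_null():
    odds, p = pc.fisher_exact([[1, 1], [1, 1]])
    assert odds == 1.0 and p == 1.0


def test_sample_odds_ratio_is_ad_over_bc():
    odds, _ = pc.fisher_exact([[20, 10], [10, 20]])
    assert odds == pytest.approx(4.0)


def test_perfect_separation_flagged_infinite():
    odds, p = pc.fisher_exact([[5, 0], [0, 5]])
    assert np.isinf(odds)
    assert p == pytest.approx(2.0 / 252.0, rel=1e-9)


def test_three_one_table_p():
    _, p = pc.fisher_exact([[3, 1], [1, 3]])
    assert p == pytest.approx(0.4857, abs=2e-4)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.integers(0, 10), st.integers(0, 10),
       st.integers(0, 10), st.integers(0, 10))
def test_fisher_matches_enumeration(a, b, c, d):
    if min(a + b, c + d, a + c, b + d) == 0:
        return
    _, p = pc.fisher_exact([[a, b], [c, d]])
    assert p == pytest.approx(_fisher_2x2_oracle(a, b, c, d), rel=1e-9)


def test_zero_margin_rejected():
    with pytest.raises(pc.ClinicalError):
        pc.fisher_exact([[0, 0], [1, 2]])


def test_rx2_enumeration_agrees_with_2x2_fisher():
    for tab in ([[3, 1], [1, 3]], [[5, 2], [1, 6]], [[2, 2], [3, 3]]):
        _, p2 = pc.fisher_exact(tab)
        assert pc.exact_rx2_test(tab) == pytest.approx(p2, rel=1e-9)


def test_rx2_detects_association_in_3x2():
    p = pc.exact_rx2_test([[9, 1], [5, 5], [1, 9]])
    assert p < 0.01
    p_null = pc.exact_rx2_test([[5, 5], [5, 5], [5, 5]])
    assert p_null == pytest.approx(1.0, abs=1e-9)


# -- clinical comparison table -------------------------------------------

def test_identical_continuous_values_give_p_one():
    cov = pd.DataFrame({"age": [60, 65, 70, 60, 65, 70.0]},
                       index=[f"s{i}" for i in range(6)])
    labels = pd.Series([1, 1, 1, 2, 2, 2], index=cov.index)
    table = pc.compare_clinical(cov, labels, types={"age": "continuous"})
    assert table.loc["age", "p"] == pytest.approx(1.0)


def test_emphysema_counts_reach_significance():
    """Planted 65/126 vs 27/115 prevalence difference is detected."""
    cov = pd.DataFrame({"emphysema": [1] * 65 + [0] * 61 + [1] * 27 + [0] * 88},
                       index=[f"s{i}" for i in range(241)])
    labels = pd.Series([1] * 126 + [2] * 115, index=cov.index)
    table = pc.compare_clinical(cov, labels)
    assert table.loc["emphysema", "type"] == "categorical"
    assert table.loc["emphysema", "p"] < 0.05
    assert table.loc["emphysema", "summary1"] == "65 (52%)"
    assert table.loc["emphysema", "summary2"] == "27 (23%)"


def test_missing_values_dropped_with_n_reported():
    cov = pd.DataFrame({"bmi": [25, np.nan, 27, 24, 26, np.nan]},
                       index=[f"s{i}" for i in range(6)])
    labels = pd.Series([1, 1, 1, 2, 2, 2], index=cov.index)
    table = pc.compare_clinical(cov, labels, types={"bmi": "continuous"})
    assert (table.loc["bmi", "n1"], table.loc["bmi", "n2"]) == (2, 2)


def test_variable_missing_in_one_group_rejected():
    cov = pd.DataFrame({"x": [1.0, 2.0, np.nan, np.nan]},
                       index=list("abcd"))
    labels = pd.Series([1, 1, 2, 2], index=cov.index)
    with pytest.raises(pc.ClinicalError, match="missing"):
        pc.compare_clinical(cov, labels, types={"x": "continuous"})


# -- logistic odds ratios -------------------------------------------------

def test_logistic_or_equals_sample_or_on_2x2_encoding():
    x = np.array([1.0] * 30 + [0.0] * 30)
    y = np.array([1] * 20 + [0] * 10 + [1] * 10 + [0] * 20)
    X = make_log2_matrix(x[:, None], proteins=["g1"])
    out = pc.protein_outcome_or(X, pd.Series(y, index=X.subject_ids),
                                standardize=False)
    assert out.loc["g1", "OR"] == pytest.approx(4.0, rel=1e-6)


def test_or_inverts_when_predictor_negated():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 80)
    y = (rng.random(80) < 1 / (1 + np.exp(-x))).astype(int)
    X = make_log2_matrix(np.column_stack([x, -x]))
    out = pc.protein_outcome_or(X, pd.Series(y, index=X.subject_ids))
    assert out.loc["g1", "OR"] * out.loc["g2", "OR"] == pytest.approx(1.0,
                                                                      rel=1e-6)
    assert out.loc["g1", "ci_low"] <= out.loc["g1", "OR"] <= \
        out.loc["g1", "ci_high"]


def test_protective_marker_has_or_below_one():
    rng = np.random.default_rng(1)
    y = np.array([1] * 60 + [0] * 60)
    x = rng.normal(10, 0.5, 120)
    x[y == 0] += 1.0            # higher expression in outcome-free subjects
    X = make_log2_matrix(x[:, None], proteins=["areg"])
    out = pc.protein_outcome_or(X, pd.Series(y, index=X.subject_ids))
    assert out.loc["areg", "OR"] < 1
    assert out.loc["areg", "q"] < 0.05


def test_null_proteins_rarely_called():
    rng = np.random.default_rng(2)
    false_rates = []
    for _ in range(20):
        X = make_log2_matrix(rng.normal(10, 1, (60, 25)))
        y = pd.Series(rng.integers(0, 2, 60), index=X.subject_ids)
        if y.nunique() < 2:
            continue
        out = pc.protein_outcome_or(X, y)
        false_rates.append((out["q"] < 0.05).mean())
        assert np.median(out["OR"]) == pytest.approx(1.0, abs=0.35)
    assert np.mean(false_rates) <= 0.10


def test_separation_is_flagged():
    x = np.array([0.0] * 10 + [1.0] * 10)
    y = pd.Series(x.astype(int), index=[f"s{i}" for i in range(20)])
    X = make_log2_matrix(x[:, None], subjects=list(y.index), proteins=["g1"])
    out = pc.protein_outcome_or(X, y, standardize=False)
    assert bool(out.loc["g1", "flagged"])


def test_degenerate_outcome_rejected():
    X = make_log2_matrix(np.random.default_rng(3).normal(10, 1, (10, 2)))
    with pytest.raises(pc.ClinicalError, match="binary"):
        pc.protein_outcome_or(X, pd.Series(1, index=X.subject_ids))


def test_bh_within_outcome_is_order_invariant():
    rng = np.random.default_rng(4)
    X = make_log2_matrix(rng.normal(10, 1, (50, 12)))
    y = pd.Series(rng.integers(0, 2, 50), index=X.subject_ids)
    a = pc.protein_outcome_or(X, y)
    perm = list(reversed(X.protein_ids))
    b = pc.protein_outcome_or(X, y, proteins=perm)
    for pid in X.protein_ids:
        assert a.loc[pid, "q"] == pytest.approx(b.loc[pid, "q"], rel=1e-12)


# -- correlations ---------------------------------------------------------

@pytest.mark.parametrize("y,expected", [([1, 2, 3], 1.0), ([-1, -2, -3], -1.0)])
def test_correlation_extremes(y, expected):
    rho, _ = pc.correlate([1, 2, 3], y)
    assert rho == pytest.approx(expected)


def test_pearson_hand_computed_example():
    rho, _ = pc.correlate([1, 2, 3], [2, 4, 7])
    assert rho == pytest.approx(0.9934, abs=1e-4)


def test_spearman_is_rank_based():
    rho, _ = pc.correlate([1, 2, 3, 4], [1, 10, 100, 1000], method="spearman")
    assert rho == pytest.approx(1.0)


def test_zero_variance_rejected():
    with pytest.raises(pc.ClinicalError):
        pc.correlate([1, 1, 1], [1, 2, 3])
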