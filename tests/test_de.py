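"""Moderated t, BH FDR and significance calls.

The moderated statistic is checked against two independent oracles: a
hand-computed ordinary t test (prior degrees of freedom forced to zero)
and values frozen from the reference empirical-Bayes implementation in
the R/Bioconductor limma package, run once on the deterministic fixture
reproduced by ``_limma_fixture``.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import proteoclust as pc
from conftest import make_log2_matrix

# -- frozen oracle: R limma (lmFit + eBayes) on the fixture below ---------

LIMMA_D0 = 3.4710031530794687
LIMMA_S02 = 0.2601344659067376
LIMMA_T_P = {
    # gene index -> (moderated t, two-sided p)
    0: (5.37449575838829, 0.0001119322666408),
    1: (7.07420932929885, 6.87761511575011e-06),
    4: (5.95194067818516, 4.14904613926459e-05),
    10: (-1.2910036203079, 0.21841833280166),
    20: (-1.93584425110675, 0.0741570659759613),
    39: (-4.5825024613772, 0.0004696852888453),
}


def _limma_fixture():
    rng = np.random.default_rng(42)
    n1, n2, n_genes = 6, 6, 40
    sd = np.exp(rng.normal(-0.5, 0.5, n_genes))
    mat = rng.normal(10, 1, (n_genes, 1)) + \
        rng.normal(0, 1, (n_genes, n1 + n2)) * sd[:, None]
    mat[:5, n1:] += 1.0
    X = make_log2_matrix(mat.T)
    labels = pd.Series([1] * n1 + [2] * n2, index=X.subject_ids)
    return X, labels


def test_moderated_t_matches_reference_implementation():
    X, labels = _limma_fixture()
    de = pc.moderated_ttest(X, labels)
    assert de.attrs["d0"] == pytest.approx(LIMMA_D0, rel=1e-9)
    assert de.attrs["s02"] == pytest.approx(LIMMA_S02, rel=1e-9)
    for idx, (t_ref, p_ref) in LIMMA_T_P.items():
        row = de.iloc[idx]
        assert row["t_mod"] == pytest.approx(t_ref, rel=1e-9)
        assert row["p"] == pytest.approx(p_ref, rel=1e-9)


def test_identical_group_means_give_null_table():
    vals = np.tile(np.arange(4, dtype=float)[:, None], (2, 5))
    X = make_log2_matrix(vals)      # groups below are mirror images
    labels = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=X.subject_ids)
    de = pc.moderated_ttest(X, labels)
    assert np.allclose(de["log2fc"], 0.0)
    assert np.allclose(de["p"], 1.0)


def test_ordinary_t_oracle_on_hand_computed_example():
    X = make_log2_matrix(np.array([[1.0], [2.0], [3.0], [3.0], [4.0], [5.0]]))
    labels = pd.Series([1, 1, 1, 2, 2, 2], index=X.subject_ids)
    de = pc.moderated_ttest(X, labels, d0=0)
    assert de["log2fc"].iloc[0] == pytest.approx(2.0)
    assert de["fold_change"].iloc[0] == pytest.approx(4.0)
    assert de["t_mod"].iloc[0] == pytest.approx(2.0 / np.sqrt(2.0 / 3.0),
                                                rel=1e-12)


def test_d0_zero_equals_scipy_equal_variance_t():
    X, labels = _limma_fixture()
    de = pc.moderated_ttest(X, labels, d0=0)
    g1 = X.values[labels == 1]
    g2 = X.values[labels == 2]
    ref = stats.ttest_ind(g2, g1, equal_var=True)
    np.testing.assert_allclose(de["t_mod"], ref.statistic, atol=1e-10)
    np.testing.assert_allclose(de["p"], ref.pvalue, atol=1e-10)


def test_d0_infinite_gives_pooled_variance_z_statistic():
    X, labels = _limma_fixture()
    de = pc.moderated_ttest(X, labels, d0=np.inf)
    s02 = de.attrs["s02"]
    se = np.sqrt(s02 * (1 / 6 + 1 / 6))
    np.testing.assert_allclose(de["t_mod"], de["log2fc"] / se, rtol=1e-12)


def test_null_type_one_error_calibrated():
    rng = np.random.default_rng(11)
    X = make_log2_matrix(rng.normal(10, 1, (40, 1000)))
    labels = pd.Series([1] * 20 + [2] * 20, index=X.subject_ids)
    de = pc.moderated_ttest(X, labels)
    rate = (de["p"] < 0.05).mean()
    assert 0.03 <= rate <= 0.07


def test_constant_protein_flagged_with_ordinary_t():
    vals = np.ones((6, 2))
    vals[:, 1] = [1, 2, 3, 4, 5, 6]
    X = make_log2_matrix(vals)
    labels = pd.Series([1, 1, 1, 2, 2, 2], index=X.subject_ids)
    de = pc.moderated_ttest(X, labels, d0=0)
    assert bool(de["degenerate"].iloc[0])
    assert de["p"].iloc[0] == 1.0


def test_group_of_one_rejected():
    X = make_log2_matrix(np.ones((3, 2)))
    labels = pd.Series([1, 2, 2], index=X.subject_ids)
    with pytest.raises(pc.DEError, match="at least 2"):
        pc.moderated_ttest(X, labels)


def test_swapping_labels_negates_fold_changes():
    X, labels = _limma_fixture()
    de = pc.differential_expression(X, labels)
    flipped = pc.differential_expression(X, labels.map({1: 2, 2: 1}))
    np.testing.assert_allclose(flipped["log2fc"], -de["log2fc"], atol=1e-12)
    up2a, up1a = pc.call_significant(de)
    up2b, up1b = pc.call_significant(flipped)
    assert up2a == up1b and up1a == up2b
    pd.testing.assert_frame_equal(pc.flip_groups(de), flipped)


# -- BH FDR ---------------------------------------------------------------

def _bh_oracle(p):
    """Literal step-up definition, quadratic time."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


def test_bh_single_p_is_unchanged():
    assert pc.bh_fdr([0.03])[0] == pytest.approx(0.03)


def test_bh_hand_computed_step_up():
    np.testing.assert_allclose(pc.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04], atol=1e-12)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
def test_bh_matches_literal_step_up_definition(pvals):
    q = pc.bh_fdr(pvals)
    np.testing.assert_allclose(q, _bh_oracle(pvals), atol=1e-12)
    assert ((q >= 0) & (q <= 1)).all()


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.floats(0, 1), min_size=2, max_size=40),
       st.randoms(use_true_random=False))
def test_bh_is_permutation_equivariant(pvals, rnd):
    perm = list(range(len(pvals)))
    rnd.shuffle(perm)
    q = pc.bh_fdr(pvals)
    q_perm = pc.bh_fdr([pvals[i] for i in perm])
    np.testing.assert_allclose([q[i] for i in perm], q_perm, atol=1e-12)


def test_bh_rejections_match_classic_rule():
    rng = np.random.default_rng(5)
    p = rng.uniform(0, 1, 200) ** 2
    q = pc.bh_fdr(p)
    alpha = 0.05
    # classic BH: reject the k smallest p where k = max rank with
    # p_(k) <= alpha * k / m
    order = np.sort(p)
    m = len(p)
    ks = np.flatnonzero(order <= alpha * (np.arange(1, m + 1)) / m)
    k = ks.max() + 1 if len(ks) else 0
    assert (q < alpha).sum() == ((q <= alpha) & (q < 1)).sum()  # strictness sanity
    assert set(np.flatnonzero(q <= alpha)) == set(np.argsort(p)[:k])


def test_bh_rejects_empty_input():
    with pytest.raises(pc.DEError):
        pc.bh_fdr([])


# -- significance rule ----------------------------------------------------

def test_fold_change_threshold_is_strict():
    de = pd.DataFrame({
        "log2fc": [np.log2(1.5), 1.0, -1.0],
        "fold_change": [1.5, 2.0, 2.0],
        "t_mod": [5.0, 5.0, -5.0],
        "p": [1e-6, 1e-6, 1e-6],
        "degenerate": [False] * 3,
    }, index=["boundary", "up", "down"])
    up2, up1 = pc.call_significant(de)
    assert "boundary" not in up2 + up1
    assert up2 == ["up"] and up1 == ["down"]


def test_planted_up_sets_recovered_at_scale(cobra_run):
    up2, up1 = pc.call_significant(cobra_run.result.de)
    truth = cobra_run.data.truth
    assert set(up2) <= set(truth.up2_ids)
    assert set(up1) <= set(truth.up1_ids)
    assert len(up2) >= 85 and len(up1) >= 4


def test_fdr_control_on_null_panels():
    """Realized false-discovery proportion <= 0.10 averaged over nulls."""
    rng = np.random.default_rng(21)
    fdps = []
    for _ in range(20):
        X = make_log2_matrix(rng.normal(10, 1, (30, 400)))
        labels = pd.Series([1] * 15 + [2] * 15, index=X.subject_ids)
        de = pc.differential_expression(X, labels)
        n_called = (de["q"] < 0.05).sum()
        fdps.append(1.0 if n_called else 0.0)  # every call on a null is false
    assert np.mean(fdps) <= 0.10
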