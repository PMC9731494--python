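"""Cluster-versus-clinical comparisons and per-protein outcome models.

Two families of statistics:

* **Group comparison tables** - continuous variables by two-sided
  equal-variance t test, binary/categorical variables by Fisher's exact
  test (2x2, or r x 2 by full enumeration for small tables).
* **Per-protein odds ratios** - univariable logistic regression of a
  binary outcome on standardized (per-SD) log2 expression, fitted by
  IRLS, with 95% Wald intervals and BH FDR across proteins within each
  outcome.  ORs are per standard deviation of log2 expression unless
  ``standardize=False``.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .de import bh_fdr
from .matrix import ExpressionMatrix, LOG2


class ClinicalError(ValueError):
    pass


# -- exact tests ----------------------------------------------------------

def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns the sample odds ratio ``ad/bc`` (``inf`` on a zero in the
    off-diagonal denominator) and the probability-mass two-sided p-value
    (sum over fixed-margin tables no more probable than the observed one).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ClinicalError("need a 2x2 table of nonnegative integers")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise ClinicalError("a margin of the 2x2 table is zero")
    res = stats.fisher_exact(np.round(t).astype(int), alternative="two-sided")
    a, b, c, d = t.ravel()
    if b * c == 0:
        odds = np.inf if a * d > 0 else (0.0 if (a == 0 or d == 0) else 1.0)
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(res.pvalue)


def _log_table_prob(col1, row_tot, n1, n) -> float:
    """Log probability of an r x 2 table conditional on both margins."""
    col1 = np.asarray(col1)
    row_tot = np.asarray(row_tot)
    lp = -(gammaln(n + 1) - gammaln(n1 + 1) - gammaln(n - n1 + 1))
    for k, r in zip(col1, row_tot):
        lp += gammaln(r + 1) - gammaln(k + 1) - gammaln(r - k + 1)
    return float(lp)


def exact_rx2_test(table, max_total: int = 200) -> float:
    """Two-sided exact test for an r x 2 table by full enumeration.

    Probability-mass rule conditional on both margins; falls back to the
    chi-square test for totals above ``max_total`` (enumeration cost).
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[1] != 2 or (t < 0).any():
        raise ClinicalError("need an r x 2 table of nonnegative integers")
    n = int(t.sum())
    if n == 0:
        raise ClinicalError("empty table")
    if n > max_total:
        return float(stats.chi2_contingency(t, correction=False)[1])
    row_tot = t.sum(axis=1)
    n1 = int(t[:, 0].sum())
    obs_lp = _log_table_prob(t[:, 0], row_tot, n1, n)
    ranges = [range(0, int(r) + 1) for r in row_tot[:-1]]
    p = 0.0
    for combo in product(*ranges):
        last = n1 - sum(combo)
        if last < 0 or last > row_tot[-1]:
            continue
        lp = _log_table_prob(list(combo) + [last], row_tot, n1, n)
        if lp <= obs_lp + 1e-9:
            p += np.exp(lp)
    return float(min(p, 1.0))


# -- clinical comparison table -------------------------------------------

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


def infer_variable_types(covariates: pd.DataFrame) -> dict[str, str]:
    """Binary/low-cardinality columns -> categorical, rest continuous."""
    types = {}
    for col in covariates.columns:
        s = covariates[col].dropna()
        if s.dtype == object or s.dtype == bool or s.nunique() <= 4:
            types[col] = CATEGORICAL
        else:
            types[col] = CONTINUOUS
    return types


def compare_clinical(covariates: pd.DataFrame, labels: pd.Series,
                     types: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-variable cluster comparison (t test / Fisher exact).

    Missing values are dropped per variable, with the remaining per-group
    n reported.  Continuous summaries are mean +/- sd, categorical ones
    counts and percentages recomputed from counts.
    """
    labels = labels.reindex(covariates.index)
    if labels.isna().any():
        raise ClinicalError("labels missing for some subjects")
    types = types or infer_variable_types(covariates)
    rows = []
    for var in covariates.columns:
        kind = types.get(var, CONTINUOUS)
        s = covariates[var]
        ok = s.notna()
        g1 = s[ok & (labels == 1)]
        g2 = s[ok & (labels == 2)]
        if len(g1) == 0 or len(g2) == 0:
            raise ClinicalError(f"variable {var!r} entirely missing in a group")
        if kind == CONTINUOUS:
            stat, p = stats.ttest_ind(g1.astype(float), g2.astype(float),
                                      equal_var=True)
            s1 = f"{g1.mean():.2f} +/- {g1.std(ddof=1):.2f}"
            s2 = f"{g2.mean():.2f} +/- {g2.std(ddof=1):.2f}"
        else:
            levels = sorted(pd.unique(s[ok]), key=str)
            tab = np.array([[(g1 == lv).sum(), (g2 == lv).sum()]
                            for lv in levels], dtype=int)
            if len(levels) < 2:
                stat, p = np.nan, 1.0
            elif len(levels) == 2:
                stat, p = fisher_exact(tab)
            else:
                stat, p = np.nan, exact_rx2_test(tab)
            top = levels[-1]  # summarize the highest level (1 for binaries)
            c1, c2 = (g1 == top).sum(), (g2 == top).sum()
            s1 = f"{c1} ({100.0 * c1 / len(g1):.0f}%)"
            s2 = f"{c2} ({100.0 * c2 / len(g2):.0f}%)"
        rows.append((var, kind, len(g1), len(g2), s1, s2, stat, p))
    return pd.DataFrame(rows, columns=["variable", "type", "n1", "n2",
                                       "summary1", "summary2", "statistic",
                                       "p"]).set_index("variable")


# -- per-protein logistic odds ratios ------------------------------------

def _fit_logistic(x: np.ndarray, y: np.ndarray,
                  tol: float = 1e-8, maxiter: int = 100):
    """Univariable logistic fit by IRLS; returns (beta, se, flagged).

    Separation (diverging coefficient) is flagged and the coefficient
    reported at the bound the iteration reached.
    """
    design = sm.add_constant(x)
    model = sm.GLM(y, design, family=sm.families.Binomial())
    try:
        with np.errstate(all="ignore"):
            fit = model.fit(maxiter=maxiter, tol=tol)  # IRLS on deviance
        beta = float(fit.params[1])
        se = float(fit.bse[1])
    except Exception:  # perfect separation aborts the IRLS
        return _fit_logistic_ridge(design, y)
    flagged = (not np.isfinite(se)) or abs(beta) > 15 or se > 100
    return beta, se, flagged


def _fit_logistic_ridge(design: np.ndarray, y: np.ndarray):
    """Fallback for separated data: tiny ridge keeps the fit finite."""
    model = sm.GLM(y, design, family=sm.families.Binomial())
    with np.errstate(all="ignore"):
        fit = model.fit_regularized(alpha=1e-6, L1_wt=0.0)
    beta = float(fit.params[1])
    return beta, np.inf, True


def protein_outcome_or(X: ExpressionMatrix, outcome: pd.Series,
                       proteins=None, standardize: bool = True) -> pd.DataFrame:
    """Univariable logistic OR of a binary outcome per protein.

    Expression is standardized to zero mean / unit sd per protein (so the
    OR is per SD of log2 expression) unless ``standardize=False``.
    Separation or non-identifiable fits are flagged and their OR reported
    at the diverged bound.  Returns OR, 95% Wald CI, p and BH q.
    """
    if X.scale != LOG2:
        raise ClinicalError("protein_outcome_or expects a log2 matrix")
    outcome = outcome.reindex(X.subject_ids)
    ok = outcome.notna()
    y = outcome[ok].astype(float).to_numpy()
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ClinicalError("outcome must be binary with both classes present")
    cols = list(X.protein_ids if proteins is None else proteins)
    missing = [p for p in cols if p not in X.protein_ids]
    if missing:
        raise ClinicalError(f"proteins absent: {', '.join(map(str, missing[:10]))}")

    z975 = stats.norm.ppf(0.975)
    rows = []
    for pid in cols:
        x = X.values.loc[ok, pid].to_numpy(dtype=float)
        if standardize:
            sd = x.std(ddof=0)
            if sd == 0:
                raise ClinicalError(f"zero-variance protein {pid!r}")
            x = (x - x.mean()) / sd
        beta, se, flagged = _fit_logistic(x, y)
        if flagged or not np.isfinite(se):
            p = 1.0 if not np.isfinite(se) else \
                2.0 * stats.norm.sf(abs(beta) / se)
        else:
            p = 2.0 * stats.norm.sf(abs(beta) / se)
        with np.errstate(over="ignore"):
            rows.append((pid, np.exp(beta), np.exp(beta - z975 * se),
                         np.exp(beta + z975 * se), p, flagged))
    out = pd.DataFrame(rows, columns=["protein_id", "OR", "ci_low", "ci_high",
                                      "p", "flagged"]).set_index("protein_id")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ClinicalError("need equal-length vectors with >= 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ClinicalError("zero-variance input")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ClinicalError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)
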