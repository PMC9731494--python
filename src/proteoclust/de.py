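"""Two-group moderated differential expression.

Per protein the statistic is an empirical-Bayes moderated t: the pooled
within-group residual variance ``s_g^2`` (``d_g`` degrees of freedom) is
shrunk toward a panel-wide prior variance ``s0^2`` with prior degrees of
freedom ``d0``,

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_g = log2fc_g / (s_tilde_g * sqrt(1/n1 + 1/n2))

with two-sided p-values from a t distribution on ``d0 + d_g`` degrees of
freedom.  The prior ``(d0, s0^2)`` is estimated by method of moments on
``log s_g^2``, using the exact mean/variance of log chi-square variables
(digamma/trigamma moments); this is the standard scaled-F empirical-Bayes
derivation.  Forcing ``d0 = 0`` recovers the ordinary equal-variance t
test; ``d0 = inf`` gives a z-like statistic with the pooled prior
variance.

Significance follows the magnitude rule: fold change ``2**|log2fc| > 1.5``
and Benjamini-Hochberg FDR ``q < 0.05`` (both strict).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, LOG2

FC_THRESHOLD = 1.5
Q_THRESHOLD = 0.05

UP_IN_2 = "up_in_2"
UP_IN_1 = "up_in_1"
NONE = "none"


class DEError(ValueError):
    pass


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log sample variances.

    Matches the first two moments of ``log(s2)`` to those of a scaled-F
    distribution; returns ``(d0, s0^2)`` with ``d0 = inf`` when the
    observed spread of log variances is no larger than expected from
    chi-square sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise DEError("need >=2 positive sample variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s02 = np.exp(emean)
    return float(d0), float(s02)


def _group_arrays(X: ExpressionMatrix, labels: pd.Series,
                  proteins=None) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    labels = labels.reindex(X.subject_ids)
    if labels.isna().any():
        raise DEError("labels missing for some subjects")
    cols = X.protein_ids if proteins is None else pd.Index(proteins)
    vals = X.values[cols]
    g1 = vals.loc[labels == 1].to_numpy(dtype=float)
    g2 = vals.loc[labels == 2].to_numpy(dtype=float)
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise DEError("each group needs at least 2 subjects")
    return g1, g2, cols


def moderated_ttest(X: ExpressionMatrix, labels: pd.Series,
                    proteins=None, d0: float | None = None) -> pd.DataFrame:
    """Moderated t per protein for groups labeled 1 and 2.

    Parameters
    ----------
    X
        log2-scale expression matrix.
    labels
        Per-subject group labels in {1, 2}, aligned by subject id.
    proteins
        Optional subset of proteins to test (default: all columns).
    d0
        Prior degrees of freedom; ``None`` estimates them from the data,
        ``0`` gives the ordinary equal-variance t test, ``inf`` the
        fully-shrunk z-like statistic.

    Returns a DataFrame indexed by protein id with columns ``log2fc``,
    ``fold_change``, ``t_mod``, ``p``, ``degenerate`` plus the fitted
    prior in ``.attrs``.
    """
    if X.scale != LOG2:
        raise DEError("moderated_ttest expects a log2-scale matrix")
    g1, g2, cols = _group_arrays(X, labels, proteins)
    n1, n2 = g1.shape[0], g2.shape[0]
    df_resid = n1 + n2 - 2

    mean1, mean2 = g1.mean(axis=0), g2.mean(axis=0)
    log2fc = mean2 - mean1
    ss = ((g1 - mean1) ** 2).sum(axis=0) + ((g2 - mean2) ** 2).sum(axis=0)
    s2 = ss / df_resid

    if d0 is None:
        d0_fit, s02 = estimate_prior(s2, df_resid)
    elif d0 == 0:
        d0_fit, s02 = 0.0, 0.0
    elif np.isinf(d0):
        _, s02 = estimate_prior(s2, df_resid)
        d0_fit = np.inf
    else:
        _, s02 = estimate_prior(s2, df_resid)
        d0_fit = float(d0)

    if np.isinf(d0_fit):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0_fit * s02 + df_resid * s2) / (d0_fit + df_resid)
        df_total = d0_fit + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, log2fc / np.where(se == 0, 1.0, se))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(degenerate, 1.0, p)

    out = pd.DataFrame({
        "log2fc": log2fc,
        "fold_change": 2.0 ** np.abs(log2fc),
        "t_mod": t,
        "p": p,
        "degenerate": degenerate,
    }, index=cols)
    out.attrs["d0"] = d0_fit
    out.attrs["s02"] = s02
    out.attrs["df_resid"] = df_resid
    out.attrs["n1"], out.attrs["n2"] = n1, n2
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DEError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DEError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def annotate_significance(de: pd.DataFrame,
                          fc_threshold: float = FC_THRESHOLD,
                          q_threshold: float = Q_THRESHOLD) -> pd.DataFrame:
    """Add ``q``, ``direction`` and ``significant`` columns to a DE table."""
    de = de.copy()
    de["q"] = bh_fdr(de["p"].to_numpy())
    de["direction"] = np.where(de["log2fc"] > 0, UP_IN_2,
                               np.where(de["log2fc"] < 0, UP_IN_1, NONE))
    de["significant"] = (de["fold_change"] > fc_threshold) & \
        (de["q"] < q_threshold)
    return de


def call_significant(de: pd.DataFrame, fc_threshold: float = FC_THRESHOLD,
                     q_threshold: float = Q_THRESHOLD,
                     ) -> tuple[list[str], list[str]]:
    """Disjoint (up_in_2, up_in_1) protein id lists, strict thresholds."""
    if "q" not in de.columns:
        de = annotate_significance(de, fc_threshold, q_threshold)
    sig = (de["fold_change"] > fc_threshold) & (de["q"] < q_threshold)
    up2 = list(de.index[sig & (de["log2fc"] > 0)])
    up1 = list(de.index[sig & (de["log2fc"] < 0)])
    return up2, up1


def differential_expression(X: ExpressionMatrix, labels: pd.Series,
                            proteins=None, d0: float | None = None,
                            fc_threshold: float = FC_THRESHOLD,
                            q_threshold: float = Q_THRESHOLD) -> pd.DataFrame:
    """Moderated t + BH FDR + significance calls in one table."""
    de = moderated_ttest(X, labels, proteins=proteins, d0=d0)
    return annotate_significance(de, fc_threshold, q_threshold)


def flip_groups(de: pd.DataFrame) -> pd.DataFrame:
    """DE table as if group labels 1 and 2 had been swapped."""
    out = de.copy()
    out["log2fc"] = -out["log2fc"]
    out["t_mod"] = -out["t_mod"]
    if "direction" in out.columns:
        out["direction"] = out["direction"].map(
            {UP_IN_2: UP_IN_1, UP_IN_1: UP_IN_2, NONE: NONE})
    return out
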