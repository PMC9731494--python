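"""Agnostic cross-cohort validation and paired-visit switching analysis.

Transfer validation re-runs the whole unsupervised stage (variance
filter, Ward clustering, DE-based canonicalization) on a new cohort's
data alone; the learned up-regulated set is used only afterwards, to
score the new clusters and to measure the up-set overlap.  The paired
analysis clusters each visit independently and classifies each subject's
visit-2 state as Cluster 1, Cluster 2 or "mixed"; a mixed call means the
subject's visit-2 protein score falls strictly inside the middle band of
the segment joining the two cluster score medians (quarter points by
default; equal fractions collapse the band and yield a plain 2x2
transition table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as cl
from . import de as de_mod
from .clinical import fisher_exact
from .enrich import hypergeom_upper, overlap_enrichment
from .matrix import ExpressionMatrix
from .score import ScoreComparison, compare_scores, protein_score


class ValidationError(ValueError):
    pass


@dataclass
class LearningResult:
    """Output of the unsupervised learning stage on one cohort/visit."""

    cluster: cl.ClusterResult
    de: pd.DataFrame
    up2: list[str]
    up1: list[str]
    scores: pd.Series
    score_comparison: ScoreComparison


def learning_pipeline(X: ExpressionMatrix, fraction: float = 0.10,
                      exclude=(), d0: float | None = None) -> LearningResult:
    """Variance filter -> Ward clustering -> DE -> canonical labels -> score."""
    panel = cl.select_variable_proteins(X, fraction, exclude)
    raw = cl.hierarchical_cluster(X, proteins=panel)
    de = de_mod.differential_expression(
        X, raw.labels, proteins=[p for p in X.protein_ids
                                 if p not in set(exclude)], d0=d0)
    result = cl.canonicalize_labels(raw, de, X)
    if not result.labels.equals(raw.labels):
        de = de_mod.flip_groups(de)
    up2, up1 = de_mod.call_significant(de)
    if up2:
        scores = protein_score(X, up2)
        comparison = compare_scores(scores, result.labels)
    else:
        scores = X.values[result.selected_proteins].median(axis=1)
        comparison = compare_scores(scores, result.labels)
    return LearningResult(cluster=result, de=de, up2=up2, up1=up1,
                          scores=scores, score_comparison=comparison)


@dataclass
class TransferReport:
    """Agnostic revalidation of the cluster structure in a new cohort."""

    learning: LearningResult
    learned_scores: pd.Series            # score with the LEARNED up-set
    learned_score_comparison: ScoreComparison
    overlap_k: int
    overlap_pct: int
    overlap_p: float


def transfer_validate(X_new: ExpressionMatrix, learned_up_set,
                      fraction: float = 0.10, exclude=(),
                      ) -> TransferReport:
    """Re-cluster a new cohort agnostically, then score with the learned set."""
    learned = list(learned_up_set)
    missing = [p for p in learned if p not in X_new.protein_ids]
    if missing:
        raise ValidationError(
            f"new cohort lacks learned proteins: {', '.join(map(str, missing[:10]))}")
    res = learning_pipeline(X_new, fraction=fraction, exclude=exclude)
    scores = protein_score(X_new, learned)
    comparison = compare_scores(scores, res.cluster.labels)
    universe = [p for p in X_new.protein_ids if p not in set(exclude)]
    # percentage reported relative to the NEW cohort's up-set
    k, pct, p = overlap_enrichment(learned, res.up2, universe)
    return TransferReport(learning=res, learned_scores=scores,
                          learned_score_comparison=comparison,
                          overlap_k=k, overlap_pct=pct, overlap_p=p)


# -- paired-visit switching ----------------------------------------------

DESTINATIONS = (1, 2, "mixed")


@dataclass
class TransitionTable:
    """Origin x destination counts for paired-visit subjects."""

    counts: pd.DataFrame                 # index {1,2}, columns {1,2,'mixed'}
    concordant: int
    total: int
    fisher_p: float
    mixed_zone: tuple[float, float]
    destinations: pd.Series = field(repr=False, default=None)

    def count(self, origin, dest) -> int:
        return int(self.counts.loc[origin, dest])


def switching_analysis(labels_v1: pd.Series, labels_v2: pd.Series,
                       scores_v2: pd.Series,
                       mixed_lo: float = 0.25, mixed_hi: float = 0.75,
                       ) -> TransitionTable:
    """Paired-visit transition table with a mixed-profile category.

    ``labels_v1`` / ``labels_v2`` are canonical per-visit cluster labels;
    ``scores_v2`` is the visit-2 protein score (learned up-set).  A
    subject's destination is "mixed" when its score lies strictly inside
    ``(m_lo + mixed_lo * d, m_lo + mixed_hi * d)`` where ``m_lo``/``m_hi``
    are the visit-2 cluster score medians and ``d = m_hi - m_lo``;
    otherwise the destination is its visit-2 cluster.  Concordance counts
    subjects with the same non-mixed identity at both visits; the Fisher
    test runs on the plain 2x2 collapse (mixed folded back into the
    visit-2 cluster label).
    """
    if not 0 <= mixed_lo <= mixed_hi <= 1:
        raise ValidationError("mixed-zone fractions must satisfy 0<=lo<=hi<=1")
    idx = labels_v1.index
    unmatched = idx.symmetric_difference(labels_v2.index)
    if len(unmatched):
        raise ValidationError(
            f"unmatched subject ids: {', '.join(map(str, unmatched[:10]))}")
    labels_v2 = labels_v2.reindex(idx)
    scores_v2 = scores_v2.reindex(idx)
    if scores_v2.isna().any():
        raise ValidationError("visit-2 scores missing for some subjects")

    med = {g: float(scores_v2[labels_v2 == g].median()) for g in (1, 2)}
    m_lo, m_hi = min(med.values()), max(med.values())
    delta = m_hi - m_lo
    lo = m_lo + mixed_lo * delta
    hi = m_lo + mixed_hi * delta
    in_zone = (scores_v2 > lo) & (scores_v2 < hi)
    dest = labels_v2.astype(object).where(~in_zone, "mixed")

    counts = pd.DataFrame(0, index=pd.Index([1, 2], name="origin"),
                          columns=pd.Index(list(DESTINATIONS), name="dest"))
    for o in (1, 2):
        for d in DESTINATIONS:
            counts.loc[o, d] = int(((labels_v1 == o) & (dest == d)).sum())
    concordant = counts.loc[1, 1] + counts.loc[2, 2]

    collapse = pd.crosstab(labels_v1, labels_v2).reindex(
        index=[1, 2], columns=[1, 2], fill_value=0)
    try:
        _, fisher_p = fisher_exact(collapse.to_numpy())
    except Exception:
        fisher_p = 1.0
    return TransitionTable(counts=counts, concordant=int(concordant),
                           total=len(idx), fisher_p=float(fisher_p),
                           mixed_zone=(lo, hi), destinations=dest)


def visit_consistency_report(de_v1: pd.DataFrame, de_v2: pd.DataFrame) -> dict:
    """Overlap of the per-visit up-regulated sets, both directions.

    Percentages are relative to the visit-2 sets; the hypergeometric p
    uses the proteins tested at both visits as the universe.
    """
    up2_v1, up1_v1 = de_mod.call_significant(de_v1)
    up2_v2, up1_v2 = de_mod.call_significant(de_v2)
    universe = de_v1.index.intersection(de_v2.index)
    out = {}
    for side, (a, b) in {"up_in_2": (up2_v1, up2_v2),
                         "up_in_1": (up1_v1, up1_v2)}.items():
        shared = sorted(set(a) & set(b))
        pct = int(round(100.0 * len(shared) / len(b))) if b else 0
        p = hypergeom_upper(len(shared), len(universe), len(a), len(b)) \
            if a and b else 1.0
        out[side] = {"n_v1": len(a), "n_v2": len(b), "shared": len(shared),
                     "pct_of_v2": pct, "p": p, "shared_ids": shared}
    return out
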