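"""Per-patient protein score and the short-signature selection procedure.

The protein score of a patient is the median log2 expression over a
designated set of up-regulated proteins (by default the proteins
up-regulated in Cluster 2).  Score separation between clusters is tested
with a two-sided rank-sum test (exact for small tie-free groups).

The 15-protein signature is selected deterministically from the DE,
enrichment and clinical-odds-ratio tables: the Cluster-2 side takes
family representatives from the top decile of up-regulated proteins
(families = each candidate's most-enriched annotated term, ranked within
family by the strongest clinical odds ratio); the Cluster-1 side takes
the largest fold changes after an exclusion list is applied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import UP_IN_1, UP_IN_2
from .matrix import ExpressionMatrix, LOG2


class ScoreError(ValueError):
    pass


def protein_score(X: ExpressionMatrix, up_set) -> pd.Series:
    """Per-subject median log2 expression over ``up_set`` columns."""
    if X.scale != LOG2:
        raise ScoreError("protein score expects a log2 matrix")
    up = list(up_set)
    if not up:
        raise ScoreError("empty up-regulated set")
    missing = [p for p in up if p not in X.protein_ids]
    if missing:
        raise ScoreError(
            f"proteins absent from the panel: {', '.join(map(str, missing[:10]))}")
    scores = X.values[up].median(axis=1)
    scores.name = "protein_score"
    return scores


@dataclass
class ScoreComparison:
    median_1: float
    median_2: float
    statistic: float
    p: float
    method: str


def compare_scores(scores: pd.Series, labels: pd.Series) -> ScoreComparison:
    """Two-sided rank-sum comparison of scores between clusters 1 and 2.

    Exact null distribution when both groups have <= 25 subjects and the
    pooled scores are tie-free; normal approximation with tie correction
    otherwise.
    """
    labels = labels.reindex(scores.index)
    g1 = scores[labels == 1].to_numpy()
    g2 = scores[labels == 2].to_numpy()
    if len(g1) == 0 or len(g2) == 0:
        raise ScoreError("both clusters must be nonempty")
    pooled = np.concatenate([g1, g2])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(g1) <= 25 and len(g2) <= 25 and tie_free) \
        else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return ScoreComparison(median_1=float(np.median(g1)),
                           median_2=float(np.median(g2)),
                           statistic=float(res.statistic), p=float(res.pvalue),
                           method=method)


# -- signature selection --------------------------------------------------

@dataclass
class SignatureConfig:
    n_cluster2: int = 11
    n_cluster1: int = 4
    de_fraction: float = 0.10
    outcomes: tuple[str, ...] | None = None  # columns of the OR table to use
    exclude: tuple[str, ...] = ()            # failed external replication


@dataclass
class SignatureSpec:
    """Selected signature members plus an auditable selection log."""

    members: pd.DataFrame          # protein_id index; side, family, log2fc
    selection_log: list[str] = field(default_factory=list)

    @property
    def cluster2_ids(self) -> list[str]:
        return list(self.members.index[self.members["side"] == "cluster2"])

    @property
    def cluster1_ids(self) -> list[str]:
        return list(self.members.index[self.members["side"] == "cluster1"])

    def to_json(self) -> str:
        return json.dumps({
            "members": self.members.reset_index().to_dict(orient="records"),
            "selection_log": self.selection_log,
        }, indent=1)


def _family_of(protein: str, enrichment: pd.DataFrame) -> str | None:
    """Most-enriched term containing the protein (smallest q, then id)."""
    hits = enrichment[[protein in m.split(";")
                       for m in enrichment["members"]]]
    if hits.empty:
        return None
    hits = hits.sort_values("q", kind="stable")
    return str(hits.index[0])


def select_signature(de: pd.DataFrame, enrichment: pd.DataFrame,
                     or_table: pd.DataFrame,
                     config: SignatureConfig | None = None) -> SignatureSpec:
    """Deterministic short-signature selection.

    Parameters
    ----------
    de
        Significance-annotated DE table (canonical labels).
    enrichment
        Enrichment table for the Cluster-2 up-set, with ``members`` and
        ``q`` columns (see :func:`proteoclust.enrich.enrich`).
    or_table
        Per-protein clinical odds ratios; either a long table with
        columns ``outcome`` and ``OR`` indexed by protein id, or a wide
        table of OR columns per outcome.
    """
    cfg = config or SignatureConfig()
    log: list[str] = []

    sig = de[de["significant"]]
    up2 = sig[sig["direction"] == UP_IN_2].copy()
    up1 = sig[sig["direction"] == UP_IN_1].copy()
    if enrichment is None or enrichment.empty:
        raise ScoreError("empty enrichment table")

    # --- cluster-2 side: family representatives from the top decile
    up2 = up2.iloc[np.lexsort((up2.index.astype(str),
                               -np.abs(up2["log2fc"].to_numpy())))]
    n_pool = max(1, math.floor(cfg.de_fraction * len(up2)))
    pool = up2.iloc[:n_pool]
    log.append(f"cluster2 pool: top {n_pool} of {len(up2)} up-regulated "
               f"proteins by |log2fc| (fraction {cfg.de_fraction})")

    strength = _or_strength(or_table, cfg.outcomes)
    families: dict[str, list[str]] = {}
    for pid in pool.index:
        fam = _family_of(str(pid), enrichment) or "_unannotated"
        families.setdefault(fam, []).append(str(pid))
    # order candidates within family by |log OR| desc, then |log2fc|, then id
    for fam, pids in families.items():
        pids.sort(key=lambda p: (-strength.get(p, 0.0),
                                 -abs(float(pool.loc[p, "log2fc"])), p))
    fam_order = [f for f in enrichment.sort_values("q", kind="stable").index
                 if str(f) in families]
    fam_order = [str(f) for f in fam_order]
    if "_unannotated" in families:
        fam_order.append("_unannotated")

    chosen2: list[str] = []
    rank = 0
    while len(chosen2) < cfg.n_cluster2:
        took = False
        for fam in fam_order:
            if len(chosen2) >= cfg.n_cluster2:
                break
            cands = families[fam]
            if rank < len(cands):
                chosen2.append(cands[rank])
                log.append(f"cluster2 pick {len(chosen2)}: {cands[rank]} "
                           f"(family {fam}, round {rank + 1})")
                took = True
        if not took:
            log.append(f"warning: only {len(chosen2)} cluster2 candidates "
                       f"available for requested {cfg.n_cluster2}")
            break
        rank += 1

    # --- cluster-1 side: largest |log2fc| after exclusions
    excluded = [p for p in cfg.exclude if p in up1.index]
    for p in excluded:
        log.append(f"cluster1 exclusion applied: {p}")
    up1 = up1.drop(index=excluded)
    up1 = up1.iloc[np.lexsort((up1.index.astype(str),
                               -np.abs(up1["log2fc"].to_numpy())))]
    chosen1 = [str(p) for p in up1.index[:cfg.n_cluster1]]
    for i, p in enumerate(chosen1):
        log.append(f"cluster1 pick {i + 1}: {p} "
                   f"(|log2fc|={abs(float(up1.loc[p, 'log2fc'])):.3f})")
    if len(chosen1) < cfg.n_cluster1:
        log.append(f"warning: only {len(chosen1)} cluster1 candidates "
                   f"available for requested {cfg.n_cluster1}")

    fam_of = {p: f for f, pids in families.items() for p in pids}
    members = pd.DataFrame({
        "side": ["cluster2"] * len(chosen2) + ["cluster1"] * len(chosen1),
        "family": [fam_of.get(p, "") for p in chosen2] + [""] * len(chosen1),
        "log2fc": [float(de.loc[p, "log2fc"]) for p in chosen2 + chosen1],
    }, index=pd.Index(chosen2 + chosen1, name="protein_id"))
    return SignatureSpec(members=members, selection_log=log)


def _or_strength(or_table: pd.DataFrame,
                 outcomes: tuple[str, ...] | None) -> dict[str, float]:
    """Max |log OR| per protein over the configured outcomes."""
    if or_table is None or len(or_table) == 0:
        return {}
    t = or_table
    if "outcome" in t.columns:      # long form
        if outcomes:
            t = t[t["outcome"].isin(outcomes)]
        grp = t.groupby(t.index)["OR"].agg(
            lambda s: np.max(np.abs(np.log(s.to_numpy(dtype=float)))))
        return {str(k): float(v) for k, v in grp.items()}
    cols = [c for c in t.columns if (outcomes is None or c in outcomes)]
    vals = np.abs(np.log(t[cols].to_numpy(dtype=float)))
    return {str(k): float(v) for k, v in
            zip(t.index, np.nanmax(vals, axis=1))}
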