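"""Variance filtering, hierarchical patient clustering, canonical labels.

Subjects are segmented by agglomerative clustering (Euclidean distance,
Ward linkage) of the top fraction of proteins by log2 standard deviation,
each selected protein standardized to zero mean / unit variance first.
Cluster numbers coming out of the tree cut are arbitrary; the canonical
convention is that **Cluster 2 is the side with more significantly
up-regulated proteins** (ties broken by the higher mean per-subject median
expression over the clustering panel).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from . import de as de_mod
from .matrix import ExpressionMatrix, LOG2


class ClusterError(ValueError):
    pass


@dataclass
class ClusterResult:
    """Two-group partition of subjects.

    ``labels`` maps subject id -> {1, 2}; ``merge_tree`` is the scipy
    linkage matrix; ``label_rule`` records how canonical identities were
    assigned (empty until :func:`canonicalize_labels` runs).
    """

    labels: pd.Series
    selected_proteins: list[str]
    merge_tree: np.ndarray
    canonicalized: bool = False
    label_rule: str = ""

    @property
    def sizes(self) -> dict[int, int]:
        vc = self.labels.value_counts()
        return {int(k): int(v) for k, v in vc.items()}

    def swapped(self) -> "ClusterResult":
        return replace(self, labels=self.labels.map({1: 2, 2: 1}))


def select_variable_proteins(X: ExpressionMatrix, fraction: float = 0.10,
                             exclude=()) -> list[str]:
    """Top ``floor(fraction * n)`` proteins by across-subject sd.

    Control probes (or any ids in ``exclude``) are dropped before
    ranking; ties are broken by column order.
    """
    if X.scale != LOG2:
        raise ClusterError("variance selection expects a log2 matrix")
    if not 0 < fraction <= 1:
        raise ClusterError("fraction must lie in (0, 1]")
    excluded = set(exclude)
    cols = [p for p in X.protein_ids if p not in excluded]
    sd = X.values[cols].std(axis=0, ddof=1)
    n_sel = int(np.floor(fraction * len(cols)))
    if n_sel < 2:
        raise ClusterError(
            f"fraction {fraction} selects {n_sel} proteins; need >= 2")
    order = np.argsort(-sd.to_numpy(), kind="stable")
    return [cols[i] for i in order[:n_sel]]


def hierarchical_cluster(X: ExpressionMatrix, proteins=None, k: int = 2,
                         fraction: float = 0.10, exclude=()) -> ClusterResult:
    """Ward clustering of subjects on z-scored selected proteins.

    ``proteins`` defaults to :func:`select_variable_proteins` output.
    Deterministic for fixed input (scipy's linkage breaks merge ties by
    smallest index).
    """
    if X.scale != LOG2:
        raise ClusterError("clustering expects a log2 matrix")
    if proteins is None:
        proteins = select_variable_proteins(X, fraction, exclude)
    proteins = list(proteins)
    if not proteins:
        raise ClusterError("empty protein panel")
    if k > X.n_subjects:
        raise ClusterError("k exceeds the number of subjects")

    panel = X.values[proteins]
    sd = panel.std(axis=0, ddof=1)
    if (sd == 0).all():
        raise ClusterError("zero-variance panel after standardization")
    keep = sd > 0
    z = (panel.loc[:, keep] - panel.loc[:, keep].mean(axis=0)) / sd[keep]

    linkage = hierarchy.linkage(z.to_numpy(), method="ward",
                                metric="euclidean")
    flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    labels = pd.Series(flat.astype(int), index=X.subject_ids)
    if labels.nunique() != k:
        raise ClusterError(f"tree cut produced {labels.nunique()} < {k} groups")
    return ClusterResult(labels=labels, selected_proteins=proteins,
                         merge_tree=linkage)


def canonicalize_labels(result: ClusterResult, de: pd.DataFrame,
                        X: ExpressionMatrix) -> ClusterResult:
    """Assign canonical Cluster 1/2 identities.

    ``de`` must be the significance-annotated DE table computed with the
    result's raw labels (group 2 = raw label 2).  The group with more
    significantly up-regulated proteins becomes Cluster 2; on a tie the
    group with the higher mean per-subject median over the clustering
    panel wins.
    """
    up2, up1 = de_mod.call_significant(de)
    if len(up2) > len(up1):
        swap = False
        rule = (f"raw group 2 kept as Cluster 2 "
                f"({len(up2)} vs {len(up1)} up-regulated proteins)")
    elif len(up2) < len(up1):
        swap = True
        rule = (f"raw groups swapped: group 1 had more up-regulated "
                f"proteins ({len(up1)} vs {len(up2)})")
    else:
        panel = result.selected_proteins or list(X.protein_ids)
        med = X.values[panel].median(axis=1)
        score1 = med[result.labels == 1].mean()
        score2 = med[result.labels == 2].mean()
        swap = score1 > score2
        rule = (f"up-regulated counts tied at {len(up2)}; higher mean panel "
                f"score labeled Cluster 2 ({score1:.3f} vs {score2:.3f})")
    out = result.swapped() if swap else replace(result)
    return replace(out, canonicalized=True, label_rule=rule)
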