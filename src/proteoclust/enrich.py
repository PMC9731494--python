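"""Over-representation analysis against a term -> protein annotation.

The test is the upper-tail hypergeometric: drawing ``n = |set|`` proteins
from a universe of ``N``, the p-value for a term with ``K`` members and
``k`` observed overlaps is ``P[X >= k]``.  Benjamini-Hochberg adjustment
runs across terms.  Depletion is not tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr

REPORT_Q = 1e-4


class EnrichError(ValueError):
    pass


def _as_term_map(annotation) -> dict[str, set]:
    """Accept {term: members} or a (term_id, protein_id) DataFrame."""
    if isinstance(annotation, pd.DataFrame):
        cols = list(annotation.columns[:2])
        return {t: set(g[cols[1]]) for t, g in annotation.groupby(cols[0])}
    return {t: set(m) for t, m in annotation.items()}


def hypergeom_upper(k: int, big_n: int, big_k: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, big_n, big_k, n))


def enrich(protein_set, annotation, universe,
           report_q: float = REPORT_Q) -> pd.DataFrame:
    """Term-by-term over-representation of ``protein_set``.

    Terms are intersected with ``universe`` first; the returned table is
    sorted by p with columns ``term_size``, ``overlap``, ``p``, ``q``,
    ``members`` (overlap ids) and ``pass_filter`` (q < ``report_q``, the
    default reporting threshold).
    """
    universe = set(universe)
    pset = set(protein_set)
    if not universe or not pset:
        raise EnrichError("empty universe or protein set")
    if not pset <= universe:
        raise EnrichError("protein set must be a subset of the universe")
    terms = _as_term_map(annotation)
    rows = []
    for term, members in sorted(terms.items()):
        members = members & universe
        if not members:
            continue
        overlap = sorted(members & pset)
        p = hypergeom_upper(len(overlap), len(universe), len(members),
                            len(pset))
        rows.append((term, len(members), len(overlap), p,
                     ";".join(overlap)))
    if not rows:
        raise EnrichError("no annotation terms intersect the universe")
    out = pd.DataFrame(rows, columns=["term_id", "term_size", "overlap",
                                      "p", "members"]).set_index("term_id")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["pass_filter"] = out["q"] < report_q
    # rows were assembled in term order, so a stable sort on p keeps
    # term-id order among ties
    return out.sort_values("p", kind="stable")


def overlap_enrichment(set_a, set_b, universe) -> tuple[int, int, float]:
    """Overlap of ``set_a`` with ``set_b`` inside ``universe``.

    Returns ``(k, percentage_of_set_b, p)`` where the percentage is
    rounded to an integer and p is the upper-tail hypergeometric
    probability of an overlap at least this large.
    """
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not b:
        raise EnrichError("empty reference set")
    if not (a <= universe and b <= universe):
        raise EnrichError("both sets must be subsets of the universe")
    k = len(a & b)
    pct = int(round(100.0 * k / len(b)))
    p = hypergeom_upper(k, len(universe), len(b), len(a))
    return k, pct, p
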