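"""Four-step intensity standardization and log2 transform.

Aptamer platforms report raw fluorescence that carries per-sample
hybridization efficiency, per-plate batch scale and residual per-sample
signal differences on top of biology.  The standardization used here is a
sequence of median-ratio scalings:

1. **Hybridization normalization** - each sample is divided by the ratio of
   its hybridization-control median to the run-wide median of those probes.
2. **Plate scaling** - each plate is multiplied by
   (grand median of plate medians) / (its plate median).
3. **Median signal normalization** - each sample is scaled so that its
   median over biological (non-control) proteins matches the run-wide
   median, within dilution group when groups are annotated.
4. **Calibration** - each plate is scaled so that its calibrator-probe
   medians match a reference (the run-wide calibrator medians by default,
   or the medians of an external reference matrix, which aligns the level
   of one run to another).

Steps 2-4 measure and correct biological-signal scale, so they are
computed from and applied to the biological columns; the control probes
carry pure technical scale and are touched only by step 1.  A single pass
of the four steps leaves small interactions behind (each scaling perturbs
the previous step's fixed point), so by default the cycle is repeated
until all four fixed points hold jointly; the result is then idempotent to
numerical precision.  Set ``single_pass=True`` for one sweep in the
listed order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import LOG2, RAW, ExpressionMatrix, MatrixError, PanelMeta


class NormalizationError(ValueError):
    """Degenerate input to the standardization procedure."""


@dataclass
class NormalizationInfo:
    """Diagnostics from :func:`standardize`.

    ``sample_factor`` is the per-sample composite scale removed from the
    data (raw / normalized median ratio); on generator output it should
    track the planted hybridization-drift x plate factors.
    """

    sample_factor: pd.Series
    n_cycles: int
    converged: bool


def _safe_median(x: pd.Series | np.ndarray, what: str) -> float:
    med = float(np.median(x))
    if not np.isfinite(med) or med <= 0:
        raise NormalizationError(f"nonpositive median for {what}")
    return med


def _one_pass(v: np.ndarray, hyb_idx: np.ndarray, cal_idx: np.ndarray,
              bio_idx: np.ndarray, groups_idx: list[np.ndarray],
              plate_rows: list[np.ndarray],
              reference: np.ndarray | None) -> np.ndarray:
    """One sweep of the four standardization steps (in place).

    Step 1 (hybridization) rescales entire samples from the
    hybridization-control probes.  Steps 2-4 estimate and correct
    biological-signal scale, so they are computed from and applied to the
    biological columns; control probes carry pure technical scale and
    keeping them out of the later steps is what lets the sweep reach an
    exact joint fixed point.
    """
    # step 1: hybridization normalization (whole sample)
    r = np.median(v[:, hyb_idx], axis=1)
    if (r <= 0).any():
        raise NormalizationError("zero hybridization-control median")
    big_r = _safe_median(r, "hybridization controls")
    v /= (r / big_r)[:, None]

    # step 2: plate scaling (plate median = median of its samples' medians)
    sample_med = np.median(v[:, bio_idx], axis=1)
    if (sample_med <= 0).any():
        raise NormalizationError("zero sample median")
    plate_med = np.array([np.median(sample_med[rows]) for rows in plate_rows])
    grand = _safe_median(plate_med, "plate medians")
    for rows, pm in zip(plate_rows, plate_med):
        v[np.ix_(rows, bio_idx)] *= grand / pm

    # step 3: median signal normalization (within dilution group if given)
    for cols in groups_idx:
        m = np.median(v[:, cols], axis=1)
        if (m <= 0).any():
            raise NormalizationError("zero sample median in dilution group")
        v[:, cols] /= (m / _safe_median(m, "sample medians"))[:, None]

    # step 4: calibration — per-plate scale from the calibrator probes,
    # aligning each plate's calibrator levels to the reference (the
    # run-wide calibrator medians when no external reference is given)
    ref = np.median(v[:, cal_idx], axis=0) if reference is None else reference
    for rows in plate_rows:
        pm = np.median(v[np.ix_(rows, cal_idx)], axis=0)
        if (pm <= 0).any():
            raise NormalizationError("zero calibrator median on a plate")
        v[np.ix_(rows, bio_idx)] *= np.median(ref / pm)
    return v


def standardize(raw: ExpressionMatrix, meta: PanelMeta,
                reference: ExpressionMatrix | None = None,
                *, single_pass: bool = False, max_cycles: int = 60,
                tol: float = 1e-12,
                return_info: bool = False):
    """Apply the four standardization steps to a raw-scale matrix.

    Parameters
    ----------
    raw
        Raw-scale, un-normalized matrix; requires hybridization-control
        and calibrator probes flagged in ``meta``.
    reference
        Optional external raw matrix whose per-protein medians serve as
        the calibration reference; within-run medians are used otherwise.
    single_pass
        Apply steps 1-4 once instead of cycling to the joint fixed point.
    return_info
        Also return a :class:`NormalizationInfo` with per-sample factors.
    """
    if raw.scale != RAW:
        raise NormalizationError("standardize expects a raw-scale matrix")
    if raw.normalized:
        raise NormalizationError("matrix is already normalized")
    if not meta.hyb_controls or not meta.calibrators:
        raise NormalizationError(
            "panel meta must flag at least one hybridization control and "
            "one calibrator probe")
    if (raw.values.to_numpy() <= 0).any():
        raise NormalizationError("raw matrix has nonpositive intensities")

    plates = raw.plate_of_subject
    if plates is None:
        plates = pd.Series("plate1", index=raw.subject_ids)

    cols = raw.protein_ids
    col_pos = {p: i for i, p in enumerate(cols)}
    hyb_cols = [p for p in meta.hyb_controls if p in col_pos]
    cal_cols = [p for p in meta.calibrators if p in col_pos]
    bio_cols = [p for p in meta.biological if p in col_pos]
    if not hyb_cols or not cal_cols:
        raise NormalizationError("no control probes in matrix")
    if not bio_cols:
        raise NormalizationError("no biological proteins in matrix")
    hyb_idx = np.array([col_pos[p] for p in hyb_cols])
    cal_idx = np.array([col_pos[p] for p in cal_cols])
    bio_idx = np.array([col_pos[p] for p in bio_cols])
    groups = meta.dilution_groups()
    if groups:
        groups_idx = [
            np.array([col_pos[p] for p in members
                      if p in col_pos and not (meta.table.loc[p, "is_hyb_control"]
                                               or meta.table.loc[p, "is_calibrator"])])
            for _, members in sorted(groups.items(), key=lambda kv: str(kv[0]))]
        groups_idx = [g for g in groups_idx if len(g)]
    else:
        groups_idx = [bio_idx]
    plate_labels = list(dict.fromkeys(plates))
    plate_rows = [np.flatnonzero((plates == p).to_numpy()) for p in plate_labels]

    ref = None
    if reference is not None:
        ref_series = reference.values.median(axis=0).reindex(cal_cols)
        if ref_series.isna().any():
            raise NormalizationError("reference matrix missing calibrator probes")
        ref = ref_series.to_numpy()

    v = raw.values.to_numpy(dtype=float).copy()
    n_cycles = 0
    converged = False
    for n_cycles in range(1, (2 if single_pass else max_cycles) + 1):
        prev = v.copy()
        v = _one_pass(v, hyb_idx, cal_idx, bio_idx, groups_idx, plate_rows, ref)
        delta = np.max(np.abs(v / prev - 1.0))
        if single_pass:
            break
        if delta < tol:
            converged = True
            break

    out = raw.with_values(
        pd.DataFrame(v, index=raw.subject_ids, columns=cols), normalized=True)
    if not return_info:
        return out
    # hybridization controls are technical-scale only, so the removed
    # per-sample factor is read off them directly
    factor = (raw.values[hyb_cols] / out.values[hyb_cols]).median(axis=1)
    return out, NormalizationInfo(sample_factor=factor, n_cycles=n_cycles,
                                  converged=converged or single_pass)


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2; requires a strictly positive raw-scale matrix."""
    if matrix.scale != RAW:
        raise MatrixError("matrix is not on the raw scale")
    vals = matrix.values.to_numpy()
    if (vals <= 0).any():
        raise MatrixError("log2 transform requires strictly positive values")
    return matrix.with_values(np.log2(matrix.values), scale=LOG2)
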