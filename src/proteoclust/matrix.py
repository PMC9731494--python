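"""Expression-matrix container and plain-text IO.

The pipeline's central object is a subjects x proteins intensity table of
aptamer readouts.  Raw values are relative fluorescence units (RFU,
nonnegative); after normalization and log2 transform the same container
carries log2 intensities.  A small per-protein metadata table distinguishes
hybridization-control and calibrator probes from biological analytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RAW = "raw"
LOG2 = "log2"


class MatrixError(ValueError):
    """Invalid expression-matrix content or metadata."""


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()].astype(str)))
        raise MatrixError(f"duplicate {what}: {', '.join(dups)}")


@dataclass
class ExpressionMatrix:
    """Subjects x proteins intensity table.

    Parameters
    ----------
    values
        DataFrame with subject ids as index and protein ids as columns.
        No missing values are allowed.
    scale
        ``"raw"`` (RFU, all values >= 0) or ``"log2"``.
    plate_of_subject
        Optional Series mapping subject id -> plate label, required for
        plate-aware normalization.
    run_id
        Free-text identifier of the assay run.
    normalized
        Whether the four-step standardization has been applied (raw scale
        only; log2 matrices are always derived from normalized data here).
    """

    values: pd.DataFrame
    scale: str = RAW
    plate_of_subject: pd.Series | None = None
    run_id: str = "run"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG2):
            raise MatrixError(f"unknown scale {self.scale!r}")
        _check_unique(self.values.index, "subject ids")
        _check_unique(self.values.columns, "protein ids")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise MatrixError("matrix values must be numeric")
        if np.isnan(vals).any():
            raise MatrixError("matrix contains missing values")
        if self.scale == RAW and (vals < 0).any():
            bad = self.values.columns[(vals < 0).any(axis=0)]
            raise MatrixError(
                f"negative raw RFU in columns: {', '.join(map(str, bad[:5]))}"
            )
        if self.plate_of_subject is not None:
            plates = self.plate_of_subject.reindex(self.values.index)
            if plates.isna().any():
                missing = plates.index[plates.isna()]
                raise MatrixError(
                    f"no plate for subjects: {', '.join(map(str, missing[:5]))}"
                )
            object.__setattr__(self, "plate_of_subject", plates)

    # -- convenience -----------------------------------------------------
    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, **changes) -> "ExpressionMatrix":
        """Copy of this matrix with new values (and optional field changes)."""
        return replace(self, values=values, **changes)

    def subset_subjects(self, subjects) -> "ExpressionMatrix":
        return self.with_values(self.values.loc[subjects])


@dataclass
class PanelMeta:
    """Per-protein probe metadata.

    ``table`` is indexed by protein id with columns ``target_name``,
    ``is_hyb_control``, ``is_calibrator`` and ``dilution_group`` (nullable).
    """

    table: pd.DataFrame

    REQUIRED = ("target_name", "is_hyb_control", "is_calibrator", "dilution_group")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise MatrixError(f"panel meta missing columns: {', '.join(missing)}")
        _check_unique(self.table.index, "protein ids in panel meta")
        for col in ("is_hyb_control", "is_calibrator"):
            self.table[col] = self.table[col].astype(bool)

    @property
    def hyb_controls(self) -> list:
        return list(self.table.index[self.table["is_hyb_control"]])

    @property
    def calibrators(self) -> list:
        return list(self.table.index[self.table["is_calibrator"]])

    @property
    def controls(self) -> list:
        mask = self.table["is_hyb_control"] | self.table["is_calibrator"]
        return list(self.table.index[mask])

    @property
    def biological(self) -> list:
        mask = ~(self.table["is_hyb_control"] | self.table["is_calibrator"])
        return list(self.table.index[mask])

    def dilution_groups(self) -> dict:
        """Map group label -> protein ids, for non-null groups only."""
        col = self.table["dilution_group"]
        groups: dict = {}
        for pid, grp in col.items():
            if pd.isna(grp):
                continue
            groups.setdefault(grp, []).append(pid)
        return groups


# -- IO -------------------------------------------------------------------

SUBJECT_COL = "subject_id"


def read_matrix(path, scale: str = RAW, plate_of_subject=None,
                run_id: str = "run") -> ExpressionMatrix:
    """Read a wide CSV (first column subject id, remaining columns proteins).

    Raises :class:`MatrixError` on duplicate ids, missing values or
    negative raw intensities; ragged rows surface as parser errors.
    """
    # pandas silently mangles duplicate header names, so check them raw
    import csv
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    _check_unique(header[1:], "protein ids")
    df = pd.read_csv(path)
    if df.columns[0] != SUBJECT_COL:
        df = df.rename(columns={df.columns[0]: SUBJECT_COL})
    _check_unique(df[SUBJECT_COL], "subject ids")
    df = df.set_index(SUBJECT_COL)
    df.index.name = None
    return ExpressionMatrix(df, scale=scale, plate_of_subject=plate_of_subject,
                            run_id=run_id)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    """Inverse of :func:`read_matrix` (modulo float formatting)."""
    out = matrix.values.copy()
    out.index.name = SUBJECT_COL
    out.to_csv(path)


def read_panel_meta(path) -> PanelMeta:
    df = pd.read_csv(path)
    if df.columns[0] != "protein_id":
        df = df.rename(columns={df.columns[0]: "protein_id"})
    df = df.set_index("protein_id")
    return PanelMeta(df)


def write_panel_meta(meta: PanelMeta, path) -> None:
    out = meta.table.copy()
    out.index.name = "protein_id"
    out.to_csv(path)
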