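"""Shared fixtures: generated scenario runs reused across test modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import proteoclust as pc


def make_log2_matrix(values, subjects=None, proteins=None) -> pc.ExpressionMatrix:
    """Small log2-scale matrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    subjects = subjects or [f"s{i + 1}" for i in range(values.shape[0])]
    proteins = proteins or [f"g{j + 1}" for j in range(values.shape[1])]
    return pc.ExpressionMatrix(
        pd.DataFrame(values, index=subjects, columns=proteins), scale="log2")


@dataclass
class PipelineRun:
    data: pc.ScenarioData
    X: pc.ExpressionMatrix          # normalized, log2
    result: pc.LearningResult


def _run(name: str, seed: int | None = None) -> PipelineRun:
    data = pc.run_scenario(name, seed)
    X = pc.log2_transform(pc.standardize(data.matrix, data.panel_meta))
    result = pc.learning_pipeline(X, exclude=data.panel_meta.controls)
    return PipelineRun(data=data, X=X, result=result)


@pytest.fixture(scope="session")
def cobra_run() -> PipelineRun:
    """Learning cohort (default seed), fully processed."""
    return _run("cobra_v1")


@pytest.fixture(scope="session")
def mlcc_run():
    """Transfer cohort, processed up to the log2 matrix."""
    data = pc.run_scenario("mlcc")
    X = pc.log2_transform(pc.standardize(data.matrix, data.panel_meta))
    return data, X


@pytest.fixture(scope="session")
def paired_run():
    """Paired-visit cohort with both visits processed independently."""
    data = pc.run_scenario("paired_visits")
    X1 = pc.log2_transform(pc.standardize(data.matrix, data.panel_meta))
    X2 = pc.log2_transform(pc.standardize(data.matrix_v2, data.panel_meta))
    r1 = pc.learning_pipeline(X1, exclude=data.panel_meta.controls)
    r2 = pc.learning_pipeline(X2, exclude=data.panel_meta.controls)
    return data, X1, X2, r1, r2
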