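"""Synthetic serum-proteomics cohorts with planted cluster structure.

Every downstream stage of the pipeline (normalization, cluster discovery,
differential expression, scoring, validation) is exercised on cohorts
generated here.  The generator emulates an aptamer panel read in RFU:

* per-protein log2 baselines spread across the panel,
* two planted patient clusters, with a set of proteins up-regulated in
  each cluster by additive log2 effects (multiplicative in RFU),
* per-sample hybridization drift and per-plate batch factors,
* noise-free hybridization-control and calibrator probes that carry the
  technical factors but no biology (so normalization is identifiable),
* cluster-correlated binary clinical covariates,
* paired-visit cohorts with a configurable transition structure, where a
  "mixed" profile carries 50% of both planted effect sets,
* a structure-free healthy cohort.

Protein identities, baselines and planted effect sizes are drawn from a
``layout_seed`` that is fixed per scenario family, so the learning cohort,
the paired-visit cohort and the transfer cohort agree on which proteins
carry signal; subject-level randomness (noise, plate assignment, drift,
covariates) is driven by ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, PanelMeta

LOG2_FC_THRESHOLD = np.log2(1.5)

#: Cluster-conditional prevalences (Cluster 1, Cluster 2) of the binary
#: clinical covariates carried by the default scenarios.
DEFAULT_COVARIATE_PREVALENCES: dict[str, tuple[float, float]] = {
    "emphysema": (0.52, 0.31),
    "exacerbations": (0.61, 0.44),
    "unscheduled_visits": (0.53, 0.33),
    "hypertension": (0.39, 0.24),
    "diabetes": (0.17, 0.06),
}


class ConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass
class GeneratorConfig:
    """Full parameterization of one synthetic cohort.

    ``n_proteins`` counts all assay columns including the control probes;
    biological analytes number ``n_proteins - n_hyb_controls -
    n_calibrators``.  Planted effects are additive on the log2 scale and
    constant across subjects; each planted protein's effect is drawn
    uniformly from ``effect_log2fc_range``.
    """

    n_subjects: int = 241
    n_proteins: int = 1305
    cluster_sizes: tuple[int, int] = (126, 115)
    up_in_c2: int = 90
    up_in_c1: int = 6
    effect_log2fc_range: tuple[float, float] = (0.8, 1.5)
    baseline_log2_mean: float = 10.6
    baseline_log2_sd: float = 1.0
    noise_sd: float = 0.5
    n_plates: int = 4
    plate_shift_sd: float = 0.10
    hyb_drift_sd: float = 0.05
    n_hyb_controls: int = 3
    n_calibrators: int = 3
    covariate_prevalences: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES))
    transition_counts: tuple[int, int, int, int] = (68, 40, 29, 26)
    shared_up_fraction: float = 0.0
    seed: int = 0
    layout_seed: int = 20220
    cohort: str = "SYNTH"

    @property
    def n_biological(self) -> int:
        return self.n_proteins - self.n_hyb_controls - self.n_calibrators

    def validate(self, paired: bool = False) -> None:
        c1, c2 = self.cluster_sizes
        if min(c1, c2) < 0 or self.n_subjects <= 0:
            raise ConfigError("negative or empty cohort sizes")
        if c1 + c2 != self.n_subjects:
            raise ConfigError(
                f"cluster sizes {self.cluster_sizes} do not sum to "
                f"n_subjects={self.n_subjects}")
        if self.up_in_c2 < 0 or self.up_in_c1 < 0:
            raise ConfigError("negative planted up-set size")
        if self.up_in_c2 + self.up_in_c1 > self.n_biological:
            raise ConfigError("planted up-sets exceed the biological panel")
        lo, hi = self.effect_log2fc_range
        if lo > hi:
            raise ConfigError("effect_log2fc_range is inverted")
        if self.n_plates < 1 or self.n_hyb_controls < 1 or self.n_calibrators < 1:
            raise ConfigError("need >=1 plate, hyb control and calibrator")
        for name, (p1, p2) in self.covariate_prevalences.items():
            if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
                raise ConfigError(f"prevalence outside [0,1] for {name!r}")
        if paired:
            if sum(self.transition_counts) != self.n_subjects:
                raise ConfigError(
                    f"transition counts {self.transition_counts} do not sum "
                    f"to the paired cohort size {self.n_subjects}")

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class TruthBundle:
    """Ground truth of everything the generator planted."""

    labels: dict[int, pd.Series]          # visit -> per-subject label (1/2/"mixed")
    up2_ids: list[str]
    up1_ids: list[str]
    effects: pd.Series                    # planted log2 effect per planted protein
    plate_of_subject: pd.Series
    plate_factors: pd.Series
    hyb_factors: dict[int, pd.Series]     # visit -> per-sample drift
    covariate_prevalences: dict[str, tuple[float, float]]

    def to_json(self) -> str:
        payload = {
            "labels": {str(v): s.astype(str).to_dict() for v, s in self.labels.items()},
            "up2_ids": list(self.up2_ids),
            "up1_ids": list(self.up1_ids),
            "effects": {k: float(v) for k, v in self.effects.items()},
            "plate_of_subject": self.plate_of_subject.astype(str).to_dict(),
            "plate_factors": {str(k): float(v) for k, v in self.plate_factors.items()},
            "hyb_factors": {str(v): {k: float(x) for k, x in s.items()}
                            for v, s in self.hyb_factors.items()},
            "covariate_prevalences": {k: list(v) for k, v in
                                      self.covariate_prevalences.items()},
        }
        return json.dumps(payload, indent=1)


@dataclass
class PanelLayout:
    """Seed-determined panel structure shared across cohorts of a family."""

    protein_ids: list[str]
    control_ids: list[str]
    baselines: pd.Series        # log2 baseline per biological protein
    control_levels: pd.Series   # raw constant level per control probe
    up2_ids: list[str]
    up1_ids: list[str]
    effects: pd.Series
    meta: PanelMeta


def _panel_layout(config: GeneratorConfig,
                  reference_truth: TruthBundle | None = None) -> PanelLayout:
    rng = np.random.default_rng(config.layout_seed)
    n_bio = config.n_biological
    width = max(4, len(str(n_bio)))
    bio_ids = [f"P{i + 1:0{width}d}" for i in range(n_bio)]
    hyb_ids = [f"HYB{i + 1}" for i in range(config.n_hyb_controls)]
    cal_ids = [f"CAL{i + 1}" for i in range(config.n_calibrators)]

    baselines = pd.Series(
        rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_bio),
        index=bio_ids)
    control_levels = pd.Series(
        2.0 ** rng.normal(config.baseline_log2_mean, 0.3,
                          len(hyb_ids) + len(cal_ids)),
        index=hyb_ids + cal_ids)

    if reference_truth is not None and config.shared_up_fraction > 0:
        ref_up2 = [p for p in reference_truth.up2_ids if p in bio_ids]
        n_shared = int(round(config.shared_up_fraction * len(ref_up2)))
        if n_shared > config.up_in_c2:
            raise ConfigError("shared up-set larger than up_in_c2")
        shared = sorted(rng.choice(ref_up2, size=n_shared, replace=False))
        taken = set(reference_truth.up2_ids) | set(reference_truth.up1_ids)
        pool = [p for p in bio_ids if p not in taken]
        fresh = list(rng.choice(pool, size=config.up_in_c2 - n_shared,
                                replace=False))
        up2 = shared + sorted(fresh)
        pool2 = [p for p in pool if p not in set(fresh)]
        up1 = sorted(rng.choice(pool2, size=config.up_in_c1, replace=False))
    else:
        chosen = rng.choice(bio_ids, size=config.up_in_c2 + config.up_in_c1,
                            replace=False)
        up2 = sorted(chosen[:config.up_in_c2])
        up1 = sorted(chosen[config.up_in_c2:])

    lo, hi = config.effect_log2fc_range
    planted = up2 + up1
    effects = pd.Series(rng.uniform(lo, hi, len(planted)), index=planted)

    all_ids = bio_ids + hyb_ids + cal_ids
    meta_df = pd.DataFrame({
        "target_name": [f"T_{p}" for p in all_ids],
        "is_hyb_control": [p in set(hyb_ids) for p in all_ids],
        "is_calibrator": [p in set(cal_ids) for p in all_ids],
        "dilution_group": [np.nan] * len(all_ids),
    }, index=pd.Index(all_ids, name="protein_id"))

    return PanelLayout(protein_ids=all_ids, control_ids=hyb_ids + cal_ids,
                       baselines=baselines, control_levels=control_levels,
                       up2_ids=list(up2), up1_ids=list(up1), effects=effects,
                       meta=PanelMeta(meta_df))


def _subject_ids(config: GeneratorConfig, n: int) -> list[str]:
    return [f"{config.cohort}_{i + 1:04d}" for i in range(n)]


def _dose_matrix(labels: pd.Series, layout: PanelLayout) -> pd.DataFrame:
    """Per subject x biological protein multiplier of the planted effect."""
    bio = layout.baselines.index
    dose = pd.DataFrame(0.0, index=labels.index, columns=bio)
    up2 = [p for p in layout.up2_ids]
    up1 = [p for p in layout.up1_ids]
    is2 = labels == 2
    is1 = labels == 1
    ismix = labels == "mixed"
    dose.loc[is2, up2] = 1.0
    dose.loc[is1, up1] = 1.0
    dose.loc[ismix, up2] = 0.5
    dose.loc[ismix, up1] = 0.5
    return dose


def _assemble_raw(labels: pd.Series, layout: PanelLayout,
                  config: GeneratorConfig, rng: np.random.Generator,
                  plate_of_subject: pd.Series, plate_factors: pd.Series,
                  ) -> tuple[ExpressionMatrix, pd.Series]:
    """Draw noise + technical factors and build the raw RFU matrix."""
    n = len(labels)
    bio = layout.baselines.index
    noise = rng.normal(0.0, config.noise_sd, size=(n, len(bio)))
    dose = _dose_matrix(labels, layout)
    eff = layout.effects.reindex(bio).fillna(0.0)
    log2sig = layout.baselines.to_numpy()[None, :] + \
        dose.to_numpy() * eff.to_numpy()[None, :] + noise

    hyb_factors = pd.Series(np.exp(rng.normal(0.0, config.hyb_drift_sd, n)),
                            index=labels.index)
    sample_scale = (hyb_factors *
                    plate_factors.reindex(plate_of_subject).to_numpy())

    raw_bio = (2.0 ** log2sig) * sample_scale.to_numpy()[:, None]
    raw_ctl = np.outer(sample_scale.to_numpy(),
                       layout.control_levels.to_numpy())
    values = pd.DataFrame(
        np.hstack([raw_bio, raw_ctl]),
        index=labels.index,
        columns=list(bio) + list(layout.control_levels.index))
    values = values[layout.protein_ids]
    matrix = ExpressionMatrix(values, scale="raw",
                              plate_of_subject=plate_of_subject,
                              run_id=config.cohort)
    return matrix, hyb_factors


def _plates(config: GeneratorConfig, subjects: list[str],
            rng: np.random.Generator) -> tuple[pd.Series, pd.Series]:
    order = rng.permutation(len(subjects))
    chunks = np.array_split(order, config.n_plates)
    plate_of_subject = pd.Series(index=pd.Index(subjects), dtype=object)
    for k, chunk in enumerate(chunks):
        for i in chunk:
            plate_of_subject.iloc[i] = f"plate{k + 1}"
    plate_factors = pd.Series(
        np.exp(rng.normal(0.0, config.plate_shift_sd, config.n_plates)),
        index=[f"plate{k + 1}" for k in range(config.n_plates)])
    return plate_of_subject, plate_factors


def generate_covariates(labels: pd.Series,
                        covariate_prevalences: dict[str, tuple[float, float]],
                        seed) -> pd.DataFrame:
    """Cluster-conditional Bernoulli covariates, one column per covariate.

    ``seed`` may be an integer or a ``numpy.random.Generator``.  Mixed
    labels draw at the midpoint of the two cluster prevalences.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = {}
    for name, (p1, p2) in covariate_prevalences.items():
        if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
            raise ConfigError(f"prevalence outside [0,1] for {name!r}")
        p = np.where(labels == 1, p1,
                     np.where(labels == 2, p2, 0.5 * (p1 + p2)))
        out[name] = (rng.random(len(labels)) < p).astype(int)
    return pd.DataFrame(out, index=labels.index)


def _annotation(config: GeneratorConfig, labels: pd.Series,
                plate_of_subject: pd.Series, visit: int,
                rng: np.random.Generator) -> pd.DataFrame:
    ann = pd.DataFrame({
        "cohort": config.cohort,
        "visit": visit,
        "plate": plate_of_subject,
    }, index=labels.index)
    cov = generate_covariates(labels, config.covariate_prevalences, rng)
    return pd.concat([ann, cov], axis=1)


def generate_cohort(config: GeneratorConfig,
                    reference_truth: TruthBundle | None = None,
                    ) -> tuple[ExpressionMatrix, pd.DataFrame, TruthBundle]:
    """Single-visit cohort with two planted clusters.

    Returns the raw RFU matrix, the subject annotation table (cohort,
    visit, plate, binary covariates) and the planted truth.
    """
    config.validate()
    layout = _panel_layout(config, reference_truth)
    rng = np.random.default_rng(config.seed)

    subjects = _subject_ids(config, config.n_subjects)
    c1, c2 = config.cluster_sizes
    labels = pd.Series([1] * c1 + [2] * c2, index=pd.Index(subjects))
    plate_of_subject, plate_factors = _plates(config, subjects, rng)
    matrix, hyb = _assemble_raw(labels, layout, config, rng,
                                plate_of_subject, plate_factors)
    annotation = _annotation(config, labels, plate_of_subject, 1, rng)
    truth = TruthBundle(labels={1: labels}, up2_ids=layout.up2_ids,
                        up1_ids=layout.up1_ids, effects=layout.effects,
                        plate_of_subject=plate_of_subject,
                        plate_factors=plate_factors, hyb_factors={1: hyb},
                        covariate_prevalences=dict(config.covariate_prevalences))
    return matrix, annotation, truth


def generate_paired_visits(config: GeneratorConfig,
                           reference_truth: TruthBundle | None = None,
                           ) -> tuple[ExpressionMatrix, ExpressionMatrix,
                                      pd.DataFrame, TruthBundle]:
    """Two-visit cohort with the configured transition structure.

    ``transition_counts`` is (stay-1, stay-2, 1->mixed, 2->1).  Visit-1
    labels follow the transition origins; visit-2 intensities are re-drawn
    with fresh noise and technical factors, subjects keep their ids and
    plate assignment.
    """
    counts = config.transition_counts
    if sum(counts) != config.n_subjects:
        raise ConfigError(
            f"transition counts {counts} do not sum to the paired cohort "
            f"size {config.n_subjects}")
    config = config.replace(
        cluster_sizes=(counts[0] + counts[2], counts[1] + counts[3]))
    config.validate(paired=True)
    layout = _panel_layout(config, reference_truth)
    rng = np.random.default_rng(config.seed)

    stay1, stay2, to_mixed, to_c1 = counts
    subjects = _subject_ids(config, config.n_subjects)
    origin = [1] * stay1 + [1] * to_mixed + [2] * stay2 + [2] * to_c1
    dest = [1] * stay1 + ["mixed"] * to_mixed + [2] * stay2 + [1] * to_c1
    labels_v1 = pd.Series(origin, index=pd.Index(subjects), dtype=object)
    labels_v2 = pd.Series(dest, index=pd.Index(subjects), dtype=object)

    plate_of_subject, plate_factors = _plates(config, subjects, rng)
    m1, hyb1 = _assemble_raw(labels_v1, layout, config, rng,
                             plate_of_subject, plate_factors)
    m2, hyb2 = _assemble_raw(labels_v2, layout, config, rng,
                             plate_of_subject, plate_factors)
    annotation = _annotation(config, labels_v1, plate_of_subject, 1, rng)
    truth = TruthBundle(labels={1: labels_v1, 2: labels_v2},
                        up2_ids=layout.up2_ids, up1_ids=layout.up1_ids,
                        effects=layout.effects,
                        plate_of_subject=plate_of_subject,
                        plate_factors=plate_factors,
                        hyb_factors={1: hyb1, 2: hyb2},
                        covariate_prevalences=dict(config.covariate_prevalences))
    return m1, m2, annotation, truth


def generate_healthy(config: GeneratorConfig,
                     ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Structure-free control cohort; requires empty planted up-sets."""
    if config.up_in_c2 != 0 or config.up_in_c1 != 0:
        raise ConfigError("healthy cohort must have no planted up-sets")
    config = config.replace(cluster_sizes=(config.n_subjects, 0))
    config.validate()
    layout = _panel_layout(config)
    rng = np.random.default_rng(config.seed)

    subjects = _subject_ids(config, config.n_subjects)
    labels = pd.Series([1] * config.n_subjects, index=pd.Index(subjects))
    plate_of_subject, plate_factors = _plates(config, subjects, rng)
    matrix, _ = _assemble_raw(labels, layout, config, rng,
                              plate_of_subject, plate_factors)
    annotation = pd.DataFrame({
        "cohort": config.cohort, "visit": 1, "plate": plate_of_subject,
    }, index=labels.index)
    return matrix, annotation


def generate_term_annotation(universe: list[str], focus_set: list[str] | None = None,
                             n_focus_terms: int = 12, n_random_terms: int = 20,
                             size_range: tuple[int, int] = (5, 40),
                             seed: int = 7) -> pd.DataFrame:
    """Synthetic term -> protein annotation (long CSV form).

    Builds ``n_focus_terms`` pathway-family terms that tile ``focus_set``
    (so the set is genuinely enriched) plus random background terms.
    Returns a two-column DataFrame (term_id, protein_id).
    """
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    rows: list[tuple[str, str]] = []
    if focus_set:
        focus = list(focus_set)
        chunks = np.array_split(np.arange(len(focus)), n_focus_terms)
        for t, chunk in enumerate(chunks):
            members = [focus[i] for i in chunk]
            # keep focus terms mostly planted members so they stay enriched
            n_pad = max(0, lo - len(members)) + int(rng.integers(0, 4))
            pad = rng.choice([p for p in universe if p not in set(members)],
                             size=n_pad, replace=False)
            for p in list(members) + list(pad):
                rows.append((f"FOCUS{t + 1:02d}", p))
    for t in range(n_random_terms):
        size = int(rng.integers(lo, hi + 1))
        for p in rng.choice(universe, size=size, replace=False):
            rows.append((f"RAND{t + 1:02d}", p))
    return pd.DataFrame(rows, columns=["term_id", "protein_id"])


# -- named scenarios ------------------------------------------------------

_COBRA_LAYOUT = 20220
_MLCC_LAYOUT = 30330

_BASE = GeneratorConfig()


def scenario_config(name: str, seed: int | None = None) -> GeneratorConfig:
    """Default configuration for a named scenario.

    Default seeds are fixed per scenario so that the packaged scenarios
    are deterministic; pass ``seed`` to override the subject-level RNG
    (the panel layout stays fixed per scenario family).
    """
    if name == "cobra_v1":
        cfg = _BASE.replace(n_subjects=241, cluster_sizes=(126, 115),
                            up_in_c2=90, up_in_c1=6, seed=2101,
                            layout_seed=_COBRA_LAYOUT, cohort="COBRA")
    elif name == "mlcc":
        cfg = _BASE.replace(n_subjects=47, cluster_sizes=(34, 13),
                            up_in_c2=114, up_in_c1=11,
                            shared_up_fraction=71 / 90, seed=2102,
                            layout_seed=_MLCC_LAYOUT, cohort="MLCC",
                            n_plates=1)
    elif name == "paired_visits":
        cfg = _BASE.replace(n_subjects=163, cluster_sizes=(97, 66),
                            up_in_c2=90, up_in_c1=6,
                            transition_counts=(68, 40, 29, 26), seed=2103,
                            layout_seed=_COBRA_LAYOUT, cohort="COBRA2V")
    elif name == "healthy":
        cfg = _BASE.replace(n_subjects=50, cluster_sizes=(50, 0),
                            up_in_c2=0, up_in_c1=0, seed=2104,
                            layout_seed=_COBRA_LAYOUT, cohort="HEALTHY",
                            n_plates=2)
    else:
        raise ConfigError(f"unknown scenario {name!r}")
    if seed is not None:
        cfg = cfg.replace(seed=int(seed))
    return cfg


SCENARIOS = ("cobra_v1", "mlcc", "paired_visits", "healthy")


@dataclass
class ScenarioData:
    name: str
    config: GeneratorConfig
    matrix: ExpressionMatrix
    annotation: pd.DataFrame
    panel_meta: PanelMeta
    truth: TruthBundle | None = None
    matrix_v2: ExpressionMatrix | None = None


def run_scenario(name: str, seed: int | None = None) -> ScenarioData:
    """Generate a named scenario end to end."""
    cfg = scenario_config(name, seed)
    layout = _panel_layout(cfg) if name != "mlcc" else None
    if name == "cobra_v1":
        m, ann, truth = generate_cohort(cfg)
        return ScenarioData(name, cfg, m, ann, layout.meta, truth)
    if name == "mlcc":
        # the transfer cohort re-plants part of the learning cohort's up-set
        ref_truth = _panel_layout(scenario_config("cobra_v1"))
        ref = TruthBundle(labels={}, up2_ids=ref_truth.up2_ids,
                          up1_ids=ref_truth.up1_ids, effects=ref_truth.effects,
                          plate_of_subject=pd.Series(dtype=object),
                          plate_factors=pd.Series(dtype=float),
                          hyb_factors={}, covariate_prevalences={})
        m, ann, truth = generate_cohort(cfg, reference_truth=ref)
        meta = _panel_layout(cfg, ref).meta
        return ScenarioData(name, cfg, m, ann, meta, truth)
    if name == "paired_visits":
        m1, m2, ann, truth = generate_paired_visits(cfg)
        return ScenarioData(name, cfg, m1, ann, layout.meta, truth,
                            matrix_v2=m2)
    if name == "healthy":
        m, ann = generate_healthy(cfg)
        return ScenarioData(name, cfg, m, ann, layout.meta, None)
    raise ConfigError(f"unknown scenario {name!r}")
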