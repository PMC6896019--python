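"""Synthetic paired tumor/normal beta-value cohorts with planted effects.

The generator emulates a multi-cancer methylation-array study design: for each
tumor type a number of primary-tumor (TP) samples and a smaller number of
adjacent-normal (NT) samples, partially paired within patients. Methylation
effects act on the logit scale so beta-values stay inside (0, 1); per-sample
values are drawn from a Beta distribution around the patient- and
tissue-specific mean, and a per-sample gene-expression value is linearly
coupled to methylation.

Model for probe j, tumor type t, tissue class c in {NT, TP}:

    u_patient ~ Normal(0, patient_sd)                      (shared by a pair)
    m = inv_logit( logit(mu0_j) + u_patient + 1[c = TP] * delta[t, j] )
    beta ~ Beta(m * phi, (1 - m) * phi)

``delta = 0`` everywhere makes tumor and normal marginals identical in
distribution. Tumor stage is drawn uniformly over I-IV independent of
methylation unless a stage-coupling effect is configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    BetaMatrix,
    Region,
    SampleMeta,
    load_cohort_registry,
    load_probe_annotation,
)

EPS = 1e-6  # clip bound applied before any logit transform


class ConfigError(ValueError):
    """Invalid generator configuration."""


def logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, EPS, 1 - EPS)
    return np.log(p / (1 - p))


def inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _default_baseline(regions: list[Region]) -> np.ndarray:
    # Normal-tissue means: promoter CpG islands mostly unmethylated, gene body
    # methylated, upstream shore-like intermediate.
    lookup = {Region.PROMOTER: 0.15, Region.GENE_BODY: 0.70, Region.UPSTREAM: 0.60}
    return np.array([lookup[r] for r in regions])


def _default_expression_slope(regions: list[Region]) -> np.ndarray:
    # Promoter methylation represses expression; other regions left uncoupled.
    return np.array([-1.0 if r is Region.PROMOTER else 0.0 for r in regions])


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters for :func:`generate_cohort`.

    Defaults reproduce the bundled 14-dataset cohort layout (719 NT / 5783 TP
    across 22 probes). ``effect`` is the (n_types, n_probes) matrix of
    tumor-vs-normal shifts on the logit scale.
    """

    probe_ids: list[str] = field(default_factory=list)
    regions: list[Region] = field(default_factory=list)
    tumor_types: list[str] = field(default_factory=list)
    n_normal: dict[str, int] = field(default_factory=dict)
    n_tumor: dict[str, int] = field(default_factory=dict)
    baseline_mean: np.ndarray | None = None
    effect: np.ndarray | None = None  # logit-scale delta[t, j]
    precision: float = 50.0  # Beta concentration phi
    patient_sd: float = 0.5  # SD of per-patient random intercept (logits)
    expression_intercept: float = 8.0
    expression_slope: np.ndarray | None = None  # per-probe, expression units/beta
    expression_noise_sd: float = 0.5
    stage_interaction: float = 0.0  # extra logit shift per stage unit on effect probes
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.probe_ids:
            ann = load_probe_annotation()
            self.probe_ids = [p.illumina_name for p in ann]
            self.regions = [p.region for p in ann]
        if not self.tumor_types:
            registry = load_cohort_registry()
            self.tumor_types = [r.dataset_code for r in registry]
            self.n_normal = {r.dataset_code: r.n_normal for r in registry}
            self.n_tumor = {r.dataset_code: r.n_tumor for r in registry}
        if self.baseline_mean is None:
            self.baseline_mean = _default_baseline(self.regions)
        self.baseline_mean = np.asarray(self.baseline_mean, dtype=float)
        if self.effect is None:
            self.effect = np.zeros((len(self.tumor_types), len(self.probe_ids)))
        self.effect = np.asarray(self.effect, dtype=float)
        if self.expression_slope is None:
            if self.regions:
                self.expression_slope = _default_expression_slope(self.regions)
            else:
                self.expression_slope = np.zeros(len(self.probe_ids))
        self.expression_slope = np.asarray(self.expression_slope, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n_p = len(self.probe_ids)
        n_t = len(self.tumor_types)
        if self.precision <= 0:
            raise ConfigError(f"precision must be > 0, got {self.precision}")
        if self.patient_sd < 0:
            raise ConfigError(f"patient_sd must be >= 0, got {self.patient_sd}")
        if self.baseline_mean.shape != (n_p,):
            raise ConfigError("baseline_mean length must match probe count")
        if np.any(self.baseline_mean <= 0) or np.any(self.baseline_mean >= 1):
            raise ConfigError("baseline_mean values must lie strictly in (0, 1)")
        if self.effect.shape != (n_t, n_p):
            raise ConfigError(
                f"effect must have shape ({n_t}, {n_p}), got {self.effect.shape}"
            )
        for t in self.tumor_types:
            if self.n_normal.get(t, -1) < 0 or self.n_tumor.get(t, -1) < 0:
                raise ConfigError(f"missing or negative sample counts for {t}")


def scale_counts(config: GeneratorConfig, factor: float, min_per_class: int = 4) -> GeneratorConfig:
    """Return a config with per-type sample counts scaled by ``factor``.

    Used to run the same study design at desk scale.
    """
    if factor <= 0:
        raise ConfigError("factor must be positive")
    n_normal = {t: max(min_per_class, round(n * factor)) for t, n in config.n_normal.items()}
    n_tumor = {t: max(min_per_class, round(n * factor)) for t, n in config.n_tumor.items()}
    return replace(config, n_normal=n_normal, n_tumor=n_tumor)


def planted_panel(
    config: GeneratorConfig,
    informative: set[int] | frozenset[int],
    delta: float = 2.0,
) -> GeneratorConfig:
    """Return a config whose effect is nonzero only on six informative probes.

    ``informative`` holds 1-based probe indices into ``config.probe_ids``; the
    shift ``delta`` (logits) is shared across all tumor types, every other
    probe is null. Used for search-recovery experiments.
    """
    informative = set(informative)
    if len(informative) != 6:
        raise ConfigError(f"informative panel must have 6 probes, got {len(informative)}")
    n_p = len(config.probe_ids)
    bad = [i for i in informative if not (1 <= i <= n_p)]
    if bad:
        raise ConfigError(f"probe indices out of range 1..{n_p}: {sorted(bad)}")
    effect = np.zeros((len(config.tumor_types), n_p))
    cols = [i - 1 for i in sorted(informative)]
    effect[:, cols] = delta
    return replace(config, effect=effect)


def generate_cohort(config: GeneratorConfig) -> tuple[BetaMatrix, list[SampleMeta]]:
    """Draw a paired NT/TP cohort under ``config``; deterministic in ``seed``."""
    rng = np.random.default_rng(config.seed)
    mu0_logit = logit(config.baseline_mean)
    n_probes = len(config.probe_ids)

    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    metas: list[SampleMeta] = []
    genders = np.array(["female", "male"])
    ethnicities = np.array(["white", "black or african american", "asian"])

    for t_idx, ttype in enumerate(config.tumor_types):
        n_nt = config.n_normal[ttype]
        n_tp = config.n_tumor[ttype]
        n_patients = max(n_nt, n_tp)
        delta_t = config.effect[t_idx]
        for p in range(n_patients):
            barcode = f"{ttype}-{p:04d}"
            u = rng.normal(0.0, config.patient_sd)
            age = float(np.clip(rng.normal(63.0, 10.0), 30.0, 90.0))
            gender = str(rng.choice(genders))
            ethnicity = str(rng.choice(ethnicities))
            stage = int(rng.integers(1, 5))  # drawn for the patient; used for TP
            for tissue in ("NT", "TP"):
                wanted = n_nt if tissue == "NT" else n_tp
                if p >= wanted:
                    continue
                lin = mu0_logit + u
                if tissue == "TP":
                    lin = lin + delta_t
                    if config.stage_interaction != 0.0:
                        lin = lin + config.stage_interaction * stage * (delta_t != 0)
                m = inv_logit(lin)
                beta = rng.beta(m * config.precision, (1 - m) * config.precision)
                beta = np.clip(beta, EPS, 1 - EPS)
                expr = (
                    config.expression_intercept
                    + float(beta @ config.expression_slope)
                    + rng.normal(0.0, config.expression_noise_sd)
                )
                sid = f"{barcode}-{tissue}"
                sample_ids.append(sid)
                rows.append(beta)
                metas.append(
                    SampleMeta(
                        sample_id=sid,
                        patient_barcode=barcode,
                        tissue=tissue,
                        tumor_type=ttype,
                        stage=stage if tissue == "TP" else None,
                        age_at_diagnosis=round(age, 1),
                        gender=gender,
                        ethnicity=ethnicity,
                        expression=expr,
                    )
                )

    values = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, n_probes)),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=config.probe_ids,
    )
    return BetaMatrix(values), metas


def generate_label_model_data(
    n: int,
    beta_coef: float,
    stage_coef: float,
    interaction_coef: float,
    seed: int,
    intercept: float = 0.0,
    beta_dist: tuple[float, float] = (2.0, 2.0),
) -> pd.DataFrame:
    """Draw (beta, stage, tissue) triples from an explicit logistic label model.

    tissue ~ Bernoulli(inv_logit(intercept + beta_coef*beta + stage_coef*stage
    + interaction_coef*beta*stage)). This is the forward model for power and
    type-I-error studies of the stage x methylation interaction test.
    """
    rng = np.random.default_rng(seed)
    beta = rng.beta(*beta_dist, size=n)
    stage = rng.integers(1, 5, size=n).astype(float)
    lin = intercept + beta_coef * beta + stage_coef * stage + interaction_coef * beta * stage
    y = rng.uniform(size=n) < inv_logit(lin)
    return pd.DataFrame({"beta": beta, "stage": stage, "tissue": y.astype(int)})
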