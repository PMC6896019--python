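"""Fixed six-probe pan-cancer logistic classifier and its evaluation.

The default panel is probes {3, 12, 14, 18, 20, 21} of the bundled 22-probe
annotation (one gene-body, four promoter, one upstream CpG). Evaluation is a
stratified 10-fold cross-validated ROC on pooled held-out scores, with
threshold metrics at a probability cut-off (tumor is the positive class;
predictions are positive when score >= cutoff). External validation refits
the same probe subset on the external cohort — coefficients are never
transferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .combo_search import compute_auc
from .data_model import BetaMatrix, SampleMeta

DEFAULT_PANEL = (3, 12, 14, 18, 20, 21)


def _fit_glm_binomial(y: np.ndarray, design: np.ndarray):
    """Logistic GLM fit; separation warnings are expected with strong panels."""
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        return sm.GLM(y, design, family=sm.families.Binomial()).fit()


@dataclass
class PanelModel:
    """Fitted logistic model over a fixed probe subset (+ optional covariates)."""

    probe_subset: tuple[int, ...]
    probe_ids: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray  # log-odds per unit beta, aligned with probe_ids
    covariates: tuple[str, ...] = ()
    covariate_coefficients: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_train: int = 0
    class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.probe_subset):
            raise ValueError("one coefficient per probe required")
        if len(self.covariate_coefficients) != len(self.covariates):
            raise ValueError("one coefficient per covariate required")

    def predict_proba(self, beta: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
        lin = self.intercept + np.asarray(beta, dtype=float) @ self.coefficients
        if self.covariates:
            if covariates is None:
                raise ValueError("model has covariates; covariate values required")
            lin = lin + np.asarray(covariates, dtype=float) @ self.covariate_coefficients
        return expit(lin)

    def to_text(self, path: str | Path) -> None:
        lines = [f"intercept\t{self.intercept:.10g}"]
        for pid, c in zip(self.probe_ids, self.coefficients):
            lines.append(f"{pid}\t{c:.10g}")
        for name, c in zip(self.covariates, self.covariate_coefficients):
            lines.append(f"cov:{name}\t{c:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RocResult:
    """Empirical ROC curve with AUC and cut-off metrics."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    threshold_metrics: list[tuple[float, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        fpr, tpr = np.asarray(self.fpr), np.asarray(self.tpr)
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("ROC curve must be non-decreasing")
        if not (fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC out of [0,1]: {self.auc}")


def _panel_design(
    bm: BetaMatrix, meta: Sequence[SampleMeta], subset: Sequence[int],
    covariates: Sequence[str] = (),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    missing = [i for i in subset if not (1 <= i <= bm.n_probes)]
    if missing:
        raise KeyError(f"probe indices missing from matrix: {missing}")
    cols = [bm.probe_ids[i - 1] for i in subset]
    order = [m.sample_id for m in meta]
    X = bm.values.loc[order, cols].to_numpy(dtype=float)
    y = np.array([1 if m.tissue == "TP" else 0 for m in meta])
    cov = np.column_stack(
        [_covariate_column(meta, c) for c in covariates]
    ) if covariates else np.empty((len(meta), 0))
    return X, y, cov, cols


def _covariate_column(meta: Sequence[SampleMeta], name: str) -> np.ndarray:
    if name == "stage":
        # stage is recorded on tumor samples only; normal samples take their
        # patient's tumor stage so the covariate carries no class information
        by_patient = {
            m.patient_barcode: m.stage for m in meta if m.stage is not None
        }
        vals = np.array(
            [
                float(m.stage if m.stage is not None
                      else by_patient.get(m.patient_barcode, np.nan))
                for m in meta
            ]
        )
    elif name == "age":
        vals = np.array(
            [np.nan if m.age_at_diagnosis is None else float(m.age_at_diagnosis)
             for m in meta]
        )
    else:
        vals = np.array(
            [np.nan if getattr(m, name) is None else float(getattr(m, name))
             for m in meta]
        )
    if np.isnan(vals).any():
        vals = np.where(np.isnan(vals), np.nanmean(vals), vals)
    return vals


def fit_panel(
    bm: BetaMatrix,
    meta: Sequence[SampleMeta],
    subset: Sequence[int] = DEFAULT_PANEL,
    covariates: Sequence[str] = (),
) -> PanelModel:
    """MLE logistic fit of tissue on the subset's beta-values."""
    subset = tuple(sorted(int(i) for i in subset))
    X, y, cov, cols = _panel_design(bm, meta, subset, covariates)
    design = sm.add_constant(np.hstack([X, cov]))
    res = _fit_glm_binomial(y, design)
    k = len(subset)
    return PanelModel(
        probe_subset=subset,
        probe_ids=tuple(cols),
        intercept=float(res.params[0]),
        coefficients=np.asarray(res.params[1 : 1 + k]),
        covariates=tuple(covariates),
        covariate_coefficients=np.asarray(res.params[1 + k :]),
        n_train=len(y),
        class_counts={"NT": int(np.sum(y == 0)), "TP": int(np.sum(y == 1))},
    )


def _strat_labels(meta: Sequence[SampleMeta], n_folds: int) -> np.ndarray:
    """Stratify by tissue x tumor type when every stratum can fill the folds."""
    fine = np.array([f"{m.tissue}|{m.tumor_type}" for m in meta])
    _, counts = np.unique(fine, return_counts=True)
    if counts.min() >= n_folds:
        return fine
    return np.array([m.tissue for m in meta])


def crossval_roc(
    bm: BetaMatrix,
    meta: Sequence[SampleMeta],
    subset: Sequence[int] = DEFAULT_PANEL,
    n_folds: int = 10,
    seed: int = 0,
    cutoffs: Sequence[float] = (0.55,),
    covariates: Sequence[str] = (),
) -> RocResult:
    """Stratified k-fold CV; held-out scores are pooled into one ROC."""
    subset = tuple(sorted(int(i) for i in subset))
    X, y, cov, _ = _panel_design(bm, meta, subset, covariates)
    if min(np.sum(y == 0), np.sum(y == 1)) < n_folds:
        raise ValueError("each class must have at least n_folds members")
    strat = _strat_labels(meta, n_folds)
    design = np.hstack([X, cov])

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pooled = np.empty(len(y))
    for train_idx, test_idx in skf.split(design, strat):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise ValueError("stratification produced a single-class fold")
        res = _fit_glm_binomial(
            y[train_idx], sm.add_constant(design[train_idx], has_constant="add")
        )
        lin = sm.add_constant(design[test_idx], has_constant="add") @ res.params
        pooled[test_idx] = expit(lin)

    return roc_from_scores(pooled, y, cutoffs)


def roc_from_scores(
    scores: np.ndarray, labels: np.ndarray, cutoffs: Sequence[float] = ()
) -> RocResult:
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = compute_auc(scores, labels)
    metrics = [
        (c, *threshold_metrics(scores, labels, c)) for c in cutoffs
    ]
    return RocResult(fpr=fpr, tpr=tpr, auc=auc, threshold_metrics=metrics)


def threshold_metrics(
    scores: np.ndarray, labels: np.ndarray, cutoff: float
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) at a probability cut-off."""
    if not (0.0 < cutoff < 1.0):
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / labels.size
    return sens, spec, acc


def validate_refit(
    subset: Sequence[int],
    external_bm: BetaMatrix,
    external_meta: Sequence[SampleMeta],
    n_folds: int = 10,
    seed: int = 0,
    cutoffs: Sequence[float] = (0.55,),
) -> RocResult:
    """Refit the same probe subset on an external cohort (CV inside)."""
    return crossval_roc(
        external_bm, external_meta, subset, n_folds=n_folds, seed=seed, cutoffs=cutoffs
    )


def validate_many(
    subset: Sequence[int],
    cohorts: dict[str, tuple[BetaMatrix, Sequence[SampleMeta]]],
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[dict[str, RocResult], RocResult]:
    """Per-cohort refit validation plus one pooled-cohort RocResult."""
    per_cohort = {
        name: validate_refit(subset, bm, meta, n_folds=n_folds, seed=seed)
        for name, (bm, meta) in cohorts.items()
    }
    pooled_values = pd.concat([bm.values for bm, _ in cohorts.values()], axis=0)
    pooled_values.index = [
        f"{name}:{sid}" for name, (bm, _) in cohorts.items() for sid in bm.sample_ids
    ]
    pooled_meta = []
    for name, (_, meta) in cohorts.items():
        for m in meta:
            pooled_meta.append(
                SampleMeta(
                    sample_id=f"{name}:{m.sample_id}",
                    patient_barcode=f"{name}:{m.patient_barcode}",
                    tissue=m.tissue, tumor_type=m.tumor_type, stage=m.stage,
                    age_at_diagnosis=m.age_at_diagnosis, gender=m.gender,
                    ethnicity=m.ethnicity, expression=m.expression,
                )
            )
    pooled = validate_refit(subset, BetaMatrix(pooled_values), pooled_meta,
                            n_folds=n_folds, seed=seed)
    return per_cohort, pooled


def roc_to_frame(roc: RocResult) -> pd.DataFrame:
    return pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr})
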