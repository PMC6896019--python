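"""Exhaustive probe-subset search scored by class-balanced bootstrapped logistic AUC.

Every subset of k probes (k in a configured range) is scored by repeatedly
drawing an equal number of tumor and normal samples, fitting a
maximum-likelihood logistic regression of tissue class on the subset's
beta-values, and recording the in-replicate AUC of the fitted scores. The
balanced resampling neutralizes the heavy tumor/normal imbalance of pooled
multi-cancer cohorts. Surviving panels must clear both a mean-AUC filter and
a worst-dataset filter.

Default caps follow the study design this package targets: pooled searches go
up to six probes, per-dataset searches up to three (larger per-dataset models
overfit); both are configuration defaults, not hard limits.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .data_model import BetaMatrix, SampleMeta

logger = logging.getLogger(__name__)

#: Published filter presets: pooled mean-AUC 0.85; per-dataset mean 0.84 with
#: a 0.80 floor on the worst dataset.
FILTER_PRESETS = {
    "pooled085": {"min_mean_auc": 0.85, "min_dataset_auc": 0.0},
    "indiv084": {"min_mean_auc": 0.84, "min_dataset_auc": 0.80},
}

SEPARATION_COEF_BOUND = 1e3  # |coef| beyond this flags quasi-separation
_RIDGE_C = 1e4  # fallback ridge strength for separable replicates


class UndefinedAUCError(ValueError):
    """AUC is undefined because only one class is present."""


@dataclass
class ComboScore:
    """Bootstrap AUC summary for one probe subset."""

    probe_subset: tuple[int, ...]
    pooled_mean_auc: float
    pooled_auc_sd: float
    per_dataset_auc: dict[str, float] = field(default_factory=dict)
    aic: float | None = None
    n_bootstrap: int = 0
    n_skipped: int = 0

    def __post_init__(self) -> None:
        subset = tuple(self.probe_subset)
        if list(subset) != sorted(set(subset)):
            raise ValueError(f"probe_subset must be sorted and unique: {subset}")
        self.probe_subset = subset
        if not (0.0 <= self.pooled_mean_auc <= 1.0):
            raise ValueError(f"mean AUC out of [0,1]: {self.pooled_mean_auc}")
        if self.pooled_auc_sd < 0:
            raise ValueError("AUC SD must be >= 0")

    @property
    def min_dataset_auc(self) -> float:
        return min(self.per_dataset_auc.values())


def enumerate_subsets(n_probes: int, k_min: int, k_max: int) -> Iterator[tuple[int, ...]]:
    """Yield every size-k subset of 1..n_probes for k in [k_min, k_max].

    Order is deterministic: by k, then lexicographic.
    """
    if not (1 <= k_min <= k_max <= n_probes):
        raise ValueError(f"invalid bounds: 1 <= {k_min} <= {k_max} <= {n_probes}")
    for k in range(k_min, k_max + 1):
        yield from itertools.combinations(range(1, n_probes + 1), k)


def count_subsets(n_probes: int, k_min: int, k_max: int) -> int:
    if not (1 <= k_min <= k_max <= n_probes):
        raise ValueError(f"invalid bounds: 1 <= {k_min} <= {k_max} <= {n_probes}")
    return sum(math.comb(n_probes, k) for k in range(k_min, k_max + 1))


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted 1/2.

    Equals the trapezoidal area under the empirical ROC curve, and the
    probability a random positive outscores a random negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n1 = int(np.sum(labels == 1))
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("both classes must be present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n1 * (n1 + 1) / 2) / (n1 * n0)


def _design(bm: BetaMatrix, subset: Sequence[int]) -> np.ndarray:
    cols = [bm.probe_ids[i - 1] for i in subset]
    return bm.values[cols].to_numpy(dtype=float)


def _labels(meta: Sequence[SampleMeta]) -> np.ndarray:
    return np.array([1 if m.tissue == "TP" else 0 for m in meta])


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """MLE logistic fit; ridge fallback on (quasi-)separation."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(C=np.inf, max_iter=200).fit(X, y)
            if np.max(np.abs(clf.coef_)) <= SEPARATION_COEF_BOUND:
                return clf
        except (ConvergenceWarning, ValueError):
            pass
    logger.debug("separation fallback: ridge-penalized refit")
    return LogisticRegression(C=_RIDGE_C, max_iter=500).fit(X, y)


def bootstrap_combo_auc(
    bm: BetaMatrix,
    meta: Sequence[SampleMeta],
    subset: Sequence[int],
    n_boot: int = 1000,
    n_per_class: int = 700,
    seed: int = 0,
    with_replacement: bool | None = None,
    oob: bool = False,
) -> ComboScore:
    """Class-balanced bootstrap of the logistic AUC for one probe subset.

    Per replicate, ``n_per_class`` tumors and ``n_per_class`` normals are
    drawn — without replacement when the class has at least that many members,
    with replacement otherwise (override with ``with_replacement``). The AUC
    is computed in-replicate on the fitted scores by default; ``oob=True``
    scores the samples left out of the replicate instead, removing the
    in-sample optimism of the fitted AUC (a null subset then calibrates to
    0.5, which the in-sample route does not).
    """
    subset = tuple(sorted(set(int(i) for i in subset)))
    X_all = _design(bm, subset)
    y_all = _labels(meta)
    idx1 = np.flatnonzero(y_all == 1)
    idx0 = np.flatnonzero(y_all == 0)
    if min(idx1.size, idx0.size) < 2:
        raise UndefinedAUCError("need >=2 samples in each class")
    if max(idx1.size, idx0.size) < n_per_class and with_replacement is False:
        raise ValueError("larger class smaller than n_per_class without replacement")

    rng = np.random.default_rng(seed)
    aucs = []
    n_skipped = 0
    for _ in range(n_boot):
        take = []
        for idx in (idx1, idx0):
            repl = with_replacement if with_replacement is not None else idx.size < n_per_class
            take.append(rng.choice(idx, size=n_per_class, replace=repl))
        sel = np.concatenate(take)
        Xb, yb = X_all[sel], y_all[sel]
        try:
            clf = _fit_logistic(Xb, yb)
            if oob:
                rest = np.setdiff1d(np.arange(y_all.size), sel)
                if len(np.unique(y_all[rest])) < 2:
                    n_skipped += 1
                    continue
                aucs.append(compute_auc(clf.decision_function(X_all[rest]), y_all[rest]))
            else:
                aucs.append(compute_auc(clf.decision_function(Xb), yb))
        except Exception:  # non-convergence even under ridge: skip replicate
            n_skipped += 1
    if n_skipped > 0.10 * n_boot:
        raise RuntimeError(
            f"subset {subset}: {n_skipped}/{n_boot} bootstrap replicates failed"
        )
    aucs = np.array(aucs)
    return ComboScore(
        probe_subset=subset,
        pooled_mean_auc=float(aucs.mean()),
        pooled_auc_sd=float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0,
        n_bootstrap=int(aucs.size),
        n_skipped=n_skipped,
    )


def per_dataset_auc(
    bm: BetaMatrix,
    meta: Sequence[SampleMeta],
    subset: Sequence[int],
    n_boot: int = 100,
    n_per_class: int = 700,
    seed: int = 0,
) -> dict[str, float]:
    """Mean bootstrap AUC of the subset within each dataset separately."""
    out: dict[str, float] = {}
    by_type: dict[str, list[SampleMeta]] = {}
    for m in meta:
        by_type.setdefault(m.tumor_type, []).append(m)
    for i, code in enumerate(sorted(by_type)):
        sub_meta = by_type[code]
        sub_bm = bm.subset_samples([m.sample_id for m in sub_meta])
        score = bootstrap_combo_auc(
            sub_bm, sub_meta, subset,
            n_boot=n_boot, n_per_class=n_per_class, seed=seed + 1 + i,
        )
        out[code] = score.pooled_mean_auc
    return out


def combo_aic(bm: BetaMatrix, meta: Sequence[SampleMeta], subset: Sequence[int]) -> float:
    """AIC (2p - 2*loglik) of the full-data MLE logistic fit on the subset."""
    subset = tuple(sorted(set(int(i) for i in subset)))
    X = sm.add_constant(_design(bm, subset))
    y = _labels(meta)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit()
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 1e6:
        raise RuntimeError(f"logistic fit did not converge for subset {subset}")
    return float(res.aic)


def filter_combos(
    scores: Iterable[ComboScore],
    min_mean_auc: float,
    min_dataset_auc: float,
) -> list[ComboScore]:
    """Dual filter: mean AUC >= threshold AND worst per-dataset AUC >= floor.

    Both comparisons are inclusive. Survivors are ordered by descending mean
    AUC, ties broken by lexicographic subset.
    """
    survivors = []
    for s in scores:
        if not s.per_dataset_auc:
            raise ValueError(f"subset {s.probe_subset}: per_dataset_auc not populated")
        if s.pooled_mean_auc >= min_mean_auc and s.min_dataset_auc >= min_dataset_auc:
            survivors.append(s)
    survivors.sort(key=lambda s: (-s.pooled_mean_auc, s.probe_subset))
    return survivors


def threshold_sweep(
    scores: Sequence[ComboScore],
    start: float = 0.80,
    step: float = 0.01,
    min_dataset_auc: float = 0.80,
) -> pd.DataFrame:
    """Survivor counts over a grid of mean-AUC thresholds.

    The grid runs from ``start`` to the maximal observed mean AUC in ``step``
    increments; both a 0.01 and a 0.1 step are supported.
    """
    if not scores:
        return pd.DataFrame(columns=["threshold", "n_surviving"])
    top = max(s.pooled_mean_auc for s in scores)
    grid = np.arange(start, top + step / 2, step)
    rows = [
        (float(t), len(filter_combos(scores, t, min_dataset_auc))) for t in grid
    ]
    return pd.DataFrame(rows, columns=["threshold", "n_surviving"])


def search(
    bm: BetaMatrix,
    meta: Sequence[SampleMeta],
    k_min: int = 1,
    k_max: int = 6,
    n_boot: int = 1000,
    n_per_class: int = 700,
    seed: int = 0,
    per_dataset: bool = False,
    per_dataset_n_boot: int = 20,
    subsets: Iterable[Sequence[int]] | None = None,
    with_aic: bool = False,
) -> list[ComboScore]:
    """Score every subset (or an explicit subset list) of the pooled cohort.

    Each subset gets its own seed derived deterministically from ``seed`` and
    the subset itself, so results do not depend on evaluation order or any
    parallel chunking.
    """
    if subsets is None:
        subsets = enumerate_subsets(bm.n_probes, k_min, k_max)
    results = []
    for subset in subsets:
        subset = tuple(sorted(int(i) for i in subset))
        sub_seed = _subset_seed(seed, subset)
        score = bootstrap_combo_auc(
            bm, meta, subset, n_boot=n_boot, n_per_class=n_per_class, seed=sub_seed
        )
        if per_dataset:
            score.per_dataset_auc = per_dataset_auc(
                bm, meta, subset,
                n_boot=per_dataset_n_boot, n_per_class=n_per_class, seed=sub_seed,
            )
        if with_aic:
            score.aic = combo_aic(bm, meta, subset)
        results.append(score)
    return results


def _subset_seed(seed: int, subset: tuple[int, ...]) -> int:
    # order-independent, stable across runs (no PYTHONHASHSEED dependence)
    h = seed & 0x7FFFFFFF
    for i in subset:
        h = (h * 1000003 + i * 2654435761) & 0x7FFFFFFF
    return h


def scores_to_frame(scores: Sequence[ComboScore]) -> pd.DataFrame:
    datasets = sorted({d for s in scores for d in s.per_dataset_auc})
    rows = []
    for s in scores:
        row = {
            "subset": "-".join(map(str, s.probe_subset)),
            "k": len(s.probe_subset),
            "mean_auc": s.pooled_mean_auc,
            "sd_auc": s.pooled_auc_sd,
            "n_bootstrap": s.n_bootstrap,
            "aic": s.aic,
        }
        if s.per_dataset_auc:
            row["min_dataset_auc"] = s.min_dataset_auc
            for d in datasets:
                row[f"auc_{d}"] = s.per_dataset_auc.get(d)
        rows.append(row)
    return pd.DataFrame(rows)
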