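"""One-vs-rest tumor-type signatures via PLS discriminant analysis.

PLSDA here is PLS2 regression of the one-hot tumor-type indicator matrix on a
probe subset's beta-values; a sample's score for class c is the predicted
value of c's indicator column, and each class is evaluated by the
cross-validated rank AUC of its own score against all other classes pooled.

Two fitting routes are provided and cross-checked: NIPALS (via scikit-learn's
PLSRegression) and SIMPLS (implemented here, following de Jong's deflation of
the cross-product matrix). Their predictions coincide exactly when the
centered response is effectively rank one (any two-class problem), when a
single latent component is used, or in the full-component limit where both
collapse to ordinary least squares; generic multiclass fits with intermediate
component counts may differ in the digits beyond those regimes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .combo_search import compute_auc
from .data_model import BetaMatrix, SampleMeta


@dataclass
class PlsdaModel:
    """Fitted PLS2 discriminant model."""

    classes: tuple[str, ...]
    probe_subset: tuple[int, ...]
    n_components: int
    algorithm: str
    x_mean: np.ndarray
    y_mean: np.ndarray
    coef: np.ndarray  # (p, n_classes) regression matrix on centered X
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray  # training latent scores (n, A)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Per-class indicator scores for new samples."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        return Xc @ self.coef + self.y_mean


def _one_hot(y: Sequence[str]) -> tuple[np.ndarray, tuple[str, ...]]:
    classes = tuple(sorted(set(map(str, y))))
    Y = np.zeros((len(y), len(classes)))
    lookup = {c: j for j, c in enumerate(classes)}
    for i, label in enumerate(y):
        Y[i, lookup[str(label)]] = 1.0
    return Y, classes


def _simpls(Xc: np.ndarray, Yc: np.ndarray, n_components: int):
    """SIMPLS: successive dominant directions of the deflated cross-product."""
    n, p = Xc.shape
    m = Yc.shape[1]
    S = Xc.T @ Yc
    R = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((m, n_components))
    V = np.zeros((p, n_components))
    for a in range(n_components):
        u, sv, _ = np.linalg.svd(S, full_matrices=False)
        r = u[:, 0]
        t = Xc @ r
        norm_t = np.linalg.norm(t)
        if norm_t < 1e-12:
            raise ValueError(
                f"component {a + 1}: no variance left to extract "
                f"(n_components exceeds the effective rank)"
            )
        t /= norm_t
        r /= norm_t
        pv = Xc.T @ t
        q = Yc.T @ t
        v = pv.copy()
        for j in range(a):
            v -= (V[:, j] @ pv) * V[:, j]
        v /= np.linalg.norm(v)
        S = S - np.outer(v, v @ S)
        R[:, a], T[:, a], P[:, a], Q[:, a], V[:, a] = r, t, pv, q, v
    coef = R @ Q.T
    return coef, R, T, P, Q


def fit_plsda(
    X: np.ndarray,
    y: Sequence[str],
    n_components: int = 2,
    algorithm: str = "simpls",
    probe_subset: Sequence[int] = (),
) -> PlsdaModel:
    """Fit a PLSDA model of tumor-type labels on probe beta-values.

    ``X`` is column-centered internally; the centering vector is stored on
    the model and re-applied at prediction time.
    """
    X = np.asarray(X, dtype=float)
    Y, classes = _one_hot(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    labels, counts = np.unique(np.asarray(y, dtype=str), return_counts=True)
    small = labels[counts < 2]
    if small.size:
        raise ValueError(f"classes with <2 samples: {small.tolist()}")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank(X)={rank}")

    if algorithm == "simpls":
        coef, R, T, P, Q = _simpls(Xc, Y - y_mean, n_components)
        W = R
    elif algorithm == "nipals":
        pls = PLSRegression(
            n_components=n_components, scale=False, tol=1e-12, max_iter=2000
        )
        pls.fit(X, Y)
        coef = pls.coef_.T  # sklearn stores (n_targets, n_features)
        W, T = pls.x_weights_, pls.x_scores_
        P, Q = pls.x_loadings_, pls.y_loadings_
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    return PlsdaModel(
        classes=classes,
        probe_subset=tuple(probe_subset),
        n_components=n_components,
        algorithm=algorithm,
        x_mean=x_mean,
        y_mean=y_mean,
        coef=coef,
        x_weights=W,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
    )


def _tumor_design(
    bm: BetaMatrix, meta: Sequence[SampleMeta], subset: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    tumors = [m for m in meta if m.tissue == "TP"]
    cols = [bm.probe_ids[i - 1] for i in subset]
    X = bm.values.loc[[m.sample_id for m in tumors], cols].to_numpy(dtype=float)
    labels = np.array([m.tumor_type for m in tumors])
    return X, labels


def ovr_cv_auc(
    bm: BetaMatrix,
    meta: Sequence[SampleMeta],
    subset: Sequence[int],
    n_components: int = 2,
    n_folds: int = 5,
    seed: int = 0,
    algorithm: str = "simpls",
) -> dict[str, float]:
    """Cross-validated one-vs-rest AUC per tumor type on the tumor-only cohort.

    Held-out class scores are pooled across folds; each class's AUC compares
    its own indicator score in its samples against all other samples.
    """
    subset = tuple(sorted(int(i) for i in subset))
    X, labels = _tumor_design(bm, meta, subset)
    classes = tuple(sorted(set(labels)))
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("every class needs at least n_folds members")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pooled = np.empty((len(labels), len(classes)))
    for train_idx, test_idx in skf.split(X, labels):
        model = fit_plsda(
            X[train_idx], labels[train_idx], n_components, algorithm, subset
        )
        # align columns in case a fold lacks a class entirely (stratification
        # prevents this when counts >= n_folds)
        pred = model.predict(X[test_idx])
        col = {c: j for j, c in enumerate(model.classes)}
        for j, c in enumerate(classes):
            pooled[test_idx, j] = pred[:, col[c]] if c in col else 0.0

    return {
        c: compute_auc(pooled[:, j], (labels == c).astype(int))
        for j, c in enumerate(classes)
    }


@dataclass
class ScanResult:
    """Summary of an exhaustive (or subsampled) signature scan."""

    n_subsets: int
    per_class_best: dict[str, tuple[tuple[int, ...], float]]
    best_subset: tuple[int, ...]  # subset with highest mean-over-classes AUC
    best_subset_mean_auc: float
    grand_mean_auc: float  # mean over subsets of the class-mean AUC
    n_components: int
    records: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def scan_signatures(
    bm: BetaMatrix,
    meta: Sequence[SampleMeta],
    k: int = 6,
    n_components: int = 2,
    n_folds: int = 5,
    seed: int = 0,
    max_subsets: int | None = None,
    algorithm: str = "simpls",
) -> ScanResult:
    """Evaluate every k-probe subset by one-vs-rest CV AUC on tumors only.

    ``max_subsets`` draws a deterministic (seeded) subsample of the subset
    list for desk-scale runs; ``None`` scans exhaustively.
    """
    all_subsets = list(itertools.combinations(range(1, bm.n_probes + 1), k))
    if max_subsets is not None and max_subsets < len(all_subsets):
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(all_subsets), size=max_subsets, replace=False)
        subsets = [all_subsets[i] for i in sorted(pick)]
    else:
        subsets = all_subsets

    rows = []
    for subset in subsets:
        aucs = ovr_cv_auc(
            bm, meta, subset, n_components=n_components,
            n_folds=n_folds, seed=seed, algorithm=algorithm,
        )
        rows.append({"subset": subset, **aucs, "mean_auc": float(np.mean(list(aucs.values())))})
    records = pd.DataFrame(rows)

    classes = [c for c in records.columns if c not in ("subset", "mean_auc")]
    per_class_best = {}
    for c in classes:
        i = int(records[c].idxmax())
        per_class_best[c] = (tuple(records.loc[i, "subset"]), float(records.loc[i, c]))
    i_best = int(records["mean_auc"].idxmax())
    return ScanResult(
        n_subsets=len(subsets),
        per_class_best=per_class_best,
        best_subset=tuple(records.loc[i_best, "subset"]),
        best_subset_mean_auc=float(records.loc[i_best, "mean_auc"]),
        grand_mean_auc=float(records["mean_auc"].mean()),
        n_components=n_components,
        records=records,
    )
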