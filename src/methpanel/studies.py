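"""End-to-end simulation studies: calibration, recovery and consistency checks.

These functions re-run the package's main claims from scratch on synthetic
cohorts drawn at the bundled study design: subset-enumeration counts, rank-AUC
agreement with a pair-counting oracle, mixed-model and interaction-test
type-I error, planted-panel recovery by the combination search, PLSDA
consistency checks, and byte-level pipeline determinism. Both the test suite
and the reproduction script drive these entry points.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np

from . import combo_search, covariate_assoc, diff_meth, pan_cancer_model
from .combo_search import bootstrap_combo_auc, compute_auc, count_subsets
from .data_model import load_cohort_registry, load_probe_annotation
from .pipeline import RunConfig, run_pipeline
from .synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_label_model_data,
    logit,
    planted_panel,
    scale_counts,
)
from .tumor_specific import fit_plsda, ovr_cv_auc, scan_signatures

PLANTED = frozenset({3, 12, 14, 18, 20, 21})


def enumeration_counts() -> dict[str, int]:
    """Subset counts of the exhaustive search over the 22-probe panel."""
    n6 = sum(1 for _ in combo_search.enumerate_subsets(22, 6, 6))
    n3 = sum(1 for _ in combo_search.enumerate_subsets(22, 3, 3))
    total = count_subsets(22, 1, 6)
    return {"n_six_probe_subsets": n6, "n_three_probe_subsets": n3,
            "n_subsets_up_to_six": total}


def fixture_summary() -> dict[str, int]:
    """Counts parsed from the bundled probe annotation and cohort registry."""
    probes = load_probe_annotation()
    cohorts = load_cohort_registry()
    return {
        "n_panel_probes": len(probes),
        "n_cohort_datasets": len(cohorts),
        "n_normal_total": sum(r.n_normal for r in cohorts),
        "n_tumor_total": sum(r.n_tumor for r in cohorts),
        "n_samples_total": sum(r.total for r in cohorts),
    }


def auc_oracle_max_diff(n_instances: int = 1000, max_n: int = 50, seed: int = 0) -> float:
    """Largest |rank AUC - pair-counting AUC| over random tied instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, max_n + 1))
        scores = np.round(rng.normal(size=n), 1)
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        pos, neg = scores[labels == 1], scores[labels == 0]
        cmp = np.sign(pos[:, None] - neg[None, :])
        brute = float(np.mean((cmp + 1) / 2))
        worst = max(worst, abs(compute_auc(scores, labels) - brute))
    return worst


def mixed_model_type1_error(
    n_probes: int = 1000, alpha: float = 0.05, seed: int = 0,
    n_pairs: int = 50,
) -> float:
    """Rejection rate of the paired mixed model on null data (patient_sd = 0).

    Each replicate cohort contributes its 22 null probes; cohorts are drawn
    until ``n_probes`` tests accumulate.
    """
    rejections = 0
    tested = 0
    rep = 0
    while tested < n_probes:
        cfg = GeneratorConfig(
            tumor_types=["T1"],
            n_normal={"T1": n_pairs},
            n_tumor={"T1": n_pairs},
            patient_sd=0.0,
            seed=seed * 100_003 % (2**31 - 1) + rep,
        )
        bm, meta = generate_cohort(cfg)
        for probe in bm.probe_ids:
            if tested >= n_probes:
                break
            res = diff_meth.test_probe(bm.values[probe], meta, alpha=alpha)
            rejections += res.direction != "ns"
            tested += 1
        rep += 1
    return rejections / tested


def panel_recovery_study(
    n_seeds: int = 5,
    seed: int = 0,
    n_boot_planted: int = 100,
    n_per_class: int = 700,
    delta: float = 2.0,
    oracle_n: int = 100_000,
) -> dict[str, float]:
    """Planted six-probe panel recovery at the bundled cohort design.

    Per seed: the planted subset's mean bootstrap AUC is compared against
    every six-probe subset disjoint from it (8008 subsets, scored with a
    single balanced replicate each); the planted panel's 10-fold CV AUC is
    compared with the AUC of the generating model's sufficient score on a
    fresh large draw.
    """
    others = [i for i in range(1, 23) if i not in PLANTED]
    disjoint = list(itertools.combinations(others, 6))
    planted_subset = tuple(sorted(PLANTED))

    wins = 0
    cv_aucs = []
    for k in range(n_seeds):
        cfg = planted_panel(GeneratorConfig(seed=seed + 1 + k), PLANTED, delta)
        bm, meta = generate_cohort(cfg)
        planted_score = bootstrap_combo_auc(
            bm, meta, planted_subset,
            n_boot=n_boot_planted, n_per_class=n_per_class, seed=seed + 11 + k,
        ).pooled_mean_auc
        best_disjoint = max(
            bootstrap_combo_auc(
                bm, meta, s, n_boot=1, n_per_class=n_per_class, seed=seed + 11 + k
            ).pooled_mean_auc
            for s in disjoint
        )
        wins += planted_score > best_disjoint
        roc = pan_cancer_model.crossval_roc(
            bm, meta, planted_subset, n_folds=10, seed=seed + 21 + k
        )
        cv_aucs.append(roc.auc)

    # generator oracle: the planted effect is shared across the six probes,
    # so the sum of their logits is a sufficient score for the class
    big = planted_panel(
        scale_counts(GeneratorConfig(seed=seed + 91), oracle_n / 6502),
        PLANTED, delta,
    )
    bm_big, meta_big = generate_cohort(big)
    cols = [bm_big.probe_ids[i - 1] for i in sorted(PLANTED)]
    score = logit(bm_big.values[cols].to_numpy()).sum(axis=1)
    labels = np.array([1 if m.tissue == "TP" else 0 for m in meta_big])
    oracle_auc = compute_auc(score, labels)
    cv_mean = float(np.mean(cv_aucs))
    return {
        "rank_recovery_rate": wins / n_seeds,
        "cv_auc": cv_mean,
        "oracle_auc": float(oracle_auc),
        "cv_vs_oracle_max_abs_diff": float(
            max(abs(a - oracle_auc) for a in cv_aucs)
        ),
        "oracle_draw_size": bm_big.n_samples,
    }


def plsda_consistency(seed: int = 0) -> dict[str, float]:
    """Cross-checks of the PLSDA implementation against exact limits."""
    rng = np.random.default_rng(seed)

    # one predictor, two classes: score is affine in the probe
    x = rng.uniform(size=(80, 1))
    y2 = np.array(["a"] * 40 + ["b"] * 40)
    model = fit_plsda(x, y2, n_components=1)
    labels = (y2 == "b").astype(int)
    auc_score = compute_auc(model.predict(x)[:, 1], labels)
    auc_raw = compute_auc(x[:, 0], labels)
    one_probe_diff = min(abs(auc_score - auc_raw), abs(auc_score - (1 - auc_raw)))

    # NIPALS vs SIMPLS where the algorithms provably coincide
    X = rng.normal(size=(60, 5))
    diffs = []
    for nc in (1, 2, 3):
        pa = fit_plsda(X, y2[:60], nc, "nipals").predict(X)
        pb = fit_plsda(X, y2[:60], nc, "simpls").predict(X)
        diffs.append(float(np.abs(pa - pb).max()))
    y3 = np.array(["a", "b", "c"] * 20)
    pa = fit_plsda(X, y3, 1, "nipals").predict(X)
    pb = fit_plsda(X, y3, 1, "simpls").predict(X)
    diffs.append(float(np.abs(pa - pb).max()))

    # toy scan: per-class maxima equal brute-force recomputation
    from .data_model import Region

    types = ["T1", "T2", "T3", "T4"]
    effect = np.zeros((4, 8))
    effect[0, :3] = 2.5
    cfg = GeneratorConfig(
        probe_ids=[f"p{j}" for j in range(1, 9)],
        regions=[Region.PROMOTER] * 8,
        tumor_types=types,
        n_normal={t: 0 for t in types},
        n_tumor={t: 25 for t in types},
        baseline_mean=np.full(8, 0.3),
        effect=effect,
        patient_sd=0.2,
        seed=seed + 17,
    )
    bm, meta = generate_cohort(cfg)
    scan = scan_signatures(bm, meta, k=3, n_components=2, n_folds=4, seed=seed)
    mismatch = 0.0
    best: dict[str, float] = {}
    for subset in itertools.combinations(range(1, 9), 3):
        for c, v in ovr_cv_auc(bm, meta, subset, n_components=2, n_folds=4,
                               seed=seed).items():
            best[c] = max(best.get(c, 0.0), v)
    for c, (_, v) in scan.per_class_best.items():
        mismatch = max(mismatch, abs(best[c] - v))
    return {
        "one_probe_auc_abs_diff": float(one_probe_diff),
        "nipals_simpls_max_pred_diff": float(max(diffs)),
        "toy_scan_n_subsets": scan.n_subsets,
        "toy_scan_max_mismatch": mismatch,
    }


def interaction_lrt_type1_error(
    n_reps: int = 1000, n: int = 800, alpha: float = 0.05, seed: int = 0
) -> float:
    """Null rejection rate of the stage x methylation LRT."""
    rejections = 0
    for r in range(n_reps):
        d = generate_label_model_data(
            n, beta_coef=1.0, stage_coef=0.0, interaction_coef=0.0,
            seed=(seed * 99_991 + r) % (2**31 - 1),
        )
        _, _, p = covariate_assoc.stage_interaction_lrt(
            d.tissue.to_numpy(), d.beta.to_numpy(), d.stage.to_numpy()
        )
        rejections += p <= alpha
    return rejections / n_reps


def pipeline_determinism(work_dir: str | Path, seed: int = 0) -> dict[str, float]:
    """Byte-identity of pipeline reruns and order-independence of the search."""
    work_dir = Path(work_dir)
    tiny = dict(
        scale=0.02, k_max=1, n_boot=10, n_per_class=30, per_dataset=False,
        signature_k=2, signature_max_subsets=5, signature_n_folds=3,
    )
    out_a = run_pipeline(RunConfig(out_dir=str(work_dir / "a"), seed=seed, **tiny))
    out_b = run_pipeline(RunConfig(out_dir=str(work_dir / "b"), seed=seed, **tiny))
    identical = all(
        (out_a / p.name).read_bytes() == p.read_bytes()
        for p in sorted(out_b.glob("*.tsv"))
    )

    # evaluation order must not matter (this is what makes results
    # independent of any parallel chunking)
    cfg = scale_counts(GeneratorConfig(seed=seed + 3), 0.03)
    cfg = planted_panel(cfg, PLANTED, 2.0)
    bm, meta = generate_cohort(cfg)
    subsets = [(1, 2), (3, 12), (5,), (14, 21)]
    fwd = combo_search.search(bm, meta, subsets=subsets, n_boot=5,
                              n_per_class=20, seed=seed)
    rev = combo_search.search(bm, meta, subsets=subsets[::-1], n_boot=5,
                              n_per_class=20, seed=seed)
    by_subset = {s.probe_subset: s.pooled_mean_auc for s in rev}
    order_free = all(
        by_subset[s.probe_subset] == s.pooled_mean_auc for s in fwd
    )
    return {
        "pipeline_rerun_identical": float(identical),
        "search_order_independent": float(order_free),
    }
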