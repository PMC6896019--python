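import itertools

import numpy as np
import pandas as pd
import pytest

from methpanel.combo_search import compute_auc
from methpanel.data_model import BetaMatrix, SampleMeta
from methpanel.synthetic import GeneratorConfig, generate_cohort
from methpanel.tumor_specific import fit_plsda, ovr_cv_auc, scan_signatures


def _typed_cohort(signature_type="T1", n_per_type=40, n_types=4, seed=8,
                  delta=2.5, n_probes=8):
    """Tumor-only cohort where one type has a unique 3-probe signature."""
    types = [f"T{i + 1}" for i in range(n_types)]
    cfg_probes = [f"p{j + 1}" for j in range(n_probes)]
    effect = np.zeros((n_types, n_probes))
    effect[types.index(signature_type), :3] = delta
    from methpanel.data_model import Region

    cfg = GeneratorConfig(
        probe_ids=cfg_probes,
        regions=[Region.PROMOTER] * n_probes,
        tumor_types=types,
        n_normal={t: 0 for t in types},
        n_tumor={t: n_per_type for t in types},
        baseline_mean=np.full(n_probes, 0.3),
        effect=effect,
        patient_sd=0.2,
        seed=seed,
    )
    return generate_cohort(cfg)


class TestFitPlsda:
    def test_one_probe_two_class_score_is_affine_in_probe(self, rng):
        # a single-predictor PLSDA score is an affine function of the probe,
        # so its one-vs-rest rank AUC equals the raw probe's AUC exactly
        x = rng.uniform(size=(80, 1))
        y = np.array(["a"] * 40 + ["b"] * 40)
        model = fit_plsda(x, y, n_components=1)
        scores = model.predict(x)
        labels = (y == "b").astype(int)
        auc_score = compute_auc(scores[:, 1], labels)
        auc_raw = compute_auc(x[:, 0], labels)
        assert auc_score in (auc_raw, 1 - auc_raw)

    @pytest.mark.parametrize("n_components", [1, 2, 3])
    def test_nipals_and_simpls_agree_binary(self, rng, n_components):
        # two-class one-hot response is rank one: both algorithms coincide
        X = rng.normal(size=(60, 5))
        y = np.array(["a", "b"] * 30)
        pa = fit_plsda(X, y, n_components, "nipals").predict(X)
        pb = fit_plsda(X, y, n_components, "simpls").predict(X)
        assert np.abs(pa - pb).max() < 1e-6

    def test_nipals_and_simpls_agree_multiclass_one_component(self, rng):
        X = rng.normal(size=(60, 5))
        y = np.array(["a", "b", "c"] * 20)
        pa = fit_plsda(X, y, 1, "nipals").predict(X)
        pb = fit_plsda(X, y, 1, "simpls").predict(X)
        assert np.abs(pa - pb).max() < 1e-6

    @pytest.mark.parametrize("algorithm", ["nipals", "simpls"])
    def test_full_component_fit_equals_ols(self, rng, algorithm):
        X = rng.normal(size=(50, 4))
        y = np.array(["a", "b", "c", "d", "e"] * 10)
        pred = fit_plsda(X, y, 4, algorithm).predict(X)
        Y = np.zeros((50, 5))
        for i, c in enumerate(sorted(set(y))):
            Y[y == c, i] = 1.0
        Xc = X - X.mean(0)
        B = np.linalg.lstsq(Xc, Y - Y.mean(0), rcond=None)[0]
        ols = Xc @ B + Y.mean(0)
        assert np.abs(pred - ols).max() < 1e-8

    @pytest.mark.parametrize("algorithm", ["nipals", "simpls"])
    def test_duplicated_columns_match_in_full_rank_limit(self, rng, algorithm):
        # PLS weights are not duplication-invariant at intermediate component
        # counts; at full rank both collapse to OLS on the column space
        X = rng.normal(size=(40, 3))
        Xdup = np.column_stack([X, X[:, 0]])
        y = np.array(["a", "b", "c", "d"] * 10)
        p_base = fit_plsda(X, y, 3, algorithm).predict(X)
        p_dup = fit_plsda(Xdup, y, 3, algorithm).predict(Xdup)
        assert np.abs(p_base - p_dup).max() < 1e-6

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(50, 6))
        y = np.array(["a", "b", "c"] * 16 + ["a", "b"])
        model = fit_plsda(X, y, 3, "simpls")
        T = model.x_scores
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_excess_components_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError, match="rank"):
            fit_plsda(X, np.array(["a", "b"] * 10), 4)

    def test_tiny_class_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="<2"):
            fit_plsda(X, np.array(["a", "a", "a", "a", "b"]), 1)


class TestOvrCvAuc:
    def test_planted_signature_type_dominates(self):
        bm, meta = _typed_cohort()
        aucs = ovr_cv_auc(bm, meta, (1, 2, 3, 4, 5, 6), n_components=2,
                          n_folds=5, seed=0)
        assert aucs["T1"] >= 0.95

    def test_permuted_labels_near_chance(self):
        bm, meta = _typed_cohort(n_per_type=200, seed=13)
        rng = np.random.default_rng(1)
        labels = [m.tumor_type for m in meta]
        rng.shuffle(labels)
        permuted = [
            SampleMeta(m.sample_id, m.patient_barcode, m.tissue, t)
            for m, t in zip(meta, labels)
        ]
        aucs = ovr_cv_auc(bm, permuted, (1, 2, 3, 4, 5, 6), n_components=2,
                          n_folds=5, seed=0)
        for v in aucs.values():
            assert abs(v - 0.5) < 0.07

    def test_identical_signature_classes_confusable(self):
        # a cohort of two classes drawn from the same distribution cannot be
        # separated: both one-vs-rest AUCs stay near chance
        bm, meta = _typed_cohort(n_types=2, seed=3, delta=0.0)
        aucs = ovr_cv_auc(bm, meta, (1, 2, 3, 4, 5, 6), n_components=2,
                          n_folds=5, seed=0)
        assert aucs["T1"] <= 0.6 and aucs["T2"] <= 0.6

    def test_invariant_to_class_renaming_and_sample_order(self):
        bm, meta = _typed_cohort(seed=4)
        aucs = ovr_cv_auc(bm, meta, (1, 2, 3), n_components=1, n_folds=4, seed=2)
        renamed = [
            SampleMeta(m.sample_id, m.patient_barcode, m.tissue,
                       m.tumor_type.replace("T", "Z"))
            for m in meta
        ]
        aucs_renamed = ovr_cv_auc(bm, renamed, (1, 2, 3), n_components=1,
                                  n_folds=4, seed=2)
        for t, v in aucs.items():
            assert aucs_renamed[t.replace("T", "Z")] == pytest.approx(v, abs=1e-12)

    def test_mean_auc_above_half_with_signal(self):
        bm, meta = _typed_cohort(seed=6)
        aucs = ovr_cv_auc(bm, meta, (1, 2, 3, 4), n_components=2, n_folds=5, seed=0)
        assert np.mean(list(aucs.values())) >= 0.5


class TestScanSignatures:
    def test_toy_scan_counts_and_brute_force_maxima(self):
        bm, meta = _typed_cohort(n_per_type=25, seed=10)
        scan = scan_signatures(bm, meta, k=3, n_components=2, n_folds=4, seed=5)
        assert scan.n_subsets == 56  # C(8,3)
        # independent recomputation of every per-class maximum
        best = {}
        for subset in itertools.combinations(range(1, 9), 3):
            aucs = ovr_cv_auc(bm, meta, subset, n_components=2, n_folds=4, seed=5)
            for c, v in aucs.items():
                if c not in best or v > best[c][1]:
                    best[c] = (subset, v)
        for c, (subset, v) in best.items():
            assert scan.per_class_best[c][1] == pytest.approx(v, abs=1e-12)
            assert scan.per_class_best[c][0] == subset

    def test_planted_signature_recovered_in_best_subset(self):
        hits = 0
        for seed in range(5):
            bm, meta = _typed_cohort(n_per_type=30, seed=100 + seed, delta=3.0)
            scan = scan_signatures(bm, meta, k=3, n_components=2, n_folds=3,
                                   seed=seed)
            best_subset = scan.per_class_best["T1"][0]
            hits += len(set(best_subset) & {1, 2, 3}) >= 2
        assert hits >= 4

    def test_subsampled_scan_is_deterministic(self):
        bm, meta = _typed_cohort(n_per_type=20, seed=2)
        a = scan_signatures(bm, meta, k=3, n_folds=3, seed=9, max_subsets=10)
        b = scan_signatures(bm, meta, k=3, n_folds=3, seed=9, max_subsets=10)
        assert a.n_subsets == b.n_subsets == 10
        assert a.per_class_best == b.per_class_best
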