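import numpy as np
import pandas as pd
import pytest

from methpanel.combo_search import compute_auc
from methpanel.data_model import SampleMeta
from methpanel.pan_cancer_model import (
    DEFAULT_PANEL,
    PanelModel,
    RocResult,
    crossval_roc,
    fit_panel,
    roc_from_scores,
    threshold_metrics,
    validate_many,
    validate_refit,
)
from methpanel.synthetic import GeneratorConfig, generate_cohort, planted_panel, scale_counts


def _permute_labels(meta, rng):
    tissues = [m.tissue for m in meta]
    rng.shuffle(tissues)
    return [
        SampleMeta(m.sample_id, f"perm{i}", t, m.tumor_type)
        for i, (m, t) in enumerate(zip(meta, tissues))
    ]


@pytest.fixture(scope="module")
def balanced_cohort():
    """One-type 500/500 paired cohort with the planted panel; tight AUC bands
    need the larger normal class."""
    cfg = GeneratorConfig(
        tumor_types=["T1"], n_normal={"T1": 500}, n_tumor={"T1": 500}, seed=19
    )
    cfg = planted_panel(cfg, {3, 12, 14, 18, 20, 21}, 2.0)
    return generate_cohort(cfg)


class TestCrossvalRoc:
    def test_planted_panel_is_highly_discriminative(self, planted_cohort):
        bm, meta = planted_cohort
        roc = crossval_roc(bm, meta, DEFAULT_PANEL, n_folds=10, seed=0)
        assert roc.auc > 0.95

    def test_permuted_labels_give_chance_auc(self, balanced_cohort):
        bm, meta = balanced_cohort
        rng = np.random.default_rng(0)
        roc = crossval_roc(bm, _permute_labels(meta, rng), DEFAULT_PANEL, seed=0)
        assert abs(roc.auc - 0.5) < 0.05

    def test_same_seed_reproduces_result(self, planted_cohort):
        bm, meta = planted_cohort
        a = crossval_roc(bm, meta, DEFAULT_PANEL, seed=3)
        b = crossval_roc(bm, meta, DEFAULT_PANEL, seed=3)
        assert np.array_equal(a.fpr, b.fpr) and np.array_equal(a.tpr, b.tpr)
        assert a.auc == b.auc and a.threshold_metrics == b.threshold_metrics

    def test_null_stage_covariate_barely_moves_auc(self, balanced_cohort):
        # stage is simulated independent of methylation: adding it as a
        # covariate must not change the cross-validated AUC materially
        bm, meta = balanced_cohort
        base = crossval_roc(bm, meta, DEFAULT_PANEL, seed=0)
        with_stage = crossval_roc(bm, meta, DEFAULT_PANEL, seed=0,
                                  covariates=("stage",))
        assert abs(base.auc - with_stage.auc) < 0.01

    def test_roc_auc_equals_rank_auc(self, rng):
        scores = rng.uniform(size=200)
        labels = rng.integers(0, 2, 200)
        roc = roc_from_scores(scores, labels)
        trapezoid = np.trapezoid(roc.tpr, roc.fpr)
        assert roc.auc == pytest.approx(trapezoid, abs=1e-10)
        assert roc.auc == pytest.approx(compute_auc(scores, labels), abs=1e-12)

    def test_too_few_class_members_rejected(self):
        ids = [f"s{i}" for i in range(8)]
        bm_df = pd.DataFrame(
            np.random.default_rng(0).uniform(size=(8, 6)), index=ids,
            columns=[f"p{j}" for j in range(6)],
        )
        from methpanel.data_model import BetaMatrix

        meta = [
            SampleMeta(s, s, "TP" if i < 6 else "NT", "T1")
            for i, s in enumerate(ids)
        ]
        with pytest.raises(ValueError, match="n_folds"):
            crossval_roc(BetaMatrix(bm_df), meta, (1, 2), n_folds=5)


class TestThresholdMetrics:
    def test_perfectly_separated(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert threshold_metrics(scores, labels, 0.5) == (1.0, 1.0, 1.0)

    def test_all_predicted_positive(self):
        scores = np.array([0.9, 0.8, 0.95, 0.99])
        labels = np.array([0, 0, 1, 1])
        sens, spec, _ = threshold_metrics(scores, labels, 0.5)
        assert sens == 1.0 and spec == 0.0

    def test_matches_brute_force_confusion_counts(self, rng):
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, 50)
        cutoff = 0.55
        sens, spec, acc = threshold_metrics(scores, labels, cutoff)
        tp = sum(s >= cutoff and l == 1 for s, l in zip(scores, labels))
        tn = sum(s < cutoff and l == 0 for s, l in zip(scores, labels))
        fn = sum(s < cutoff and l == 1 for s, l in zip(scores, labels))
        fp = sum(s >= cutoff and l == 0 for s, l in zip(scores, labels))
        assert sens == tp / (tp + fn)
        assert spec == tn / (tn + fp)
        assert acc == (tp + tn) / 50

    @pytest.mark.parametrize("cutoff", [0.0, 1.0, -0.5, 1.5])
    def test_cutoff_outside_unit_interval_rejected(self, cutoff):
        with pytest.raises(ValueError, match="cutoff"):
            threshold_metrics(np.array([0.4, 0.6]), np.array([0, 1]), cutoff)


class TestValidateRefit:
    def _external(self, seed, delta=2.0):
        cfg = GeneratorConfig(seed=seed)
        cfg = scale_counts(cfg, 0.05)
        cfg = planted_panel(cfg, {3, 12, 14, 18, 20, 21}, delta)
        return generate_cohort(cfg)

    def test_exchangeable_external_cohort_matches_training(self, planted_cohort):
        bm, meta = planted_cohort
        train = crossval_roc(bm, meta, DEFAULT_PANEL, seed=0)
        ext_bm, ext_meta = self._external(seed=77)
        ext = validate_refit(DEFAULT_PANEL, ext_bm, ext_meta, seed=0)
        assert abs(ext.auc - train.auc) < 0.03

    def test_null_external_cohort_near_chance(self):
        cfg = GeneratorConfig(
            tumor_types=["T1"], n_normal={"T1": 400}, n_tumor={"T1": 400},
            patient_sd=0.0, seed=5,
        )
        bm, meta = generate_cohort(cfg)
        roc = validate_refit(DEFAULT_PANEL, bm, meta, seed=1)
        assert abs(roc.auc - 0.5) < 0.05

    def test_multiple_cohorts_and_pooled_contract(self):
        cohorts = {
            f"c{i}": self._external(seed=100 + i) for i in range(3)
        }
        per_cohort, pooled = validate_many(DEFAULT_PANEL, cohorts, seed=0)
        assert set(per_cohort) == set(cohorts)
        for roc in (*per_cohort.values(), pooled):
            assert 0.0 <= roc.auc <= 1.0

    def test_missing_probe_index_named_in_error(self, planted_cohort):
        bm, meta = planted_cohort
        with pytest.raises(KeyError, match="23"):
            crossval_roc(bm, meta, (1, 2, 23), seed=0)


class TestPanelModel:
    def test_coefficient_count_enforced(self):
        with pytest.raises(ValueError):
            PanelModel((1, 2), ("a", "b"), 0.0, np.zeros(3))

    def test_predictions_in_open_unit_interval(self, planted_cohort):
        bm, meta = planted_cohort
        model = fit_panel(bm, meta, DEFAULT_PANEL)
        grid = np.array([[0.0] * 6, [1.0] * 6, [0.5] * 6])
        p = model.predict_proba(grid)
        assert np.all(p > 0) and np.all(p < 1)

    def test_text_serialization_round_trip_fields(self, planted_cohort, tmp_path):
        bm, meta = planted_cohort
        model = fit_panel(bm, meta, DEFAULT_PANEL)
        model.to_text(tmp_path / "model.txt")
        lines = (tmp_path / "model.txt").read_text().strip().splitlines()
        assert lines[0].startswith("intercept\t")
        assert len(lines) == 1 + len(DEFAULT_PANEL)

    def test_roc_curve_shape_invariants(self):
        with pytest.raises(ValueError):
            RocResult(fpr=np.array([0, 0.5, 0.4, 1]), tpr=np.array([0, 0.5, 0.7, 1]),
                      auc=0.7)
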