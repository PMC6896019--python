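import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methpanel.combo_search import (
    ComboScore,
    UndefinedAUCError,
    bootstrap_combo_auc,
    combo_aic,
    compute_auc,
    count_subsets,
    enumerate_subsets,
    filter_combos,
    threshold_sweep,
)
from methpanel.data_model import BetaMatrix, SampleMeta


def pair_counting_auc(scores, labels):
    """O(n^2) oracle: concordant pairs + half ties over all case/control pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestEnumerateSubsets:
    @pytest.mark.parametrize(
        "args, expected",
        [((22, 6, 6), 74613), ((22, 3, 3), 1540), ((5, 5, 5), 1), ((22, 1, 6), 110055)],
    )
    def test_counts_match_binomial_sums(self, args, expected):
        assert count_subsets(*args) == expected
        assert sum(1 for _ in enumerate_subsets(*args)) == expected

    def test_lexicographic_deterministic_order(self):
        subsets = list(enumerate_subsets(4, 2, 3))
        assert subsets[:3] == [(1, 2), (1, 3), (1, 4)]
        assert subsets == sorted(subsets, key=lambda s: (len(s), s))

    @pytest.mark.parametrize("bounds", [(5, 0, 3), (5, 4, 2), (5, 2, 6)])
    def test_invalid_bounds_rejected(self, bounds):
        with pytest.raises(ValueError):
            list(enumerate_subsets(*bounds))

    @given(n=st.integers(2, 22), k=st.integers(1, 6))
    @settings(max_examples=25, deadline=None)
    def test_count_equals_binomial(self, n, k):
        if k <= n:
            assert count_subsets(n, k, k) == math.comb(n, k)


class TestComputeAuc:
    def test_perfect_separation(self):
        assert compute_auc(np.array([0.1, 0.9]), np.array([0, 1])) == 1.0

    def test_all_tied_scores(self):
        assert compute_auc(np.full(10, 0.3), np.array([0, 1] * 5)) == 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_counting_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = 20
        scores = np.round(r.normal(size=n), 1)  # rounding induces ties
        labels = r.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert compute_auc(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            compute_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance_and_complement(self, seed):
        r = np.random.default_rng(seed)
        scores = r.normal(size=25)
        labels = r.integers(0, 2, 25)
        if labels.sum() in (0, 25):
            labels[0] = 1 - labels[0]
        auc = compute_auc(scores, labels)
        assert compute_auc(np.exp(scores), labels) == pytest.approx(auc, abs=1e-12)
        assert compute_auc(scores, 1 - labels) == pytest.approx(1 - auc, abs=1e-12)


def _binary_toy():
    """10 cases (8 exposed), 10 controls (2 exposed) on one 0/1 probe."""
    x = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8, dtype=float)
    y = [1] * 10 + [0] * 10
    ids = [f"s{i}" for i in range(20)]
    bm = BetaMatrix(pd.DataFrame({"p1": x}, index=ids))
    meta = [
        SampleMeta(s, f"pat{i}", "TP" if t else "NT", "T1")
        for i, (s, t) in enumerate(zip(ids, y))
    ]
    return bm, meta, x, np.array(y)


class TestBootstrapComboAuc:
    def test_two_by_two_toy_log_odds_and_auc(self):
        # closed form: fitted log-odds = ln[(8*8)/(2*2)]; AUC = pair oracle
        bm, meta, x, y = _binary_toy()
        score = bootstrap_combo_auc(
            bm, meta, (1,), n_boot=1, n_per_class=10, seed=0, with_replacement=False
        )
        assert score.pooled_mean_auc == pytest.approx(pair_counting_auc(x, y), abs=1e-12)
        from methpanel.combo_search import _fit_logistic

        clf = _fit_logistic(x[:, None], y)
        assert clf.coef_[0, 0] == pytest.approx(np.log(64 / 4), abs=1e-3)

    @pytest.fixture(scope="class")
    def balanced_null(self):
        from methpanel.synthetic import GeneratorConfig, generate_cohort

        cfg = GeneratorConfig(
            tumor_types=["T1"], n_normal={"T1": 400}, n_tumor={"T1": 400},
            patient_sd=0.0, seed=41,
        )
        return generate_cohort(cfg)

    def test_null_cohort_oob_auc_calibrates_to_half(self, balanced_null):
        # out-of-bag scoring removes the in-sample optimism of the fitted AUC
        bm, meta = balanced_null
        score = bootstrap_combo_auc(
            bm, meta, (1, 5, 9, 13, 17, 21), n_boot=60, n_per_class=200,
            seed=4, oob=True,
        )
        assert abs(score.pooled_mean_auc - 0.5) < 0.03

    def test_in_sample_optimism_is_small_and_positive(self, balanced_null):
        bm, meta = balanced_null
        score = bootstrap_combo_auc(
            bm, meta, (1, 5, 9, 13, 17, 21), n_boot=60, n_per_class=200, seed=4
        )
        assert 0.5 < score.pooled_mean_auc < 0.60

    def test_identical_seed_reproduces_score_exactly(self, planted_cohort):
        bm, meta = planted_cohort
        a = bootstrap_combo_auc(bm, meta, (3, 12, 14), n_boot=10, n_per_class=50, seed=9)
        b = bootstrap_combo_auc(bm, meta, (3, 12, 14), n_boot=10, n_per_class=50, seed=9)
        assert a.pooled_mean_auc == b.pooled_mean_auc
        assert a.pooled_auc_sd == b.pooled_auc_sd


class TestComboAic:
    def test_predictor_beats_intercept_on_informative_toy(self, planted_cohort):
        bm, meta = planted_cohort
        aic_planted = combo_aic(bm, meta, (3,))
        aic_null = combo_aic(bm, meta, (1,))
        assert aic_planted < aic_null

    def test_aic_equals_direct_log_likelihood_summation(self):
        bm, meta, x, y = _binary_toy()
        aic = combo_aic(bm, meta, (1,))
        import statsmodels.api as sm

        res = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        p_hat = res.predict(sm.add_constant(x))
        ll = np.sum(y * np.log(p_hat) + (1 - y) * np.log1p(-p_hat))
        assert aic == pytest.approx(2 * 2 - 2 * ll, abs=1e-8)

    def test_nested_model_aic_identity(self, planted_cohort):
        # child = parent + one noise probe: AIC_child - AIC_parent = 2 - LRT,
        # with LRT >= 0
        bm, meta = planted_cohort
        aic_parent = combo_aic(bm, meta, (3, 12))
        aic_child = combo_aic(bm, meta, (2, 3, 12))
        lrt = aic_parent + 2 - aic_child
        assert lrt >= -1e-6
        assert aic_child <= aic_parent + 2 + 1e-6


def _score(subset, mean, per_ds, sd=0.01):
    return ComboScore(
        probe_subset=subset, pooled_mean_auc=mean, pooled_auc_sd=sd,
        per_dataset_auc=per_ds, n_bootstrap=10,
    )


class TestFilterCombos:
    def test_min_dataset_failure_excludes(self):
        s = _score((1, 2, 3), 0.86, {"A": 0.90, "B": 0.79})
        assert filter_combos([s], 0.84, 0.80) == []

    def test_boundary_values_included(self):
        s = _score((1, 2, 3), 0.84, {"A": 0.80, "B": 0.92})
        assert filter_combos([s], 0.84, 0.80) == [s]

    def test_matches_brute_force_predicate(self, rng):
        scores = []
        for i in range(100):
            subset = tuple(sorted(rng.choice(22, size=3, replace=False) + 1))
            scores.append(
                _score(subset, float(rng.uniform(0.5, 1.0)),
                       {d: float(rng.uniform(0.5, 1.0)) for d in "ABC"})
            )
        got = filter_combos(scores, 0.84, 0.80)
        expected = [
            s for s in scores
            if s.pooled_mean_auc >= 0.84 and min(s.per_dataset_auc.values()) >= 0.80
        ]
        assert sorted(got, key=id) == sorted(expected, key=id)
        # deterministic ordering
        assert got == sorted(got, key=lambda s: (-s.pooled_mean_auc, s.probe_subset))

    def test_missing_per_dataset_entries_rejected(self):
        s = ComboScore((1, 2), 0.9, 0.01, {}, n_bootstrap=5)
        with pytest.raises(ValueError, match="per_dataset"):
            filter_combos([s], 0.8, 0.8)

    def test_threshold_sweep_counts_decrease(self):
        scores = [
            _score((i, i + 1), 0.80 + 0.02 * i, {"A": 0.85}) for i in range(1, 8)
        ]
        sweep = threshold_sweep(scores, start=0.80, step=0.01, min_dataset_auc=0.0)
        assert (np.diff(sweep["n_surviving"]) <= 0).all()


class TestComboScoreInvariants:
    def test_unsorted_subset_rejected(self):
        with pytest.raises(ValueError):
            ComboScore((3, 1), 0.7, 0.0, {}, n_bootstrap=1)

    def test_out_of_range_auc_rejected(self):
        with pytest.raises(ValueError):
            ComboScore((1, 2), 1.3, 0.0, {}, n_bootstrap=1)
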