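import numpy as np
import pytest
from scipy import stats
from sklearn.model_selection import KFold

import oracles
from sfcoupling import (
    CVConfig,
    DataError,
    compare_features,
    permutation_test,
    run_cv,
    spearman_filter,
)
from sfcoupling.features import FeatureTable


class TestSpearmanFilter:
    def test_matches_scipy_and_t_approximation(self, rng):
        x = rng.standard_normal((40, 9))
        y = rng.standard_normal(40)
        sel, rho, p = spearman_filter(x, y, 0.05)
        for j in range(9):
            rho_o = oracles.spearman_rho(x[:, j], y)
            assert rho[j] == pytest.approx(rho_o, abs=1e-10)
            assert p[j] == pytest.approx(oracles.spearman_p_t_approx(rho_o, 40), abs=1e-10)
        assert set(sel) == {j for j in range(9) if p[j] < 0.05}

    def test_perfect_monotone_column_selected(self, rng):
        y = rng.standard_normal(30)
        x = np.column_stack([np.exp(y), rng.standard_normal(30)])
        sel, rho, _ = spearman_filter(x, y, 0.05)
        assert rho[0] == pytest.approx(1.0)
        assert 0 in sel

    def test_null_columns_selected_at_alpha_rate(self, rng):
        x = rng.standard_normal((95, 1000))
        y = rng.standard_normal(95)
        sel, _, _ = spearman_filter(x, y, 0.05)
        assert 0.03 <= sel.size / 1000 <= 0.07

    def test_constant_column_warned_and_never_selected(self, rng):
        x = rng.standard_normal((30, 3))
        x[:, 1] = 7.0
        y = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="constant"):
            sel, rho, p = spearman_filter(x, y, 0.9)
        assert 1 not in sel and np.isnan(rho[1]) and np.isnan(p[1])

    def test_too_few_subjects_raise(self, rng):
        with pytest.raises(DataError):
            spearman_filter(rng.standard_normal((4, 2)), rng.standard_normal(4), 0.05)


class TestRunCV:
    def test_noiseless_linear_signal_recovered(self, rng):
        n = 60
        x = rng.standard_normal((n, 6))
        y = 3.0 * x[:, 2] + 10.0
        cfg = CVConfig(n_folds=10, C=1e6, tol=1e-12, seed=0)
        res = run_cv(x, y, None, cfg)
        assert res.roi_summary.loc[2, "selected_count"] == 10
        assert res.metrics["spearman_rho"] == pytest.approx(1.0, abs=1e-6)
        assert res.metrics["mae"] < 1e-6
        assert res.most_predictive == ["ROI002"]

    def test_no_information_leaks_from_test_folds(self):
        """A feature equal to the score only on one fold's held-out subjects
        (noise elsewhere) must not be selected in that fold: the filter sees
        training data only."""
        rng = np.random.default_rng(5)
        n, n_folds = 50, 10
        y = rng.standard_normal(n)
        cfg = CVConfig(n_folds=n_folds, seed=3)
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed)
        splits = list(kf.split(np.zeros((n, 1))))
        tr0, te0 = splits[0]
        x = rng.standard_normal((n, 4))
        x[te0, 0] = y[te0]  # plant a perfect signal in the held-out block only
        # precondition: on training data the planted column is pure noise
        _, _, p = spearman_filter(x[tr0], y[tr0], 0.05)
        assert p[0] > 0.05
        res = run_cv(x, y, None, cfg)
        assert 0 not in res.per_fold[0].selected
        assert abs(res.metrics["spearman_rho"]) < 0.5

    def test_empty_selection_predicts_training_mean(self, rng):
        n = 40
        x = rng.standard_normal((n, 3))
        y = rng.standard_normal(n)
        cfg = CVConfig(n_folds=5, filter_alpha=1e-6, seed=1)
        res = run_cv(x, y, None, cfg)
        assert res.degenerate
        for fold in res.per_fold:
            expected = y[fold.train_idx].mean()
            np.testing.assert_allclose(res.oof_predictions[fold.test_idx], expected)
        assert np.all(res.roi_summary["total_weight"].to_numpy() == 0.0)

    def test_unselected_roi_has_exactly_zero_total_weight(self, rng):
        n = 80
        x = rng.standard_normal((n, 5))
        y = 2 * x[:, 0] + 0.3 * rng.standard_normal(n)
        res = run_cv(x, y, None, CVConfig(n_folds=8, seed=2))
        never = res.roi_summary["selected_count"] == 0
        assert never.any()
        assert np.all(res.roi_summary.loc[never, "total_weight"] == 0.0)

    def test_fold_assignment_depends_only_on_seed(self, rng):
        x = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        r1 = run_cv(x, y, None, CVConfig(n_folds=5, seed=9))
        r2 = run_cv(x, y, None, CVConfig(n_folds=5, seed=9))
        for f1, f2 in zip(r1.per_fold, r2.per_fold):
            np.testing.assert_array_equal(f1.test_idx, f2.test_idx)
        np.testing.assert_array_equal(r1.oof_predictions, r2.oof_predictions)
        r3 = run_cv(x, y, None, CVConfig(n_folds=5, seed=10))
        assert any(
            not np.array_equal(a.test_idx, b.test_idx)
            for a, b in zip(r1.per_fold, r3.per_fold)
        )

    def test_null_features_give_nonpositive_oof_rho_on_average(self):
        rhos, n_mp = [], 0
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            x = rng.standard_normal((50, 10))
            y = rng.standard_normal(50)
            res = run_cv(x, y, None, CVConfig(seed=seed))
            rhos.append(res.metrics["spearman_rho"])
            n_mp += len(res.most_predictive) > 0
        assert np.mean(rhos) <= 0.05
        assert n_mp <= 3  # most-predictive sets almost always empty

    def test_covariate_residualization_removes_confounded_signal(self, rng):
        n = 80
        motion = rng.standard_normal(n)
        y = motion + 0.3 * rng.standard_normal(n)
        x = np.column_stack([motion + 0.1 * rng.standard_normal(n), rng.standard_normal(n)])
        naive = run_cv(x, y, None, CVConfig(n_folds=5, covariate_mode="none", seed=0))
        adjusted = run_cv(
            x,
            y,
            motion[:, None],
            CVConfig(n_folds=5, covariate_mode="residualize_both", seed=0),
        )
        assert naive.metrics["spearman_rho"] > 0.7
        assert adjusted.roi_summary.loc[0, "selected_count"] < 5


class TestPermutation:
    def test_p_floor_and_identity(self, rng):
        n = 40
        x = rng.standard_normal((n, 2))
        y = 2 * x[:, 0]
        cfg = CVConfig(n_folds=5, n_permutations=99, seed=4)
        res = run_cv(x, y, None, cfg)
        assert res.metrics["spearman_rho"] == pytest.approx(1.0, abs=1e-9)
        perm = permutation_test(x, y, None, cfg, observed=res)
        assert perm.observed_rho == res.metrics["spearman_rho"]
        assert perm.null_rhos.shape == (99,)
        assert perm.p_value == pytest.approx(1 / 100)
        # identity permutation reproduces the observed statistic exactly
        ident = run_cv(x, y[np.arange(n)], None, cfg)
        assert ident.metrics["spearman_rho"] == res.metrics["spearman_rho"]

    def test_p_value_in_unit_interval(self, rng):
        x = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        perm = permutation_test(x, y, None, CVConfig(n_folds=5, n_permutations=19, seed=0))
        assert 0.0 < perm.p_value <= 1.0


class TestCompareFeatures:
    def _tables(self, rng, y):
        n = y.size
        signal = np.column_stack([y + 0.3 * rng.standard_normal(n), rng.standard_normal(n)])
        noise = rng.standard_normal((n, 2))
        ids = [f"s{i}" for i in range(n)]
        rois = ["ROI000", "ROI001"]
        return [
            FeatureTable("coupling", signal, ids, rois),
            FeatureTable("alff", noise, ids, rois),
        ]

    def test_signal_feature_ranks_first(self, rng):
        y = rng.standard_normal(60)
        report, results = compare_features(self._tables(rng, y), y, None, CVConfig(n_folds=5))
        assert report.iloc[0]["feature"] == "coupling"
        assert report.iloc[0]["spearman_rho"] > report.iloc[1]["spearman_rho"]
        assert set(results) == {"coupling", "alff"}

    def test_single_feature_gives_single_row(self, rng):
        y = rng.standard_normal(60)
        report, _ = compare_features(self._tables(rng, y)[:1], y, None, CVConfig(n_folds=5))
        assert len(report) == 1
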