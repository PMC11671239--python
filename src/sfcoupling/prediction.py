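"""Feature-filtered cross-validated support vector regression.

The behavioral score is predicted from one subjects x ROIs feature table
with K-fold cross-validation.  Inside each training fold, and only there:
features are optionally residualized on covariates, filtered by Spearman
correlation with the score at an uncorrected alpha, standardized, and fed
to an L2-regularized L2-loss (squared-epsilon-insensitive) linear SVR.  The
held-out fold is scored with the training fold's parameters, so no
information leaks from test to train.  Model significance comes from a
permutation test that reshuffles the score and reruns the whole pipeline.

ROI-level summaries follow the weight-aggregation convention: each ROI's
total weight is the sum of its signed SVR weights over the folds where the
filter selected it (zero elsewhere), and ROIs selected in every fold are
the "most predictive" set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.svm import LinearSVR

from .errors import ConfigError, DataError
from .features import FeatureTable

__all__ = [
    "CVConfig",
    "PredictionResult",
    "PermutationResult",
    "spearman_filter",
    "run_cv",
    "permutation_test",
    "compare_features",
]


@dataclass
class CVConfig:
    """Cross-validation, filtering and SVR settings.

    The SVR is liblinear-style: squared-epsilon-insensitive loss with L2
    regularization, C=1 and epsilon=0 by default.  ``covariate_mode``
    controls how covariates are handled: ``residualize_features`` regresses
    each feature column on the covariates within the training fold and
    applies those coefficients to the test fold; ``residualize_both`` also
    residualizes the score; ``none`` ignores covariates.
    """

    n_folds: int = 10
    filter_alpha: float = 0.05
    n_permutations: int = 5000
    C: float = 1.0
    epsilon: float = 0.0
    tol: float = 1e-4
    covariate_mode: Literal["residualize_features", "residualize_both", "none"] = (
        "residualize_features"
    )
    standardize: bool = True
    seed: int = 0

    def validate(self, n_subjects: int | None = None) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if n_subjects is not None and self.n_folds > n_subjects:
            raise ConfigError("n_folds cannot exceed the number of subjects")
        if not (0.0 < self.filter_alpha < 1.0):
            raise ConfigError("filter_alpha must be in (0, 1)")
        if self.C <= 0 or self.epsilon < 0:
            raise ConfigError("need C > 0 and epsilon >= 0")
        if self.covariate_mode not in ("residualize_features", "residualize_both", "none"):
            raise ConfigError(f"unknown covariate_mode {self.covariate_mode!r}")


@dataclass
class FoldResult:
    train_idx: np.ndarray
    test_idx: np.ndarray
    selected: np.ndarray  # ROI indices passing the filter
    weights: np.ndarray  # signed SVR weights, aligned with `selected`
    intercept: float
    filter_rho: np.ndarray  # per-ROI filter correlation on this training fold


@dataclass
class PredictionResult:
    per_fold: list[FoldResult]
    oof_predictions: np.ndarray
    actual: np.ndarray
    metrics: dict
    roi_summary: pd.DataFrame
    most_predictive: list[str]
    degenerate: bool = False


@dataclass
class PermutationResult:
    observed_rho: float
    null_rhos: np.ndarray
    p_value: float


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0)


def spearman_filter(
    train_features: np.ndarray,
    train_scores: np.ndarray,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Select ROIs whose Spearman correlation with the score has p < alpha.

    P-values use the two-sided t approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on n-2 degrees of freedom.
    Constant feature columns (rho undefined) are excluded with a warning and
    never selected; their rho and p are NaN.

    Returns ``(selected_indices, rho, p)``.
    """
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_scores, dtype=float)
    n = x.shape[0]
    if n < 5:
        raise DataError("need at least 5 training subjects for the filter")
    if np.isnan(x).any():
        raise DataError("feature matrix contains NaN columns; drop them first")
    const = np.ptp(x, axis=0) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature column(s) excluded from the filter",
            stacklevel=2,
        )
    rx = _rank(x)
    ry = _rank(y)
    rx = rx - rx.mean(axis=0, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx * ry[:, None]).sum(axis=0) / denom
    rho = np.where(const, np.nan, np.clip(rho, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p = np.where(np.isnan(rho), np.nan, p)
    selected = np.flatnonzero(~np.isnan(p) & (p < alpha))
    return selected, rho, p


def _residualize_design(covariates: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(covariates.shape[0]), covariates])


def _fit_svr(x: np.ndarray, y: np.ndarray, config: CVConfig) -> LinearSVR:
    model = LinearSVR(
        loss="squared_epsilon_insensitive",
        dual=False,
        C=config.C,
        epsilon=config.epsilon,
        tol=config.tol,
        fit_intercept=True,
        max_iter=10000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # liblinear convergence chatter
        model.fit(x, y)
    return model


def run_cv(
    feature: FeatureTable | np.ndarray,
    scores: np.ndarray,
    covariates: np.ndarray | None = None,
    config: CVConfig | None = None,
) -> PredictionResult:
    """Cross-validated prediction of the score from one feature table.

    Every data-dependent step (covariate residualization, Spearman filter,
    standardization, SVR fit) uses training-fold data only.  Held-out folds
    with zero selected features receive the training-score mean as
    prediction so each subject stays out-of-fold exactly once; a run where
    every fold is empty is returned with ``degenerate=True``.

    Metrics are computed on the pooled out-of-fold predictions: Spearman
    rho (the headline statistic), Pearson r, MAE and MSE.
    """
    config = config or CVConfig()
    if isinstance(feature, FeatureTable):
        values = feature.values
        roi_labels = list(feature.roi_labels)
    else:
        values = np.asarray(feature, dtype=float)
        roi_labels = [f"ROI{i:03d}" for i in range(values.shape[1])]
    y = np.asarray(scores, dtype=float)
    n, n_rois = values.shape
    if y.shape != (n,):
        raise DataError("scores length must match the feature table")
    config.validate(n_subjects=n)
    if np.isnan(values).any():
        raise DataError("feature table contains NaN; apply drop_undefined_rois first")
    cov = None
    if covariates is not None and config.covariate_mode != "none":
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise DataError("covariate rows must match subjects")

    kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    oof = np.full(n, np.nan)
    folds: list[FoldResult] = []
    filter_rhos = np.full((config.n_folds, n_rois), np.nan)
    any_selected = False
    for k, (tr, te) in enumerate(kf.split(values)):
        x_tr, x_te = values[tr].copy(), values[te].copy()
        y_tr = y[tr].copy()
        if cov is not None:
            d_tr = _residualize_design(cov[tr])
            d_te = _residualize_design(cov[te])
            beta, *_ = np.linalg.lstsq(d_tr, x_tr, rcond=None)
            x_tr = x_tr - d_tr @ beta
            x_te = x_te - d_te @ beta
            if config.covariate_mode == "residualize_both":
                beta_y, *_ = np.linalg.lstsq(d_tr, y_tr, rcond=None)
                y_tr = y_tr - d_tr @ beta_y
                # test-fold scores for metrics are residualized with the
                # training-fold coefficients as well (leakage-free)
                oof_target_shift = d_te @ beta_y
            else:
                oof_target_shift = None
        else:
            oof_target_shift = None

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            selected, rho, _p = spearman_filter(x_tr, y_tr, config.filter_alpha)
        filter_rhos[k] = rho
        if selected.size == 0:
            pred = np.full(te.size, y_tr.mean())
            weights = np.zeros(0)
            intercept = float(y_tr.mean())
        else:
            any_selected = True
            xs_tr = x_tr[:, selected]
            xs_te = x_te[:, selected]
            if config.standardize:
                mu = xs_tr.mean(axis=0)
                sd = xs_tr.std(axis=0, ddof=0)
                sd[sd == 0] = 1.0
                xs_tr = (xs_tr - mu) / sd
                xs_te = (xs_te - mu) / sd
            model = _fit_svr(xs_tr, y_tr, config)
            pred = model.predict(xs_te)
            weights = model.coef_.copy()
            intercept = float(np.ravel(model.intercept_)[0])
        if oof_target_shift is not None:
            pred = pred + oof_target_shift
        oof[te] = pred
        folds.append(
            FoldResult(
                train_idx=tr,
                test_idx=te,
                selected=selected,
                weights=weights,
                intercept=intercept,
                filter_rho=rho,
            )
        )

    assert not np.isnan(oof).any(), "every subject must be predicted exactly once"
    rho_s = stats.spearmanr(y, oof).statistic if np.ptp(oof) > 0 else 0.0
    pearson = stats.pearsonr(y, oof).statistic if np.ptp(oof) > 0 else 0.0
    metrics = {
        "spearman_rho": float(rho_s),
        "pearson_r": float(pearson),
        "mae": float(np.mean(np.abs(y - oof))),
        "mse": float(np.mean((y - oof) ** 2)),
    }

    selected_count = np.zeros(n_rois, dtype=int)
    total_weight = np.zeros(n_rois)
    for f in folds:
        selected_count[f.selected] += 1
        total_weight[f.selected] += f.weights
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_rho = np.nanmean(filter_rhos, axis=0)
        sd_rho = np.nanstd(filter_rhos, axis=0, ddof=1)
    roi_summary = pd.DataFrame(
        {
            "roi": roi_labels,
            "selected_count": selected_count,
            "total_weight": total_weight,
            "mean_filter_rho": mean_rho,
            "sd_filter_rho": sd_rho,
        }
    )
    most_predictive = [
        roi_labels[i] for i in np.flatnonzero(selected_count == config.n_folds)
    ]
    return PredictionResult(
        per_fold=folds,
        oof_predictions=oof,
        actual=y.copy(),
        metrics=metrics,
        roi_summary=roi_summary,
        most_predictive=most_predictive,
        degenerate=not any_selected,
    )


def permutation_test(
    feature: FeatureTable | np.ndarray,
    scores: np.ndarray,
    covariates: np.ndarray | None = None,
    config: CVConfig | None = None,
    observed: PredictionResult | None = None,
) -> PermutationResult:
    """Permutation null for the out-of-fold Spearman rho.

    Each permutation reshuffles the scores across subjects (covariates stay
    put) and reruns the full cross-validation pipeline, filter included, so
    the null honors every data-dependent step.  The one-sided p-value uses
    the add-one convention ``p = (1 + #{null >= observed}) / (1 + B)`` and
    can therefore never be zero.
    """
    config = config or CVConfig()
    if observed is None:
        observed = run_cv(feature, scores, covariates, config)
    obs_rho = observed.metrics["spearman_rho"]
    rng = np.random.default_rng(config.seed + 1)
    y = np.asarray(scores, dtype=float)
    nulls = np.empty(config.n_permutations)
    for b in range(config.n_permutations):
        perm = rng.permutation(y.shape[0])
        res = run_cv(feature, y[perm], covariates, config)
        nulls[b] = res.metrics["spearman_rho"]
    p = (1.0 + np.sum(nulls >= obs_rho)) / (1.0 + config.n_permutations)
    return PermutationResult(observed_rho=float(obs_rho), null_rhos=nulls, p_value=float(p))


def compare_features(
    tables: Sequence[FeatureTable],
    scores: np.ndarray,
    covariates: np.ndarray | None = None,
    config: CVConfig | None = None,
    with_permutation: bool = False,
) -> tuple[pd.DataFrame, dict[str, PredictionResult]]:
    """Run the prediction pipeline per feature and rank by out-of-fold rho.

    Returns a report DataFrame (one row per feature: rho, Pearson r, MAE,
    MSE, number of most-predictive ROIs, optional permutation p) and the
    per-feature :class:`PredictionResult` objects.
    """
    config = config or CVConfig()
    rows = []
    results: dict[str, PredictionResult] = {}
    for table in tables:
        res = run_cv(table, scores, covariates, config)
        results[table.name] = res
        row = {
            "feature": table.name,
            **res.metrics,
            "n_most_predictive": len(res.most_predictive),
            "degenerate": res.degenerate,
        }
        if with_permutation:
            perm = permutation_test(table, scores, covariates, config, observed=res)
            row["permutation_p"] = perm.p_value
        rows.append(row)
    report = pd.DataFrame(rows).sort_values("spearman_rho", ascending=False)
    return report.reset_index(drop=True), results
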