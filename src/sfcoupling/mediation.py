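"""Simple (single-mediator) mediation with bootstrap confidence intervals.

The model is the classic three-regression decomposition: with independent
variable X, mediator M, outcome Y and optional covariates Z,

    M = a X + Z g1 + e1        (path a)
    Y = c' X + b M + Z g2 + e2 (paths b and c')
    Y = c X + Z g3 + e3        (total effect c)

all fitted by OLS, so ``c = c' + a*b`` holds exactly on a given sample.
The indirect effect is ``a*b``; its partially standardized form divides by
the sample SD of Y, making it scale-free in the outcome.  Uncertainty is
quantified with a percentile bootstrap over subjects.  "Full mediation" is
reported as a label when the indirect-effect CI excludes zero while the
direct path c' is not significant at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

__all__ = ["MediationResult", "mediate", "specificity_correlations"]


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ps_indirect: float
    ci_level: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    full_mediation: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and two-sided p-values (t-tests)."""
    n, k = x.shape
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = n - k
    if dof <= 0:
        raise DataError("not enough observations for OLS")
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.pinv(x.T @ x)
    se = np.sqrt(np.clip(sigma2 * np.diagonal(xtx_inv), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    return beta, p


def _paths(x, m, y, z):
    """(a, b, c, c_prime) plus p-values, given raw vectors and covariates."""
    n = x.shape[0]
    ones = np.ones(n)
    dz = [z] if z is not None else []
    d_a = np.column_stack([ones, x, *dz])
    d_b = np.column_stack([ones, x, m, *dz])
    beta_a, p_a = _ols(d_a, m)
    beta_b, p_b = _ols(d_b, y)
    beta_c, p_c = _ols(d_a, y)
    a, b = beta_a[1], beta_b[2]
    c, c_prime = beta_c[1], beta_b[1]
    return (a, b, c, c_prime), (p_a[1], p_b[2], p_c[1], p_b[1])


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 5000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> MediationResult:
    """Fit the mediation model and bootstrap the partially standardized
    indirect effect.

    Bootstrap resamples subjects with replacement, refits all paths, and
    takes a percentile interval of ``a*b / SD(Y)`` at ``ci_level``.
    Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if not (m.shape[0] == n and y.shape[0] == n):
        raise DataError("x, m, y must have equal length")
    if n < 10:
        raise DataError("mediation needs at least 10 subjects")
    for name, v in (("x", x), ("m", m), ("y", y)):
        if not np.all(np.isfinite(v)):
            raise DataError(f"{name} contains non-finite values")
    if y.std(ddof=1) == 0:
        raise DataError("outcome y has zero variance")
    r_xm = np.corrcoef(x, m)[0, 1]
    if abs(r_xm) > 0.999:
        raise DataError(f"x and m are collinear (|r| = {abs(r_xm):.4f} > 0.999)")
    if not (0.0 < ci_level < 1.0):
        raise ConfigError("ci_level must be in (0, 1)")
    z = None
    if covariates is not None:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != n:
            raise DataError("covariate rows must match subjects")

    (a, b, c, c_prime), (p_a, p_b, p_c, p_cp) = _paths(x, m, y, z)
    indirect = a * b
    sd_y = y.std(ddof=1)
    ps_indirect = indirect / sd_y

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    ones = np.ones(n)
    base_a = np.column_stack([ones, x] + ([z] if z is not None else []))
    base_b = np.column_stack([ones, x, m] + ([z] if z is not None else []))
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        sd_b = yb.std(ddof=1)
        if sd_b == 0:
            boot[i] = np.nan
            continue
        # only paths a and b are needed for the indirect effect
        d_a, d_b = base_a[idx], base_b[idx]
        beta_a, *_ = np.linalg.lstsq(d_a, m[idx], rcond=None)
        beta_b, *_ = np.linalg.lstsq(d_b, yb, rcond=None)
        boot[i] = beta_a[1] * beta_b[2] / sd_b
    boot = boot[np.isfinite(boot)]
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    ci_excludes_zero = (lo > 0) or (hi < 0)
    return MediationResult(
        a=float(a),
        b=float(b),
        c=float(c),
        c_prime=float(c_prime),
        indirect=float(indirect),
        ps_indirect=float(ps_indirect),
        ci_level=ci_level,
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_boot=n_boot,
        p_a=float(p_a),
        p_b=float(p_b),
        p_c=float(p_c),
        p_c_prime=float(p_cp),
        full_mediation=bool(ci_excludes_zero and p_cp >= 0.05),
    )


def specificity_correlations(
    feature_columns: pd.DataFrame,
    irrelevant_variables: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman rho and p between every feature column and every check variable.

    Used to verify that a feature's association is specific to the behavior
    of interest: variables like IQ or hearing threshold should show no
    systematic correlation.  Returns one row per (feature, variable) pair.
    """
    rows = []
    for feat in feature_columns.columns:
        for var in irrelevant_variables.columns:
            res = stats.spearmanr(
                feature_columns[feat].to_numpy(dtype=float),
                irrelevant_variables[var].to_numpy(dtype=float),
            )
            rows.append(
                {
                    "feature": feat,
                    "variable": var,
                    "rho": float(res.statistic),
                    "p": float(res.pvalue),
                }
            )
    return pd.DataFrame(rows)
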