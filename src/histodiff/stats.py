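"""Group tests, fold changes and covariate-conditioned false-discovery control.

Differential calls follow the FDR-regression approach: rather than a single
global null proportion, the proportion of true nulls pi0 is allowed to depend
on a per-hypothesis covariate (here, the modification type as a Unimod
accession).  For each threshold lambda on a grid, the indicator 1(p > lambda)
is regressed on the covariate design; the fitted probability divided by
(1 - lambda) estimates pi0(x; lambda); a cubic smoothing spline over lambda,
evaluated at the largest lambda, gives the per-test pi0_hat, clipped to
[0, 1].  Conditioned q-values are then pi0_hat times the Benjamini-Hochberg
adjusted p-values, monotonized in the order of increasing p and capped at 1.
With pi0_hat fixed at 1 this reduces exactly to plain BH.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import UnivariateSpline
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "welch_t_test",
    "student_t_test",
    "fold_change",
    "estimate_pi0_regression",
    "conditioned_q_values",
    "volcano_class",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))

VAR_FLOOR = 1e-12


def welch_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided unequal-variance t-test on two groups of M-values.

    Degrees of freedom follow Welch-Satterthwaite.  A variance floor of 1e-12
    per group guards the degenerate zero-variance case: two constant groups
    with equal means give p = 1; with different means, a finite, very small p.

    Requires >= 2 values per group (raises ValueError otherwise; the caller
    treats that as an untestable hypothesis, not a failure).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need >= 2 values per group, got {a.size} and {b.size}")
    va = max(a.var(ddof=1), VAR_FLOOR)
    vb = max(b.var(ddof=1), VAR_FLOOR)
    sa, sb = va / a.size, vb / b.size
    se = np.sqrt(sa + sb)
    t = (a.mean() - b.mean()) / se
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def student_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided pooled-variance t-test (config alternative to Welch)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need >= 2 values per group, got {a.size} and {b.size}")
    df = a.size + b.size - 2
    sp2 = max(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df, VAR_FLOOR)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def fold_change(mean_ra_a: float, mean_ra_b: float, *, eps_ra: float = 0.01) -> float:
    """log2 ratio of mean relative abundances (percent scale), A over B.

    Means are clamped below at ``eps_ra`` percent so zero-occupancy groups
    yield a large but finite fold change.
    """
    a = max(float(mean_ra_a), eps_ra)
    b = max(float(mean_ra_b), eps_ra)
    return float(np.log2(a / b))


def _one_hot(covariates: Sequence, min_level_size: int = 2) -> tuple[np.ndarray, list]:
    """Intercept + one-hot design; levels with < min_level_size tests merge
    into the reference class (logged)."""
    cov = pd.Series(list(covariates), dtype="object").astype(str)
    counts = cov.value_counts()
    rare = set(counts[counts < min_level_size].index)
    if rare:
        logger.info("pi0 regression: merging rare covariate level(s) %s into reference",
                    sorted(rare))
        cov = cov.mask(cov.isin(rare), "_reference")
    levels = sorted(cov.unique())
    ref = levels[0]
    X = np.column_stack(
        [np.ones(len(cov))] + [(cov == lev).to_numpy(float) for lev in levels if lev != ref]
    )
    return X, list(cov)


def _fit_indicator(y: np.ndarray, X: np.ndarray, link: str) -> np.ndarray:
    """Fitted P(p > lambda | x); falls back to intercept-only on separation
    or non-convergence."""
    ybar = y.mean()
    if ybar in (0.0, 1.0) or X.shape[1] == 1:
        return np.full(len(y), ybar)
    try:
        if link == "logistic":
            import warnings

            from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
            if not np.all(np.isfinite(res.params)):
                raise ValueError("non-finite coefficients")
            fitted = np.asarray(res.fittedvalues)
        elif link == "linear":
            res = sm.OLS(y, X).fit()
            fitted = np.asarray(res.fittedvalues)
        else:
            raise ValueError(f"unknown link {link!r}")
    except (np.linalg.LinAlgError, ValueError, Warning) as exc:
        logger.info("pi0 regression: fall back to intercept-only fit (%s)", exc)
        fitted = np.full(len(y), ybar)
    return np.clip(fitted, 0.0, 1.0)


def estimate_pi0_regression(
    p_values: Sequence[float],
    covariates: Sequence | None = None,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    *,
    link: str = "logistic",
) -> np.ndarray:
    """Per-test covariate-conditioned estimate of the null proportion pi0(x).

    Parameters
    ----------
    p_values : array of p in (0, 1].
    covariates : categorical labels (e.g. Unimod accessions), or None for an
        intercept-only (global) estimate.
    lambda_grid : strictly increasing thresholds within (0, 1).
    link : "logistic" (default) or "linear" for a linear-probability fit.

    Returns per-test pi0_hat in [0, 1].  With a single lambda the spline
    smoothing step is skipped.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    grid = np.asarray(lambda_grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid >= 1) or np.any(np.diff(grid) <= 0):
        raise ValueError("lambda_grid must be strictly increasing within (0, 1)")

    if covariates is None:
        X, cov = np.ones((p.size, 1)), ["_all"] * p.size
    else:
        if len(covariates) != p.size:
            raise ValueError("covariates length must match p_values")
        X, cov = _one_hot(covariates)

    # pi0(x; lambda) per lambda; identical within a covariate level, so smooth
    # per level rather than per test
    pi0_by_lambda = np.empty((grid.size, p.size))
    for j, lam in enumerate(grid):
        fitted = _fit_indicator((p > lam).astype(float), X, link)
        pi0_by_lambda[j] = fitted / (1.0 - lam)

    if grid.size == 1:
        pi0 = pi0_by_lambda[0]
    elif grid.size < 4:
        # too few knots for a cubic spline: take the largest-lambda estimate
        pi0 = pi0_by_lambda[-1]
    else:
        # inverse-sd weights: sd(pi0(lambda)) ~ sqrt(lambda / (n (1 - lambda)))
        # for a binomial indicator mean, so the noisy right end of the grid is
        # down-weighted rather than allowed to tilt the fit
        w = np.sqrt((1.0 - grid) / grid)
        w = w / w.mean()
        pi0 = np.empty(p.size)
        cov_arr = np.asarray(cov, dtype=object)
        for lev in pd.unique(cov_arr):
            idx = np.nonzero(cov_arr == lev)[0]
            curve = pi0_by_lambda[:, idx[0]]
            spline = UnivariateSpline(grid, curve, w=w, k=3, s=float(grid.size))
            pi0[idx] = spline(grid[-1])
    return np.clip(pi0, 0.0, 1.0)


def conditioned_q_values(p_values: Sequence[float], pi0_hat: Sequence[float] | float) -> np.ndarray:
    """q_i = pi0_hat_i * BH-adjusted p_i, monotone in p and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    pi0 = np.broadcast_to(np.asarray(pi0_hat, dtype=float), p.shape).copy()
    if p.size == 0:
        return p
    if pi0.shape != p.shape:
        raise ValueError("pi0_hat length must match p_values")
    bh = multipletests(p, method="fdr_bh")[1]
    q = pi0 * bh
    order = np.argsort(p, kind="stable")
    q[order] = np.maximum.accumulate(q[order])
    return np.minimum(q, 1.0)


def volcano_class(q: float, log2_fc: float, *, q_threshold: float = 0.1,
                  fc_threshold: float = 1.0) -> str:
    """Volcano-plot class: red = q- and fold-change-significant, blue = q only,
    green = fold change only, gray = neither."""
    q_sig = q < q_threshold
    fc_sig = abs(log2_fc) > fc_threshold
    if q_sig and fc_sig:
        return "red"
    if q_sig:
        return "blue"
    if fc_sig:
        return "green"
    return "gray"
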