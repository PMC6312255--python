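"""Per-feature QC and transformation: Dixon outlier screening, Shapiro-Wilk
normality, and Box-Cox transformation to approximate Gaussianity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .io import ValidationError

__all__ = [
    "dixon_ratio",
    "dixon_critical_value",
    "dixon_outlier_test",
    "shapiro_normality",
    "boxcox_loglik",
    "boxcox_mle",
    "TransformResult",
]

_DIXON_ALPHAS = (0.01, 0.05, 0.10)


def _dixon_variant(n: int) -> str:
    """Ratio variant by sample size, the conventional staircase: r10 for
    n<=7, r11 for 8-10, r21 for 11-13, r22 for n>=14."""
    if n <= 7:
        return "r10"
    if n <= 10:
        return "r11"
    if n <= 13:
        return "r21"
    return "r22"


def _dixon_ratios_sorted(x: np.ndarray, variant: str) -> tuple[float, float]:
    """Two-sided Dixon ratios (low end, high end) for sorted data.

    The second index of the variant name widens the denominator away from
    the opposite extreme; the first widens the numerator gap.
    """
    n = len(x)
    j, k = int(variant[1]), int(variant[2])
    denom_lo = x[n - 1 - k] - x[0]
    denom_hi = x[n - 1] - x[k]
    r_lo = (x[1 + j - 1] - x[0]) / denom_lo if denom_lo > 0 else 0.0
    r_hi = (x[n - 1] - x[n - 1 - j]) / denom_hi if denom_hi > 0 else 0.0
    return r_lo, r_hi


def dixon_ratio(values: np.ndarray) -> float:
    """Two-sided Dixon statistic: the larger of the low- and high-end ratios,
    using the size-dependent ratio variant."""
    x = np.sort(np.asarray(values, float))
    return max(_dixon_ratios_sorted(x, _dixon_variant(len(x))))


@lru_cache(maxsize=None)
def dixon_critical_value(n: int, alpha: float, n_rep: int = 1_000_000) -> float:
    """Monte-Carlo critical value of the two-sided Dixon statistic.

    The null distribution of max(low ratio, high ratio) under i.i.d.
    Gaussian sampling is simulated once per (n, alpha) and cached. The
    simulation seed is a fixed function of n so results are reproducible
    across processes.
    """
    if not 3 <= n <= 30:
        raise ValidationError(f"Dixon test defined for 3 <= n <= 30, got n={n}")
    if alpha not in _DIXON_ALPHAS:
        raise ValidationError(f"alpha must be one of {_DIXON_ALPHAS}")
    rng = np.random.default_rng(123456789 + n)
    variant = _dixon_variant(n)
    j, k = int(variant[1]), int(variant[2])
    x = np.sort(rng.standard_normal((n_rep, n)), axis=1)
    denom_lo = x[:, n - 1 - k] - x[:, 0]
    denom_hi = x[:, n - 1] - x[:, k]
    r_lo = (x[:, j] - x[:, 0]) / denom_lo
    r_hi = (x[:, n - 1] - x[:, n - 1 - j]) / denom_hi
    stat = np.maximum(r_lo, r_hi)
    return float(np.quantile(stat, 1.0 - alpha))


def dixon_outlier_test(values, alpha: float = 0.05) -> np.ndarray:
    """Flag at most one extreme value per call by Dixon's ratio criterion.

    Returns a boolean mask over ``values`` (True = flagged). The flagged
    point, if any, is the extreme (smallest or largest) whose gap ratio
    exceeds the Monte-Carlo critical value at ``alpha``. A zero-range
    vector has no outliers by definition.
    """
    x = np.asarray(values, float)
    if x.ndim != 1 or len(x) < 3:
        raise ValidationError("Dixon test needs a 1-d vector with n >= 3")
    if not np.all(np.isfinite(x)):
        raise ValidationError("Dixon test requires finite values")
    flags = np.zeros(len(x), bool)
    if np.ptp(x) == 0:
        return flags
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    variant = _dixon_variant(len(x))
    r_lo, r_hi = _dixon_ratios_sorted(xs, variant)
    crit = dixon_critical_value(len(x), alpha)
    if max(r_lo, r_hi) > crit:
        idx = order[0] if r_lo >= r_hi else order[-1]
        flags[idx] = True
    return flags


def shapiro_normality(values) -> float:
    """Shapiro-Wilk p-value for the hypothesis that the sample is Gaussian."""
    x = np.asarray(values, float)
    if not 3 <= len(x) <= 5000:
        raise ValidationError("Shapiro-Wilk defined for 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValidationError("Shapiro-Wilk undefined for a constant sample")
    return float(stats.shapiro(x).pvalue)


@dataclass(frozen=True)
class TransformResult:
    """Outcome of a Box-Cox fit: the MLE lambda, the positivity shift that
    was applied before transforming, and the transformed values."""

    lambda_hat: float
    shift: float
    transformed_values: np.ndarray


def boxcox_loglik(lmbdas: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Profile log-likelihood of the Box-Cox model, vectorized over lambda.

    llf(lmbda) = (lmbda - 1) * sum(log y) - n/2 * log(sigma2_hat(lmbda))
    """
    y = np.asarray(y, float)
    lmbdas = np.atleast_1d(np.asarray(lmbdas, float))
    n = len(y)
    logy = np.log(y)
    with np.errstate(over="ignore"):
        z = np.where(
            np.abs(lmbdas[:, None]) > 1e-12,
            (np.power(y[None, :], lmbdas[:, None]) - 1.0) / np.where(
                np.abs(lmbdas[:, None]) > 1e-12, lmbdas[:, None], 1.0
            ),
            logy[None, :],
        )
    var = z.var(axis=1)
    return (lmbdas - 1.0) * logy.sum() - 0.5 * n * np.log(var)


def _boxcox_apply(y: np.ndarray, lmbda: float) -> np.ndarray:
    if abs(lmbda) > 1e-12:
        return (np.power(y, lmbda) - 1.0) / lmbda
    return np.log(y)


def boxcox_mle(values, grid: tuple[float, float, float] = (-3.0, 3.0, 0.01)) -> TransformResult:
    """Box-Cox transform with lambda chosen by profile maximum likelihood.

    Non-positive inputs are first shifted by ``1 - min(y)`` (the minimal
    shift restoring positivity, recorded in the result). Lambda is located
    on a dense grid over [-3, 3] and refined by bounded golden-section
    search around the best grid point.
    """
    y = np.asarray(values, float)
    if y.ndim != 1 or len(y) < 3:
        raise ValidationError("Box-Cox needs a 1-d vector with n >= 3")
    if not np.all(np.isfinite(y)):
        raise ValidationError("Box-Cox requires finite values")
    if np.ptp(y) == 0:
        raise ValidationError("Box-Cox undefined for a constant sample")
    shift = 0.0
    if y.min() <= 0:
        shift = 1.0 - y.min()
        y = y + shift
    lo, hi, step = grid
    lmbdas = np.arange(lo, hi + step / 2, step)
    llf = boxcox_loglik(lmbdas, y)
    best = int(np.argmax(llf))
    a = lmbdas[max(best - 1, 0)]
    b = lmbdas[min(best + 1, len(lmbdas) - 1)]
    res = optimize.minimize_scalar(
        lambda l: -boxcox_loglik(np.array([l]), y)[0],
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(res.x) if -res.fun >= llf[best] else float(lmbdas[best])
    return TransformResult(lam, shift, _boxcox_apply(y, lam))
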