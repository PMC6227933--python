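"""Paired-posterior probability-of-change statistics and trend regressions.

The central statistic: given posterior draws of the same quantity in two
periods, the probability that the quantity is higher in period B than in
period A is the fraction of index-wise paired draws where b > a, with ties
counted half. The tie rule makes the statistic exactly antisymmetric
(P(b>a) + P(a>b) = 1) and coincides with the strict count whenever the
draws are continuous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "DirectionalProbability",
    "TrendFit",
    "probability_greater",
    "linear_trend",
    "logit",
    "inverse_logit",
]

#: Proportions of exactly 0 or 1 are clamped this far inside (0, 1)
#: before the logit transform.
_LOGIT_EPS = 1e-4


@dataclass(frozen=True)
class DirectionalProbability:
    quantity: str
    direction: str  # "greater" | "less"
    probability: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.direction not in ("greater", "less"):
            raise ValueError("direction must be 'greater' or 'less'")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


def probability_greater(
    draws_b: np.ndarray,
    draws_a: np.ndarray,
    quantity: str = "",
    seed: int = 0,
) -> DirectionalProbability:
    """P(quantity higher under B than A) from paired posterior draws.

    Draws are paired index-wise; if lengths differ the longer vector is
    subsampled without replacement (seeded) down to the shorter. Ties count
    one half.
    """
    b = np.asarray(draws_b, dtype=float).ravel()
    a = np.asarray(draws_a, dtype=float).ravel()
    if b.size == 0 or a.size == 0:
        raise RuntimeError("posterior draw vectors must be non-empty")
    rng = np.random.default_rng(seed)
    if b.size > a.size:
        b = b[np.sort(rng.choice(b.size, size=a.size, replace=False))]
    elif a.size > b.size:
        a = a[np.sort(rng.choice(a.size, size=b.size, replace=False))]
    n = b.size
    p = (np.count_nonzero(b > a) + 0.5 * np.count_nonzero(b == a)) / n
    return DirectionalProbability(
        quantity=quantity, direction="greater", probability=float(p), n_pairs=int(n)
    )


@dataclass(frozen=True)
class TrendFit:
    """Ordinary least-squares fit of a yearly series."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_years: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_years < 3:
            raise ValueError("need at least 3 years")


def linear_trend(years: np.ndarray, values: np.ndarray) -> TrendFit:
    """OLS slope/intercept with the standard t-based slope p-value."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.shape != values.shape or years.ndim != 1:
        raise ValueError("years and values must be equal-length 1-D arrays")
    if len(years) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(years) == 0:
        raise ValueError("years are constant: singular design")
    fit = stats.linregress(years, values)
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_years=len(years),
    )


def logit(p: float | np.ndarray) -> float | np.ndarray:
    """log(p / (1 - p)); exact 0 or 1 is clamped to within 1e-4 (warned)."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("proportions must lie in [0, 1]")
    if np.any(arr == 0) or np.any(arr == 1):
        warnings.warn(
            f"proportion of exactly 0 or 1 clamped to within {_LOGIT_EPS}",
            stacklevel=2,
        )
        arr = np.clip(arr, _LOGIT_EPS, 1.0 - _LOGIT_EPS)
    out = special.logit(arr)
    return float(out) if np.isscalar(p) or out.ndim == 0 else out


def inverse_logit(x: float | np.ndarray) -> float | np.ndarray:
    """Exact inverse of :func:`logit` on (0, 1)."""
    out = special.expit(np.asarray(x, dtype=float))
    return float(out) if np.isscalar(x) or out.ndim == 0 else out
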