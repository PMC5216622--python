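"""Weighted and unweighted summary statistics and Welch two-sample tests.

The community-level analyses weight each cyst observation by its species'
relative abundance in the assemblage, so every statistic here comes in a
weighted form. Conventions:

* weighted mean      x̄_w = Σ(w·x) / Σw  (invariant to rescaling of w);
* weighted SD        sqrt( [Σw(x − x̄_w)² / Σw] · n/(n − 1) ), where n is
  the *effective observation count* ``n_obs`` (the small-sample correction
  makes the uniform-weight case coincide with the ordinary sample SD);
* weighted SE        SD_w / sqrt(n_obs).

``n_obs`` is the number of measured cysts at the observation level and
the number of species at the interspecific (species-turnover) level,
where each "observation" is a species mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateWeightsError,
    InsufficientDataError,
    UndefinedStatisticError,
)

__all__ = [
    "WeightedSample",
    "TestResult",
    "weighted_mean",
    "weighted_sd",
    "weighted_se",
    "welch_t_test",
    "welch_t_test_from_summary",
    "weighted_welch_t_test",
]


@dataclass(frozen=True)
class WeightedSample:
    """Values with non-negative weights and an effective observation count.

    ``n_obs`` equals ``len(values)`` for observation-level samples; for
    species-level samples (values are species means) it equals the number
    of species.
    """

    values: tuple[float, ...]
    weights: tuple[float, ...]
    n_obs: int

    def __init__(self, values: Sequence[float], weights: Sequence[float], n_obs: int | None = None):
        values = tuple(float(v) for v in values)
        weights = tuple(float(w) for w in weights)
        if len(values) != len(weights):
            raise ValueError("values and weights must have equal length")
        if len(values) == 0:
            raise ValueError("sample must be non-empty")
        if any(w < 0 for w in weights):
            raise ValueError("weights must be non-negative")
        if not any(w > 0 for w in weights):
            raise DegenerateWeightsError("all weights are zero")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "n_obs", len(values) if n_obs is None else int(n_obs))
        if self.n_obs < 1:
            raise ValueError("n_obs must be positive")

    @classmethod
    def uniform(cls, values: Sequence[float]) -> "WeightedSample":
        """Equal-weight sample; weighted statistics then reduce to the
        ordinary unweighted ones."""
        values = list(values)
        return cls(values, [1.0] * len(values))


@dataclass(frozen=True)
class TestResult:
    """Two-sided two-sample test result; mean_difference is b − a (μm)."""

    t_statistic: float
    df: float
    p_value: float
    mean_difference: float


def weighted_mean(sample: WeightedSample) -> float:
    """Abundance-weighted mean, Σ(w·x)/Σw."""
    w = np.asarray(sample.weights)
    x = np.asarray(sample.values)
    total = w.sum()
    if total <= 0:
        raise DegenerateWeightsError("weights sum to zero")
    return float((w * x).sum() / total)


def weighted_sd(sample: WeightedSample, correction: bool = True) -> float:
    """Weighted standard deviation with an n/(n−1) small-sample correction.

    With ``correction=True`` (default) the uniform-weight case equals the
    ordinary sample SD (ddof=1); ``correction=False`` gives the plain
    weighted population SD.
    """
    n = sample.n_obs
    if n < 2:
        raise InsufficientDataError("weighted SD requires n_obs >= 2")
    w = np.asarray(sample.weights)
    x = np.asarray(sample.values)
    mu = weighted_mean(sample)
    var = float((w * (x - mu) ** 2).sum() / w.sum())
    if correction:
        var *= n / (n - 1)
    return math.sqrt(var)


def weighted_se(sd: float, n_obs: int) -> float:
    """Standard error sd/√n_obs; n_obs is cysts at observation level and
    species count at the interspecific level."""
    if n_obs < 1:
        raise InsufficientDataError("n_obs must be >= 1")
    return sd / math.sqrt(n_obs)


def _welch_from_moments(
    mean_a: float, var_a: float, n_a: float, mean_b: float, var_b: float, n_b: float
) -> TestResult:
    va, vb = var_a / n_a, var_b / n_b
    if va + vb == 0:
        raise UndefinedStatisticError("both samples have zero variance")
    diff = mean_b - mean_a
    t = diff / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(t_statistic=t, df=df, p_value=float(p), mean_difference=diff)


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch two-sample t-test for unequal variances, two-sided.

    t = (mean_b − mean_a) / sqrt(s_a²/n_a + s_b²/n_b), with
    Welch–Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each sample needs at least 2 values")
    return _welch_from_moments(
        a.mean(), a.var(ddof=1), len(a), b.mean(), b.var(ddof=1), len(b)
    )


def welch_t_test_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> TestResult:
    """Welch test from summary statistics (mean, sample SD, n) per group."""
    if n_a < 2 or n_b < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    return _welch_from_moments(mean_a, sd_a**2, n_a, mean_b, sd_b**2, n_b)


def weighted_welch_t_test(
    sample_a: WeightedSample,
    sample_b: WeightedSample,
    df_mode: str = "satterthwaite",
    sd_correction: bool = True,
) -> TestResult:
    """Welch two-sample test on abundance-weighted means.

    t = (x̄_w,b − x̄_w,a)/sqrt(se_a² + se_b²) with weighted means and SDs;
    SE terms are weighted_sd²/n_obs. ``df_mode`` is ``"satterthwaite"``
    (component dfs n_obs − 1, default) or ``"pooled"`` (n_a + n_b − 2).

    With uniform weights and n_obs = len(values) this reduces exactly to
    :func:`welch_t_test`.
    """
    if sample_a.n_obs < 2 or sample_b.n_obs < 2:
        raise InsufficientDataError("each sample needs n_obs >= 2")
    n_a, n_b = sample_a.n_obs, sample_b.n_obs
    var_a = weighted_sd(sample_a, correction=sd_correction) ** 2
    var_b = weighted_sd(sample_b, correction=sd_correction) ** 2
    va, vb = var_a / n_a, var_b / n_b
    if va + vb == 0:
        raise UndefinedStatisticError("both samples have zero weighted variance")
    diff = weighted_mean(sample_b) - weighted_mean(sample_a)
    t = diff / math.sqrt(va + vb)
    if df_mode == "satterthwaite":
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    elif df_mode == "pooled":
        df = n_a + n_b - 2
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(t_statistic=t, df=float(df), p_value=float(p), mean_difference=diff)
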