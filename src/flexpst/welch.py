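"""Welch's unequal-variance two-sample t test from summary statistics.

Everything downstream (the error model, the threshold solver, the
simulator) consumes per-arm sufficient statistics — sample size, mean,
standard deviation — so the test is computed from :class:`GroupSummary`
objects rather than raw data.  :func:`summarize_sample` bridges raw
numeric samples to that representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["GroupSummary", "WelchResult", "summarize_sample", "welch_t"]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics for one trial arm.

    Parameters
    ----------
    n : int
        Number of subjects in the arm (at least 2).
    mean : float
        Arithmetic mean of the outcome, in outcome units (e.g. g/dL).
    sd : float
        Sample standard deviation (n-1 denominator), strictly positive.
    """

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"arm needs at least 2 subjects, got n={self.n}")
        if not self.sd > 0:
            raise ValueError(f"arm sd must be > 0, got sd={self.sd}")
        if not np.isfinite(self.mean) or not np.isfinite(self.sd):
            raise ValueError("mean and sd must be finite")

    @property
    def variance_of_mean(self) -> float:
        """s^2 / n, the squared standard error of this arm's mean."""
        return self.sd * self.sd / self.n


@dataclass(frozen=True)
class WelchResult:
    """Welch test output: statistic, SE of the difference, df, p value."""

    t: float
    se_delta: float
    nu: float
    p_two: float


def summarize_sample(values: Sequence[float]) -> GroupSummary:
    """Reduce a raw numeric sample to its :class:`GroupSummary`.

    The sd uses the n-1 denominator (sample SD, as reported in trials).
    A constant sample yields sd = 0 and is rejected, because a zero-sd
    arm is invalid downstream.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need at least 2 values in a one-dimensional sample")
    return GroupSummary(n=int(arr.size), mean=float(arr.mean()),
                        sd=float(arr.std(ddof=1)))


def welch_t(placebo: GroupSummary, treatment: GroupSummary) -> WelchResult:
    """Welch's two-sample t test for unequal variances.

    The statistic is t = (m2 - m1) / se_D with
    se_D = sqrt(s1^2/n1 + s2^2/n2), the degrees of freedom follow the
    Welch–Satterthwaite equation

        nu = (s1^2/n1 + s2^2/n2)^2 /
             [ (s1^2/n1)^2/(n1-1) + (s2^2/n2)^2/(n2-1) ]

    (generally non-integer; used as-is, never rounded), and the
    two-tailed p value is 2*F_nu(-|t|) with F_nu the central Student-t
    CDF.
    """
    v1 = placebo.variance_of_mean
    v2 = treatment.variance_of_mean
    se = float(np.sqrt(v1 + v2))
    nu = (v1 + v2) ** 2 / (v1 * v1 / (placebo.n - 1) + v2 * v2 / (treatment.n - 1))
    t = (treatment.mean - placebo.mean) / se
    p = float(2.0 * stats.t.cdf(-abs(t), df=nu))
    return WelchResult(t=float(t), se_delta=se, nu=float(nu), p_two=min(p, 1.0))
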