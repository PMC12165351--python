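"""Weighted error cost for a two-tailed t test and its ingredients.

The decision-theoretic model: a two-arm trial is analyzed with a t
statistic; declaring significance whenever |t| exceeds a critical value
x incurs a type I error with probability alpha(x) when the null is true
and a type II error with probability beta(x) when the alternative (a
mean shift of delta on the t scale) is true.  The cost of choosing x is
the weighted sum

    epsilon(x) = C * pr * beta(x) + (1 - pr) * alpha(x)

where pr is the prior probability that the alternative is true and C
the seriousness of a type II error relative to a type I error.  The
flexible significance threshold is alpha evaluated at the x minimizing
epsilon; stationarity of epsilon reduces to the transcendental equation

    t_nu(|x|) / [ t_nu(|x| - delta) + t_nu(|x| + delta) ] = k,
    k = C * pr / (2 * (1 - pr)),

with t_nu the central Student-t density.  Both tails are modelled with
the shifted *central* t (the noncentral t enters only the Bayesian
likelihood-ratio module).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .welch import GroupSummary, welch_t

__all__ = [
    "InferenceWeights",
    "TestGeometry",
    "ErrorRates",
    "geometry_from_summaries",
    "geometry_equal_variance",
    "alpha_of_x",
    "beta_of_x",
    "t_density",
    "epsilon_of_x",
    "stationarity_residual",
]


@dataclass(frozen=True)
class InferenceWeights:
    """Decision parameters of the weighted error cost.

    pr : prior probability that the alternative hypothesis is true,
        strictly inside (0, 1).
    C : seriousness of a type II error relative to a type I error
        (0.25 means a false negative is a quarter as bad as a false
        positive, the conventional 0.05-vs-0.2 trade-off).
    d : minimum effect size of interest, in units of the placebo-arm
        SD (Cohen's d convention; 0.5 is a medium effect).
    """

    pr: float
    C: float
    d: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pr < 1.0:
            raise ValueError(f"pr must lie in (0, 1), got {self.pr}")
        if not self.C > 0:
            raise ValueError(f"C must be > 0, got {self.C}")
        if not self.d > 0:
            raise ValueError(f"d must be > 0, got {self.d}")

    @property
    def k(self) -> float:
        """Stationarity constant C*pr / (2*(1-pr))."""
        return self.C * self.pr / (2.0 * (1.0 - self.pr))


@dataclass(frozen=True)
class TestGeometry:
    """Distributional geometry of one test: df, shift, and constant k.

    nu : Welch–Satterthwaite degrees of freedom (positive, non-integer
        in general).
    delta : the minimum effect of interest translated to the t scale,
        d * s1 / se_D (non-negative).
    k : the right-hand constant of the stationarity equation.
    """

    nu: float
    delta: float
    k: float

    __test__ = False  # not a test class despite the Test* name

    def __post_init__(self) -> None:
        if not self.nu > 0:
            raise ValueError(f"nu must be > 0, got {self.nu}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k}")


@dataclass(frozen=True)
class ErrorRates:
    """alpha, beta and their weighted sum epsilon at one critical value."""

    alpha: float
    beta: float
    epsilon: float


def geometry_from_summaries(
    placebo: GroupSummary, treatment: GroupSummary, weights: InferenceWeights
) -> TestGeometry:
    """Geometry measured from the observed per-arm summaries.

    delta anchors the minimum effect to the placebo-arm SD:
    delta = d * s1 / se_D, with se_D the Welch standard error of the
    mean difference; nu is the Welch–Satterthwaite df.
    """
    res = welch_t(placebo, treatment)
    delta = weights.d * placebo.sd / res.se_delta
    return TestGeometry(nu=res.nu, delta=delta, k=weights.k)


def geometry_equal_variance(n: int, weights: InferenceWeights) -> TestGeometry:
    """A-priori geometry assuming equal variances and equal arms of size n.

    Then se_D = s1 * sqrt(2/n), so delta = d * sqrt(n/2) and the df
    reduce to 2n - 2 exactly.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 per arm, got {n}")
    return TestGeometry(nu=2.0 * n - 2.0, delta=weights.d * np.sqrt(n / 2.0),
                        k=weights.k)


def alpha_of_x(x, nu):
    """Two-tailed type I error at critical value x: 2*F_nu(-|x|)."""
    return 2.0 * stats.t.cdf(-np.abs(x), df=nu)


def beta_of_x(x, nu, delta):
    """Two-tailed type II error at critical value x under a shift delta.

    beta(x) = F_nu(|x| - delta) - F_nu(-|x| - delta): the probability
    that a t statistic centred at delta lands inside the acceptance
    region (-|x|, |x|).
    """
    ax = np.abs(x)
    return stats.t.cdf(ax - delta, df=nu) - stats.t.cdf(-ax - delta, df=nu)


def t_density(x, nu):
    """Central Student-t probability density, from its closed form.

    t_nu(x) = Gamma((nu+1)/2) / (sqrt(pi*nu) * Gamma(nu/2))
              * (1 + x^2/nu)^(-(nu+1)/2)

    Evaluated in log space for stability at large nu and |x|.
    """
    x = np.asarray(x, dtype=float)
    nu = np.asarray(nu, dtype=float)
    log_norm = gammaln((nu + 1.0) / 2.0) - gammaln(nu / 2.0) - 0.5 * np.log(np.pi * nu)
    out = np.exp(log_norm - (nu + 1.0) / 2.0 * np.log1p(x * x / nu))
    return float(out) if out.ndim == 0 else out


def epsilon_of_x(x: float, geometry: TestGeometry, weights: InferenceWeights) -> ErrorRates:
    """Evaluate alpha, beta and the weighted sum epsilon at x."""
    a = float(alpha_of_x(x, geometry.nu))
    b = float(beta_of_x(x, geometry.nu, geometry.delta))
    eps = weights.C * weights.pr * b + (1.0 - weights.pr) * a
    return ErrorRates(alpha=a, beta=b, epsilon=eps)


def stationarity_residual(x, geometry: TestGeometry):
    """Residual of the stationarity equation at critical value x.

    Returns t_nu(|x|) / [t_nu(|x|-delta) + t_nu(|x|+delta)] - k, an even
    function of x whose positive root is a stationary point of epsilon.
    The density ratio is computed from log densities so the (nu+1)/2
    powers never overflow; the normalizing constants cancel, making this
    form identical to the ratio of (1 + x^2/nu) powers.
    """
    ax = np.abs(np.asarray(x, dtype=float))
    nu, delta = geometry.nu, geometry.delta
    lf = stats.t.logpdf
    l0 = lf(ax, df=nu)
    ratio = 1.0 / (np.exp(lf(ax - delta, df=nu) - l0) + np.exp(lf(ax + delta, df=nu) - l0))
    out = ratio - geometry.k
    return float(out) if np.ndim(out) == 0 else out
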