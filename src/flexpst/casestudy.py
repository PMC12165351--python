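"""Worked example: two replicas of a hemoglobin trial, analyzed end to end.

A hypothetical iron-deficiency-anemia trial with 50 patients per arm is
run twice.  The first replica observes hemoglobin 11.1 (SD 2.0) g/dL on
placebo vs 13.4 (SD 4.3) g/dL on treatment; the second, 11.0 (1.8) vs
12.4 (4.4).  With a prior of 0.5 that the drug works, a minimum effect
of interest of half a placebo SD, and a type II error a quarter as
serious as a type I, the two replicas land on opposite sides of their
own flexible thresholds (p = 0.001 < 0.033 vs p = 0.041 > 0.027) — the
frequentist conclusions flip between replicas — while the Bayesian
update moves the posterior to roughly 0.97 and 0.86 without
dichotomizing.
"""

from __future__ import annotations

import pandas as pd

from .bayes import likelihood_ratio, posterior_update
from .errors import InferenceWeights, geometry_from_summaries
from .solver import solve_flexible_pst
from .welch import GroupSummary, welch_t

__all__ = ["REPLICAS", "WEIGHTS", "analyze_replica", "case_study_table"]

#: observed per-arm summaries (placebo, treatment) of the two replicas.
REPLICAS = {
    "replica 1": (GroupSummary(n=50, mean=11.1, sd=2.0),
                  GroupSummary(n=50, mean=13.4, sd=4.3)),
    "replica 2": (GroupSummary(n=50, mean=11.0, sd=1.8),
                  GroupSummary(n=50, mean=12.4, sd=4.4)),
}

#: decision parameters of the example.
WEIGHTS = InferenceWeights(pr=0.5, C=0.25, d=0.5)


def analyze_replica(placebo: GroupSummary, treatment: GroupSummary,
                    weights: InferenceWeights = WEIGHTS,
                    lr_method: str = "shifted") -> dict[str, float]:
    """Full pipeline for one replica: test, flexible threshold, Bayes.

    Returns a flat dict with the Welch statistic/df/p value, the
    critical value and flexible threshold, the error rates at the
    threshold, and the likelihood-ratio posterior update.
    """
    res = welch_t(placebo, treatment)
    geom = geometry_from_summaries(placebo, treatment, weights)
    sol = solve_flexible_pst(geom, weights)
    lr = likelihood_ratio(res.t, geom, method=lr_method)
    bayes = posterior_update(lr, weights.pr)
    return {
        "t": res.t, "nu": res.nu, "se_delta": res.se_delta, "p": res.p_two,
        "delta": geom.delta, "x_crit": sol.x_crit, "pst": sol.pst,
        "alpha": sol.rates.alpha, "beta": sol.rates.beta,
        "epsilon": sol.rates.epsilon, "converged": sol.converged,
        "significant": res.p_two < sol.pst,
        "lr": lr, "posterior_odds": bayes.posterior_odds,
        "posterior_prob": bayes.posterior_prob,
    }


def case_study_table(lr_method: str = "shifted") -> pd.DataFrame:
    """Both replicas analyzed end to end, one row each."""
    rows = {name: analyze_replica(p, t, WEIGHTS, lr_method)
            for name, (p, t) in REPLICAS.items()}
    return pd.DataFrame.from_dict(rows, orient="index")
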