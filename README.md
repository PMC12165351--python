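# flexpst

Flexible p-value significance thresholds for two-arm randomized trials:
choose the significance cut-off that minimizes a weighted sum of type I
and type II errors instead of a fixed 0.05 or 0.005, compare the
criteria by Monte Carlo simulation, and compute the likelihood-ratio
Bayesian update as the non-dichotomizing alternative.

## Who this is for

Biostatisticians and methodologists studying the reproducibility
consequences of significance thresholds. The conventional p < 0.05 (or
the stricter p < 0.005) fixes the false-positive rate and lets the
false-negative rate fall where it may. This package implements the
decision-theoretic alternative: for a trial analyzed with Welch's
unequal-variance t test, the critical value x minimizing

    epsilon(x) = C·pr·beta(x) + (1 − pr)·alpha(x)

where `alpha(x) = 2·F_nu(−|x|)` and
`beta(x) = F_nu(|x|−delta) − F_nu(−|x|−delta)`, with `F_nu` the central
Student-t CDF at the Welch–Satterthwaite degrees of freedom,
`delta = d·s1/se_D` the minimum effect size of interest on the t scale,
`pr` the prior probability of a real effect and `C` the seriousness of
a type II relative to a type I error. Stationarity reduces to the
transcendental equation

    t_nu(|x|) / [ t_nu(|x|−delta) + t_nu(|x|+delta) ] = C·pr / (2(1−pr))

solved by bracketed root finding; the flexible threshold (PST) is
`alpha` at the root. See `docs/methods.md` for the full model,
numerical choices and limitations.

## Worked example

Two replicas of a hemoglobin trial (50 patients/arm), with prior 0.5,
type-II seriousness 0.25 and a medium minimum effect (d = 0.5):

```python
from flexpst import (GroupSummary, InferenceWeights, welch_t,
                     geometry_from_summaries, solve_flexible_pst)

placebo = GroupSummary(n=50, mean=11.1, sd=2.0)    # g/dL
treatment = GroupSummary(n=50, mean=13.4, sd=4.3)
weights = InferenceWeights(pr=0.5, C=0.25, d=0.5)

res = welch_t(placebo, treatment)
sol = solve_flexible_pst(geometry_from_summaries(placebo, treatment, weights),
                         weights)
print(res.p_two, sol.pst)   # 0.00102...  0.03348...
```

Running `python examples/flexible_threshold.py` prints:

```
replica 1: p = 0.001, flexible threshold = 0.033 (critical t = 2.169) -> significant
  at the threshold: alpha = 0.033, beta = 0.750, weighted error = 0.1105
replica 2: p = 0.041, flexible threshold = 0.027 (critical t = 2.266) -> not significant
  at the threshold: alpha = 0.027, beta = 0.821, weighted error = 0.1160
```

The two replicas of the *same* trial get different thresholds from
sampling variation alone and reach opposite conclusions — the threshold
can only be computed a posteriori, which is the method's central
caveat. The Bayesian route (`examples/bayesian_update.py`) avoids the
dichotomy: the observed t statistics carry likelihood ratios of ≈39 and
≈6, moving a 50:50 prior to posteriors of 0.975 and 0.864 — both
replicas agree the drug is probably effective, just with different
strength.

The other examples: `examples/welch_test.py` (the summary-statistics
Welch test) and `examples/simulation_grid.py` (a small Monte Carlo grid
comparing all four criteria).

## Command line

The same pipelines as one-liners:

```
flexpst test --n1 50 --m1 11.1 --s1 2.0 --n2 50 --m2 13.4 --s2 4.3
flexpst threshold --n1 50 --m1 11.1 --s1 2.0 --n2 50 --m2 13.4 --s2 4.3
flexpst bayes --n1 50 --m1 11.1 --s1 2.0 --n2 50 --m2 13.4 --s2 4.3
flexpst simulate --config scenario.yaml --out results.csv
flexpst case-study
```

`simulate` reads a YAML/JSON config (see `ScenarioConfig`) and writes a
tidy CSV with per-condition false-positive/false-negative rates,
weighted error sums and threshold dispersion for each criterion.

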