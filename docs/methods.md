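# Methods

## The decision model

A two-arm randomized trial (placebo vs treatment, n subjects per arm)
is analyzed with Welch's unequal-variance t test computed from the
per-arm sufficient statistics (n, mean m, sample SD s):

    t = (m2 - m1) / se_D,      se_D = sqrt(s1^2/n1 + s2^2/n2),

with Welch–Satterthwaite degrees of freedom

    nu = (s1^2/n1 + s2^2/n2)^2
         / [ (s1^2/n1)^2/(n1-1) + (s2^2/n2)^2/(n2-1) ],

used without rounding, and a two-tailed p value 2·F_nu(−|t|).

Declaring significance whenever |t| exceeds a critical value x trades
off two errors. With F_nu the central t CDF,

    alpha(x) = 2·F_nu(−|x|)                       (type I)
    beta(x)  = F_nu(|x| − delta) − F_nu(−|x| − delta)   (type II)

where delta = d·s1/se_D is the minimum effect size of interest d
(placebo-SD units, Cohen's-d convention) translated to the t scale. The
cost of the choice of x is the weighted error sum

    epsilon(x) = C·pr·beta(x) + (1 − pr)·alpha(x),

with pr the prior probability that the alternative is true and C the
seriousness of a type II error relative to a type I error. The
*flexible p significance threshold* (PST) is alpha evaluated at the x
minimizing epsilon. Note that beta uses the central t displaced by
delta, not the noncentral t; this is the model's stated approximation
to power, and a dedicated test confirms the Monte Carlo false-negative
rate tracks it to within 0.03.

Setting d(epsilon)/dx = 0 and using d(alpha)/dx = −2·t_nu(|x|),
d(beta)/dx = t_nu(|x|−delta) + t_nu(|x|+delta) (t_nu the central t
density) gives the stationarity equation

    t_nu(|x|) / [ t_nu(|x|−delta) + t_nu(|x|+delta) ] = k,
    k = C·pr / (2·(1 − pr)).

The density normalizers cancel, so this is identical to the ratio of
(1 + x²/nu) powers; the implementation evaluates it as a log-space
density ratio, which cannot overflow at large nu or |x| and agrees with
the power form to 1e−10 on a broad grid (tested).

## Solving the stationarity equation

The residual is smooth and even in x. As x → 0+ the ratio is at least
1/2 (the density peak dominates), and because t tails decay
polynomially the ratio returns to 1/2 as x → ∞; in between it dips.
Hence for k < 1/2 there are generically two positive roots: the smaller
is the local minimum of epsilon, the larger a local maximum. The solver

1. scans x over [1e−3, delta + 12] on a log-then-linear grid
   (348 points) for sign changes of the residual;
2. refines each bracket with Brent's method (xtol 1e−10);
3. keeps the root with the smallest epsilon (always the first), and
4. declares convergence iff the residual there is ≤ 1e−8 in magnitude.

Bracketing-plus-Brent was chosen over an unguarded quasi-Newton start
because it cannot diverge on this even, flat-tailed residual; where
both converge they agree, and the convergence flag is explicit. If no
sign change is found, a bounded scalar minimization of epsilon over
(0, delta + 12] is attempted (`method="fallback_minimize"`); a minimum
on the boundary means no stationary point exists — delta = 0 (the ratio
is constant 1/2), or k above the ratio's range (large C·pr with a small
delta), or k below its dip minimum — and the solution is returned with
`converged=False` and a diagnostic rather than a fabricated threshold.
The tolerances (residual 1e−8, x 1e−10) are the package's own choices.

Two deliberate boundary semantics: the solver returns the *stationary*
local minimum. For heavy tails (small nu) epsilon can drift below that
local minimum again as x → ∞ (its infimum C·pr); that infimum is not a
usable threshold (it corresponds to never rejecting), so it is not
returned, and the brute-force oracles in the tests compare against the
interior local minimum accordingly.

`solve_pst_batch` solves the same equation for whole arrays of
(nu, delta) by vectorized bracketing on a 160-point grid followed by 72
bisection steps; it agrees with the scalar path to below 1e−9 on x
(tested) and is what makes per-replica thresholds affordable in the
simulator.

## The Bayesian update

The non-dichotomizing alternative: the observed t statistic updates the
prior odds of H1 by the likelihood ratio

    LR = density of t_obs under H1 / density under H0,

with H1 a point alternative at the minimum effect size of interest.
Two H1 densities are offered. The default, `shifted`, is the central t
density displaced by delta — the same approximation the error model
uses, and the variant that reproduces the worked example's printed
ratios (38.6 → 39 and 6.4 → 6). `noncentral` is the exact sampling
density of the t statistic under H1 (noncentral t with noncentrality
delta) and gives slightly larger ratios (41.0 for the first replica);
it is provided because it is the statistically exact choice. Posterior
odds = LR × pr/(1 − pr); posterior probability = odds/(1 + odds).

## The Monte Carlo engine

What it emulates: a heteroscedastic two-arm Gaussian trial. Placebo
outcomes are Normal(0, 1); treatment outcomes Normal(0, s2) under H0 or
Normal(0.5, s2) under H1 (the effect equals the minimum effect of
interest). Each replica is analyzed end to end and judged by four
criteria: fixed p < 0.05, fixed p < 0.005, the flexible threshold
computed a priori under an equal-variance assumption (df = 2n − 2,
delta = d·sqrt(n/2); one value per n), and the flexible threshold
recomputed a posteriori from the replica's own SDs. Significance is the
strict inequality p < threshold; p equal to the threshold counts as not
significant. A non-converged per-replica solve is tallied and that
replica counts as not significant for the measured criterion (it is
never dropped).

Default grid: n ∈ {50, 100, 200, 500, 1000} per arm, s2 ∈ {0.5, 1, 2},
pr = 0.5, C = 0.25, d = 0.5, equal arms. These are the conditions the
engine is meant to reproduce; pr ∈ {0.25, 0.75} and C = 1 variants are
a config change away. n_reps defaults to 10 000 per hypothesis per
condition for production runs; the test suite runs reduced grids
(150–10 000 replicas depending on what the assertion needs) purely as
its own problem-size choice, with binomial-noise-aware tolerances.

Randomness: each (n, s2, hypothesis) cell draws from
`default_rng(SeedSequence([seed, i_n, i_s2, hyp]))`, so any cell is
independently reproducible and full summaries are bit-identical given
(config, seed). The engine draws each cell as an (n_reps × n) matrix
and computes the Welch test and per-replica thresholds vectorized;
`run_replica` offers the same single-trial pipeline for inspection
(identical distribution, different stream consumption order).

Box statistics of the measured-threshold distribution (pooled across
the H0/H1 cells, whose threshold distributions are identical because
the threshold depends only on the SDs) use linear interpolation between
order statistics for the quartiles and whiskers at the most extreme
values within 1.5×IQR of the quartiles; points beyond are outliers.

What the generator does *not* emulate: non-Gaussian outcomes, unequal
arms, dropout, sequential looks, or estimation of d from data. Passing
tests therefore show the criteria's behaviour under the idealized
Gaussian trial, not robustness to real-data pathologies.

## Worked example

The built-in case study is a two-replica hemoglobin trial (50 patients
per arm; 11.1 ± 2.0 vs 13.4 ± 4.3 g/dL, then 11.0 ± 1.8 vs 12.4 ± 4.4)
with pr = 0.5, C = 0.25, d = 0.5. The computed p values are 0.001 and
0.041; the flexible thresholds 0.033 and 0.027; the likelihood ratios
round to 39 and 6, giving posteriors 0.975 and 0.857. The stated arm
size reproduces all of these figures; the replica-2 threshold is
sensitive at the third decimal to the one-decimal rounding of its
summary inputs.

## Known limitations

- The flexible threshold requires the measured SDs, so it is only
  computable after the data are in; replicas of the same study get
  different thresholds. The package computes this honestly rather than
  hiding it — it is the method's central caveat.
- beta is the shifted-central-t approximation, not exact noncentral-t
  power; the discrepancy is within 0.03 at the default conditions.
- H1 in the Bayesian module is a point alternative; no effect-size
  prior is averaged over.
- The simulator reports tables, not figures; plotting is left to the
  caller (the CSV output is tidy/long format for that purpose).
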