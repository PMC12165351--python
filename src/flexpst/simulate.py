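"""Monte Carlo comparison of significance criteria in two-arm trials.

Each replica draws a placebo arm from Normal(0, 1) and a treatment arm
from Normal(0, sd_treatment) under H0 or Normal(effect_size,
sd_treatment) under H1, analyzes it with Welch's t test, and applies
four significance criteria to the p value:

``fixed_0.05`` / ``fixed_0.005``
    the conventional and the stricter fixed thresholds;
``flexible_equal``
    the flexible threshold computed a priori assuming equal variances
    (df = 2n - 2, delta = d * sqrt(n/2)) — one value per sample size;
``flexible_measured``
    the flexible threshold recomputed a posteriori from each replica's
    own sample SDs.

A replica is "significant" iff p < threshold (p equal to the threshold
counts as not significant).  Per condition the engine reports the
false-positive rate (H0 replicas declared significant), false-negative
rate (H1 replicas declared not significant), the weighted error sum
C*pr*fn + (1-pr)*fp with the empirical rates, solver convergence
tallies, and box statistics of the measured-threshold distribution.

Reproducibility: every (sample size, treatment SD, hypothesis) cell
gets its own substream spawned deterministically from the master seed,
so any cell can be re-run independently and results are bit-identical
for a given (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import InferenceWeights, geometry_equal_variance, geometry_from_summaries
from .solver import solve_flexible_pst, solve_pst_batch
from .welch import GroupSummary, summarize_sample, welch_t

__all__ = [
    "CRITERIA",
    "ScenarioConfig",
    "ReplicaRecord",
    "CriterionStats",
    "BoxStats",
    "ScenarioSummary",
    "box_statistics",
    "run_replica",
    "run_scenario",
    "summaries_to_frame",
    "default_config",
]

logger = logging.getLogger(__name__)

#: the four significance criteria and their kind.
CRITERIA = ("fixed_0.05", "fixed_0.005", "flexible_equal", "flexible_measured")
_FIXED_LEVELS = {"fixed_0.05": 0.05, "fixed_0.005": 0.005}


@dataclass(frozen=True)
class ScenarioConfig:
    """Simulation grid and decision parameters.

    The defaults of :func:`default_config` are the study conditions the
    engine is meant to emulate: equal arms of 50–1000 subjects, placebo
    SD fixed at 1, treatment SD in {0.5, 1, 2}, a medium minimum effect
    size (0.5), prior 0.5 and type-II seriousness 0.25.
    """

    n_per_arm: tuple[int, ...]
    sd_treatment: tuple[float, ...]
    weights: InferenceWeights
    effect_size: float = 0.5
    criteria: tuple[str, ...] = CRITERIA
    n_reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_arm or any(n < 2 for n in self.n_per_arm):
            raise ValueError("n_per_arm must be a non-empty list of integers >= 2")
        if not self.sd_treatment or any(s <= 0 for s in self.sd_treatment):
            raise ValueError("sd_treatment must be a non-empty list of positive reals")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        unknown = set(self.criteria) - set(CRITERIA)
        if unknown or not self.criteria:
            raise ValueError(f"criteria must be a non-empty subset of {CRITERIA}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScenarioConfig":
        d = dict(data)
        w = d.pop("weights")
        weights = InferenceWeights(pr=float(w["pr"]), C=float(w["C"]), d=float(w["d"]))
        return cls(
            n_per_arm=tuple(int(n) for n in d["n_per_arm"]),
            sd_treatment=tuple(float(s) for s in d["sd_treatment"]),
            weights=weights,
            effect_size=float(d.get("effect_size", 0.5)),
            criteria=tuple(d.get("criteria", CRITERIA)),
            n_reps=int(d.get("n_reps", 10_000)),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        """Load a config from a YAML (or JSON, a YAML subset) file."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(n_reps: int = 2_000, seed: int = 0) -> ScenarioConfig:
    """The default scenario grid covering the conditions the engine targets."""
    return ScenarioConfig(
        n_per_arm=(50, 100, 200, 500, 1000),
        sd_treatment=(0.5, 1.0, 2.0),
        weights=InferenceWeights(pr=0.5, C=0.25, d=0.5),
        effect_size=0.5,
        n_reps=n_reps,
        seed=seed,
    )


@dataclass(frozen=True)
class ReplicaRecord:
    """One simulated trial analyzed end-to-end."""

    p_value: float
    pst_equal: float
    pst_measured: float
    converged_flags: dict[str, bool]
    decisions: dict[str, bool]


@dataclass(frozen=True)
class BoxStats:
    """Five-number box summary with a 1.5*IQR whisker/outlier rule."""

    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = ()


@dataclass(frozen=True)
class CriterionStats:
    """Empirical error rates for one criterion in one condition."""

    fp_rate: float
    fn_rate: float
    weighted_error: float
    n_converged: int
    n_solves: int


@dataclass(frozen=True)
class ScenarioSummary:
    """Per-condition summary over n_reps H0 and n_reps H1 replicas."""

    n_per_arm: int
    sd_treatment: float
    pr: float
    C: float
    effect_size: float
    n_reps: int
    seed: int
    criteria: dict[str, CriterionStats]
    pst_equal: float
    pst_measured_box: BoxStats | None = None


def box_statistics(values: Sequence[float]) -> BoxStats:
    """Quartiles plus whiskers at the most extreme data within 1.5*IQR.

    Quartiles use linear interpolation between order statistics.  Points
    beyond the whiskers are returned as outliers.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    q25, med, q75 = np.percentile(arr, [25.0, 50.0, 75.0])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return BoxStats(
        median=float(med), q25=float(q25), q75=float(q75),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=tuple(np.sort(arr[(arr < lo_fence) | (arr > hi_fence)]).tolist()),
    )


def _thresholds(config: ScenarioConfig, n: int,
                pst_equal: float, pst_measured: float) -> dict[str, float]:
    out: dict[str, float] = {}
    for c in config.criteria:
        if c in _FIXED_LEVELS:
            out[c] = _FIXED_LEVELS[c]
        elif c == "flexible_equal":
            out[c] = pst_equal
        else:
            out[c] = pst_measured
    return out


def run_replica(n: int, sd_treatment: float, hypothesis: str,
                config: ScenarioConfig, rng: np.random.Generator) -> ReplicaRecord:
    """Draw, test and classify a single trial under H0 or H1.

    The placebo arm is n draws from Normal(0, 1); the treatment arm is n
    draws from Normal(0, sd_treatment) under H0 or
    Normal(effect_size, sd_treatment) under H1.  Both flexible
    thresholds are computed; solver non-convergence is recorded in
    ``converged_flags`` (a non-converged measured threshold makes that
    criterion's decision "not significant") and the replica is retained.
    """
    if hypothesis not in ("H0", "H1"):
        raise ValueError(f"hypothesis must be 'H0' or 'H1', got {hypothesis!r}")
    m2 = config.effect_size if hypothesis == "H1" else 0.0
    placebo = summarize_sample(rng.normal(0.0, 1.0, size=n))
    treatment = summarize_sample(rng.normal(m2, sd_treatment, size=n))
    res = welch_t(placebo, treatment)

    sol_eq = solve_flexible_pst(geometry_equal_variance(n, config.weights), config.weights)
    sol_me = solve_flexible_pst(
        geometry_from_summaries(placebo, treatment, config.weights), config.weights)
    thresholds = _thresholds(config, n, sol_eq.pst, sol_me.pst)
    decisions = {c: bool(res.p_two < thr) for c, thr in thresholds.items()}
    return ReplicaRecord(
        p_value=res.p_two, pst_equal=sol_eq.pst, pst_measured=sol_me.pst,
        converged_flags={"flexible_equal": sol_eq.converged,
                         "flexible_measured": sol_me.converged},
        decisions=decisions,
    )


def _run_cell(n: int, sd_t: float, hypothesis: str, config: ScenarioConfig,
              rng: np.random.Generator, need_measured: bool):
    """All n_reps replicas of one (n, sd, hypothesis) cell, vectorized."""
    reps = config.n_reps
    m2 = config.effect_size if hypothesis == "H1" else 0.0
    a = rng.normal(0.0, 1.0, size=(reps, n))
    b = rng.normal(m2, sd_t, size=(reps, n))
    m1, s1 = a.mean(axis=1), a.std(axis=1, ddof=1)
    m2_, s2 = b.mean(axis=1), b.std(axis=1, ddof=1)
    v1, v2 = s1 * s1 / n, s2 * s2 / n
    se = np.sqrt(v1 + v2)
    t = (m2_ - m1) / se
    nu = (v1 + v2) ** 2 / (v1 * v1 / (n - 1) + v2 * v2 / (n - 1))
    p = 2.0 * stats.t.cdf(-np.abs(t), df=nu)
    if need_measured:
        delta = config.weights.d * s1 / se
        _, pst_meas, conv = solve_pst_batch(nu, delta, config.weights.k)
    else:
        pst_meas = np.full(reps, np.nan)
        conv = np.zeros(reps, dtype=bool)
    return p, pst_meas, conv


def run_scenario(config: ScenarioConfig) -> list[ScenarioSummary]:
    """Run the full grid; one summary per (n_per_arm, sd_treatment).

    For each condition, n_reps replicas are simulated under H0 and
    n_reps under H1 on independent substreams.  fp_rate is the share of
    H0 replicas declared significant, fn_rate the share of H1 replicas
    declared not significant, and the weighted error combines the two
    empirical rates.  A comparison with NaN (non-converged measured
    threshold) is False, i.e. not significant.
    """
    need_measured = "flexible_measured" in config.criteria
    need_equal = "flexible_equal" in config.criteria
    w = config.weights
    summaries: list[ScenarioSummary] = []

    pst_equal_cache: dict[int, float] = {}
    for n in config.n_per_arm:
        if need_equal:
            pst_equal_cache[n] = solve_flexible_pst(
                geometry_equal_variance(n, w), w).pst
        else:
            pst_equal_cache[n] = float("nan")

    for i_n, n in enumerate(config.n_per_arm):
        for i_s, sd_t in enumerate(config.sd_treatment):
            sig: dict[str, dict[str, float]] = {}
            conv_tally: dict[str, int] = {c: 0 for c in config.criteria}
            pooled_pst: list[np.ndarray] = []
            for hyp, code in (("H0", 0), ("H1", 1)):
                rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, i_n, i_s, code]))
                p, pst_meas, conv = _run_cell(n, sd_t, hyp, config, rng, need_measured)
                thr = _thresholds(config, n, pst_equal_cache[n], float("nan"))
                for c in config.criteria:
                    if c == "flexible_measured":
                        with np.errstate(invalid="ignore"):
                            dec = p < pst_meas
                        conv_tally[c] += int(conv.sum())
                    else:
                        dec = p < thr[c]
                        conv_tally[c] += config.n_reps
                    sig.setdefault(c, {})[hyp] = float(dec.mean())
                if need_measured:
                    pooled_pst.append(pst_meas[conv])
            crit_stats = {}
            for c in config.criteria:
                fp = sig[c]["H0"]
                fn = 1.0 - sig[c]["H1"]
                crit_stats[c] = CriterionStats(
                    fp_rate=fp, fn_rate=fn,
                    weighted_error=w.C * w.pr * fn + (1.0 - w.pr) * fp,
                    n_converged=conv_tally[c], n_solves=2 * config.n_reps)
            box = (box_statistics(np.concatenate(pooled_pst))
                   if need_measured and pooled_pst else None)
            summaries.append(ScenarioSummary(
                n_per_arm=n, sd_treatment=sd_t, pr=w.pr, C=w.C,
                effect_size=config.effect_size, n_reps=config.n_reps,
                seed=config.seed, criteria=crit_stats,
                pst_equal=pst_equal_cache[n], pst_measured_box=box))
            logger.info(
                "condition n=%d sd=%g: %d replicas per hypothesis, "
                "measured-threshold solves converged %s",
                n, sd_t, config.n_reps,
                ", ".join(f"{c}={conv_tally[c]}/{2 * config.n_reps}"
                          for c in config.criteria if c.startswith("flexible")))
    return summaries


def summaries_to_frame(summaries: Sequence[ScenarioSummary]) -> pd.DataFrame:
    """Long-format table: one row per condition x criterion."""
    rows = []
    for s in summaries:
        for c, st in s.criteria.items():
            box = s.pst_measured_box
            if c in _FIXED_LEVELS:
                med = q25 = q75 = _FIXED_LEVELS[c]
            elif c == "flexible_equal":
                med = q25 = q75 = s.pst_equal
            else:
                med = box.median if box else float("nan")
                q25 = box.q25 if box else float("nan")
                q75 = box.q75 if box else float("nan")
            rows.append({
                "n_per_arm": s.n_per_arm, "sd_treatment": s.sd_treatment,
                "hypothesis": "H0+H1", "pr": s.pr, "c_ratio": s.C,
                "criterion": c, "fp_rate": st.fp_rate, "fn_rate": st.fn_rate,
                "weighted_error": st.weighted_error,
                "pst_median": med, "pst_q25": q25, "pst_q75": q75,
                "n_converged": st.n_converged, "n_reps": s.n_reps,
                "seed": s.seed,
            })
    return pd.DataFrame(rows)
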