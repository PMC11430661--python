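"""Monte Carlo sample-size machinery for median-curve estimation accuracy.

The design question: how many children must a cross-sectional normative
cohort contain so that the fitted median curve's error is no greater than
E score points (default 2, on the 0-64 scale) at every integer age 1..72
months, with probability at least P (default 0.90)?  Each Monte Carlo
replicate simulates one cohort from a reference percentile table, refits
the tau = 0.5 logistic quantile curve, and records the maximum absolute
deviation from the generating median over the evaluation ages; the
probability is estimated by the proportion of replicates within the bound,
and the candidate sample sizes are scanned for the smallest that meets P.

Replicates whose fit fails are counted as exceeding the bound
(conservative) and reported separately, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from flipnorms.cohort import AgeBlockDesign, GeneratorConfig, generate_cohort, generate_uniform_cohort
from flipnorms.growth import PercentileTable, logistic_eval
from flipnorms.quantile import FitDataError, fit_quantile_curve

EVAL_AGES = np.arange(1, 73, dtype=float)  # integer months 1..72


@dataclass
class SampleSizeConfig:
    seed: int
    error_bound: float = 2.0      # E, score points
    prob_target: float = 0.90     # P
    replicates: int = 200
    candidates: tuple = (72, 144, 288, 432)
    n_starts: int = 8             # fit restarts per replicate
    max_fev: int = 2000

    def __post_init__(self) -> None:
        if self.error_bound < 0:
            raise ValueError("error bound must be non-negative")
        if not 0 < self.prob_target < 1:
            raise ValueError("probability target must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class CandidateEstimate:
    n: int
    prob: float
    se: float                      # binomial Monte Carlo standard error
    replicates: int
    failed_fits: int
    max_errors: list[float] = field(default_factory=list)


@dataclass
class SampleSizeResult:
    candidates: list[CandidateEstimate]
    selected_n: int | None
    config: SampleSizeConfig


def _true_median(table: PercentileTable, ages: np.ndarray) -> np.ndarray:
    if 0.5 not in table.entries:
        raise ValueError("table must contain a median (tau = 0.5) curve")
    return np.asarray(logistic_eval(table.entries[0.5], ages))


def replicate_max_error(n_or_design, table: PercentileTable, seed: int,
                        n_starts: int = 8, max_fev: int = 2000,
                        rounding: str = "continuous") -> float:
    """One replicate: simulate, refit the median curve, max error over 1..72.

    ``n_or_design`` is either a bare sample size (ages uniform over the
    age range) or an :class:`AgeBlockDesign`.  Raises
    :class:`flipnorms.quantile.FitDataError` when the fit cannot proceed;
    callers aggregating replicates treat that as exceeding any bound.
    """
    gen_cfg = GeneratorConfig(seed=seed, rounding=rounding)
    if isinstance(n_or_design, AgeBlockDesign):
        records = generate_cohort(n_or_design, table, gen_cfg)
    else:
        n = int(n_or_design)
        if n < 40:
            raise ValueError(f"bare sample size must be >= 40, got {n}")
        records = generate_uniform_cohort(n, table, gen_cfg, age_range=(1.5, 72.0))
    fit = fit_quantile_curve(records, tau=0.5, n_starts=n_starts,
                             seed=seed, max_fev=max_fev)
    fitted = np.asarray(logistic_eval(fit.params, EVAL_AGES))
    truth = _true_median(table, EVAL_AGES)
    return float(np.max(np.abs(fitted - truth)))


def estimate_probability(config: SampleSizeConfig, n_or_design,
                         table: PercentileTable) -> CandidateEstimate:
    """Proportion of replicates whose max error stays within the bound.

    Replicate seeds are spawned deterministically from ``config.seed``;
    failed fits count as exceeding the bound.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(config.replicates)
    seeds = (seeds % (2**31 - 1)).astype(np.int64)
    max_errors: list[float] = []
    failed = 0
    hits = 0
    for s in seeds:
        try:
            err = replicate_max_error(n_or_design, table, seed=int(s),
                                      n_starts=config.n_starts,
                                      max_fev=config.max_fev)
        except FitDataError:
            failed += 1
            max_errors.append(float("inf"))
            continue
        max_errors.append(err)
        if err <= config.error_bound:
            hits += 1
    prob = hits / config.replicates
    se = float(np.sqrt(prob * (1 - prob) / config.replicates))
    n_label = n_or_design.total if isinstance(n_or_design, AgeBlockDesign) else int(n_or_design)
    return CandidateEstimate(n=n_label, prob=prob, se=se,
                             replicates=config.replicates, failed_fits=failed,
                             max_errors=max_errors)


def find_min_sample_size(config: SampleSizeConfig,
                         table: PercentileTable) -> SampleSizeResult:
    """Smallest candidate n with estimated probability >= the target.

    Scans the ascending candidate list; the full probability profile is
    reported alongside the selection (``selected_n`` is None when no
    candidate qualifies).
    """
    candidates = list(config.candidates)
    if not candidates:
        raise ValueError("candidate sample sizes must be non-empty")
    if sorted(candidates) != candidates:
        raise ValueError("candidate sample sizes must be ascending")
    estimates = []
    selected = None
    for n in candidates:
        est = estimate_probability(config, n, table)
        estimates.append(est)
        if selected is None and est.prob >= config.prob_target:
            selected = n
    return SampleSizeResult(candidates=estimates, selected_n=selected,
                           config=config)
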