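"""Synthetic normative cohorts induced by a percentile table.

The normative study's raw data are commercially restricted, so simulation
stands in for them.  Only seven percentile curves of the conditional score
distribution are published; the generator completes the conditional law by
normal-score (probit) interpolation: at a given age the seven curve values
are paired with z = Phi^-1(tau), a child's latent rank u in (0,1) is mapped
to z_u = Phi^-1(u), the score interpolated linearly in z between the
bracketing curves (linearly extrapolated from the outermost segment beyond
the 5th/95th), then clamped to the instrument range [0, 64].  This is the
completion consistent with reading the 16th/84th percentiles as one SD
either side of the median.

Cross-sectional cohorts follow an age-block recruitment design (twelve
6-month blocks over 0-72 months); ages are drawn uniformly within block.
Longitudinal series add the two variability components of the sample-size
simulation: a per-child lognormal rate multiplier acting on effective age
(between-child variation in the rate of skill growth) and independent
Gaussian within-child measurement noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.stats import norm

from flipnorms.growth import AGE_MAX, SCORE_MAX, PercentileTable
from flipnorms.quantile import CohortRecord


@dataclass(frozen=True)
class AgeBlock:
    lo: float
    hi: float
    count: int


@dataclass
class AgeBlockDesign:
    """Recruitment design: ordered 6-month age blocks with target counts.

    ``min_child_age`` floors the first block's lower edge (the youngest
    child the design admits, default 1.5 months).
    """

    blocks: list[AgeBlock]
    min_child_age: float = 1.5
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.blocks) != 12:
            raise ValueError(f"expected 12 age blocks, got {len(self.blocks)}")
        lo = 0.0
        for b in self.blocks:
            if b.lo != lo:
                raise ValueError(f"blocks must be contiguous from 0; got lower edge {b.lo}, expected {lo}")
            if b.hi - b.lo != 6.0:
                raise ValueError(f"blocks must be 6 months wide, got ({b.lo}, {b.hi}]")
            if b.count < 0:
                raise ValueError("block counts must be >= 0")
            lo = b.hi
        if lo != AGE_MAX:
            raise ValueError(f"blocks must cover (0, {AGE_MAX}]")

    @property
    def total(self) -> int:
        return sum(b.count for b in self.blocks)


@dataclass
class GeneratorConfig:
    seed: int
    rounding: str = "continuous"        # {"integer", "continuous"}
    tail_handling: str = "extrapolate-then-clamp"   # or "clamp"

    def __post_init__(self) -> None:
        if self.rounding not in ("integer", "continuous"):
            raise ValueError(f"rounding must be 'integer' or 'continuous', got {self.rounding!r}")
        if self.tail_handling not in ("clamp", "extrapolate-then-clamp"):
            raise ValueError(f"unknown tail handling {self.tail_handling!r}")


@dataclass
class LongitudinalModelConfig:
    """Two-component longitudinal variability model.

    sigma_b: SD of the log rate multiplier (dimensionless); between-child
    spread in the rate of score increase with age.  sigma_w: SD (score
    points) of within-child assessment noise.  Neither has a published
    value; defaults (0.15, 2.0) are the package's documented choice.
    """

    seed: int
    sigma_b: float = 0.15
    sigma_w: float = 2.0
    schedule: tuple = tuple(range(6, 73, 6))

    def __post_init__(self) -> None:
        if self.sigma_b < 0 or self.sigma_w < 0:
            raise ValueError("variability parameters must be >= 0")
        if len(self.schedule) == 0:
            raise ValueError("assessment schedule must be non-empty")
        if any(not 0 < a <= AGE_MAX for a in self.schedule):
            raise ValueError(f"schedule ages must lie in (0, {AGE_MAX}]")


@dataclass
class ChildTrajectory:
    """Ordered (age, score) series for one child, with optional event markers."""

    child_id: str
    points: list[tuple[float, float]]
    annotations: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ages = [a for a, _ in self.points]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("trajectory ages must be strictly increasing")
        if any(not 0 <= s <= SCORE_MAX for _, s in self.points):
            raise ValueError(f"trajectory scores must lie in [0, {SCORE_MAX}]")


def quantile_function(table: PercentileTable, age, u) -> float | np.ndarray:
    """Continuous conditional quantile of score at ``age`` for rank ``u``.

    Normal-score construction over the table's curves (see module
    docstring); non-decreasing in u at fixed age, values in [0, 64].
    Vectorised over ``u``.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= 0) or np.any(u_arr >= 1):
        raise ValueError("latent rank u must lie strictly in (0, 1)")
    if not 0 < age <= AGE_MAX:
        raise ValueError(f"age {age} outside (0, {AGE_MAX}] months")
    taus = np.asarray(table.taus)
    zs = norm.ppf(taus)
    vals = table.curve_values(float(age))
    vals = np.maximum.accumulate(vals)  # guard against user-table crossings
    zu = norm.ppf(u_arr)
    # linear interpolation in z with linear extrapolation from the outer segments
    out = np.interp(zu, zs, vals)
    lo_mask = zu < zs[0]
    hi_mask = zu > zs[-1]
    if np.any(lo_mask):
        slope = (vals[1] - vals[0]) / (zs[1] - zs[0])
        out = np.where(lo_mask, vals[0] + slope * (zu - zs[0]), out)
    if np.any(hi_mask):
        slope = (vals[-1] - vals[-2]) / (zs[-1] - zs[-2])
        out = np.where(hi_mask, vals[-1] + slope * (zu - zs[-1]), out)
    out = np.clip(out, 0.0, SCORE_MAX)
    return float(out) if out.ndim == 0 else out


def _emit_records(ages: np.ndarray, table: PercentileTable,
                  config: GeneratorConfig, rng: np.random.Generator,
                  prefix: str) -> list[CohortRecord]:
    records = []
    for i, age in enumerate(ages):
        u = rng.uniform()
        if config.tail_handling == "clamp":
            u = min(max(u, 0.05), 0.95)
        score = quantile_function(table, float(age), u)
        if config.rounding == "integer":
            score = float(np.clip(np.rint(score), 0, SCORE_MAX))
        records.append(CohortRecord(child_id=f"{prefix}{i:05d}",
                                    age=float(age), score=score))
    return records


def generate_cohort(design: AgeBlockDesign, table: PercentileTable,
                    config: GeneratorConfig) -> list[CohortRecord]:
    """Cross-sectional cohort under an age-block design.

    Per block: ``count`` children, age uniform on the block interval (the
    first block respects ``min_child_age``), latent rank uniform on (0, 1),
    score via :func:`quantile_function`.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    ages = []
    for b in design.blocks:
        lo = max(b.lo, design.min_child_age)
        ages.append(rng.uniform(lo, b.hi, size=b.count))
    ages = np.concatenate(ages) if ages else np.array([])
    return _emit_records(ages, table, config, rng, prefix="sim-")


def generate_uniform_cohort(n: int, table: PercentileTable,
                            config: GeneratorConfig,
                            age_range: tuple[float, float] = (3.0, 72.0)) -> list[CohortRecord]:
    """Cohort of ``n`` children with ages uniform on ``age_range``."""
    lo, hi = age_range
    if not 0 < lo < hi <= AGE_MAX:
        raise ValueError(f"age range must satisfy 0 < lo < hi <= {AGE_MAX}")
    rng = np.random.default_rng(config.seed)
    ages = rng.uniform(lo, hi, size=n)
    return _emit_records(ages, table, config, rng, prefix="sim-")


def generate_longitudinal_child(table: PercentileTable,
                                config: LongitudinalModelConfig,
                                child_id: str = "sim-long-0") -> ChildTrajectory:
    """One longitudinal series under the two-component variability model.

    A rate multiplier r ~ LogNormal(0, sigma_b) is drawn once per child;
    the latent score at age x is the median curve at effective age r*x
    (clamped into (0, 72]); each scheduled observation adds independent
    N(0, sigma_w^2) noise and clamps to [0, 64].
    """
    if 0.5 not in table.entries:
        raise ValueError("table must contain a median (tau = 0.5) curve")
    rng = np.random.default_rng(config.seed)
    r = float(np.exp(rng.normal(0.0, config.sigma_b))) if config.sigma_b > 0 else 1.0
    median = table.entries[0.5]
    points = []
    for age in config.schedule:
        eff = min(max(r * age, 1e-6), AGE_MAX)
        latent = median.a1 + (median.a2 - median.a1) / (
            1.0 + np.exp(-median.a3 * (eff - median.a4)))
        noise = rng.normal(0.0, config.sigma_w) if config.sigma_w > 0 else 0.0
        score = float(np.clip(latent + noise, 0.0, SCORE_MAX))
        points.append((float(age), score))
    return ChildTrajectory(child_id=child_id, points=points)


def load_design(name_or_path: str | Path) -> AgeBlockDesign:
    """Load an age-block design: the packaged names ``"target"`` (12 x 36
    children, total 432) and ``"actual"`` (the achieved per-block counts),
    or a path to a design JSON."""
    if name_or_path in ("target", "actual"):
        res = resources.files("flipnorms.data").joinpath(f"design_{name_or_path}.json")
        with res.open() as fh:
            doc = json.load(fh)
    else:
        with open(name_or_path) as fh:
            doc = json.load(fh)
    blocks = [AgeBlock(float(b["lo"]), float(b["hi"]), int(b["count"]))
              for b in doc["blocks"]]
    return AgeBlockDesign(blocks=blocks,
                          min_child_age=float(doc.get("min_child_age", 1.5)),
                          name=doc.get("name", str(name_or_path)))
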