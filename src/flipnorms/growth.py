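"""Four-parameter logistic percentile curves and the packaged reference norms.

A percentile curve is the sigmoid

    q(x) = a1 + (a2 - a1) / (1 + exp(-a3 * (x - a4)))

with ``x`` the child's age in months, ``a1``/``a2`` the lower/upper
asymptotes (score points), ``a3`` the growth rate (per month) and ``a4``
the inflection age (months).  A :class:`PercentileTable` holds one such
curve per quantile level tau; the packaged reference table carries the
fitted parameters for the 5th, 10th, 16th, 50th, 84th, 90th and 95th
percentiles of FLI-P score against age, recommended for reporting from
3 months of age.

Scores live on the instrument scale [0, 64]; reported curve values are
clamped to that range (the raw curve is negative at very young ages for
the lowest percentiles) while unclamped values remain available for
fitting and simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.stats import norm

SCORE_MAX = 64.0
AGE_MAX = 72.0

#: quantile levels of the reference norms
DEFAULT_TAUS = (0.05, 0.10, 0.16, 0.50, 0.84, 0.90, 0.95)

#: band labels relative to the fitted percentile family
BANDS = ("below-5th", "5th-16th", "16th-84th", "84th-95th", "above-95th")


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of one four-parameter logistic percentile curve."""

    a1: float  # lower asymptote, score points
    a2: float  # upper asymptote, score points
    a3: float  # growth rate, per month
    a4: float  # inflection age, months

    def __post_init__(self) -> None:
        if not self.a2 > self.a1:
            raise ValueError(f"upper asymptote a2={self.a2} must exceed a1={self.a1}")
        if not self.a3 > 0:
            raise ValueError(f"growth rate a3={self.a3} must be positive")
        if self.a2 > SCORE_MAX:
            raise ValueError(f"a2={self.a2} exceeds the instrument maximum {SCORE_MAX}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3, self.a4], dtype=float)


@dataclass
class PercentileTable:
    """Map from quantile level tau to a fitted logistic curve.

    ``min_age`` is the youngest age (months) at which the norms are
    recommended for reporting; evaluation below it warns but still computes.
    """

    entries: dict[float, LogisticParams]
    min_age: float = 3.0

    def __post_init__(self) -> None:
        taus = list(self.entries)
        if not taus:
            raise ValueError("percentile table must contain at least one entry")
        if any(not 0 < t < 1 for t in taus):
            raise ValueError("quantile levels must lie strictly between 0 and 1")
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValueError("quantile levels must be strictly increasing")

    @property
    def taus(self) -> tuple[float, ...]:
        return tuple(self.entries)

    def curve_values(self, age: float, clamp: bool = False) -> np.ndarray:
        """Evaluate every curve at ``age``, in tau order."""
        vals = np.array([logistic_eval(p, age) for p in self.entries.values()])
        if clamp:
            vals = np.clip(vals, 0.0, SCORE_MAX)
        return vals

    def to_dict(self) -> dict:
        return {
            "min_age": self.min_age,
            "entries": [
                {"tau": t, "a1": p.a1, "a2": p.a2, "a3": p.a3, "a4": p.a4}
                for t, p in self.entries.items()
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PercentileTable":
        entries = {
            float(e["tau"]): LogisticParams(e["a1"], e["a2"], e["a3"], e["a4"])
            for e in payload["entries"]
        }
        entries = dict(sorted(entries.items()))
        return cls(entries=entries, min_age=float(payload.get("min_age", 3.0)))


@dataclass
class NormEvaluation:
    """Clamped percentile values at one age, with clamping provenance."""

    age: float
    values: dict[float, float]
    clamped: dict[float, bool]
    below_min_age: bool = False
    warnings: list[str] = field(default_factory=list)


def logistic_eval(params: LogisticParams, age) -> float | np.ndarray:
    """Evaluate the four-parameter logistic at ``age`` (months), unclamped.

    Strictly increasing in age, approaching ``a2`` as age grows.  Total on
    all finite ages.
    """
    age = np.asarray(age, dtype=float)
    out = params.a1 + (params.a2 - params.a1) / (1.0 + np.exp(-params.a3 * (age - params.a4)))
    return float(out) if out.ndim == 0 else out


def load_reference_table() -> PercentileTable:
    """Load the packaged reference percentile parameter table.

    Seven curves (5th...95th percentile of FLI-P score against age in
    months), parameters stored at their published 4-decimal precision,
    reporting minimum age 3 months.
    """
    with resources.files("flipnorms.data").joinpath("reference_table.json").open() as fh:
        payload = json.load(fh)
    table = PercentileTable.from_dict(payload)
    if tuple(table.entries) != DEFAULT_TAUS:
        raise RuntimeError("packaged reference table is corrupted: unexpected quantile levels")
    if len(table.entries) != 7:
        raise RuntimeError("packaged reference table is corrupted: wrong entry count")
    return table


def evaluate_norms(table: PercentileTable, age: float) -> NormEvaluation:
    """Evaluate all percentile curves at one age, clamped to [0, 64].

    Ages below ``table.min_age`` are flagged (``below_min_age``) but still
    evaluated; ages outside (0, 72] raise.
    """
    if not 0 < age <= AGE_MAX:
        raise ValueError(f"age {age} outside (0, {AGE_MAX}] months")
    values: dict[float, float] = {}
    clamped: dict[float, bool] = {}
    for tau, params in table.entries.items():
        raw = logistic_eval(params, age)
        val = min(max(raw, 0.0), SCORE_MAX)
        values[tau] = val
        clamped[tau] = val != raw
    below = age < table.min_age
    warnings = []
    if below:
        warnings.append(
            f"age {age} months is below the recommended reporting minimum "
            f"of {table.min_age} months"
        )
    return NormEvaluation(age=age, values=values, clamped=clamped,
                          below_min_age=below, warnings=warnings)


def check_non_crossing(table: PercentileTable, ages) -> dict:
    """Check that curve values are non-decreasing in tau at every grid age.

    Quantile curves fitted independently per tau can in principle cross;
    this guards the family's joint coherence.  Ties are allowed
    (tolerance 1e-9).  Returns ``{"ok": bool, "violations": [(age, (tau_lo,
    tau_hi)), ...]}``.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("age grid must be non-empty")
    if np.any(ages <= 0) or np.any(ages > AGE_MAX + 1e-6):
        raise ValueError(f"age grid must lie within (0, {AGE_MAX}]")
    taus = table.taus
    violations = []
    for age in ages:
        vals = table.curve_values(float(age))
        diffs = np.diff(vals)
        for i in np.nonzero(diffs < -1e-9)[0]:
            violations.append((float(age), (taus[i], taus[i + 1])))
    return {"ok": not violations, "violations": violations}


def score_to_percentile(table: PercentileTable, age: float, score: float) -> dict:
    """Estimate the percentile of a score at an age by inverting the family.

    Interpolation is monotone in normal-score space: each table level tau is
    mapped to z = Phi^-1(tau) and the score is interpolated linearly in z
    between the bracketing curves, consistent with reading the 16th/84th
    percentiles as one SD either side of the median.  Scores outside the
    fitted [5th, 95th] range return the boundary tau with an
    ``outside_fitted_range`` flag rather than extrapolating.

    Returns ``{"tau", "band", "outside_fitted_range", "below_min_age"}``
    with band one of :data:`BANDS`.
    """
    if not 0 < age <= AGE_MAX:
        raise ValueError(f"age {age} outside (0, {AGE_MAX}] months")
    if not 0 <= score <= SCORE_MAX:
        raise ValueError(f"score {score} outside [0, {SCORE_MAX}]")
    taus = np.asarray(table.taus)
    zs = norm.ppf(taus)
    vals = table.curve_values(age, clamp=True)
    # enforce non-decreasing values for interpolation robustness; the
    # packaged table never needs this, a crossing user table might
    vals = np.maximum.accumulate(vals)

    outside = False
    if score <= vals[0]:
        tau = float(taus[0])
        outside = score < vals[0]
    elif score >= vals[-1]:
        tau = float(taus[-1])
        outside = score > vals[-1]
    else:
        z = _interp_with_ties(score, vals, zs)
        tau = float(norm.cdf(z))

    band = _band_for(score, dict(zip(table.taus, vals)))
    return {
        "tau": tau,
        "band": band,
        "outside_fitted_range": outside,
        "below_min_age": age < table.min_age,
    }


def _interp_with_ties(x: float, xp: np.ndarray, fp: np.ndarray) -> float:
    """np.interp with exact-node lookup so ties in xp cannot blur nodes."""
    exact = np.nonzero(xp == x)[0]
    if exact.size:
        return float(fp[exact[0]])
    return float(np.interp(x, xp, fp))


def _band_for(score: float, values_by_tau: dict[float, float]) -> str:
    def val(t, default):
        return values_by_tau.get(t, default)

    if score < val(0.05, -np.inf):
        return "below-5th"
    if score < val(0.16, -np.inf):
        return "5th-16th"
    if score <= val(0.84, np.inf):
        return "16th-84th"
    if score <= val(0.95, np.inf):
        return "84th-95th"
    return "above-95th"
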