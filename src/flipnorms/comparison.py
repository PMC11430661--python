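"""Validation against binned sample percentiles and trajectory comparison.

Three consumers of a fitted or packaged percentile family:

* a rough empirical check: sample percentiles computed within 6-month age
  bins, plotted/compared at bin midpoints against the continuous curves;
* a descriptive three-segment linear fit of score against age (skills are
  acquired steeply in the first ~30 months, then progressively flatter);
* individual-child trajectory reports: per-assessment percentile band
  relative to the normative envelope (16th-84th percentiles) plus
  qualitative flags for divergence below the envelope, plateauing while
  the median climbs, and late convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from flipnorms.cohort import ChildTrajectory
from flipnorms.growth import AGE_MAX, PercentileTable, logistic_eval, score_to_percentile

__all__ = [
    "BinSummary", "ChildTrajectory", "TrajectoryReport", "FlagRules",
    "binned_sample_percentiles", "compare_bins_to_curves",
    "segmented_linear_fit", "trajectory_report",
]


@dataclass
class BinSummary:
    lo: float
    hi: float                      # bin is (lo, hi] months
    count: int
    percentiles: dict[float, float]  # empty when count < the minimum

    @property
    def midpoint(self) -> float:
        return (self.lo + self.hi) / 2.0


@dataclass
class SegmentFit:
    lo: float
    hi: float
    slope: float        # score points per month
    intercept: float
    r2: float
    n: int


@dataclass
class FlagRules:
    """Thresholds for qualitative trajectory flags.

    divergence: >= k consecutive assessments strictly below the
    16th-percentile curve.  plateau: score gain < d points over a span of
    >= m months while the median curve gains >= 2d over the same span.
    converging: the percentile band improves across the last two
    assessments.
    """

    k_consecutive: int = 2
    plateau_gain: float = 2.0      # d, score points
    plateau_span: float = 6.0      # m, months


@dataclass
class PointAssessment:
    age: float
    score: float
    tau: float
    band: str
    outside_fitted_range: bool


@dataclass
class TrajectoryReport:
    child_id: str
    points: list[PointAssessment]
    divergence: bool
    plateau: bool
    converging: bool
    plateau_intervals: list[tuple[float, float]] = field(default_factory=list)


def binned_sample_percentiles(records, taus, bin_width: float = 6.0,
                              min_count: int = 5) -> list[BinSummary]:
    """Sample percentiles of score within equal age bins over (0, 72].

    Bins are lower-open/upper-closed; ``bin_width`` must divide 72.  Sample
    percentiles use the linear order-statistic interpolation rule with
    plotting position p(k) = (k-1)/(n-1) (numpy's default). Bins holding
    fewer than ``min_count`` records carry no percentile values.
    """
    if bin_width <= 0 or AGE_MAX % bin_width != 0:
        raise ValueError(f"bin width must divide {AGE_MAX}, got {bin_width}")
    taus = list(taus)
    edges = np.arange(0.0, AGE_MAX + 1e-9, bin_width)
    out = []
    ages = np.array([r.age for r in records])
    scores = np.array([r.score for r in records])
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (ages > lo) & (ages <= hi)
        n = int(mask.sum())
        if n >= min_count:
            vals = np.quantile(scores[mask], taus)  # linear interpolation rule
            pct = dict(zip(taus, map(float, vals)))
        else:
            pct = {}
        out.append(BinSummary(lo=float(lo), hi=float(hi), count=n, percentiles=pct))
    return out


def compare_bins_to_curves(bins, table: PercentileTable) -> dict:
    """Differences (sample - fitted) at bin midpoints, per quantile level.

    Returns ``{"per_tau": {tau: {"diffs": [(midpoint, diff), ...],
    "max_abs": float}}, "max_abs": float}``; empty input gives an empty
    report.
    """
    per_tau: dict[float, dict] = {}
    overall = 0.0
    for b in bins:
        for tau, sample_val in b.percentiles.items():
            if tau not in table.entries:
                raise ValueError(f"bin quantile level {tau} absent from the table")
            fitted = float(logistic_eval(table.entries[tau], b.midpoint))
            diff = sample_val - fitted
            entry = per_tau.setdefault(tau, {"diffs": [], "max_abs": 0.0})
            entry["diffs"].append((b.midpoint, diff))
            entry["max_abs"] = max(entry["max_abs"], abs(diff))
            overall = max(overall, abs(diff))
    return {"per_tau": per_tau, "max_abs": overall}


def segmented_linear_fit(records, breakpoints=(30.0, 54.0)) -> list[SegmentFit]:
    """Independent least-squares line per age segment.

    Default segments (0, 30], (30, 54], (54, 72] months, the descriptive
    early/middle/late split of the acquisition trajectory.  Each segment
    needs >= 3 records; an empty or undersized segment raises naming it.
    """
    bps = sorted(breakpoints)
    edges = [0.0] + [float(b) for b in bps] + [AGE_MAX]
    ages = np.array([r.age for r in records])
    scores = np.array([r.score for r in records])
    fits = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (ages > lo) & (ages <= hi)
        n = int(mask.sum())
        if n < 3:
            raise ValueError(
                f"segment ({lo:g}, {hi:g}] months holds {n} record(s); >= 3 required")
        x, y = ages[mask], scores[mask]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        fits.append(SegmentFit(lo=lo, hi=hi, slope=float(slope),
                               intercept=float(intercept), r2=r2, n=n))
    return fits


def trajectory_report(trajectory: ChildTrajectory, table: PercentileTable,
                      rules: FlagRules | None = None) -> TrajectoryReport:
    """Compare one child's trajectory with the normative envelope.

    Each assessment gets a percentile estimate and band (via
    :func:`flipnorms.growth.score_to_percentile`); trend flags follow
    :class:`FlagRules`.  Single-point trajectories get bands but no trend
    flags.
    """
    rules = rules or FlagRules()
    pts = []
    for age, score in trajectory.points:
        res = score_to_percentile(table, age, score)
        pts.append(PointAssessment(age=age, score=score, tau=res["tau"],
                                   band=res["band"],
                                   outside_fitted_range=res["outside_fitted_range"]))

    # divergence: k consecutive assessments strictly below the 16th curve
    divergence = False
    if 0.16 in table.entries and len(pts) >= rules.k_consecutive:
        below = [p.score < float(logistic_eval(table.entries[0.16], p.age))
                 for p in pts]
        run = 0
        for flag in below:
            run = run + 1 if flag else 0
            if run >= rules.k_consecutive:
                divergence = True
                break

    # plateau: child nearly flat over >= m months while the median climbs
    plateau = False
    plateau_intervals: list[tuple[float, float]] = []
    if 0.5 in table.entries and len(pts) >= 2:
        med = table.entries[0.5]
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                span = pts[j].age - pts[i].age
                if span < rules.plateau_span:
                    continue
                child_gain = pts[j].score - pts[i].score
                median_gain = float(logistic_eval(med, pts[j].age)
                                    - logistic_eval(med, pts[i].age))
                if child_gain < rules.plateau_gain and median_gain >= 2 * rules.plateau_gain:
                    plateau = True
                    plateau_intervals.append((pts[i].age, pts[j].age))

    converging = False
    if len(pts) >= 2:
        order = {b: i for i, b in enumerate(
            ("below-5th", "5th-16th", "16th-84th", "84th-95th", "above-95th"))}
        prev, last = pts[-2], pts[-1]
        converging = order[last.band] > order[prev.band]

    return TrajectoryReport(child_id=trajectory.child_id, points=pts,
                            divergence=divergence, plateau=plateau,
                            converging=converging,
                            plateau_intervals=_merge_intervals(plateau_intervals))


def _merge_intervals(intervals):
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(m) for m in merged]
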