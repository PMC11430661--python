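"""Nonlinear quantile regression for logistic percentile growth curves.

The conditional tau-quantile of score given age is modelled as the
four-parameter logistic of :mod:`flipnorms.growth` and estimated by direct
minimisation of the quantile-regression check (pinball) loss

    L_tau(r) = sum_i r_i * (tau - 1[r_i < 0]),    r_i = y_i - q(x_i)

over the parameter box.  The loss is piecewise linear in the residuals and
non-smooth, so optimisation is derivative-free: bounded Nelder-Mead simplex
restarted from deterministic jittered perturbations of a moment-based
initial guess.  The upper asymptote is bounded at the instrument maximum
(64 score points); for high percentiles that bound is typically active.

The estimation surface follows the scikit-learn protocol:
:class:`LogisticQuantileRegressor` fits one quantile level,
:class:`PercentileGrowthModel` a whole percentile family.  The module-level
functions (:func:`fit_quantile_curve`, :func:`fit_all_percentiles`) are
thin wrappers over the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from flipnorms.growth import AGE_MAX, SCORE_MAX, DEFAULT_TAUS, LogisticParams, PercentileTable, check_non_crossing

#: default parameter box: a1, a2, a3, a4 (a2 additionally >= a1 + 1)
DEFAULT_BOUNDS = ((-40.0, 30.0), (1.0, 64.0), (1e-4, 1.0), (1.0, 60.0))

_MIN_RECORDS = 20
_MIN_AGE_SPAN = 12.0


class FitDataError(ValueError):
    """Too few records or degenerate age span for curve fitting."""


@dataclass(frozen=True)
class CohortRecord:
    """One child's cross-sectional observation: age (months) and score.

    Scores are integers for real assessments; continuous values are allowed
    for synthetic validation data.
    """

    child_id: str
    age: float
    score: float

    def __post_init__(self) -> None:
        if not 0 < self.age <= AGE_MAX:
            raise ValueError(f"age {self.age} outside (0, {AGE_MAX}] months")
        if not 0 <= self.score <= SCORE_MAX:
            raise ValueError(f"score {self.score} outside [0, {SCORE_MAX}]")


@dataclass
class FitResult:
    tau: float
    params: LogisticParams
    loss: float
    n: int
    converged: bool
    starts_used: int


def pinball_loss(residuals, tau: float) -> float:
    """Quantile-regression check loss sum r*(tau - 1[r<0]).

    Zero iff every residual is zero; minimised in expectation when the
    fitted value is the conditional tau-quantile.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(r * (tau - (r < 0))))


def _logistic(theta: np.ndarray, ages: np.ndarray) -> np.ndarray:
    a1, a2, a3, a4 = theta
    return a1 + (a2 - a1) / (1.0 + np.exp(-a3 * (ages - a4)))


def _records_to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    ages = np.array([r.age for r in records], dtype=float)
    scores = np.array([r.score for r in records], dtype=float)
    return ages, scores


def _moment_start(ages: np.ndarray, scores: np.ndarray, bounds) -> np.ndarray:
    """Moment-based initial guess for the logistic parameters.

    a2 from the top of the observed scores, a1 from the bottom, a4 the age
    nearest the half-range score, a3 from the classic logistic slope
    relation slope = a3*(a2-a1)/4 at the inflection.
    """
    a2 = float(np.max(scores))
    a1 = float(np.min(scores))
    if a2 - a1 < 1.0:
        a2 = a1 + 1.0
    half = (a1 + a2) / 2.0
    a4 = float(ages[np.argmin(np.abs(scores - half))])
    lo, hi = float(np.min(ages)), float(np.max(ages))
    span = max(hi - lo, 1.0)
    slope = (a2 - a1) / span
    a3 = 4.0 * slope / max(a2 - a1, 1.0)
    theta = np.array([a1, a2, a3, a4])
    return _clip_to_bounds(theta, bounds)


def _clip_to_bounds(theta: np.ndarray, bounds) -> np.ndarray:
    out = np.array([np.clip(v, b[0], b[1]) for v, b in zip(theta, bounds)])
    if out[1] < out[0] + 1.0:  # keep a2 >= a1 + 1
        out[1] = min(out[0] + 1.0, bounds[1][1])
        out[0] = min(out[0], out[1] - 1.0)
    return out


class LogisticQuantileRegressor(RegressorMixin, BaseEstimator):
    """Single-quantile four-parameter logistic growth-curve regressor.

    Parameters
    ----------
    tau : float, default=0.5
        Quantile level in (0, 1).
    bounds : tuple of 4 (lo, hi) pairs, optional
        Parameter box for (a1, a2, a3, a4); the fit additionally enforces
        a2 >= a1 + 1.  Defaults bound a2 at the instrument maximum 64.
    n_starts : int, default=16
        Number of deterministic jittered restarts around the moment-based
        initial guess.
    random_state : int, default=0
        Seed for the jittered starts; fits are bit-reproducible given
        identical data, parameters and seed.
    max_fev : int, default=2000
        Function-evaluation cap per local search.
    tol : float, default=1e-8
        Absolute loss-change convergence tolerance of each local search.

    Attributes
    ----------
    params_ : LogisticParams
        Fitted curve parameters.
    loss_ : float
        Final pinball loss at ``params_``.
    converged_ : bool
        True when at least one local search met the tolerance.
    n_features_in_ : int
    """

    def __init__(self, tau: float = 0.5, bounds=None, n_starts: int = 16,
                 random_state: int = 0, max_fev: int = 2000, tol: float = 1e-8):
        self.tau = tau
        self.bounds = bounds
        self.n_starts = n_starts
        self.random_state = random_state
        self.max_fev = max_fev
        self.tol = tol

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be a single column of ages in months")
        y = np.asarray(y, dtype=float)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        return X, y

    def fit(self, X, y):
        """Fit the curve to ages ``X`` (n, 1) and scores ``y``."""
        if not 0 < self.tau < 1:
            raise ValueError(f"tau must lie in (0, 1), got {self.tau}")
        X, y = self._validate(X, y)
        ages, scores = X[:, 0], y
        if ages.size < _MIN_RECORDS:
            raise FitDataError(
                f"need >= {_MIN_RECORDS} records to fit, got {ages.size}")
        if np.ptp(ages) < _MIN_AGE_SPAN:
            raise FitDataError(
                f"age span {np.ptp(ages):.2f} months < required {_MIN_AGE_SPAN}")
        bounds = tuple(self.bounds) if self.bounds is not None else DEFAULT_BOUNDS

        def objective(theta):
            if theta[1] < theta[0] + 1.0:  # a2 > a1 constraint as penalty
                return 1e12 + 1e6 * (theta[0] + 1.0 - theta[1])
            return pinball_loss(scores - _logistic(theta, ages), self.tau)

        theta0 = _moment_start(ages, scores, bounds)
        rng = np.random.default_rng(self.random_state)
        widths = np.array([b[1] - b[0] for b in bounds])
        starts = [theta0]
        for _ in range(max(self.n_starts - 1, 0)):
            jitter = rng.normal(scale=0.10, size=4) * widths
            starts.append(_clip_to_bounds(theta0 + jitter, bounds))

        best = None
        converged = False
        for start in starts:
            res = minimize(
                objective, start, method="Nelder-Mead", bounds=bounds,
                options={"fatol": self.tol, "xatol": 1e-8,
                         "maxfev": self.max_fev, "maxiter": self.max_fev},
            )
            if best is None or res.fun < best.fun:
                best = res
            converged = converged or bool(res.success)
        theta = _clip_to_bounds(best.x, bounds)
        self.params_ = LogisticParams(*theta)
        self.loss_ = float(objective(theta))
        self.converged_ = converged
        self.n_starts_used_ = len(starts)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Evaluate the fitted quantile curve at ages ``X``."""
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return _logistic(self.params_.as_array(), X[:, 0])


class PercentileGrowthModel(BaseEstimator):
    """Family of independently fitted percentile curves.

    Fits one :class:`LogisticQuantileRegressor` per quantile level
    (mirroring per-percentile estimation with no joint non-crossing
    constraint) and reports a non-crossing diagnostic on the fitted family.

    Attributes
    ----------
    table_ : PercentileTable
        The fitted percentile parameter table.
    results_ : dict tau -> FitResult
    failures_ : dict tau -> str, fit errors for levels that failed
    non_crossing_ : dict
        Report of :func:`flipnorms.growth.check_non_crossing` on a
        0.5-month grid.
    """

    def __init__(self, taus=DEFAULT_TAUS, bounds=None, n_starts: int = 16,
                 random_state: int = 0, max_fev: int = 2000, tol: float = 1e-8,
                 min_age: float = 3.0):
        self.taus = taus
        self.bounds = bounds
        self.n_starts = n_starts
        self.random_state = random_state
        self.max_fev = max_fev
        self.tol = tol
        self.min_age = min_age

    def fit(self, X, y):
        taus = list(self.taus)
        if not taus:
            raise ValueError("need at least one quantile level")
        if sorted(set(taus)) != taus:
            raise ValueError("quantile levels must be strictly increasing")
        self.results_ = {}
        self.failures_ = {}
        entries = {}
        for i, tau in enumerate(taus):
            est = LogisticQuantileRegressor(
                tau=tau, bounds=self.bounds, n_starts=self.n_starts,
                random_state=self.random_state + i, max_fev=self.max_fev,
                tol=self.tol)
            try:
                est.fit(X, y)
            except (FitDataError, ValueError) as exc:
                self.failures_[tau] = str(exc)
                continue
            entries[tau] = est.params_
            self.results_[tau] = FitResult(
                tau=tau, params=est.params_, loss=est.loss_,
                n=np.asarray(X).shape[0], converged=est.converged_,
                starts_used=est.n_starts_used_)
        if not entries:
            raise FitDataError(f"every quantile level failed: {self.failures_}")
        self.table_ = PercentileTable(entries=dict(sorted(entries.items())),
                                      min_age=self.min_age)
        grid = np.arange(max(self.min_age, 0.5), AGE_MAX + 1e-9, 0.5)
        self.non_crossing_ = check_non_crossing(self.table_, grid)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Curve values at ages ``X``; shape (n_ages, n_taus), tau order."""
        check_is_fitted(self, "table_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return np.column_stack(
            [_logistic(p.as_array(), X[:, 0]) for p in self.table_.entries.values()])


def fit_quantile_curve(records, tau: float, bounds=None, n_starts: int = 16,
                       seed: int = 0, max_fev: int = 2000,
                       tol: float = 1e-8) -> FitResult:
    """Fit one percentile curve to cohort records; see
    :class:`LogisticQuantileRegressor`."""
    ages, scores = _records_to_arrays(records)
    est = LogisticQuantileRegressor(
        tau=tau, bounds=bounds, n_starts=n_starts, random_state=seed,
        max_fev=max_fev, tol=tol).fit(ages[:, None], scores)
    return FitResult(tau=tau, params=est.params_, loss=est.loss_,
                     n=ages.size, converged=est.converged_,
                     starts_used=est.n_starts_used_)


def fit_all_percentiles(records, taus=DEFAULT_TAUS, bounds=None,
                        n_starts: int = 16, seed: int = 0, max_fev: int = 2000,
                        tol: float = 1e-8, min_age: float = 3.0):
    """Fit a percentile family; returns (PercentileTable, per-tau FitResults,
    non-crossing report, per-tau failures)."""
    ages, scores = _records_to_arrays(records)
    model = PercentileGrowthModel(
        taus=taus, bounds=bounds, n_starts=n_starts, random_state=seed,
        max_fev=max_fev, tol=tol, min_age=min_age).fit(ages[:, None], scores)
    return model.table_, model.results_, model.non_crossing_, model.failures_


def brute_force_fit(records, tau: float, grid) -> tuple[LogisticParams, float]:
    """Exhaustive pinball-loss minimisation over a Cartesian parameter grid.

    A testing oracle: slow but unambiguous.  ``grid`` is a sequence of four
    value lists for (a1, a2, a3, a4); ties break by first-in-enumeration
    order, a1 varying slowest.  Grid size is capped at 10^6 points.
    """
    grid = [np.asarray(g, dtype=float) for g in grid]
    if len(grid) != 4:
        raise ValueError("grid must list values for each of the 4 parameters")
    size = int(np.prod([g.size for g in grid]))
    if size > 10**6:
        raise ValueError(f"grid of {size} points exceeds the 10^6 cap")
    ages, scores = _records_to_arrays(records)
    best_theta, best_loss = None, np.inf
    for a1 in grid[0]:
        for a2 in grid[1]:
            if a2 <= a1:
                continue
            for a3 in grid[2]:
                for a4 in grid[3]:
                    theta = np.array([a1, a2, a3, a4])
                    loss = pinball_loss(scores - _logistic(theta, ages), tau)
                    if loss < best_loss:
                        best_theta, best_loss = theta, loss
    if best_theta is None:
        raise ValueError("grid contains no admissible point (need a2 > a1)")
    return LogisticParams(*best_theta), float(best_loss)
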