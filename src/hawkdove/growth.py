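"""Sigmoid growth-curve fitting, model selection, and phase partitioning.

Abundance time series (qPCR-scale, monoculture or co-culture) are fitted
with the three classic sigmoid growth equations in their Zwietering
re-parameterization, whose parameters are directly interpretable:

* ``A``     — asymptotic abundance,
* ``mu_m``  — maximum specific growth rate (slope at the inflection,
  abundance per hour),
* ``lam``   — lag time (hours), the intercept of the inflection tangent
  with the baseline,
* ``nu``    — shape parameter (Richards only; ``nu = 1`` recovers the
  logistic curve exactly).

Model forms::

    gompertz:  N(t) = A * exp(-exp(mu_m*e/A * (lam - t) + 1))
    logistic:  N(t) = A / (1 + exp(4*mu_m/A * (lam - t) + 2))
    richards:  N(t) = A * (1 + nu * exp(1+nu)
                             * exp(mu_m/A * (1+nu)**(1+1/nu) * (lam - t))
                          ) ** (-1/nu)

The fitted curve splits the observation window into three phases: the lag
phase ``[t_min, lam]``, the linear (exponential-to-linear) phase
``(lam, t95]``, and the asymptotic phase ``(t95, t_max]``, where ``t95`` is
the fitted time of reaching 95% of ``A`` (fraction configurable).

Usage follows the Model -> fit() -> Results pattern::

    model = GrowthCurveModel(times, values, model="logistic")
    res = model.fit()
    res.A, res.mu_m, res.lam, res.rss
    print(res.summary())
    part = partition_phases(res)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

_E = np.e
_MODELS = ("gompertz", "logistic", "richards")

#: Default fraction of the asymptote marking the linear -> asymptotic boundary.
PHASE_CUTOFF_DEFAULT = 0.95


class FitError(RuntimeError):
    """Growth-curve fit failed to converge; carries the best attempt."""

    def __init__(self, message, best_params=None, best_rss=None):
        super().__init__(message)
        self.best_params = best_params
        self.best_rss = best_rss


class DegenerateSeriesError(FitError):
    """Series carries no growth signal (constant or near-constant)."""


@dataclass(frozen=True)
class AbundanceSeries:
    """One strain's abundance trajectory under one culture condition."""

    times: np.ndarray
    values: np.ndarray
    strain_id: str = ""
    condition: str = "monoculture"  # or "coculture"
    pair_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if len(t) < 6:
            raise ValueError(
                f"series {self.strain_id!r}/{self.condition!r} has {len(t)} points; "
                "at least 6 are required for growth-curve fitting"
            )
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"times must be strictly increasing for series "
                f"{self.strain_id!r}/{self.condition!r}"
            )
        if np.any(v <= 0):
            raise ValueError(
                f"abundances must be positive for series "
                f"{self.strain_id!r}/{self.condition!r}"
            )


def _clip_exp(z):
    return np.exp(np.clip(z, -700.0, 700.0))


def gompertz(t, A, mu_m, lam):
    return A * _clip_exp(-_clip_exp(mu_m * _E / A * (lam - t) + 1.0))


def logistic(t, A, mu_m, lam):
    return A / (1.0 + _clip_exp(4.0 * mu_m / A * (lam - t) + 2.0))


def richards(t, A, mu_m, lam, nu):
    expo = mu_m / A * (1.0 + nu) ** (1.0 + 1.0 / nu) * (lam - t)
    return A * (1.0 + nu * _clip_exp(1.0 + nu) * _clip_exp(expo)) ** (-1.0 / nu)


_CURVES = {"gompertz": gompertz, "logistic": logistic, "richards": richards}
_NPARAMS = {"gompertz": 3, "logistic": 3, "richards": 4}


class GrowthCurveModel:
    """Least-squares sigmoid growth model for one abundance series.

    Parameters
    ----------
    times, values
        Sampling times (hours, strictly increasing) and positive abundances;
        alternatively pass an :class:`AbundanceSeries` via
        :meth:`from_series`.
    model
        "gompertz", "logistic" or "richards".
    log_scale
        Fit on log-abundance instead of raw abundance (default False:
        unweighted least squares on the raw scale).
    """

    def __init__(self, times, values, model="logistic", log_scale=False):
        if model not in _MODELS:
            raise ValueError(f"unknown model {model!r}; choose from {_MODELS}")
        self.series = AbundanceSeries(np.asarray(times, float), np.asarray(values, float))
        self.model = model
        self.log_scale = bool(log_scale)

    @classmethod
    def from_series(cls, series: AbundanceSeries, model="logistic", log_scale=False):
        m = cls.__new__(cls)
        m.series = series
        if model not in _MODELS:
            raise ValueError(f"unknown model {model!r}; choose from {_MODELS}")
        m.model = model
        m.log_scale = bool(log_scale)
        return m

    # -- initialization ----------------------------------------------------
    def _initial_guess(self):
        t, v = self.series.times, self.series.values
        A0 = float(np.max(v))
        slopes = np.diff(v) / np.diff(t)
        i = int(np.argmax(slopes))
        mu0 = max(float(slopes[i]), 1e-8)
        t_mid = 0.5 * (t[i] + t[i + 1])
        v_mid = 0.5 * (v[i] + v[i + 1])
        # intercept of the max-slope tangent with the baseline (min value)
        lam0 = t_mid - (v_mid - float(np.min(v))) / mu0
        lam0 = float(np.clip(lam0, 0.0, t[-1]))
        return A0, mu0, lam0

    def _residuals(self, params):
        curve = _CURVES[self.model]
        pred = curve(self.series.times, *params)
        if self.log_scale:
            return np.log(np.maximum(pred, 1e-300)) - np.log(self.series.values)
        return pred - self.series.values

    def fit(self, n_restarts: int = 5, seed: int = 0, xtol: float = 1e-12) -> "GrowthResults":
        """Multi-start bounded least squares; deterministic given ``seed``.

        Raises
        ------
        DegenerateSeriesError
            If the series is (near-)constant: no growth signal to fit.
        FitError
            If no start converges; carries the best attempt found.
        """
        t, v = self.series.times, self.series.values
        k = _NPARAMS[self.model]
        if len(t) <= k:
            raise ValueError(
                f"{len(t)} points cannot identify a {k}-parameter {self.model} fit"
            )
        spread = np.max(v) - np.min(v)
        if spread < 1e-12 * max(np.max(v), 1.0):
            raise DegenerateSeriesError(
                f"series {self.series.strain_id!r} is constant at {v[0]:.6g}; "
                "growth parameters are unidentifiable (mu_m -> 0)"
            )

        A0, mu0, lam0 = self._initial_guess()
        base = [A0, mu0, lam0] + ([1.0] if self.model == "richards" else [])
        lo = [1e-12 * A0, 1e-12, 0.0] + ([1e-3] if self.model == "richards" else [])
        hi = [10.0 * A0, np.inf, t[-1]] + ([50.0] if self.model == "richards" else [])

        rng = np.random.default_rng(seed)
        starts = [np.array(base)]
        for _ in range(n_restarts):
            jit = np.array(base) * rng.uniform(0.5, 1.5, size=len(base))
            starts.append(np.clip(jit, np.array(lo) * 1.01 + 1e-12, None))

        best = None
        for p0 in starts:
            try:
                sol = least_squares(
                    self._residuals, p0, bounds=(lo, hi), xtol=xtol, ftol=1e-14,
                    gtol=1e-12, max_nfev=2000,
                )
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if sol.success and (best is None or rss < best[1]):
                best = (sol.x, rss)
        if best is None:
            raise FitError(
                f"{self.model} fit failed to converge for series "
                f"{self.series.strain_id!r} after {len(starts)} starts"
            )
        params, rss = best
        return GrowthResults(self, params, rss)


class GrowthResults:
    """Converged growth-curve fit: parameters, fit quality, phase boundaries."""

    def __init__(self, model: GrowthCurveModel, params: np.ndarray, rss: float):
        self.model_obj = model
        self.model = model.model
        self.params = np.asarray(params, float)
        self.rss = float(rss)
        self.nobs = len(model.series.times)
        self.selection_criterion: str | None = None

    # -- named parameters --------------------------------------------------
    @property
    def A(self) -> float:
        return float(self.params[0])

    @property
    def mu_m(self) -> float:
        return float(self.params[1])

    @property
    def lam(self) -> float:
        return float(self.params[2])

    @property
    def nu(self) -> float | None:
        return float(self.params[3]) if self.model == "richards" else None

    @property
    def k_params(self) -> int:
        return _NPARAMS[self.model]

    @property
    def aicc(self) -> float:
        """Small-sample AIC with Gaussian errors; k counts sigma^2 too."""
        n, k = self.nobs, self.k_params + 1
        aic = n * np.log(max(self.rss, 1e-300) / n) + 2 * k
        if n - k - 1 <= 0:
            return np.inf
        return float(aic + 2 * k * (k + 1) / (n - k - 1))

    def predict(self, t) -> np.ndarray:
        return _CURVES[self.model](np.asarray(t, float), *self.params)

    def t_at_fraction(self, frac: float = PHASE_CUTOFF_DEFAULT) -> float:
        """Fitted time of reaching ``frac * A``; +inf if never within reach.

        Solved by bracketed root-finding on the fitted curve (the Zwietering
        forms are strictly increasing, so the root is unique).
        """
        target = frac * self.A
        t0 = self.model_obj.series.times[0]

        def f(t):
            return float(self.predict(t) - target)

        if f(t0) >= 0:
            return float(t0)
        hi = max(self.lam, t0) + 1.0
        for _ in range(200):
            if f(hi) > 0:
                break
            hi = t0 + 2.0 * (hi - t0)
        else:
            return np.inf
        return float(brentq(f, t0, hi, xtol=1e-10))

    def summary(self) -> str:
        lines = [
            "Growth-curve fit",
            "=" * 46,
            f"model:          {self.model}",
            f"n observations: {self.nobs}",
            f"A (asymptote):  {self.A:.6g}",
            f"mu_m (max rate):{self.mu_m:.6g} /h",
            f"lam (lag):      {self.lam:.6g} h",
        ]
        if self.nu is not None:
            lines.append(f"nu (shape):     {self.nu:.6g}")
        lines += [
            f"RSS:            {self.rss:.6g}",
            f"AICc:           {self.aicc:.6g}",
        ]
        if self.selection_criterion:
            lines.append(f"selected by:    {self.selection_criterion}")
        return "\n".join(lines)


def fit_growth(series: AbundanceSeries, model="logistic", log_scale=False,
               n_restarts=5, seed=0) -> GrowthResults:
    """Convenience wrapper: build a :class:`GrowthCurveModel` and fit it."""
    return GrowthCurveModel.from_series(series, model=model, log_scale=log_scale).fit(
        n_restarts=n_restarts, seed=seed
    )


def fit_all_models(series: AbundanceSeries, **kw) -> dict[str, GrowthResults]:
    """Fit every model that converges; at least one must."""
    fits = {}
    for m in _MODELS:
        try:
            fits[m] = fit_growth(series, model=m, **kw)
        except FitError:
            continue
    if not fits:
        raise FitError(f"no growth model converged for series {series.strain_id!r}")
    return fits


def select_model(fits: dict[str, GrowthResults], alpha: float = 0.05) -> GrowthResults:
    """Choose the best fit: extra-sum-of-squares F-test for nested pairs,
    AICc for non-nested ones, parsimony on ties.

    Logistic and Gompertz (3 parameters each) are compared by AICc; the
    winner is then tested against Richards (which nests the logistic at
    nu = 1 and is treated as the general alternative) with a one-extra-
    parameter F-test at level ``alpha``.  Identical RSS always resolves to
    the model with fewer parameters.
    """
    from scipy.stats import f as f_dist

    if not fits:
        raise ValueError("no successful fits to select among")
    three = [fits[m] for m in ("logistic", "gompertz") if m in fits]
    rich = fits.get("richards")

    # AICc ranks the equal-parameter pair; name breaks exact ties deterministically
    best3 = min(three, key=lambda r: (r.aicc, r.k_params, r.model)) if three else None

    if best3 is None:
        rich.selection_criterion = "only converged model"
        return rich
    if rich is None:
        best3.selection_criterion = "AICc among 3-parameter models"
        return best3

    if rich.rss >= best3.rss:
        best3.selection_criterion = "parsimony (Richards gains no RSS)"
        return best3

    n = best3.nobs
    df2 = n - rich.k_params
    if df2 <= 0 or rich.rss <= 0:
        best3.selection_criterion = "parsimony (F-test undefined)"
        return best3
    F = (best3.rss - rich.rss) / 1.0 / (rich.rss / df2)
    p = float(f_dist.sf(F, 1, df2))
    if p < alpha:
        rich.selection_criterion = f"extra-SS F-test (F={F:.3g}, p={p:.3g} < {alpha})"
        return rich
    best3.selection_criterion = f"extra-SS F-test (F={F:.3g}, p={p:.3g} >= {alpha})"
    return best3


@dataclass(frozen=True)
class PhasePartition:
    """Lag / linear / asymptotic phase boundaries and per-time labels."""

    t_lag_end: float  # = fitted lag time lam
    t_linear_end: float  # = t at cutoff fraction of A (may be +inf)
    labels: np.ndarray = field(repr=False)  # one of "lag","linear","asymptotic" per time
    times: np.ndarray = field(repr=False)

    def counts(self) -> dict:
        lab, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))


def partition_phases(fit: GrowthResults, cutoff: float = PHASE_CUTOFF_DEFAULT) -> PhasePartition:
    """Label every observation time with exactly one growth phase.

    lag = [t_min, lam]; linear = (lam, t95]; asymptotic = (t95, t_max],
    where t95 is the fitted time of reaching ``cutoff * A``.  If the curve
    never reaches the cutoff inside the window the asymptotic phase is
    empty and a warning is issued.
    """
    t = fit.model_obj.series.times
    t95 = fit.t_at_fraction(cutoff)
    if not np.isfinite(t95) or t95 > t[-1]:
        warnings.warn(
            f"fitted curve reaches {cutoff:.0%} of A at t={t95:.3g}, beyond the "
            f"observation window (t_max={t[-1]:.3g}); asymptotic phase is empty",
            stacklevel=2,
        )
    labels = np.where(t <= fit.lam, "lag", np.where(t <= t95, "linear", "asymptotic"))
    return PhasePartition(t_lag_end=float(fit.lam), t_linear_end=float(t95),
                          labels=labels, times=t)
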