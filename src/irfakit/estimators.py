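"""The two competing extrapolation methods for the immunoreactive fraction.

Both estimate ``(r, K_D)`` from bound fractions measured along an
antigen series and extrapolate ``r`` to infinite antigen excess:

* :class:`HyperbolaBinding` — unconstrained nonlinear least squares of
  the rectangular hyperbola ``B/T = r*ag0/(ag0 + KD)`` on the raw data;
* :class:`LindmoBinding` — ordinary least squares on the double-inverse
  (Lindmo) transform ``T/B = 1/r + (KD/r)/ag0``; the y-intercept gives
  ``1/r`` and the slope times ``r`` gives ``K_D``.

Both are scikit-learn regressors (``fit(X, y)`` with ``X`` the antigen
concentrations as a single column, ``predict`` on the bound-fraction
scale) and compose with sklearn pipelines and model selection.  Fits are
unconstrained on purpose: estimates above 100% or negative are the
diagnostic signal this package studies, so they are reported as-is and
flagged, never clipped.

The functional wrappers :func:`fit_hyperbola` and :func:`fit_lindmo`
return a :class:`FitResult` record; :func:`apply_exclusion` implements
the stepwise deletion of low-antigen points that the Lindmo method
needs on nonequilibrium data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .binding import BindingParameters, CurvePoint, lindmo_transform
from .kinetics import KineticSettings, build_antigen_series, distort_grid
from .binding import generate_ideal_grid

__all__ = [
    "FitResult",
    "ExclusionPolicy",
    "HyperbolaBinding",
    "LindmoBinding",
    "fit_hyperbola",
    "fit_lindmo",
    "apply_exclusion",
    "r_vs_time",
    "EXCLUSION_THRESHOLDS",
]

#: Stepwise low-antigen exclusion thresholds studied (nM); None = no exclusion.
EXCLUSION_THRESHOLDS: tuple[float | None, ...] = (None, 1.25, 2.5, 5.0)

#: r-hat beyond which an estimate is flagged implausible (fraction units).
_IMPLAUSIBLE_R = 1.25


@dataclass(frozen=True)
class ExclusionPolicy:
    """Drop curve points with ag0 at or below ``threshold`` (nM)."""

    threshold: float | None = None


@dataclass(frozen=True)
class FitResult:
    """Outcome of one extrapolation fit.

    ``r_hat`` may exceed 1 or be negative; ``flagged`` marks estimates
    that are physically impossible or come from a failed fit.
    """

    method: str
    r_hat: float
    kd_hat: float
    exclusion_threshold: float | None
    n_points_used: int
    n_points_dropped: int
    rss: float
    converged: bool

    @property
    def flagged(self) -> bool:
        bad = (
            not self.converged
            or not math.isfinite(self.r_hat)
            or not math.isfinite(self.kd_hat)
            or self.r_hat <= 0
            or self.r_hat > _IMPLAUSIBLE_R
        )
        return bad

    @property
    def r_percent(self) -> float:
        return 100.0 * self.r_hat

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "r_hat_percent": round(self.r_percent),
            "kd_hat_nM": float(f"{self.kd_hat:.3g}") if math.isfinite(self.kd_hat) else np.nan,
            "exclusion_nM": self.exclusion_threshold,
            "n_used": self.n_points_used,
            "n_dropped": self.n_points_dropped,
            "rss": self.rss,
            "converged": self.converged,
            "flagged": self.flagged,
        }


def _as_xy(points: Sequence[CurvePoint]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([p.ag0 for p in points], dtype=float)
    y = np.array([p.bound_fraction for p in points], dtype=float)
    return x, y


class HyperbolaBinding(RegressorMixin, BaseEstimator):
    """Rectangular-hyperbola saturation fit (Langmuir isotherm).

    Unconstrained Levenberg-Marquardt least squares of
    ``y = r*x/(x + KD)``.  Initialization: ``r`` at the maximum observed
    bound fraction and ``KD`` at the first antigen level whose bound
    fraction exceeds half of it (median antigen level as fallback).

    Parameters
    ----------
    r_init, kd_init : float or None
        Optional starting values overriding the data-driven defaults.
    max_iter : int
        Function-evaluation budget for the optimizer.
    tol : float
        Relative convergence tolerance on parameters and residuals.

    Attributes
    ----------
    r_ : float
        Estimated immunoreactive fraction (may exceed 1).
    kd_ : float
        Estimated dissociation constant (nM).
    rss_ : float
        Residual sum of squares on the training points.
    converged_ : bool
        Whether the optimizer reported success.
    """

    def __init__(
        self,
        r_init: float | None = None,
        kd_init: float | None = None,
        max_iter: int = 10000,
        tol: float = 1e-10,
    ):
        self.r_init = r_init
        self.kd_init = kd_init
        self.max_iter = max_iter
        self.tol = tol

    @staticmethod
    def _model(x, r, kd):
        return r * x / (x + kd)

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        if X.shape[1] != 1:
            raise ValueError("X must be a single column of antigen concentrations (nM)")
        x = X[:, 0]
        if np.unique(x).size < 2:
            raise ValueError("need at least 2 distinct antigen concentrations")
        r0 = self.r_init if self.r_init is not None else float(np.max(y))
        if r0 <= 0:
            r0 = 0.5
        if self.kd_init is not None:
            kd0 = self.kd_init
        else:
            above = np.nonzero(y > r0 / 2)[0]
            kd0 = float(x[above[0]]) if above.size else float(np.median(x))
        try:
            popt, _, infodict, _, ier = curve_fit(
                self._model,
                x,
                y,
                p0=[r0, kd0],
                method="lm",
                maxfev=self.max_iter,
                xtol=self.tol,
                ftol=self.tol,
                full_output=True,
            )
            self.converged_ = ier in (1, 2, 3, 4)
            self.r_, self.kd_ = float(popt[0]), float(popt[1])
            self.rss_ = float(np.sum(infodict["fvec"] ** 2))
        except RuntimeError:
            self.converged_ = False
            self.r_, self.kd_, self.rss_ = np.nan, np.nan, np.nan
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "r_")
        X = check_array(X)
        return self._model(X[:, 0], self.r_, self.kd_)


class LindmoBinding(RegressorMixin, BaseEstimator):
    """Double-inverse (Lindmo) linear extrapolation.

    Transforms each point to ``(1/ag0, T/B)`` and fits an ordinary
    least-squares line; ``r = 1/intercept`` and ``KD = slope/intercept``.
    Points with nonpositive bound fraction have no reciprocal and are
    dropped (counted in ``n_dropped_``).  The regression is unweighted:
    the transform silently assumes a constant coefficient of variation,
    and propagating that assumption is precisely what makes this method
    fragile at low bound fractions.

    Attributes
    ----------
    r_, kd_ : float
        Back-transformed estimates (negative intercepts give negative
        ``r_``; reported, not clipped).
    intercept_, slope_ : float
        The fitted line in transformed coordinates.
    n_dropped_ : int
        Points excluded for nonpositive bound fraction.
    rss_ : float
        Residual sum of squares in transformed coordinates.
    """

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        if X.shape[1] != 1:
            raise ValueError("X must be a single column of antigen concentrations (nM)")
        points = [CurvePoint(a, b) for a, b in zip(X[:, 0], y)]
        pairs, dropped = lindmo_transform(points)
        self.n_dropped_ = dropped
        if len(pairs) < 2:
            raise ValueError("fewer than 2 points with positive bound fraction")
        inv_ag = np.array([p[0] for p in pairs])
        inv_bf = np.array([p[1] for p in pairs])
        slope, intercept = np.polyfit(inv_ag, inv_bf, 1)
        self.slope_, self.intercept_ = float(slope), float(intercept)
        resid = inv_bf - (slope * inv_ag + intercept)
        self.rss_ = float(np.sum(resid**2))
        if intercept == 0:
            self.r_, self.kd_ = np.nan, np.nan
            self.converged_ = False
        else:
            self.r_ = 1.0 / intercept
            self.kd_ = slope / intercept
            self.converged_ = True
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "r_")
        X = check_array(X)
        return self.r_ * X[:, 0] / (X[:, 0] + self.kd_)


def _result_from(est, method: str, threshold: float | None, n_used: int, n_dropped: int) -> FitResult:
    return FitResult(
        method=method,
        r_hat=est.r_,
        kd_hat=est.kd_,
        exclusion_threshold=threshold,
        n_points_used=n_used,
        n_points_dropped=n_dropped,
        rss=est.rss_,
        converged=est.converged_,
    )


def fit_hyperbola(
    points: Sequence[CurvePoint], exclusion_threshold: float | None = None
) -> FitResult:
    """Fit the rectangular hyperbola to curve points; see HyperbolaBinding."""
    if exclusion_threshold is not None:
        points = apply_exclusion(points, ExclusionPolicy(exclusion_threshold))
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    x, y = _as_xy(points)
    est = HyperbolaBinding().fit(x[:, None], y)
    return _result_from(est, "hyperbola", exclusion_threshold, len(points), 0)


def fit_lindmo(points: Sequence[CurvePoint], exclusion_threshold: float | None = None) -> FitResult:
    """Fit the Lindmo double-inverse line to curve points; see LindmoBinding."""
    if exclusion_threshold is not None:
        points = apply_exclusion(points, ExclusionPolicy(exclusion_threshold))
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    x, y = _as_xy(points)
    est = LindmoBinding().fit(x[:, None], y)
    return _result_from(est, "lindmo", exclusion_threshold, len(points) - est.n_dropped_, est.n_dropped_)


def apply_exclusion(points: Sequence[CurvePoint], policy: ExclusionPolicy) -> list[CurvePoint]:
    """Drop points with ag0 <= threshold, preserving order."""
    if policy.threshold is None:
        return list(points)
    kept = [p for p in points if p.ag0 > policy.threshold]
    return kept


def r_vs_time(
    params: BindingParameters,
    settings: KineticSettings,
    times: Iterable[float],
    thresholds: tuple[float | None, ...] = EXCLUSION_THRESHOLDS,
) -> pd.DataFrame:
    """Time-dependence of the extrapolated r on noise-free kinetic data.

    For each time point the equilibrium grid row at ``params.kd`` is
    distorted by the integrated rate factor (plus any scenario artefact)
    and refit with the hyperbola and with the Lindmo plot at every
    exclusion threshold.  Returns a long table with one row per
    (time, method, threshold); failed fits are recorded with NaN
    estimates and ``converged=False`` rather than aborting.
    """
    antigen = build_antigen_series(settings.scenario, cap=settings.saturation_cap)
    base = generate_ideal_grid([params.kd], antigen, params)
    rows = []
    for t in times:
        st = KineticSettings(
            kon=settings.kon,
            time=float(t),
            scenario=settings.scenario,
            saturation_cap=settings.saturation_cap,
            desorption_factor=settings.desorption_factor,
        )
        points = distort_grid(base, st).row_points(params.kd)
        fits = [fit_hyperbola(points)]
        for thr in thresholds:
            try:
                fits.append(fit_lindmo(points, thr))
            except ValueError:
                fits.append(
                    FitResult("lindmo", np.nan, np.nan, thr, 0, len(points), np.nan, False)
                )
        for f in fits:
            rows.append({"time_min": float(t), **f.to_row(), "r_hat": f.r_hat})
    return pd.DataFrame.from_records(rows)
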