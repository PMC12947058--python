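"""Microdosimetric one-hit detector model and its calibration.

A one-hit detector responds once a sensitive volume (SV) — here a LiPCDA
monomer crystal in the film's active layer — receives at least one
effective hit.  With saturation parameter ``alpha`` (probability per unit
specific energy of a hit), the fraction of affected SVs at dose D is

    R_theory(D) = 1 - integral_0^inf exp(-alpha z) f(z; D) dz,

and the measured film response (net OD or normalized Raman intensity) is
modelled with a scaling factor and an offset:

    R(D) = m * R_theory(D) + C.

The integral is evaluated against explicit f(z; D) histograms (zero spike
plus binned density) or, for compound-Poisson fields, via the closed-form
survival transform.  Calibration is nonlinear least squares
(Levenberg-Marquardt) for (m, alpha, C), with positivity of m and alpha
enforced by log-reparameterization inside the optimizer.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DomainError
from .field_stats import SpecificEnergyHistogram

__all__ = [
    "DoseResponseCurve",
    "OneHitFit",
    "OneHitResponseModel",
    "response_integral",
    "r_theory",
    "r_response",
    "fit_onehit",
]

_MASS_TOL = 1e-6


@dataclass
class DoseResponseCurve:
    """Measured response vs dose for one modality ('OD' or 'RS')."""

    doses: np.ndarray
    responses: np.ndarray
    uncertainties: np.ndarray | None = None
    modality: str = "OD"

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.ndim != 1 or self.doses.shape != self.responses.shape:
            raise DomainError("doses and responses must be 1-D and equal length")
        if (self.doses < 0).any():
            raise DomainError("doses must be non-negative")
        if (np.diff(self.doses) <= 0).any():
            raise DomainError("doses must be strictly increasing")
        if self.uncertainties is not None:
            self.uncertainties = np.asarray(self.uncertainties, dtype=float)
            if self.uncertainties.shape != self.doses.shape:
                raise DomainError("uncertainties must match doses in length")

    def __len__(self):
        return self.doses.size


@dataclass
class OneHitFit:
    """Fitted (m, alpha, C) with residuals and percent differences."""

    m: float
    alpha: float
    c: float
    residuals: np.ndarray
    percent_differences: np.ndarray
    converged: bool
    message: str = ""
    n_evaluations: int = 0
    cost: float = float("nan")

    @property
    def max_percent_difference(self) -> float:
        return float(np.nanmax(np.abs(self.percent_differences)))


def _check_hist(hist: SpecificEnergyHistogram) -> None:
    if abs(hist.total_mass - 1.0) > _MASS_TOL:
        raise DomainError(
            f"histogram not normalized: total mass {hist.total_mass:.6g} != 1"
        )


def response_integral(hist: SpecificEnergyHistogram, alpha: float) -> float:
    """E[exp(-alpha Z)] against a normalized histogram (midpoint rule)."""
    if np.any(np.asarray(alpha) < 0):
        raise DomainError("alpha must be non-negative")
    _check_hist(hist)
    mass = hist.densities * hist.widths
    if mass.size == 0:
        return float(hist.zero_mass) * np.ones_like(np.asarray(alpha, dtype=float))[()]
    val = hist.zero_mass + np.exp(-np.multiply.outer(np.asarray(alpha, float), hist.mids)) @ mass
    return val[()]


def r_theory(hist: SpecificEnergyHistogram, alpha: float) -> float:
    """Fraction of affected SVs, 1 - E[exp(-alpha Z)]; in [0, 1 - f_{z=0}]."""
    return 1.0 - response_integral(hist, alpha)


def r_response(hist: SpecificEnergyHistogram, m: float, alpha: float, c: float) -> float:
    """Modelled measured response m * R_theory + C.

    At D = 0 (unit zero spike) this returns exactly C.
    """
    if m <= 0:
        raise DomainError("scaling factor m must be positive")
    return m * r_theory(hist, alpha) + c


class OneHitResponseModel(RegressorMixin, BaseEstimator):
    """Sklearn-style regressor fitting R(D) = m * R_theory(D; alpha) + C.

    Parameters
    ----------
    init : tuple (m0, alpha0, c0) or None
        Starting point.  Default: c0 = response at the lowest dose,
        m0 = max response - c0, alpha0 = 1 / Gy.
    weighted : bool
        If True and measurement uncertainties are supplied to ``fit``,
        minimize sum((residual / sigma)^2) instead of unweighted.
    event_model : SingleEventModel or None
        When given, R_theory is evaluated with the closed-form survival
        transform of the compound-Poisson engine instead of histograms.

    The per-dose specific-energy histograms are data, not hyperparameters,
    so they are passed to :meth:`fit` alongside X (the dose vector).

    Attributes
    ----------
    m_, alpha_, c_ : float
        Fitted natural-scale parameters (m, alpha > 0 guaranteed).
    residuals_ : ndarray
        Predicted minus measured response at the training doses.
    percent_differences_ : ndarray
        100 * |pred - meas| / meas per dose (NaN where meas == 0).
    converged_ : bool
    """

    def __init__(self, init=None, weighted: bool = False, event_model=None):
        self.init = init
        self.weighted = weighted
        self.event_model = event_model

    # -- internals ---------------------------------------------------------
    def _theory_fn(self, doses, histograms):
        """Return vectorized alpha -> R_theory at each dose."""
        if histograms is not None:
            if len(histograms) != len(doses):
                raise DomainError("need one histogram per dose")
            packed = []
            for h in histograms:
                _check_hist(h)
                packed.append((h.zero_mass, h.mids, h.densities * h.widths))

            def theory(alpha):
                return np.array(
                    [1.0 - (z0 + np.exp(-alpha * mids) @ mass) for z0, mids, mass in packed]
                )

            return theory
        if self.event_model is None:
            raise DomainError("provide per-dose histograms or an event_model")
        from .engine import survival_transform

        def theory(alpha):
            return np.array(
                [1.0 - survival_transform(self.event_model, d, alpha) for d in doses]
            )

        return theory

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y, histograms=None, uncertainties=None):
        doses = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if doses.size != y.size:
            raise DomainError("X and y must have the same length")
        if doses.size < 4:
            raise DomainError("need at least 4 dose points to fit 3 parameters")
        theory = self._theory_fn(doses, histograms)

        if self.init is None:
            c0 = y[np.argmin(doses)]
            m0 = max(y.max() - c0, 1e-6)
            a0 = 1.0
        else:
            m0, a0, c0 = self.init
            if m0 <= 0 or a0 <= 0:
                raise DomainError("initial m and alpha must be positive")

        w = np.ones_like(y)
        if self.weighted and uncertainties is not None:
            sigma = np.asarray(uncertainties, dtype=float)
            if (sigma <= 0).any():
                raise DomainError("uncertainties must be positive")
            w = 1.0 / sigma

        def resid(p):
            m, alpha, c = np.exp(p[0]), np.exp(p[1]), p[2]
            return w * (m * theory(alpha) + c - y)

        sol = least_squares(resid, x0=[np.log(m0), np.log(a0), c0], method="lm",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        self.m_ = float(np.exp(sol.x[0]))
        self.alpha_ = float(np.exp(sol.x[1]))
        self.c_ = float(sol.x[2])
        pred = self.m_ * theory(self.alpha_) + self.c_
        self.residuals_ = pred - y
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * np.abs(pred - y) / np.abs(y)
            pct[y == 0] = np.nan
        self.percent_differences_ = pct
        self.converged_ = bool(sol.success)
        self.message_ = sol.message
        self.n_evaluations_ = int(sol.nfev)
        self.cost_ = float(sol.cost)
        self._train_doses = doses
        self._train_theory = theory
        return self

    def predict(self, X, histograms=None):
        doses = np.asarray(X, dtype=float).reshape(-1)
        if histograms is not None:
            theory = self._theory_fn(doses, histograms)
        elif self.event_model is not None:
            theory = self._theory_fn(doses, None)
        elif np.array_equal(doses, self._train_doses):
            theory = self._train_theory
        else:
            raise DomainError(
                "predicting at new doses needs histograms or an event_model"
            )
        return self.m_ * theory(self.alpha_) + self.c_

    def fit_result(self) -> OneHitFit:
        return OneHitFit(
            m=self.m_, alpha=self.alpha_, c=self.c_,
            residuals=self.residuals_,
            percent_differences=self.percent_differences_,
            converged=self.converged_, message=self.message_,
            n_evaluations=self.n_evaluations_, cost=self.cost_,
        )


def fit_onehit(curve: DoseResponseCurve, histograms, init=None,
               weighted: bool = False) -> OneHitFit:
    """Least-squares (m, alpha, C) calibration of the one-hit response.

    Thin wrapper over :class:`OneHitResponseModel`; ``histograms`` is one
    normalized f(z; D) per dose in ``curve``.
    """
    est = OneHitResponseModel(init=init, weighted=weighted)
    est.fit(curve.doses, curve.responses, histograms=histograms,
            uncertainties=curve.uncertainties)
    return est.fit_result()
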