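"""Log-log allometric estimation of body mass and maximum prey size.

Craniodental dimensions scale with body mass as power laws, so mass
prediction reduces to ordinary least squares on log10-transformed data.
Back-transformation to the arithmetic scale is biased low; the ratio
estimator (Snowdon's correction, ``RE = sum(y) / sum(yhat)`` over the
training set) multiplies predictions to remove that bias.  Reported
uncertainty comes either from a published prediction-error fraction
(``point * (1 -/+ PE)``) or, for prey-size extrapolation, from the
regression's 95% prediction interval back-transformed from log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


__all__ = [
    "LogLogRegression",
    "AllometricModel",
    "MassEstimate",
    "PreySizeEstimate",
    "RpsValue",
    "fit_loglog",
    "estimate_body_mass",
    "scale_total_skull_length",
    "estimate_max_prey_size",
    "relative_premolar_size",
]


class LogLogRegression(BaseEstimator, RegressorMixin):
    """Ordinary least squares of log10(y) on log10(x), with ratio-estimator
    bias correction for predictions on the original scale.

    Parameters
    ----------
    pe_fraction : float or None
        Published prediction error as a fraction of the point estimate
        (e.g. 0.14 for 14%).  Optional; required only by the
        multiplicative reporting interval of :func:`estimate_body_mass`.
    response_units : str
        Unit label carried through to estimates ("kg" or "N").

    Attributes
    ----------
    slope_ : float
        Allometric exponent (slope in log10-log10 space).
    intercept_ : float
        Intercept in log10 units of the response.
    residuals_ : ndarray
        log10 residuals, one per training pair; sum to 0 under OLS.
    re_factor_ : float
        Snowdon ratio estimator, sum(y) / sum(10**fitted); equals 1
        exactly when back-transformed predictions are unbiased in sum.
    n_ : int
        Number of training pairs.
    """

    def __init__(self, pe_fraction: float | None = None, response_units: str = "kg"):
        self.pe_fraction = pe_fraction
        self.response_units = response_units

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape[0] != y.shape[0]:
            raise ValueError(
                f"x and y lengths differ ({x.shape[0]} vs {y.shape[0]})"
            )
        if x.shape[0] < 3:
            raise ValueError("allometric fit needs at least 3 pairs")
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("allometric data must be strictly positive")
        lx, ly = np.log10(x), np.log10(y)
        res = stats.linregress(lx, ly)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        fitted = self.intercept_ + self.slope_ * lx
        self.residuals_ = ly - fitted
        self.re_factor_ = float(np.sum(y) / np.sum(10.0 ** fitted))
        self.n_ = int(x.shape[0])
        # retained for the prediction interval of extrapolated estimates
        self._x_log_mean_ = float(np.mean(lx))
        self._x_log_ssx_ = float(np.sum((lx - self._x_log_mean_) ** 2))
        dof = self.n_ - 2
        self._log_mse_ = float(np.sum(self.residuals_**2) / dof) if dof > 0 else 0.0
        return self

    def predict(self, X):
        """Bias-corrected point prediction on the original (arithmetic) scale."""
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float).reshape(-1)
        if np.any(x <= 0):
            raise ValueError("predictors must be strictly positive")
        return self.re_factor_ * 10.0 ** (self.intercept_ + self.slope_ * np.log10(x))

    def predict_log10(self, X):
        """Uncorrected prediction in log10 units of the response."""
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * np.log10(x)

    def prediction_interval(self, x0: float, level: float = 0.95) -> tuple[float, float]:
        """Back-transformed prediction interval for a new observation at x0.

        Computed on the log10 scale (t-quantile times the standard error of
        a new observation), then exponentiated and RE-corrected, so the
        interval is asymmetric on the arithmetic scale.
        """
        check_is_fitted(self, "slope_")
        if x0 <= 0:
            raise ValueError("predictor must be strictly positive")
        dof = self.n_ - 2
        lx0 = np.log10(x0)
        center = self.intercept_ + self.slope_ * lx0
        if dof <= 0 or self._log_mse_ == 0.0:
            half = 0.0
        else:
            se = np.sqrt(
                self._log_mse_
                * (1.0 + 1.0 / self.n_ + (lx0 - self._x_log_mean_) ** 2 / self._x_log_ssx_)
            )
            half = stats.t.ppf(0.5 + level / 2.0, dof) * se
        lo = self.re_factor_ * 10.0 ** (center - half)
        hi = self.re_factor_ * 10.0 ** (center + half)
        return float(lo), float(hi)

    def to_model(self) -> "AllometricModel":
        check_is_fitted(self, "slope_")
        return AllometricModel(
            slope=self.slope_,
            intercept=self.intercept_,
            n=self.n_,
            residuals=self.residuals_.copy(),
            pe_fraction=self.pe_fraction,
            re_factor=self.re_factor_,
            response_units=self.response_units,
            _regression=self,
        )


@dataclass
class AllometricModel:
    """A fitted (or externally supplied) log10-log10 allometric model."""

    slope: float
    intercept: float
    n: int = 3
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    pe_fraction: float | None = None
    re_factor: float = 1.0
    response_units: str = "kg"
    _regression: LogLogRegression | None = None

    def __post_init__(self):
        if self.re_factor <= 0:
            raise ValueError("re_factor must be positive")
        if self.n < 3:
            raise ValueError("allometric model needs n >= 3")

    def predict(self, x: float) -> float:
        if x <= 0:
            raise ValueError("predictor must be strictly positive")
        return self.re_factor * 10.0 ** (self.intercept + self.slope * np.log10(x))


@dataclass
class MassEstimate:
    point_kg: float
    lo_kg: float
    hi_kg: float
    predictor_name: str = ""
    specimen_id: str = ""

    def __post_init__(self):
        if not (0 < self.lo_kg <= self.point_kg <= self.hi_kg):
            raise ValueError("mass estimate interval must satisfy 0 < lo <= point <= hi")

    def rounded(self, ndigits: int = 1) -> "MassEstimate":
        """Reporting-layer rounding; internal values stay full precision."""
        return MassEstimate(
            round(self.point_kg, ndigits),
            round(self.lo_kg, ndigits),
            round(self.hi_kg, ndigits),
            self.predictor_name,
            self.specimen_id,
        )


@dataclass
class PreySizeEstimate:
    point_kg: float
    ci95_lo_kg: float
    ci95_hi_kg: float
    predator_mass_kg: float

    def __post_init__(self):
        if not (self.ci95_lo_kg <= self.point_kg <= self.ci95_hi_kg):
            raise ValueError("prey size CI must bracket the point estimate")


@dataclass
class RpsValue:
    premolar_width_mm: float
    body_mass_kg: float
    rps: float


def fit_loglog(x, y, pe_fraction: float | None = None,
               response_units: str = "kg") -> AllometricModel:
    """OLS of log10(y) on log10(x); returns the fitted allometric model."""
    reg = LogLogRegression(pe_fraction=pe_fraction, response_units=response_units)
    reg.fit(x, y)
    return reg.to_model()


def estimate_body_mass(measurement_mm: float, model: AllometricModel,
                       predictor_name: str = "", specimen_id: str = "") -> MassEstimate:
    """Point mass from the model plus the multiplicative prediction-error
    interval ``point * (1 -/+ PE)``."""
    if measurement_mm <= 0:
        raise ValueError("measurement must be strictly positive")
    if model.pe_fraction is None:
        raise ValueError("model has no pe_fraction; cannot form the reporting interval")
    point = model.predict(measurement_mm)
    pe = model.pe_fraction
    return MassEstimate(
        point_kg=point,
        lo_kg=point * (1.0 - pe),
        hi_kg=point * (1.0 + pe),
        predictor_name=predictor_name,
        specimen_id=specimen_id,
    )


def scale_total_skull_length(reference_tsl_mm: float, reference_part_mm: float,
                             target_part_mm: float) -> float:
    """Scale a reference skull length by the ratio of a shared part length.

    Used to reconstruct total skull length of an incomplete specimen from
    a complete reference specimen and a snout segment both preserve.
    """
    if min(reference_tsl_mm, reference_part_mm, target_part_mm) <= 0:
        raise ValueError("all lengths must be strictly positive")
    return reference_tsl_mm * (target_part_mm / reference_part_mm)


def estimate_max_prey_size(predator_mass_kg: float,
                           model: AllometricModel) -> PreySizeEstimate:
    """Maximum prey mass from predator mass, with a back-transformed 95%
    prediction interval when the model carries its training regression."""
    if predator_mass_kg <= 0:
        raise ValueError("predator mass must be strictly positive")
    if model.n < 3:
        raise ValueError("prey-size model needs n >= 3")
    point = model.predict(predator_mass_kg)
    if model._regression is not None:
        lo, hi = model._regression.prediction_interval(predator_mass_kg)
        # the RE-corrected point can sit slightly off-centre of the raw
        # interval; clamp so the CI always brackets the reported point
        lo, hi = min(lo, point), max(hi, point)
    else:
        lo = hi = point
    return PreySizeEstimate(point, lo, hi, predator_mass_kg)


def relative_premolar_size(premolar_width_mm: float, body_mass_kg: float) -> RpsValue:
    """Relative premolar size: ultimate premolar width (mm) over the cube
    root of body mass (kg).  Large values flag crushing/durophagous teeth."""
    if premolar_width_mm <= 0 or body_mass_kg <= 0:
        raise ValueError("width and mass must be strictly positive")
    rps = premolar_width_mm / body_mass_kg ** (1.0 / 3.0)
    return RpsValue(premolar_width_mm, body_mass_kg, rps)
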