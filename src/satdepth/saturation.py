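"""Asymptotic saturation-curve fitting and plateau (saturation depth) estimation.

Detection counts as a function of sequencing depth x are modelled with the
three-parameter asymptotic regression (monomolecular growth) curve

    y(x) = ymax + (y0 - ymax) * exp(-exp(lrc) * x)

where ``ymax`` is the asymptote, ``y0`` the response at x = 0 and ``lrc`` the
natural log of the rate constant.  The saturation depth is the point where the
curve's slope falls to a marginal-gain threshold s (default 1e-4 genes per
read, i.e. one additional gene per 10,000 extra reads); solving
``y'(x) = s`` gives the closed form

    x_plateau = -(ln(s / (ymax - y0)) - lrc) / exp(lrc).

Fitting is by damped nonlinear least squares with a self-start initialisation
(asymptote from the data maximum, rate from a log-linear regression), the
standard self-start logic for this model family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from ._errors import FitError, ParameterError

__all__ = [
    "AsymptoticFit",
    "PlateauResult",
    "model_predict",
    "model_derivative",
    "fit_asymptotic",
    "plateau",
    "marginal_gain",
]

#: Default marginal-gain threshold: one gene per 10,000 extra reads.
DEFAULT_SLOPE_THRESHOLD = 1e-4


@dataclass(frozen=True)
class AsymptoticFit:
    """Fitted parameters of the asymptotic regression model."""

    y0: float
    ymax: float
    lrc: float
    residual_sse: float = 0.0
    n_obs: int = 0
    converged: bool = True

    @property
    def rate_constant(self) -> float:
        return float(np.exp(self.lrc))

    @property
    def saturating(self) -> bool:
        """True when the curve increases toward its asymptote (ymax > y0)."""
        return self.ymax > self.y0


@dataclass(frozen=True)
class PlateauResult:
    """Saturation depth and the model's predicted response there."""

    x_plateau: float
    y_at_plateau: float
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD
    extrapolated: bool | None = field(default=None)


def model_predict(fit: AsymptoticFit, x) -> np.ndarray | float:
    """Model response y(x) = ymax + (y0 - ymax) exp(-exp(lrc) x)."""
    x = np.asarray(x, dtype=float)
    y = fit.ymax + (fit.y0 - fit.ymax) * np.exp(-np.exp(fit.lrc) * x)
    return float(y) if y.ndim == 0 else y


def model_derivative(fit: AsymptoticFit, x) -> np.ndarray | float:
    """Slope y'(x) = (ymax - y0) exp(lrc) exp(-exp(lrc) x)."""
    x = np.asarray(x, dtype=float)
    rate = np.exp(fit.lrc)
    slope = (fit.ymax - fit.y0) * rate * np.exp(-rate * x)
    return float(slope) if slope.ndim == 0 else slope


def _self_start(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Initial (y0, ymax, lrc): asymptote slightly above max(y), rate from
    OLS of log(ymax0 - y) on x."""
    ymax0 = float(y.max()) * 1.05 if y.max() > 0 else float(y.max()) + 1.0
    y00 = float(y.min())
    resid = np.clip(ymax0 - y, 1e-12, None)
    slope = np.polyfit(x, np.log(resid), 1)[0]
    if slope < 0:
        lrc0 = float(np.log(-slope))
    else:  # non-decaying residuals: fall back to the depth scale
        lrc0 = float(-np.log(max(x.mean(), 1.0)))
    return np.array([y00, ymax0, lrc0])


def fit_asymptotic(
    x, y, max_iter: int = 500, tol: float = 1e-10
) -> AsymptoticFit:
    """Least-squares fit of the asymptotic model to pooled (x, y) points.

    Requires at least three distinct x values and non-constant responses.
    Raises :class:`FitError` on non-convergence.  A decreasing trend yields a
    fit flagged non-saturating (``saturating`` False) rather than a silent
    plateau.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ParameterError("x and y must have equal length")
    if np.unique(x).size < 3:
        raise ParameterError("need >= 3 distinct x values")
    if np.allclose(y, y[0]):
        raise ParameterError("responses are constant; nothing to fit")

    theta0 = _self_start(x, y)

    def residuals(theta: np.ndarray) -> np.ndarray:
        y0, ymax, lrc = theta
        return ymax + (y0 - ymax) * np.exp(-np.exp(lrc) * x) - y

    sol = least_squares(
        residuals,
        theta0,
        method="lm",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter * 4,
    )
    if not sol.success:
        raise FitError(
            f"asymptotic fit did not converge (status {sol.status}, "
            f"init {theta0.tolist()})"
        )
    sse = float(np.sum(sol.fun**2))
    sse0 = float(np.sum(residuals(theta0) ** 2))
    if sse > sse0 * (1 + 1e-9):
        raise FitError("fit did not improve on self-start initialisation")
    y0, ymax, lrc = map(float, sol.x)
    return AsymptoticFit(
        y0=y0,
        ymax=ymax,
        lrc=lrc,
        residual_sse=sse,
        n_obs=int(x.size),
        converged=True,
    )


def plateau(
    fit: AsymptoticFit,
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
    x_max_observed: float | None = None,
) -> PlateauResult:
    """Closed-form saturation depth where the fitted slope equals the threshold.

    ``x_plateau = -(ln(slope_threshold / (ymax - y0)) - lrc) / exp(lrc)``.
    Raises :class:`FitError` for a non-saturating fit and
    :class:`ParameterError` when the threshold exceeds the slope at the
    origin (the curve is flatter than the threshold from the start).  When
    ``x_max_observed`` is given, the result carries an ``extrapolated`` flag
    marking plateaus beyond the observed depth range.
    """
    if slope_threshold <= 0:
        raise ParameterError("slope_threshold must be positive")
    if not fit.saturating:
        raise FitError("non-saturating fit (ymax <= y0); no plateau exists")
    rate = np.exp(fit.lrc)
    slope_at_origin = (fit.ymax - fit.y0) * rate
    if slope_threshold > slope_at_origin:
        raise ParameterError(
            f"slope threshold {slope_threshold} exceeds the slope at x=0 "
            f"({slope_at_origin:.6g}); the curve is everywhere flatter"
        )
    x_plateau = float(
        -(np.log(slope_threshold / (fit.ymax - fit.y0)) - fit.lrc) / rate
    )
    extrapolated = None if x_max_observed is None else x_plateau > x_max_observed
    return PlateauResult(
        x_plateau=x_plateau,
        y_at_plateau=float(model_predict(fit, x_plateau)),
        slope_threshold=slope_threshold,
        extrapolated=extrapolated,
    )


def marginal_gain(fit: AsymptoticFit, x_from: float, x_to: float) -> float:
    """Predicted additional detections when deepening from x_from to x_to."""
    if x_from < 0 or x_to < x_from:
        raise ParameterError("need 0 <= x_from <= x_to")
    return float(model_predict(fit, x_to) - model_predict(fit, x_from))
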