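"""Sigmoidal logistic dose-response fitting and inverse calibration.

The model is a three-parameter logistic on a log10-dilution axis,

    R(c) = Rmax / (1 + exp(-h * (c - EC50)))

with ``Rmax`` the maximum-response asymptote, ``EC50`` the half-effective
log10 dilution, and ``h`` the steepness (reminiscent of a Hill
coefficient, but per log10 unit).  The lower asymptote is zero; inhibitory
responses are handled upstream by sign, not by a fourth parameter.

``invert_logistic`` is the calibration read-off: given a measured
(normalized) response it returns the log10 dilution that would have
produced it,

    c = EC50 - (1/h) * ln(Rmax / R - 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitConvergenceError, ResponseOutOfRange, TraceValidationError


@dataclass(frozen=True)
class DoseResponsePoint:
    """One point of a dose-response curve.

    ``c`` is the log10 dilution (e.g. -5.0); ``response`` is the
    normalized amplitude (reference peak = 1.0).  ``n_animals`` and
    ``sem`` are carried for reporting; the fit itself is unweighted.
    """

    c: float
    response: float
    n_animals: int = 1
    sem: float = 0.0

    def __post_init__(self):
        if not math.isfinite(self.c):
            raise TraceValidationError("dose must be finite")
        if self.n_animals < 1:
            raise TraceValidationError("n_animals must be >= 1")


@dataclass(frozen=True)
class LogisticFit:
    """Fitted (Rmax, EC50, h) of the logistic dose-response model."""

    rmax: float
    ec50: float
    h: float
    rss: float = 0.0
    converged: bool = True

    def __post_init__(self):
        if self.rmax <= 0:
            raise TraceValidationError("Rmax must be > 0")


def logistic(c, rmax, ec50, h):
    """Vectorized logistic model; usable directly with curve_fit."""
    return rmax / (1.0 + np.exp(-h * (np.asarray(c, dtype=float) - ec50)))


def predict_response(fit: LogisticFit, c: float | np.ndarray) -> float | np.ndarray:
    """Model response at log10 dilution ``c``."""
    out = logistic(c, fit.rmax, fit.ec50, fit.h)
    return float(out) if np.isscalar(c) else out


def fit_logistic(points: Sequence[DoseResponsePoint]) -> LogisticFit:
    """Unweighted least-squares fit of the logistic model.

    Requires >= 4 points spanning >= 2 log10 units with at least one
    nonzero response.  Initialization: ``Rmax0`` = max response, ``EC500``
    = the dose whose response is closest to half of ``Rmax0``, ``h0`` = 1;
    bounded restarts vary ``h0``.  Deterministic given identical inputs.

    Raises
    ------
    TraceValidationError
        Too few points, insufficient span, or all-zero responses
        (unidentifiable).
    FitConvergenceError
        No restart converged; carries the best parameters so far.
    """
    pts = list(points)
    if len(pts) < 4:
        raise TraceValidationError("logistic fit needs >= 4 points")
    c = np.array([p.c for p in pts], dtype=float)
    r = np.array([p.response for p in pts], dtype=float)
    if c.max() - c.min() < 2.0:
        raise TraceValidationError("doses must span >= 2 log10 units")
    if np.all(r == 0.0):
        raise TraceValidationError("all responses are zero; model unidentifiable")

    rmax0 = float(r.max())
    if rmax0 <= 0:
        raise TraceValidationError("maximum response must be > 0")
    ec500 = float(c[np.argmin(np.abs(r - rmax0 / 2.0))])
    bounds = ([1e-12, c.min() - 10.0, 1e-6],
              [10.0 * rmax0, c.max() + 10.0, 50.0])

    best = None
    best_rss = math.inf
    for h0 in (1.0, 0.3, 3.0, 10.0):
        try:
            popt, _ = curve_fit(
                logistic, c, r, p0=(rmax0, ec500, h0), bounds=bounds,
                maxfev=20000, xtol=1e-14, ftol=1e-14)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((logistic(c, *popt) - r) ** 2))
        if rss < best_rss:
            best, best_rss = popt, rss
        if rss <= 1e-14 * max(1.0, float(np.sum(r ** 2))):
            break
    if best is None:
        raise FitConvergenceError("logistic fit did not converge")
    rmax, ec50, h = (float(v) for v in best)
    return LogisticFit(rmax=rmax, ec50=ec50, h=h, rss=best_rss)


def invert_logistic(fit: LogisticFit, response: float) -> float:
    """Log10 dilution producing ``response`` under the fitted model.

    Exact algebraic inverse of :func:`predict_response`; the round trip
    ``invert(predict(c)) == c`` holds to floating-point precision.

    Raises
    ------
    ResponseOutOfRange
        ``kind="below_detection"`` when response <= 0 and
        ``kind="saturated"`` when response >= Rmax.
    """
    if response <= 0.0:
        raise ResponseOutOfRange(
            f"response {response} <= 0 cannot be inverted", kind="below_detection")
    if response >= fit.rmax:
        raise ResponseOutOfRange(
            f"response {response} >= Rmax={fit.rmax}", kind="saturated")
    return fit.ec50 - math.log(fit.rmax / response - 1.0) / fit.h
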