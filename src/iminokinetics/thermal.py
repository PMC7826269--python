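"""Melting-temperature extraction from UV absorbance melting curves.

Tm is taken as the temperature of the maximum of the first derivative of
absorbance with respect to temperature, after light smoothing; the discrete
maximum is refined by quadratic vertex interpolation so Tm is not quantized
to the temperature step.  The result is invariant under affine transforms of
the absorbance (a*A + b, a > 0), as it must be for an instrument-arbitrary
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .types import ValidationError

__all__ = ["MeltingCurve", "TmResult", "tm_from_first_derivative", "NoTransitionError"]


class NoTransitionError(ValidationError):
    """The derivative has no interior maximum: no melting transition in range."""


@dataclass(frozen=True)
class MeltingCurve:
    temperatures: np.ndarray  # degrees C, strictly increasing
    absorbance: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "absorbance", a)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValidationError("temperatures and absorbance must be equal-length 1-D")
        if len(t) < 10:
            raise ValidationError(f"need >= 10 points, got {len(t)}")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("temperatures must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
            raise ValidationError("non-finite values in melting curve")


@dataclass(frozen=True)
class TmResult:
    tm: float  # degrees C
    tm_err: float  # degrees C (bootstrap SD; 0 when bootstrap disabled)
    derivative_max: float  # dA/dT at the maximum


def _derivative(curve: MeltingCurve, window: int, polyorder: int) -> np.ndarray:
    a = curve.absorbance
    if window >= 3 and len(a) >= window:
        a = savgol_filter(a, window_length=window, polyorder=min(polyorder, window - 1))
    return np.gradient(a, curve.temperatures)


def _peak(t: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    i = int(np.argmax(d))
    spread = float(np.max(d) - np.min(d))
    if spread <= 1e-12 * max(1.0, abs(float(np.max(d)))):
        raise NoTransitionError(
            "derivative is constant over the temperature range: "
            "no melting transition detected"
        )
    if i == 0 or i == len(d) - 1:
        raise NoTransitionError(
            "derivative maximum at the edge of the temperature range: "
            "no interior melting transition detected"
        )
    # quadratic vertex through the three points around the discrete maximum
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    d0, d1, d2 = d[i - 1], d[i], d[i + 1]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a_coef = (t2 * (d1 - d0) + t1 * (d0 - d2) + t0 * (d2 - d1)) / denom
    b_coef = (t2 * t2 * (d0 - d1) + t1 * t1 * (d2 - d0) + t0 * t0 * (d1 - d2)) / denom
    if a_coef >= 0:
        return float(t1), float(d1)
    tv = -b_coef / (2.0 * a_coef)
    dv = d1 - a_coef * (t1 - tv) ** 2
    return float(tv), float(dv)


def tm_from_first_derivative(curve: MeltingCurve, window: int = 7,
                             polyorder: int = 2, bootstrap: int = 100,
                             seed: int | None = None) -> TmResult:
    """Tm from the first-derivative maximum of the melting curve.

    Parameters
    ----------
    window, polyorder
        Moving polynomial (Savitzky-Golay) smoothing applied before
        differentiation; window 7 / order 2 by default, window < 3 disables.
    bootstrap
        Residual-bootstrap replicates for the Tm uncertainty (0 disables).
    """
    d = _derivative(curve, window, polyorder)
    tm, dmax = _peak(curve.temperatures, d)
    if bootstrap <= 0:
        return TmResult(tm=tm, tm_err=0.0, derivative_max=dmax)

    # residuals about the smoothed curve drive the bootstrap
    w = max(window, 5)
    smooth = savgol_filter(curve.absorbance, window_length=w,
                           polyorder=min(polyorder, w - 1))
    resid = curve.absorbance - smooth
    rng = np.random.default_rng(seed)
    tms = []
    for _ in range(bootstrap):
        fake = smooth + rng.choice(resid, size=len(resid), replace=True)
        try:
            fc = MeltingCurve(curve.temperatures, fake)
            tms.append(_peak(curve.temperatures, _derivative(fc, window, polyorder))[0])
        except NoTransitionError:
            continue
    err = float(np.std(tms, ddof=1)) if len(tms) > 1 else math.nan
    return TmResult(tm=tm, tm_err=err, derivative_max=dmax)
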