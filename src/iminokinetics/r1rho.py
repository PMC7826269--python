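"""On-resonance imino 1H R1rho relaxation-dispersion analysis.

Effective rotating-frame relaxation rates are computed from spin-lock /
reference intensity pairs, R1rho = -(1/T) ln(I_SL / I0), with errors
propagated from the spectral baseline noise.  Dispersion profiles R1rho(nu1)
are fitted to a two-state (closed <-> open) chemical-exchange model whose
exchange contribution decays with increasing spin-lock field:

    R1rho = R2^0 + pA pB dw^2 kex / D
    D = wAe^2 wBe^2 / we^2 + kex^2
        - pA pB dw^2 (1 + 2 kex^2 (pA wAe^2 + pB wBe^2) / (wAe^2 wBe^2 + we^2 kex^2))
    wAe^2 = w1^2 ; wBe^2 = dw^2 + w1^2 ; we^2 = OmegaA^2 + w1^2
    OmegaA = -pB kex^2 dw / (kex^2 + dw^2)

with w1 = 2*pi*nu1 the spin-lock field and dw the open/closed chemical-shift
difference in rad/s.  For fast exchange (kex >> dw) only the composite
amplitude phi_ex = pA*pB*dw^2 is identifiable, so the default fit
parameterization is {r20, kex, phi_ex} with pb fixed by assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np

from .types import DispersionCurve, ExchangeFit, ValidationError

__all__ = [
    "r1rho_from_intensities",
    "r1rho_error_from_noise",
    "dispersion_model",
    "dispersion_model_phi",
    "fit_dispersion",
    "rex_at_min_spinlock",
    "DispersionFitConfig",
    "DispersionDomainError",
]

TWO_PI = 2.0 * math.pi


class DispersionDomainError(ValidationError):
    """Model evaluated outside the validity domain of the two-state expression."""


def r1rho_from_intensities(i_sl, i_0, relax_period: float):
    """R1rho = -(1/T) ln(I_SL/I0) from one spin-lock/reference intensity pair."""
    i_sl = np.asarray(i_sl, dtype=float)
    i_0 = np.asarray(i_0, dtype=float)
    if np.any(i_sl <= 0) or np.any(i_0 <= 0):
        bad = i_sl[i_sl <= 0] if np.any(i_sl <= 0) else i_0[i_0 <= 0]
        raise ValidationError(
            f"non-positive intensity {float(np.atleast_1d(bad)[0])!r}: check baseline "
            "correction and phasing"
        )
    if relax_period <= 0:
        raise ValidationError("relax_period must be > 0")
    out = -np.log(i_sl / i_0) / relax_period
    return float(out) if out.ndim == 0 else out


def r1rho_error_from_noise(i_sl, i_0, baseline_sigma: float, relax_period: float):
    """First-order error on R1rho from the spectral baseline-noise amplitude.

    sigma(R1rho) = (1/T) sqrt((sigma/I_SL)^2 + (sigma/I0)^2).
    """
    i_sl = np.asarray(i_sl, dtype=float)
    i_0 = np.asarray(i_0, dtype=float)
    if np.any(i_sl <= 0) or np.any(i_0 <= 0):
        raise ValidationError("intensities must be > 0")
    if baseline_sigma < 0:
        raise ValidationError("baseline_sigma must be >= 0")
    if relax_period <= 0:
        raise ValidationError("relax_period must be > 0")
    out = np.sqrt((baseline_sigma / i_sl) ** 2 + (baseline_sigma / i_0) ** 2) / relax_period
    return float(out) if out.ndim == 0 else out


def dispersion_model(nu1, r20: float, kex: float, pb: float, dw: float):
    """Two-state on-resonance R1rho at spin-lock field nu1 (Hz).

    ``dw`` is in rad/s.  ``pb == 0`` or ``dw == 0`` return ``r20`` exactly.
    Parameter sets that drive the printed denominator non-positive (outside
    the approximation's validity domain) raise :class:`DispersionDomainError`.
    """
    if r20 <= 0 or kex <= 0:
        raise ValidationError(f"rates must be > 0 (r20={r20}, kex={kex})")
    if not (0.0 <= pb < 1.0):
        raise ValidationError(f"pb must be in [0, 1), got {pb}")
    w1 = TWO_PI * np.asarray(nu1, dtype=float)
    if np.any(w1 <= 0):
        raise ValidationError("nu1 must be > 0")
    pa = 1.0 - pb
    phi = pa * pb * dw * dw
    if phi == 0.0:
        out = np.full_like(w1, r20)
        return float(out) if out.ndim == 0 else out
    wae2 = w1 * w1
    wbe2 = dw * dw + w1 * w1
    omega_a = -pb * kex * kex * dw / (kex * kex + dw * dw)
    we2 = omega_a * omega_a + w1 * w1
    kex2 = kex * kex
    denom = (
        wae2 * wbe2 / we2
        + kex2
        - phi * (1.0 + 2.0 * kex2 * (pa * wae2 + pb * wbe2) / (wae2 * wbe2 + we2 * kex2))
    )
    if np.any(denom <= 0):
        raise DispersionDomainError(
            f"denominator non-positive for r20={r20}, kex={kex}, pb={pb}, dw={dw}: "
            "parameters outside the two-state expression's validity domain"
        )
    out = r20 + phi * kex / denom
    return float(out) if out.ndim == 0 else out


def dispersion_model_phi(nu1, r20: float, kex: float, phi_ex: float, pb_fixed: float):
    """Fast-exchange parameterization: evaluate the model from {r20, kex, phi_ex}.

    dw is derived as sqrt(phi_ex / ((1-pb)*pb)) with the assumed minor-state
    population ``pb_fixed``; in the fast-exchange regime the result is nearly
    independent of that assumption.
    """
    if phi_ex < 0:
        raise ValidationError("phi_ex must be >= 0")
    if phi_ex == 0.0:
        w1 = np.asarray(nu1, dtype=float)
        out = np.full_like(w1, r20, dtype=float)
        return float(out) if out.ndim == 0 else out
    if not (0.0 < pb_fixed < 1.0):
        raise ValidationError("pb_fixed must be in (0, 1)")
    dw = math.sqrt(phi_ex / ((1.0 - pb_fixed) * pb_fixed))
    return dispersion_model(nu1, r20, kex, pb_fixed, dw)


@dataclass
class DispersionFitConfig:
    """Settings for :func:`fit_dispersion`.

    mode
        ``"fast_exchange"`` fits {r20, kex, phi_ex} with ``pb`` fixed at
        ``pb_fixed`` (the open population of a base pair is far too small to
        be separable from dw); ``"full"`` frees pb and dw, which is degenerate
        for fast exchange and flagged accordingly.
    """

    mode: str = "fast_exchange"
    pb_fixed: float = 0.001
    mc_draws: int = 200
    seed: int | None = None
    kex_bounds: tuple[float, float] = (1e2, 1e7)
    r20_bounds: tuple[float, float] = (0.1, 500.0)

    def __post_init__(self) -> None:
        if self.mode not in ("fast_exchange", "full"):
            raise ValidationError(f"unknown fit mode {self.mode!r}")
        if not (0.0 < self.pb_fixed <= 0.5):
            raise ValidationError("pb_fixed must be in (0, 0.5]")


def _initial_guess(curve: DispersionCurve, cfg: DispersionFitConfig):
    r20_0 = float(curve.r1rho[-1])  # high-power limit quenches exchange
    rex0 = max(float(curve.r1rho[0] - curve.r1rho[-1]), 1e-3)
    half = r20_0 + 0.5 * rex0
    idx = int(np.argmin(np.abs(curve.r1rho - half)))
    kex0 = TWO_PI * float(curve.spinlock_nu1[idx])
    kex0 = min(max(kex0, cfg.kex_bounds[0] * 1.01), cfg.kex_bounds[1] * 0.99)
    phi0 = rex0 * kex0
    return r20_0, kex0, phi0


def _residual_factory(curve: DispersionCurve, r1rho: np.ndarray, cfg: DispersionFitConfig):
    nu1 = curve.spinlock_nu1

    def residual(p):
        try:
            if cfg.mode == "fast_exchange":
                model = dispersion_model_phi(
                    nu1, p["r20"].value, p["kex"].value, p["phi_ex"].value, cfg.pb_fixed
                )
            else:
                model = dispersion_model(
                    nu1, p["r20"].value, p["kex"].value, p["pb"].value, p["dw"].value
                )
        except DispersionDomainError:
            return np.full(len(nu1), 1e6)
        return (r1rho - model) / curve.r1rho_errors

    return residual


def _make_params(cfg: DispersionFitConfig, start) -> lmfit.Parameters:
    r20_0, kex0, phi0 = start
    params = lmfit.Parameters()
    params.add("r20", value=r20_0, min=cfg.r20_bounds[0], max=cfg.r20_bounds[1])
    params.add("kex", value=kex0, min=cfg.kex_bounds[0], max=cfg.kex_bounds[1])
    if cfg.mode == "fast_exchange":
        params.add("phi_ex", value=phi0, min=0.0)
    else:
        params.add("pb", value=cfg.pb_fixed, min=1e-6, max=0.5)
        params.add("dw", value=math.sqrt(phi0 / cfg.pb_fixed), min=1.0, max=1e6)
    return params


def _aicc(chi2: float, n: int, k: int) -> float:
    # Gaussian-likelihood corrected AIC on the weighted residual sum of squares
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(max(chi2, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_dispersion(curve: DispersionCurve, config: DispersionFitConfig | None = None) -> ExchangeFit:
    """Weighted least-squares fit of the two-state model to one dispersion profile.

    A flat model (r20 only) is compared against the exchange model by
    corrected AIC; if flat wins the site is reported with ``no_rex=True`` and
    no exchange parameters, mirroring profiles without measurable dispersion.
    """
    cfg = config or DispersionFitConfig()
    n = len(curve.spinlock_nu1)
    if n < 4:
        raise ValidationError(f"need >= 4 dispersion points, got {n}")
    if curve.spinlock_nu1[-1] / curve.spinlock_nu1[0] < 10.0:
        raise ValidationError("spin-lock fields must span at least one decade")

    start = _initial_guess(curve, cfg)
    residual = _residual_factory(curve, curve.r1rho, cfg)
    res = lmfit.minimize(residual, _make_params(cfg, start), method="least_squares")
    nvary = len([p for p in res.params.values() if p.vary])

    # Flat comparison: exchange-free model is the inverse-variance weighted mean.
    w = 1.0 / curve.r1rho_errors**2
    r20_flat = float(np.sum(w * curve.r1rho) / np.sum(w))
    chi2_flat = float(np.sum(w * (curve.r1rho - r20_flat) ** 2))
    if _aicc(chi2_flat, n, 1) <= _aicc(float(res.chisqr), n, nvary):
        return ExchangeFit(
            r20=r20_flat, kex=math.nan, pb=math.nan, dw=math.nan, phi_ex=0.0,
            r20_err=float(1.0 / math.sqrt(np.sum(w))),
            kex_err=math.nan, pb_err=math.nan, dw_err=math.nan, phi_ex_err=math.nan,
            chi2_reduced=chi2_flat / max(n - 1, 1),
            parameterization_mode=cfg.mode, no_rex=True, converged=True,
        )

    return _to_exchange_fit(res, curve, cfg)


def _params_to_tuple(p: lmfit.Parameters, cfg: DispersionFitConfig):
    if cfg.mode == "fast_exchange":
        return p["r20"].value, p["kex"].value, p["phi_ex"].value
    return p["r20"].value, p["kex"].value, p["pb"].value, p["dw"].value


def _to_exchange_fit(res, curve: DispersionCurve, cfg: DispersionFitConfig) -> ExchangeFit:
    best = _params_to_tuple(res.params, cfg)
    if cfg.mc_draws > 0:
        errs = _mc_errors(curve, cfg, res.params)
    else:
        errs = tuple(
            float(res.params[name].stderr) if res.params[name].stderr is not None else math.nan
            for name in res.params if res.params[name].vary
        )
    if cfg.mode == "fast_exchange":
        r20, kex, phi = best
        pb = cfg.pb_fixed
        pa = 1.0 - pb
        dw = math.sqrt(phi / (pa * pb)) if phi > 0 else 0.0
        r20_err, kex_err, phi_err = errs
        dw_err = 0.5 * phi_err / math.sqrt(phi * pa * pb) if phi > 0 else math.nan
        return ExchangeFit(
            r20=float(r20), kex=float(kex), pb=pb, dw=dw, phi_ex=float(phi),
            r20_err=r20_err, kex_err=kex_err, pb_err=0.0, dw_err=dw_err, phi_ex_err=phi_err,
            chi2_reduced=float(res.redchi), parameterization_mode="fast_exchange",
            no_rex=False, converged=bool(res.success),
        )
    r20, kex, pb, dw = best
    r20_err, kex_err, pb_err, dw_err = errs
    phi = (1.0 - pb) * pb * dw * dw
    phi_err = math.hypot((1.0 - 2.0 * pb) * dw * dw * pb_err, 2.0 * (1.0 - pb) * pb * dw * dw_err) \
        if not math.isnan(pb_err) and not math.isnan(dw_err) else math.nan
    return ExchangeFit(
        r20=float(r20), kex=float(kex), pb=float(pb), dw=float(dw), phi_ex=float(phi),
        r20_err=r20_err, kex_err=kex_err, pb_err=pb_err, dw_err=dw_err, phi_ex_err=phi_err,
        chi2_reduced=float(res.redchi), parameterization_mode="full",
        no_rex=False, converged=bool(res.success),
    )


def _mc_errors(curve: DispersionCurve, cfg: DispersionFitConfig, best_params: lmfit.Parameters):
    """Parameter SDs from refits on residual-resampled synthetic profiles."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.mode == "fast_exchange":
        r20, kex, phi = _params_to_tuple(best_params, cfg)
        model = dispersion_model_phi(curve.spinlock_nu1, r20, kex, phi, cfg.pb_fixed)
        names = ("r20", "kex", "phi_ex")
    else:
        r20, kex, pb, dw = _params_to_tuple(best_params, cfg)
        model = dispersion_model(curve.spinlock_nu1, r20, kex, pb, dw)
        names = ("r20", "kex", "pb", "dw")
    draws = np.empty((cfg.mc_draws, len(names)))
    for i in range(cfg.mc_draws):
        fake = model + rng.normal(0.0, curve.r1rho_errors)
        residual = _residual_factory(curve, fake, cfg)
        params = lmfit.Parameters()
        for name in best_params:
            p = best_params[name]
            params.add(name, value=p.value, min=p.min, max=p.max, vary=p.vary)
        res = lmfit.minimize(residual, params, method="least_squares")
        draws[i] = [res.params[n].value for n in names]
    sd = draws.std(axis=0, ddof=1)
    return tuple(float(s) for s in sd)


def rex_at_min_spinlock(fit: ExchangeFit, nu1_min: float) -> float:
    """Exchange contribution Rex to R1rho at the weakest spin-lock field used."""
    if fit.no_rex or fit.phi_ex == 0.0:
        return 0.0
    return float(dispersion_model(nu1_min, fit.r20, fit.kex, fit.pb, fit.dw) - fit.r20)
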