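"""Shared domain types for the imino-proton exchange / relaxation-dispersion pipeline.

Conventions used throughout the package:

* Angular frequencies (``dw``, ``phi_ex``) are stored in rad/s; all user-facing
  I/O quotes spin-lock fields as nu1 = omega1/(2*pi) in Hz.  The conversion
  happens exactly once, at the I/O boundary.
* Base-pair positions are 1-based along the duplex numbering.
* Duplex labels name the modification state of the CpG positions on each
  strand, e.g. ``"C/C"``, ``"5mC/C"``, ``"5hmC/5mC"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ModificationState",
    "DuplexSite",
    "BuildUpCurve",
    "DispersionCurve",
    "CleanexFit",
    "ExchangeFit",
    "KineticsSummary",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


class ModificationState(str, Enum):
    """Epigenetic modification state of a cytosine base.

    ``C5CA`` (5-carboxylcytosine) is accepted for completeness but carries no
    default pKa entry; supplying one explicitly is required for normalization.
    """

    C = "C"
    M5C = "5mC"
    HM5C = "5hmC"
    CA5C = "5caC"

    @classmethod
    def parse(cls, label: str) -> "ModificationState":
        for m in cls:
            if m.value == label:
                return m
        raise ValidationError(
            f"unknown modification state {label!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


def _as_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class DuplexSite:
    """One imino-bearing base-pair position in a named duplex.

    Only guanine (N1-H) and thymine (N3-H) carry imino protons.  For a GC pair
    the partner cytosine's modification state governs the intrinsic exchange
    chemistry; AT pairs have no cytosine partner, so ``partner_modification``
    must be ``None`` exactly when ``base == "T"``.
    """

    duplex_id: str
    position: int
    base: str
    partner_modification: Optional[ModificationState] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.base not in ("G", "T"):
            raise ValidationError(
                f"base must be 'G' or 'T' (imino-bearing), got {self.base!r}"
            )
        if (self.partner_modification is None) != (self.base == "T"):
            raise ValidationError(
                "partner_modification must be None if and only if base is 'T' "
                f"(got base={self.base!r}, partner={self.partner_modification!r})"
            )

    def to_dict(self) -> dict:
        return {
            "duplex": self.duplex_id,
            "position": self.position,
            "base": self.base,
            "partner_mod": None
            if self.partner_modification is None
            else self.partner_modification.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DuplexSite":
        pm = d.get("partner_mod")
        return cls(
            duplex_id=str(d["duplex"]),
            position=int(d["position"]),
            base=str(d["base"]),
            partner_modification=None if pm in (None, "", "none") else ModificationState.parse(str(pm)),
        )

    @property
    def key(self) -> tuple:
        return (self.duplex_id, self.position)


@dataclass(frozen=True)
class BuildUpCurve:
    """CLEANEX-PM intensity-ratio build-up I(tau_m)/I0 versus mixing time."""

    site: DuplexSite
    mixing_times: np.ndarray  # s
    ratios: np.ndarray  # dimensionless
    ratio_errors: np.ndarray  # dimensionless, > 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mixing_times", _as_array(self.mixing_times, "mixing_times"))
        object.__setattr__(self, "ratios", _as_array(self.ratios, "ratios"))
        object.__setattr__(self, "ratio_errors", _as_array(self.ratio_errors, "ratio_errors"))
        n = len(self.mixing_times)
        if n < 3:
            raise ValidationError(f"need >= 3 mixing times, got {n}")
        if len(self.ratios) != n or len(self.ratio_errors) != n:
            raise ValidationError("mixing_times, ratios and ratio_errors must have equal length")
        if np.any(self.mixing_times <= 0) or np.any(np.diff(self.mixing_times) <= 0):
            raise ValidationError("mixing_times must be strictly increasing and > 0")
        if np.any(self.ratios < 0):
            raise ValidationError("intensity ratios must be >= 0")
        if np.any(self.ratio_errors <= 0):
            raise ValidationError("ratio_errors must be > 0")


@dataclass(frozen=True)
class DispersionCurve:
    """Effective R1rho versus spin-lock field strength, at constant relaxation period."""

    site: DuplexSite
    spinlock_nu1: np.ndarray  # Hz
    r1rho: np.ndarray  # 1/s
    r1rho_errors: np.ndarray  # 1/s
    relax_period: float  # s

    def __post_init__(self) -> None:
        object.__setattr__(self, "spinlock_nu1", _as_array(self.spinlock_nu1, "spinlock_nu1"))
        object.__setattr__(self, "r1rho", _as_array(self.r1rho, "r1rho"))
        object.__setattr__(self, "r1rho_errors", _as_array(self.r1rho_errors, "r1rho_errors"))
        n = len(self.spinlock_nu1)
        if n < 4:
            raise ValidationError(f"need >= 4 spin-lock points, got {n}")
        if len(self.r1rho) != n or len(self.r1rho_errors) != n:
            raise ValidationError("spinlock_nu1, r1rho and r1rho_errors must have equal length")
        if np.any(self.spinlock_nu1 <= 0) or np.any(np.diff(self.spinlock_nu1) <= 0):
            raise ValidationError("spinlock_nu1 must be strictly increasing and > 0")
        if np.any(self.r1rho <= 0):
            raise ValidationError("r1rho values must be > 0")
        if np.any(self.r1rho_errors <= 0):
            raise ValidationError("r1rho_errors must be > 0")
        if self.relax_period <= 0:
            raise ValidationError("relax_period must be > 0")


@dataclass
class CleanexFit:
    """Fitted CLEANEX-PM build-up parameters.

    ``ra`` and ``rb`` are the apparent relaxation rates of the imino proton and
    the water proton respectively.  When the build-up amplitude is below the
    detection limit, ``detected`` is False and ``k1h`` is NaN ("not determined"
    rather than zero).
    """

    k1h: float
    ra: float
    rb: float
    k1h_err: float = 0.0
    ra_err: float = 0.0
    rb_err: float = 0.0
    chi2_reduced: float = math.nan
    detected: bool = True
    converged: bool = True
    at_bound: bool = False

    def __post_init__(self) -> None:
        if self.detected:
            for name in ("k1h", "ra", "rb"):
                v = getattr(self, name)
                if not (v >= 0):
                    raise ValidationError(f"{name} must be >= 0, got {v}")
        for name in ("k1h_err", "ra_err", "rb_err"):
            v = getattr(self, name)
            if not (math.isnan(v) or v >= 0):
                raise ValidationError(f"{name} must be >= 0, got {v}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CleanexFit":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


_PHI_CONSISTENCY_RTOL = 1e-12


@dataclass
class ExchangeFit:
    """Fitted two-state exchange parameters from an R1rho dispersion profile.

    ``kex = kopen + kclose``.  In the fast-exchange parameterization only the
    composite amplitude ``phi_ex = pA*pB*dw**2`` is identifiable; ``pb`` is then
    a fixed assumption and ``dw`` is derived from it, so the invariant
    ``phi_ex == (1-pb)*pb*dw**2`` holds in either mode.
    """

    r20: float
    kex: float
    pb: float
    dw: float  # rad/s
    phi_ex: float  # rad^2/s^2
    r20_err: float = 0.0
    kex_err: float = 0.0
    pb_err: float = 0.0
    dw_err: float = 0.0
    phi_ex_err: float = 0.0
    chi2_reduced: float = math.nan
    parameterization_mode: str = "fast_exchange"
    no_rex: bool = False
    converged: bool = True

    def __post_init__(self) -> None:
        if self.parameterization_mode not in ("full", "fast_exchange"):
            raise ValidationError(
                f"parameterization_mode must be 'full' or 'fast_exchange', "
                f"got {self.parameterization_mode!r}"
            )
        if not (self.r20 > 0):
            raise ValidationError(f"r20 must be > 0, got {self.r20}")
        if self.no_rex:
            return
        if not (self.kex > 0):
            raise ValidationError(f"kex must be > 0, got {self.kex}")
        if not (0.0 <= self.pb <= 0.5):
            raise ValidationError(f"pb must be in [0, 0.5], got {self.pb}")
        expected = (1.0 - self.pb) * self.pb * self.dw**2
        if expected > 0 and self.phi_ex > 0:
            if abs(self.phi_ex - expected) > _PHI_CONSISTENCY_RTOL * max(abs(expected), abs(self.phi_ex)):
                raise ValidationError(
                    f"phi_ex={self.phi_ex} inconsistent with (1-pb)*pb*dw^2={expected}"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExchangeFit":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass
class KineticsSummary:
    """Combined per-site opening/closing summary.

    ``k1h_norm`` is the exchange rate normalized by the modification-dependent
    intrinsic rate, interpretable as the opening equilibrium constant Kop on a
    common arbitrary scale.  ``kclose_approx`` equals kex under the
    small-open-population assumption; ``rel_kopen_index = k1h_norm * kex`` is a
    relative opening-rate index (Kop*kclose up to one unknown constant).
    ``ex2_ok`` flags whether the fast-closing (EX2) assumption is credible.
    """

    site: DuplexSite
    k1h_norm: float = math.nan
    k1h_norm_err: float = math.nan
    rel_kop: float = math.nan
    kclose_approx: float = math.nan
    rel_kopen_index: float = math.nan
    ex2_ok: bool = False
    detected: bool = True
    no_rex: bool = False

    def __post_init__(self) -> None:
        if not math.isnan(self.rel_kopen_index) and self.rel_kopen_index < 0:
            raise ValidationError("rel_kopen_index must be >= 0")

    def to_dict(self) -> dict:
        d = self.site.to_dict()
        d.update(
            k1h_norm=self.k1h_norm,
            k1h_norm_err=self.k1h_norm_err,
            rel_kop=self.rel_kop,
            kclose_approx=self.kclose_approx,
            rel_kopen_index=self.rel_kopen_index,
            ex2_ok=self.ex2_ok,
            detected=self.detected,
            no_rex=self.no_rex,
        )
        return d
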