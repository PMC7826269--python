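"""Study configuration: YAML schema, validation, defaults.

User-facing units follow laboratory convention — mixing times in ms,
spin-lock fields in kHz, relaxation period in ms — and are converted to SI
exactly once, when the config is turned into a :class:`StudyDesign`.
Unknown keys anywhere in the file are rejected by name, so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .kinetics import DEFAULT_EX2_THRESHOLD, PkaTable
from .synthetic import DEFAULT_MIXING_TIMES, DEFAULT_NU1_GRID, StudyDesign
from .types import ModificationState, ValidationError

__all__ = ["StudyConfig", "load_config"]


@dataclass
class StudyConfig:
    """Validated pipeline settings (see package docs for the YAML layout)."""

    seed: int = 0
    # acquisition
    mixing_times_ms: list[float] = field(
        default_factory=lambda: (DEFAULT_MIXING_TIMES * 1e3).tolist())
    spinlock_min_khz: float = 0.5
    spinlock_max_khz: float = 15.0
    spinlock_points: int = 12
    relax_period_ms: float = 20.0
    baseline_sigma: float = 0.005
    # fitting
    fit_mode: str = "fast_exchange"
    pb: float = 0.001
    mc_draws: int = 200
    ex2_threshold: float = DEFAULT_EX2_THRESHOLD
    # normalization
    normalization: str = "rounded_2sf"
    pka_overrides: dict = field(default_factory=dict)
    pka_guanine_n1: float = 9.4
    reference_duplex: str = "C/C"
    duplexes: list[str] = field(default_factory=lambda: [
        "C/C", "5mC/C", "5mC/5mC", "C/5mC", "5hmC/C", "5hmC/5mC"])
    sequence: str | None = None  # optional 12-bp duplex sequence annotation

    def __post_init__(self) -> None:
        if not (0.0 < self.pb <= 0.5):
            raise ValidationError(f"pb must be in (0, 0.5], got {self.pb}")
        if self.fit_mode not in ("fast_exchange", "full"):
            raise ValidationError(f"unknown fit mode {self.fit_mode!r}")
        if self.normalization not in ("rounded_2sf", "full_precision"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        if self.spinlock_min_khz <= 0 or self.spinlock_max_khz <= self.spinlock_min_khz:
            raise ValidationError("spin-lock range must satisfy 0 < min < max")
        if self.mc_draws < 0:
            raise ValidationError("mc_draws must be >= 0")
        if any(t <= 0 for t in self.mixing_times_ms):
            raise ValidationError("mixing times must be > 0")

    def design(self) -> StudyDesign:
        nu1 = (np.geomspace(self.spinlock_min_khz, self.spinlock_max_khz,
                            self.spinlock_points) * 1e3
               if self.spinlock_points != len(DEFAULT_NU1_GRID)
               or self.spinlock_min_khz != 0.5 or self.spinlock_max_khz != 15.0
               else DEFAULT_NU1_GRID.copy())
        return StudyDesign(
            duplexes=tuple(self.duplexes),
            mixing_times=np.asarray(self.mixing_times_ms) * 1e-3,
            spinlock_nu1=nu1,
            relax_period=self.relax_period_ms * 1e-3,
            baseline_sigma=self.baseline_sigma,
        )

    def pka_table(self) -> PkaTable:
        n3 = dict(PkaTable().pka_n3)
        for label, value in self.pka_overrides.items():
            n3[ModificationState.parse(str(label))] = float(value)
        return PkaTable(pka_n3=n3, pka_n1_g=self.pka_guanine_n1)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "acquisition": {
                "mixing_times_ms": list(self.mixing_times_ms),
                "spinlock_min_khz": self.spinlock_min_khz,
                "spinlock_max_khz": self.spinlock_max_khz,
                "spinlock_points": self.spinlock_points,
                "relax_period_ms": self.relax_period_ms,
                "baseline_sigma": self.baseline_sigma,
            },
            "fit": {
                "mode": self.fit_mode,
                "pb": self.pb,
                "mc_draws": self.mc_draws,
                "ex2_threshold": self.ex2_threshold,
            },
            "normalization": self.normalization,
            "pka": {**{k: v for k, v in self.pka_overrides.items()},
                    "guanine_n1": self.pka_guanine_n1},
            "reference_duplex": self.reference_duplex,
            "duplexes": list(self.duplexes),
            "sequence": self.sequence,
        }


_TOP_KEYS = {"seed", "acquisition", "fit", "normalization", "pka",
             "reference_duplex", "duplexes", "sequence"}
_ACQ_KEYS = {"mixing_times_ms", "spinlock_min_khz", "spinlock_max_khz",
             "spinlock_points", "relax_period_ms", "baseline_sigma"}
_FIT_KEYS = {"mode", "pb", "mc_draws", "ex2_threshold"}


def _check_keys(d: dict, allowed: set, scope: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in {scope}; allowed: {sorted(allowed)}"
        )


def load_config(path) -> StudyConfig:
    """Load and validate a YAML study configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config must be a YAML mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    acq = raw.get("acquisition", {}) or {}
    fit = raw.get("fit", {}) or {}
    pka = dict(raw.get("pka", {}) or {})
    _check_keys(acq, _ACQ_KEYS, "acquisition")
    _check_keys(fit, _FIT_KEYS, "fit")
    guanine = float(pka.pop("guanine_n1", 9.4))
    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    for k in _ACQ_KEYS & set(acq):
        kwargs[k] = acq[k]
    if "mode" in fit:
        kwargs["fit_mode"] = fit["mode"]
    for k in ("pb", "mc_draws", "ex2_threshold"):
        if k in fit:
            kwargs[k] = fit[k]
    if "normalization" in raw:
        kwargs["normalization"] = raw["normalization"]
    if "reference_duplex" in raw:
        kwargs["reference_duplex"] = raw["reference_duplex"]
    if "duplexes" in raw:
        kwargs["duplexes"] = list(raw["duplexes"])
    if "sequence" in raw:
        kwargs["sequence"] = raw["sequence"]
    return StudyConfig(pka_overrides=pka, pka_guanine_n1=guanine, **kwargs)
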