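"""Synthetic study generation and numerical two-pool/two-state exchange oracles.

This module plays two roles.  First, it provides numerical simulators that are
independent of the closed-form expressions fitted elsewhere in the package:

* a coupled two-pool ODE for CLEANEX-PM magnetization transfer, integrated
  numerically (the closed-form build-up equation is its exact solution);
* a six-dimensional two-state Bloch-McConnell propagator for the on-resonance
  spin-lock experiment, from which R1rho is extracted by the same two-point
  log formula the experiment uses.

Second, it assembles a full synthetic six-duplex study — build-up and
dispersion tables with baseline-noise-limited Gaussian errors plus a manifest
of ground-truth parameters — so that every fitting stage can be validated by
parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .cleanex import cleanex_model
from .r1rho import r1rho_error_from_noise
from .types import (
    BuildUpCurve,
    DispersionCurve,
    DuplexSite,
    ModificationState,
    ValidationError,
)

__all__ = [
    "GroundTruthSite",
    "StudyDesign",
    "SyntheticStudy",
    "cleanex_ratios_numeric",
    "simulate_cleanex_numeric",
    "simulate_r1rho_bm",
    "r1rho_bm_eigenvalue",
    "estimate_cross_relaxation_bias",
    "generate_study",
    "default_truths",
    "synthetic_melting_curve",
    "DEFAULT_MIXING_TIMES",
    "DEFAULT_NU1_GRID",
    "DEFAULT_RELAX_PERIOD",
]

TWO_PI = 2.0 * math.pi

# Acquisition defaults: mixing times 5-200 ms, spin-lock fields 0.5-15 kHz
# (12 log-spaced points), constant relaxation period 20 ms.
DEFAULT_MIXING_TIMES = np.array([0.005, 0.010, 0.015, 0.020, 0.050, 0.100, 0.200])
DEFAULT_NU1_GRID = np.geomspace(500.0, 15000.0, 12)
DEFAULT_RELAX_PERIOD = 0.020


@dataclass(frozen=True)
class GroundTruthSite:
    """True simulation parameters for one imino site."""

    site: DuplexSite
    k1h_true: float  # 1/s
    ra_true: float  # 1/s
    rb_true: float  # 1/s
    r20_true: float  # 1/s
    kex_true: float  # 1/s
    pb_true: float
    dw_true: float  # rad/s
    noise_sigma: float = 0.002  # sd of the intensity-ratio noise

    def __post_init__(self) -> None:
        for name in ("k1h_true", "ra_true", "rb_true", "r20_true", "kex_true"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0.0 < self.pb_true < 0.5):
            raise ValidationError(f"pb_true must be in (0, 0.5), got {self.pb_true}")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")

    @property
    def phi_ex_true(self) -> float:
        return (1.0 - self.pb_true) * self.pb_true * self.dw_true**2

    def to_dict(self) -> dict:
        d = self.site.to_dict()
        d.update(
            k1h_true=self.k1h_true, ra_true=self.ra_true, rb_true=self.rb_true,
            r20_true=self.r20_true, kex_true=self.kex_true, pb_true=self.pb_true,
            dw_true=self.dw_true, noise_sigma=self.noise_sigma,
        )
        return d


@dataclass
class StudyDesign:
    """Acquisition design of a synthetic multi-duplex study."""

    duplexes: tuple[str, ...] = (
        "C/C", "5mC/C", "5mC/5mC", "C/5mC", "5hmC/C", "5hmC/5mC",
    )
    positions: tuple[int, ...] = (6, 7, 8, 9)
    mixing_times: np.ndarray = field(default_factory=lambda: DEFAULT_MIXING_TIMES.copy())
    spinlock_nu1: np.ndarray = field(default_factory=lambda: DEFAULT_NU1_GRID.copy())
    relax_period: float = DEFAULT_RELAX_PERIOD
    baseline_sigma: float = 0.005  # spectral baseline noise relative to I0

    def __post_init__(self) -> None:
        self.mixing_times = np.asarray(self.mixing_times, dtype=float)
        self.spinlock_nu1 = np.asarray(self.spinlock_nu1, dtype=float)
        if np.any(self.mixing_times <= 0) or np.any(np.diff(self.mixing_times) <= 0):
            raise ValidationError("mixing_times must be strictly increasing and > 0")
        if np.any(self.spinlock_nu1 <= 0) or np.any(np.diff(self.spinlock_nu1) <= 0):
            raise ValidationError("spinlock_nu1 must be strictly increasing and > 0")
        if self.relax_period <= 0:
            raise ValidationError("relax_period must be > 0")


# --------------------------------------------------------------------------
# CLEANEX two-pool ODE oracle


def cleanex_ratios_numeric(k1h: float, ra: float, rb: float, mixing_times) -> np.ndarray:
    """Noise-free build-up ratios by numerical integration of the two-pool ODE.

    The model treats water as a large labeled reservoir whose magnetization
    decays at RB while feeding the imino pool through exchange at k1H:

        d(imino)/dt = -(RA + k1H) * imino + k1H * water
        d(water)/dt = -RB * water,    water(0) = 1, imino(0) = 0

    The closed-form build-up equation is the exact solution of this system,
    so the integrator serves as an independent oracle for it.
    """
    tau = np.atleast_1d(np.asarray(mixing_times, dtype=float))
    if np.any(tau <= 0):
        raise ValidationError("mixing times must be > 0")

    def rhs(_t, y):
        imino, water = y
        return [-(ra + k1h) * imino + k1h * water, -rb * water]

    sol = solve_ivp(
        rhs, (0.0, float(tau[-1])), [0.0, 1.0], t_eval=tau,
        method="DOP853", rtol=1e-12, atol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(
            f"CLEANEX ODE integration failed for k1h={k1h}, ra={ra}, rb={rb}: {sol.message}"
        )
    return sol.y[0]


def simulate_cleanex_numeric(truth: GroundTruthSite, mixing_times,
                             noise: bool = False, rng=None) -> BuildUpCurve:
    """CLEANEX-PM build-up curve via the two-pool ODE (see
    :func:`cleanex_ratios_numeric`), optionally with seeded Gaussian noise."""
    tau = np.asarray(mixing_times, dtype=float)
    ratios = cleanex_ratios_numeric(truth.k1h_true, truth.ra_true, truth.rb_true, tau)
    errors = np.full_like(ratios, max(truth.noise_sigma, 1e-6))
    if noise:
        rng = np.random.default_rng(rng)
        ratios = np.clip(ratios + rng.normal(0.0, truth.noise_sigma, size=ratios.shape), 0.0, None)
    return BuildUpCurve(
        site=truth.site, mixing_times=tau, ratios=ratios, ratio_errors=errors
    )


# --------------------------------------------------------------------------
# Two-state Bloch-McConnell spin-lock oracle


def _bm_matrix(w1: float, dw: float, r20: float, kex: float, pb: float,
               r1: float) -> np.ndarray:
    """Evolution matrix for (MxA, MyA, MzA, MxB, MyB, MzB).

    Spin-lock field w1 along +x; state A exactly on resonance (offset 0),
    state B offset by dw about z.  Exchange kAB = pb*kex, kBA = (1-pb)*kex
    couples matching components.
    """
    kab = pb * kex
    kba = (1.0 - pb) * kex

    def block(offset: float) -> np.ndarray:
        return np.array([
            [-r20, offset, 0.0],
            [-offset, -r20, w1],
            [0.0, -w1, -r1],
        ])

    L = np.zeros((6, 6))
    L[:3, :3] = block(0.0) - kab * np.eye(3)
    L[3:, 3:] = block(dw) - kba * np.eye(3)
    L[:3, 3:] += kba * np.eye(3)
    L[3:, :3] += kab * np.eye(3)
    return L


def simulate_r1rho_bm(truth: GroundTruthSite, nu1: float, relax_period: float,
                      r1: float = 1.5) -> float:
    """Effective R1rho from propagating the two-state Bloch-McConnell system.

    Magnetization starts locked along +x with equilibrium populations and is
    propagated for the relaxation period T; the rate is extracted by the same
    two-point formula as the experiment, R1rho = -(1/T) ln(Mx(T)/Mx(0)).

    ``r1`` is the longitudinal rate of both states; with an on-resonance lock
    the result is insensitive to it (only exchange-generated z-magnetization
    feels R1).
    """
    if nu1 <= 0:
        raise ValidationError("nu1 must be > 0")
    if relax_period <= 0:
        raise ValidationError("relax_period must be > 0")
    w1 = TWO_PI * nu1
    pb = truth.pb_true
    L = _bm_matrix(w1, truth.dw_true, truth.r20_true, truth.kex_true, pb, r1)
    m0 = np.array([1.0 - pb, 0.0, 0.0, pb, 0.0, 0.0])
    m_t = expm(L * relax_period) @ m0
    locked = m_t[0] + m_t[3]
    if locked <= 0:
        raise ValidationError(
            f"locked magnetization non-positive at T={relax_period}s for "
            f"kex={truth.kex_true}, pb={pb}, dw={truth.dw_true}; "
            "choose a shorter relaxation period for these parameters"
        )
    return float(-math.log(locked) / relax_period)


def r1rho_bm_eigenvalue(truth: GroundTruthSite, nu1: float, r1: float = 1.5) -> float:
    """Cross-check extraction: R1rho as the slowest-decaying eigenmode.

    Returns minus the real part of the eigenvalue of the Bloch-McConnell
    matrix whose eigenvector has the largest projection on the locked axis.
    Agrees with the two-point extraction when the decay is single-exponential.
    """
    w1 = TWO_PI * nu1
    L = _bm_matrix(w1, truth.dw_true, truth.r20_true, truth.kex_true, truth.pb_true, r1)
    vals, vecs = np.linalg.eig(L)
    lock = np.zeros(6)
    lock[0] = 1.0 - truth.pb_true
    lock[3] = truth.pb_true
    weights = np.abs(vecs.conj().T @ lock)
    return float(-vals[int(np.argmax(weights))].real)


def estimate_cross_relaxation_bias(truth: GroundTruthSite, neighbor_sigma: float,
                                   nu1_grid, relax_period: float = DEFAULT_RELAX_PERIOD,
                                   neighbor_offset: float = TWO_PI * 500.0,
                                   neighbor_r2: float = 30.0, r1: float = 1.5) -> float:
    """Maximum relative R1rho bias from rotating-frame cross-relaxation.

    A Solomon-type reconstruction: one passive neighbor proton (offset
    ``neighbor_offset`` rad/s, transverse rate ``neighbor_r2``) is appended to
    the Bloch-McConnell system and coupled to the observed spin's transverse
    components by a rotating-frame cross-relaxation rate ``neighbor_sigma``.
    Returns max over the nu1 grid of |R1rho(sigma) - R1rho(0)| / R1rho(0).
    """
    if not math.isfinite(neighbor_sigma):
        raise ValidationError("neighbor_sigma must be finite")
    nu1_grid = np.asarray(nu1_grid, dtype=float)
    worst = 0.0
    for nu1 in nu1_grid:
        base = simulate_r1rho_bm(truth, float(nu1), relax_period, r1=r1)
        with_sigma = _r1rho_with_neighbor(
            truth, float(nu1), relax_period, neighbor_sigma,
            neighbor_offset, neighbor_r2, r1,
        )
        worst = max(worst, abs(with_sigma - base) / base)
    return worst


def _r1rho_with_neighbor(truth: GroundTruthSite, nu1: float, relax_period: float,
                         sigma: float, offset: float, r2n: float, r1: float) -> float:
    w1 = TWO_PI * nu1
    pb = truth.pb_true
    L = np.zeros((9, 9))
    L[:6, :6] = _bm_matrix(w1, truth.dw_true, truth.r20_true, truth.kex_true, pb, r1)
    # passive neighbor spin, also under the lock, at its own offset
    L[6:, 6:] = np.array([
        [-r2n, offset, 0.0],
        [-offset, -r2n, w1],
        [0.0, -w1, -r1],
    ])
    # rotating-frame cross-relaxation couples transverse x/y of both spins
    for i in (0, 1):  # MxA/MyA <-> Mx/My of neighbor
        L[i, 6 + i] += -sigma
        L[6 + i, i] += -sigma
        L[3 + i, 6 + i] += -sigma * pb / max(1.0 - pb, 1e-12)
    m0 = np.zeros(9)
    m0[0], m0[3], m0[6] = 1.0 - pb, pb, 1.0
    m_t = expm(L * relax_period) @ m0
    locked = m_t[0] + m_t[3]
    if locked <= 0:
        raise ValidationError("locked magnetization non-positive in neighbor simulation")
    return float(-math.log(locked / (1.0 - pb + pb)) / relax_period)


# --------------------------------------------------------------------------
# Full-study generation

# Intrinsic-exchange scale relative to unmodified cytosine, 10^(dpKa) exact.
_KINT_REL = {
    ModificationState.C: 1.0,
    ModificationState.M5C: 10.0 ** -0.1,
    ModificationState.HM5C: 10.0 ** -0.5,
}

# Per-duplex partner-cytosine modification at each guanine position.
_DUPLEX_MODS = {
    "C/C": {},
    "5mC/C": {7: ModificationState.M5C},
    "5mC/5mC": {7: ModificationState.M5C, 8: ModificationState.M5C},
    "C/5mC": {8: ModificationState.M5C},
    "5hmC/C": {7: ModificationState.HM5C},
    "5hmC/5mC": {7: ModificationState.HM5C, 8: ModificationState.M5C},
}

# Baseline opening equilibrium scale (arbitrary units = k1H of C/C, 1/s).
_BASE_K1H = {6: 0.3, 7: 1.0, 8: 1.2, 9: 0.8}

# Relative Kop multipliers: hemi-methylation at position 7 opens G6-G9,
# >4-fold at the CpG itself; other duplexes stay near the unmodified baseline.
_REL_KOP = {
    "5mC/C": {6: 3.0, 7: 4.0, 8: 4.0, 9: 2.0},
    "C/5mC": {6: 1.5, 8: 1.5},
}

# Exchange (closing) rates: modifications speed up closing; order 1e4 1/s.
_KEX = {
    "C/C": 1.5e4, "5mC/C": 3.0e4, "5mC/5mC": 2.5e4,
    "C/5mC": 3.5e4, "5hmC/C": 2.5e4, "5hmC/5mC": 3.0e4,
}


def default_truths(design: StudyDesign | None = None) -> list[GroundTruthSite]:
    """Ground truths emulating the six-duplex CpG study.

    G6 in the unmodified duplex carries no exchange broadening (phi_ex set via
    a negligibly small dw) and the guanine paired with 5hmC has its exchange
    below the CLEANEX detection limit, mirroring sites reported as absent.
    """
    design = design or StudyDesign()
    truths: list[GroundTruthSite] = []
    for duplex in design.duplexes:
        mods = _DUPLEX_MODS.get(duplex, {})
        for pos in design.positions:
            mod = mods.get(pos, ModificationState.C)
            rel_kop = _REL_KOP.get(duplex, {}).get(pos, 1.0)
            k1h = _BASE_K1H[pos] * rel_kop * _KINT_REL[mod]
            if mod is ModificationState.HM5C:
                k1h = 0.02  # below detection: exchange not observed at 5hmC-paired G
            no_rex = duplex == "C/C" and pos == 6
            truths.append(
                GroundTruthSite(
                    site=DuplexSite(duplex_id=duplex, position=pos, base="G",
                                    partner_modification=mod),
                    k1h_true=k1h,
                    ra_true=25.0,
                    rb_true=0.5,
                    r20_true=25.0 + pos,
                    kex_true=_KEX.get(duplex, 2.0e4),
                    pb_true=0.001,
                    dw_true=TWO_PI * (0.01 if no_rex else 2800.0),
                    noise_sigma=0.002,
                )
            )
    return truths


@dataclass
class SyntheticStudy:
    """One generated study: per-site curves plus the ground-truth manifest."""

    design: StudyDesign
    truths: list[GroundTruthSite]
    buildup_curves: list[BuildUpCurve]
    dispersion_curves: list[DispersionCurve]
    seed: int

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "design": {
                "duplexes": list(self.design.duplexes),
                "positions": list(self.design.positions),
                "mixing_times_s": self.design.mixing_times.tolist(),
                "spinlock_nu1_hz": self.design.spinlock_nu1.tolist(),
                "relax_period_s": self.design.relax_period,
                "baseline_sigma": self.design.baseline_sigma,
            },
            "truths": [t.to_dict() for t in self.truths],
        }


def generate_study(design: StudyDesign, truths: list[GroundTruthSite],
                   seed: int) -> SyntheticStudy:
    """Generate a full noisy synthetic study, deterministically from the seed.

    Build-up means come from the closed-form build-up equation; dispersion
    means come from the Bloch-McConnell propagator, so downstream dispersion
    fits are validated against the independent numerical model rather than
    against the fitted expression itself.  All noise flows from a single seed,
    split per site and per experiment.
    """
    keys = [t.site.key for t in truths]
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate (duplex, position) in ground truths")

    root = np.random.SeedSequence(seed)
    site_seeds = root.spawn(len(truths))
    buildups: list[BuildUpCurve] = []
    dispersions: list[DispersionCurve] = []
    for truth, ss in zip(truths, site_seeds):
        rng_b, rng_d = (np.random.default_rng(s) for s in ss.spawn(2))

        means = cleanex_model(design.mixing_times, truth.k1h_true,
                              truth.ra_true, truth.rb_true)
        sigma = truth.noise_sigma
        ratios = means if sigma == 0 else np.clip(
            means + rng_b.normal(0.0, sigma, size=means.shape), 0.0, None)
        buildups.append(BuildUpCurve(
            site=truth.site, mixing_times=design.mixing_times.copy(),
            ratios=ratios, ratio_errors=np.full_like(means, max(sigma, 1e-6)),
        ))

        r_means = np.array([
            simulate_r1rho_bm(truth, float(nu1), design.relax_period)
            for nu1 in design.spinlock_nu1
        ])
        i_sl = np.exp(-r_means * design.relax_period)
        r_err = r1rho_error_from_noise(i_sl, 1.0, design.baseline_sigma,
                                       design.relax_period)
        r_err = np.maximum(np.asarray(r_err, dtype=float), 1e-6)
        r_obs = r_means if design.baseline_sigma == 0 else np.maximum(
            r_means + rng_d.normal(0.0, r_err), 1e-3)
        dispersions.append(DispersionCurve(
            site=truth.site, spinlock_nu1=design.spinlock_nu1.copy(),
            r1rho=r_obs, r1rho_errors=r_err, relax_period=design.relax_period,
        ))
    return SyntheticStudy(design=design, truths=list(truths),
                          buildup_curves=buildups, dispersion_curves=dispersions,
                          seed=seed)


# --------------------------------------------------------------------------
# Melting-curve synthesis (for validating Tm extraction)


def synthetic_melting_curve(tm: float, width: float = 5.0,
                            t_min: float = 25.0, t_max: float = 95.0,
                            step: float = 1.0, baseline: float = 0.4,
                            amplitude: float = 0.35, slope: float = 0.0005,
                            noise_sigma: float = 0.0, rng=None):
    """Two-state sigmoidal UV melting curve with midpoint ``tm`` (degrees C).

    Returns ``(temperatures, absorbance)``.  The transition is a logistic in
    temperature with 10-90% width ~ 4.4*width; gentle linear baselines and
    optional Gaussian noise emulate instrument output.
    """
    t = np.arange(t_min, t_max + 0.5 * step, step)
    a = baseline + slope * (t - t_min) + amplitude / (1.0 + np.exp(-(t - tm) / width))
    if noise_sigma > 0:
        rng = np.random.default_rng(rng)
        a = a + rng.normal(0.0, noise_sigma, size=a.shape)
    return t, a
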