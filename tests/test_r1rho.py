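"""R1rho computation, two-state dispersion model and fitting."""

import math

import numpy as np
import pytest

from iminokinetics.r1rho import (
    DispersionFitConfig,
    dispersion_model,
    dispersion_model_phi,
    fit_dispersion,
    r1rho_error_from_noise,
    r1rho_from_intensities,
    rex_at_min_spinlock,
)
from iminokinetics.types import DispersionCurve, ValidationError

FAST_CFG = DispersionFitConfig(mc_draws=0)


class TestR1rhoFromIntensities:
    def test_no_decay_gives_zero(self):
        assert r1rho_from_intensities(1.0, 1.0, 0.02) == 0.0

    def test_unit_decay(self):
        assert r1rho_from_intensities(math.exp(-1.0), 1.0, 0.02) == pytest.approx(50.0)

    def test_half_decay(self):
        assert r1rho_from_intensities(0.5, 1.0, 0.02) == pytest.approx(
            math.log(2.0) / 0.02)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValidationError, match="non-positive intensity"):
            r1rho_from_intensities(-0.1, 1.0, 0.02)

    def test_error_propagation(self):
        assert r1rho_error_from_noise(1.0, 1.0, 0.0, 0.02) == 0.0
        assert r1rho_error_from_noise(1.0, 1.0, 0.01, 0.02) == pytest.approx(
            50.0 * math.sqrt(2.0) * 0.01)
        # weaker surviving signal -> larger error
        assert (r1rho_error_from_noise(0.5, 1.0, 0.01, 0.02)
                > r1rho_error_from_noise(1.0, 1.0, 0.01, 0.02))


class TestDispersionModel:
    def test_no_minor_state_returns_r20(self, nu1_grid):
        assert np.all(dispersion_model(nu1_grid, 30.0, 2e4, 0.0, 5000.0) == 30.0)

    def test_degenerate_states_return_r20(self, nu1_grid):
        assert np.all(dispersion_model(nu1_grid, 30.0, 2e4, 0.01, 0.0) == 30.0)

    def test_monotone_decay_toward_r20(self, nu1_grid):
        vals = dispersion_model(nu1_grid, 30.0, 2e4, 0.005, 2 * np.pi * 1200.0)
        assert np.all(np.diff(vals) < 0)
        assert np.all(vals > 30.0)

    def test_high_power_limit(self):
        for kex in (5e3, 2e4, 1e5):
            v = dispersion_model(1e6, 30.0, kex, 0.005, 2 * np.pi * 1200.0)
            assert v - 30.0 < 1e-3

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            dispersion_model(1000.0, -1.0, 2e4, 0.005, 100.0)
        with pytest.raises(ValidationError):
            dispersion_model(1000.0, 30.0, 2e4, 1.5, 100.0)


class TestFit:
    def _curve(self, nu1_grid, r20, kex, phi, pb=0.001, sigma=0.5, rng=None,
               site=None):
        from iminokinetics.types import DuplexSite, ModificationState
        site = site or DuplexSite("C/C", 7, "G", ModificationState.C)
        means = dispersion_model_phi(nu1_grid, r20, kex, phi, pb)
        vals = means if rng is None else means + rng.normal(0, sigma, means.shape)
        return DispersionCurve(site, nu1_grid, vals, np.full_like(means, sigma), 0.02)

    def test_noise_free_self_consistency(self, nu1_grid):
        curve = self._curve(nu1_grid, 30.0, 2e4, 4e5)
        fit = fit_dispersion(curve, FAST_CFG)
        assert fit.r20 == pytest.approx(30.0, rel=1e-6)
        assert fit.kex == pytest.approx(2e4, rel=1e-6)
        assert fit.phi_ex == pytest.approx(4e5, rel=1e-6)
        assert fit.parameterization_mode == "fast_exchange"
        assert not fit.no_rex

    def test_noisy_bm_oracle_recovery(self, nu1_grid, g_site):
        """Median kex over noisy Bloch-McConnell curves within 10% of truth."""
        from iminokinetics.synthetic import GroundTruthSite, simulate_r1rho_bm
        truth = GroundTruthSite(g_site, 1.0, 25.0, 0.5, 30.0, 2.0e4, 0.001,
                                2 * np.pi * 2800.0)
        means = np.array([simulate_r1rho_bm(truth, nu, 0.02) for nu in nu1_grid])
        rng = np.random.default_rng(23)
        kexs = []
        for _ in range(50):
            vals = means + rng.normal(0, 0.5, means.shape)
            curve = DispersionCurve(g_site, nu1_grid, np.maximum(vals, 1e-3),
                                    np.full_like(means, 0.5), 0.02)
            fit = fit_dispersion(curve, FAST_CFG)
            if not fit.no_rex:
                kexs.append(fit.kex)
        assert np.median(kexs) == pytest.approx(2.0e4, rel=0.10)

    def test_flat_profile_flagged_no_rex(self, nu1_grid):
        rng = np.random.default_rng(2)
        curve = self._curve(nu1_grid, 30.0, 2e4, 0.0, rng=rng)
        fit = fit_dispersion(curve, FAST_CFG)
        assert fit.no_rex
        assert math.isnan(fit.kex)
        assert fit.r20 == pytest.approx(30.0, abs=0.5)

    def test_pb_assumption_insensitive_in_fast_exchange(self, nu1_grid):
        """Deep in fast exchange, pb fixed at 0.001 vs 0.01 moves the fit < 1%."""
        true = dict(r20=30.0, kex=5e4, pb=0.002, dw=2 * np.pi * 600.0)
        means = dispersion_model(nu1_grid, **true)
        from iminokinetics.types import DuplexSite, ModificationState
        site = DuplexSite("C/C", 7, "G", ModificationState.C)
        curve = DispersionCurve(site, nu1_grid, means, np.full_like(means, 0.5), 0.02)
        fits = [fit_dispersion(curve, DispersionFitConfig(pb_fixed=pb, mc_draws=0))
                for pb in (0.001, 0.01)]
        for attr in ("r20", "kex", "phi_ex"):
            a, b = (getattr(f, attr) for f in fits)
            assert abs(a - b) / a < 0.01

    def test_larger_phi_yields_larger_rex(self, nu1_grid):
        """AT-like (larger dw) sites show larger fitted Rex than GC-like sites."""
        rng = np.random.default_rng(9)
        rex = []
        for phi in (1e5, 4e5):
            curve = self._curve(nu1_grid, 30.0, 2e4, phi, rng=rng)
            fit = fit_dispersion(curve, FAST_CFG)
            rex.append(rex_at_min_spinlock(fit, float(nu1_grid[0])))
        assert rex[1] > rex[0] > 0.0

    def test_rex_at_min_spinlock_matches_model(self):
        from iminokinetics.types import ExchangeFit
        pb, dw = 0.005, 2 * np.pi * 1200.0
        fit = ExchangeFit(r20=30.0, kex=2e4, pb=pb, dw=dw,
                          phi_ex=(1 - pb) * pb * dw**2)
        expected = dispersion_model(500.0, 30.0, 2e4, pb, dw) - 30.0
        assert rex_at_min_spinlock(fit, 500.0) == pytest.approx(expected, rel=1e-12)
        assert rex_at_min_spinlock(fit, 5000.0) < rex_at_min_spinlock(fit, 500.0)

    def test_too_few_points_rejected(self, g_site):
        nu1 = np.array([500.0, 1000.0, 2000.0, 4000.0])
        curve = DispersionCurve(g_site, nu1, np.full(4, 30.0), np.full(4, 0.5), 0.02)
        with pytest.raises(ValidationError, match="decade"):
            fit_dispersion(curve, FAST_CFG)
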