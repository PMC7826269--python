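"""pKa normalization, EX2 bookkeeping and comparative reporting."""

import math

import numpy as np
import pytest

from iminokinetics.kinetics import (
    PkaTable,
    combine_kinetics,
    comparative_report,
    intrinsic_exchange_ratio,
    normalization_factor,
    normalize_k1h,
    round_sig,
)
from iminokinetics.types import (
    CleanexFit,
    DuplexSite,
    ExchangeFit,
    ModificationState,
    ValidationError,
)

M = ModificationState


class TestIntrinsicRatio:
    @pytest.mark.parametrize("mod,exact,rounded", [
        (M.C, 10.0**-4.9, 1.3e-5),
        (M.M5C, 10.0**-5.0, 1.0e-5),
        (M.HM5C, 10.0**-5.4, 0.40e-5),
    ])
    def test_default_pka_values(self, mod, exact, rounded):
        e, r = intrinsic_exchange_ratio(mod)
        assert e == pytest.approx(exact, rel=1e-12)
        assert r == pytest.approx(rounded, rel=1e-12)

    def test_missing_pka_entry_instructive_error(self):
        with pytest.raises(ValidationError, match="supply one explicitly"):
            intrinsic_exchange_ratio(M.CA5C)

    def test_round_sig(self):
        assert round_sig(1.2589e-5) == 1.3e-5
        assert round_sig(3.981e-6) == 4.0e-6
        assert round_sig(0.0) == 0.0


class TestNormalizationFactor:
    @pytest.mark.parametrize("mod,expected", [(M.M5C, 1.3), (M.HM5C, 3.3)])
    def test_rounded_convention(self, mod, expected):
        assert normalization_factor(mod, convention="rounded_2sf") == pytest.approx(
            expected, rel=1e-12)

    @pytest.mark.parametrize("mod,expected", [
        (M.M5C, 10.0**0.1), (M.HM5C, 10.0**0.5)])
    def test_full_precision_convention(self, mod, expected):
        assert normalization_factor(mod, convention="full_precision") == pytest.approx(
            expected, rel=1e-12)

    @pytest.mark.parametrize("convention", ["rounded_2sf", "full_precision"])
    def test_unmodified_is_unity(self, convention):
        assert normalization_factor(M.C, convention=convention) == 1.0

    def test_conventions_agree_within_six_percent(self):
        for mod in (M.M5C, M.HM5C):
            a = normalization_factor(mod, convention="rounded_2sf")
            b = normalization_factor(mod, convention="full_precision")
            assert abs(a - b) / b < 0.06


class TestNormalizeK1h:
    def test_factor_application(self):
        fit = CleanexFit(k1h=2.0, ra=25.0, rb=0.5, k1h_err=0.2)
        site = DuplexSite("5mC/C", 7, "G", M.M5C)
        nk, nke = normalize_k1h(fit, site)
        assert nk == pytest.approx(2.6)
        assert nke == pytest.approx(0.26)

        site_c = DuplexSite("C/C", 7, "G", M.C)
        assert normalize_k1h(fit, site_c)[0] == pytest.approx(2.0)

        fit1 = CleanexFit(k1h=1.0, ra=25.0, rb=0.5)
        site_h = DuplexSite("5hmC/C", 7, "G", M.HM5C)
        assert normalize_k1h(fit1, site_h)[0] == pytest.approx(3.3)

    def test_thymine_passes_through(self):
        fit = CleanexFit(k1h=5.0, ra=25.0, rb=0.5, k1h_err=0.5)
        site = DuplexSite("C/C", 4, "T", None)
        assert normalize_k1h(fit, site) == (5.0, 0.5)

    def test_undetected_propagates_nan(self):
        fit = CleanexFit(k1h=math.nan, ra=math.nan, rb=math.nan, detected=False)
        site = DuplexSite("5hmC/C", 7, "G", M.HM5C)
        nk, nke = normalize_k1h(fit, site)
        assert math.isnan(nk) and math.isnan(nke)


def _exchange(kex=4e4, pb=0.001, dwhz=1200.0):
    dw = 2 * math.pi * dwhz
    return ExchangeFit(r20=30.0, kex=kex, pb=pb, dw=dw,
                       phi_ex=(1 - pb) * pb * dw**2)


class TestCombine:
    def test_index_arithmetic_and_ex2_flag(self, g_site):
        s = combine_kinetics(2.6, 0.26, g_site, _exchange(kex=4e4))
        assert s.kclose_approx == 4e4
        assert s.rel_kopen_index == pytest.approx(1.04e5)
        assert s.ex2_ok

    def test_slow_closing_fails_ex2(self, g_site):
        s = combine_kinetics(2.6, 0.26, g_site, _exchange(kex=2000.0))
        assert not s.ex2_ok

    def test_missing_pieces_yield_partial_summary(self, g_site):
        s = combine_kinetics(math.nan, math.nan, g_site, _exchange())
        assert not s.detected and math.isnan(s.rel_kopen_index)
        s2 = combine_kinetics(2.0, 0.2, g_site, None)
        assert s2.no_rex and math.isnan(s2.rel_kopen_index)

    def test_index_proportional_to_k1h_norm(self, g_site):
        a = combine_kinetics(1.0, 0.1, g_site, _exchange())
        b = combine_kinetics(4.0, 0.4, g_site, _exchange())
        assert b.rel_kopen_index == pytest.approx(4.0 * a.rel_kopen_index)

    def test_index_invariant_under_common_kint_rescaling(self):
        """Only pKa differences matter: shifting every pKa equally is a no-op."""
        fit = CleanexFit(k1h=2.0, ra=25.0, rb=0.5, k1h_err=0.2)
        site = DuplexSite("5mC/C", 7, "G", M.M5C)
        base = PkaTable()
        shifted = PkaTable(
            pka_n3={k: v + 0.3 for k, v in base.pka_n3.items()},
            pka_n1_g=base.pka_n1_g + 0.3,
        )
        nk_a, _ = normalize_k1h(fit, site, base, "full_precision")
        nk_b, _ = normalize_k1h(fit, site, shifted, "full_precision")
        sa = combine_kinetics(nk_a, 0.1, site, _exchange())
        sb = combine_kinetics(nk_b, 0.1, site, _exchange())
        assert sa.rel_kopen_index == pytest.approx(sb.rel_kopen_index, rel=1e-12)


class TestComparativeReport:
    def _summary(self, duplex, pos, k1h, kex=4e4, mod=M.C):
        site = DuplexSite(duplex, pos, "G", mod)
        return combine_kinetics(k1h, 0.1 * k1h, site, _exchange(kex=kex))

    def test_identical_duplicates_fold_one(self):
        summaries = [self._summary("C/C", p, 1.0 + p) for p in (6, 7)]
        summaries += [self._summary("dup", p, 1.0 + p) for p in (6, 7)]
        report = comparative_report(summaries, "C/C")
        assert np.allclose(report["fold_k1h_norm"], 1.0)
        assert np.allclose(report["fold_kopen_index"], 1.0)

    def test_four_fold_contrast_reported(self):
        summaries = [self._summary("C/C", 7, 1.0),
                     self._summary("5mC/C", 7, 4.0, mod=M.M5C)]
        report = comparative_report(summaries, "C/C")
        row = report[(report.duplex == "5mC/C")].iloc[0]
        assert row.fold_k1h_norm == pytest.approx(4.0)

    def test_reference_vs_itself_exactly_one(self):
        summaries = [self._summary("C/C", 7, 1.2345)]
        report = comparative_report(summaries, "C/C")
        assert report.fold_k1h_norm.iloc[0] == 1.0

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError, match="reference duplex"):
            comparative_report([self._summary("C/C", 7, 1.0)], "nope")
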