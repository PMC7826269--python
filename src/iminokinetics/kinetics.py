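"""pKa-based normalization of exchange rates and opening/closing summaries.

Imino-proton exchange of a guanine in a GC pair is base-catalysed by the
partner cytosine's N3, so the intrinsic open-state exchange rate scales as

    kint ∝ 10^(pKa(N3;C) - pKa(N1;G)).

Cytosine modification shifts pKa(N3;C) (4.5 for C, 4.4 for 5mC, 4.0 for
5hmC; guanine N1 at 9.4), so measured k1H rates from differently modified
duplexes are only comparable after dividing out this kint difference.  Under
EX2 (closing much faster than intrinsic exchange) k1H = Kop*kint, so the
normalized rate is the opening equilibrium constant Kop on a common arbitrary
scale.  Combined with kex ≈ kclose from relaxation dispersion (open
population ≪ 1), the product (normalized k1H)×kex is a relative opening-rate
index — semi-quantitative by construction, since kint's absolute scale is
unknown.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .types import (
    CleanexFit,
    DuplexSite,
    ExchangeFit,
    KineticsSummary,
    ModificationState,
    ValidationError,
)

__all__ = [
    "PkaTable",
    "round_sig",
    "intrinsic_exchange_ratio",
    "normalization_factor",
    "normalize_k1h",
    "combine_kinetics",
    "comparative_report",
]

#: Default EX2 credibility threshold on kex / normalized-k1H.
DEFAULT_EX2_THRESHOLD = 1e3


@dataclass(frozen=True)
class PkaTable:
    """pKa values governing intrinsic imino exchange of GC pairs.

    Defaults: cytosine N3 pKa 4.5 (C), 4.4 (5mC), 4.0 (5hmC); guanine N1 pKa
    9.4.  5caC carries no default and must be supplied by the user.
    """

    pka_n3: dict = field(default_factory=lambda: {
        ModificationState.C: 4.5,
        ModificationState.M5C: 4.4,
        ModificationState.HM5C: 4.0,
    })
    pka_n1_g: float = 9.4

    def n3(self, mod: ModificationState) -> float:
        try:
            return self.pka_n3[mod]
        except KeyError:
            raise ValidationError(
                f"no pKa(N3) entry for {mod.value}; supply one explicitly "
                "(e.g. PkaTable(pka_n3={..., ModificationState.CA5C: value}))"
            ) from None


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half away from zero (0 maps to 0).

    Half-away rounding matches the convention used when quoting factors such
    as 3.25 -> 3.3; Python's built-in banker's rounding would give 3.2.
    """
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (sig - 1 - exponent)
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def intrinsic_exchange_ratio(mod: ModificationState,
                             table: PkaTable | None = None) -> tuple[float, float]:
    """Relative intrinsic exchange factor 10^(pKa(N3;C) - pKa(N1;G)).

    Returns ``(exact, rounded)`` where ``rounded`` is the value at two
    significant figures, the conventional reporting precision.
    """
    table = table or PkaTable()
    exact = 10.0 ** (table.n3(mod) - table.pka_n1_g)
    return exact, round_sig(exact, 2)


def normalization_factor(mod: ModificationState, table: PkaTable | None = None,
                         convention: str = "rounded_2sf") -> float:
    """Multiplier bringing a modified-partner k1H onto the unmodified scale.

    ``rounded_2sf``
        ratio of the two-significant-figure kint values, itself rounded to
        two significant figures (1.3 for 5mC, 3.3 for 5hmC) — the factors
        conventionally quoted.
    ``full_precision``
        exact ratio 10^(pKa(N3;C) - pKa(N3;mod)) (1.2589... for 5mC,
        3.1623... for 5hmC), preferred for new analyses.
    """
    table = table or PkaTable()
    if convention == "rounded_2sf":
        ref = intrinsic_exchange_ratio(ModificationState.C, table)[1]
        this = intrinsic_exchange_ratio(mod, table)[1]
        return round_sig(ref / this, 2)
    if convention == "full_precision":
        ref = intrinsic_exchange_ratio(ModificationState.C, table)[0]
        this = intrinsic_exchange_ratio(mod, table)[0]
        return ref / this
    raise ValidationError(
        f"unknown convention {convention!r}; use 'rounded_2sf' or 'full_precision'"
    )


def normalize_k1h(fit: CleanexFit, site: DuplexSite,
                  table: PkaTable | None = None,
                  convention: str = "rounded_2sf") -> tuple[float, float]:
    """Normalized k1H (relative-Kop scale) with its propagated error.

    Guanine sites are multiplied by the partner modification's normalization
    factor; thymine sites pass through unchanged (the pKa scheme is specific
    to cytosine-catalysed GC imino exchange).  Undetected sites propagate NaN.
    """
    if not fit.detected:
        return math.nan, math.nan
    if site.base == "T":
        return fit.k1h, fit.k1h_err
    if site.partner_modification is None:
        raise ValidationError(
            f"guanine site {site.duplex_id} position {site.position} lacks a "
            "partner modification state"
        )
    factor = normalization_factor(site.partner_modification, table, convention)
    return fit.k1h * factor, fit.k1h_err * factor


def combine_kinetics(norm_k1h: float, norm_k1h_err: float, site: DuplexSite,
                     exchange: ExchangeFit | None,
                     ex2_threshold: float = DEFAULT_EX2_THRESHOLD) -> KineticsSummary:
    """Merge the thermodynamic (Kop) and kinetic (kex) views of one site.

    ``kclose_approx = kex`` (open population ≪ 1) and
    ``rel_kopen_index = norm_k1h * kex``, i.e. Kop*kclose up to the unknown
    kint constant.  Missing pieces — an undetected build-up or a flat
    dispersion profile — yield a partial summary with the matching flag set
    rather than an error.
    """
    detected = not math.isnan(norm_k1h)
    no_rex = exchange is None or exchange.no_rex
    kex = math.nan if no_rex else exchange.kex
    index = norm_k1h * kex if detected and not no_rex else math.nan
    ex2_ok = bool(
        detected and not no_rex and norm_k1h > 0 and kex / norm_k1h >= ex2_threshold
    )
    return KineticsSummary(
        site=site,
        k1h_norm=norm_k1h,
        k1h_norm_err=norm_k1h_err,
        kclose_approx=kex,
        rel_kopen_index=index,
        ex2_ok=ex2_ok,
        detected=detected,
        no_rex=no_rex,
    )


def comparative_report(summaries: list[KineticsSummary],
                       reference_duplex: str) -> pd.DataFrame:
    """Per-position fold changes of each duplex against a reference duplex.

    Columns: duplex, position, fold changes of normalized k1H, kex and the
    opening-rate index relative to the same position in ``reference_duplex``.
    Rows where either side is missing carry NaN fold changes; the reference
    duplex compared against itself gives exactly 1.
    """
    ref = {s.site.position: s for s in summaries
           if s.site.duplex_id == reference_duplex}
    if not ref:
        raise ValidationError(f"reference duplex {reference_duplex!r} not in summaries")
    rows = []
    for s in summaries:
        r = ref.get(s.site.position)
        rows.append({
            "duplex": s.site.duplex_id,
            "position": s.site.position,
            "k1h_norm": s.k1h_norm,
            "kex": s.kclose_approx,
            "fold_k1h_norm": _ratio(s.k1h_norm, r.k1h_norm if r else math.nan),
            "fold_kex": _ratio(s.kclose_approx, r.kclose_approx if r else math.nan),
            "fold_kopen_index": _ratio(s.rel_kopen_index,
                                       r.rel_kopen_index if r else math.nan),
        })
    df = pd.DataFrame(rows)
    return df.sort_values(["duplex", "position"]).reset_index(drop=True)


def _ratio(a: float, b: float) -> float:
    if math.isnan(a) or math.isnan(b) or b == 0:
        return math.nan
    if a == b:
        return 1.0
    return a / b


def rel_kop_vs_reference(summaries: list[KineticsSummary],
                         reference_duplex: str) -> list[KineticsSummary]:
    """Fill each summary's ``rel_kop`` with its k1h_norm fold change vs the reference."""
    ref = {s.site.position: s.k1h_norm for s in summaries
           if s.site.duplex_id == reference_duplex}
    out = []
    for s in summaries:
        out.append(replace(s, rel_kop=_ratio(s.k1h_norm, ref.get(s.site.position, math.nan))))
    return out
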