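"""Tab-delimited interchange tables for every pipeline stage.

All tables are plain text, tab-separated, with a mandatory header and
``#``-prefixed comment lines; numbers are serialized at full precision
(``repr``), so write-then-read round-trips losslessly.  Column schemas:

build-up      duplex position base partner_mod tau_m_s ratio ratio_err
dispersion    duplex position base partner_mod nu1_hz r1rho_s r1rho_err_s T_s
cleanex fits  duplex position base partner_mod k1h_s k1h_err_s ra_s ra_err_s
              rb_s rb_err_s chi2_reduced detected converged
exchange fits duplex position base partner_mod r20_s r20_err_s kex_s kex_err_s
              pb pb_err dw_rad_s dw_err_rad_s phi_ex phi_ex_err chi2_reduced
              mode no_rex converged
summary       duplex position base partner_mod k1h_norm k1h_norm_err rel_kop
              kclose_approx rel_kopen_index ex2_ok detected no_rex
"""

from __future__ import annotations

import io
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BuildUpCurve,
    CleanexFit,
    DispersionCurve,
    DuplexSite,
    ExchangeFit,
    KineticsSummary,
    ValidationError,
)

__all__ = [
    "read_table",
    "write_table",
    "write_buildup_curves",
    "read_buildup_curves",
    "write_dispersion_curves",
    "read_dispersion_curves",
    "write_cleanex_fits",
    "read_cleanex_fits",
    "write_exchange_fits",
    "read_exchange_fits",
    "write_summaries",
    "read_melting_curve",
    "read_helical_table",
]

BUILDUP_COLUMNS = ["duplex", "position", "base", "partner_mod",
                   "tau_m_s", "ratio", "ratio_err"]
DISPERSION_COLUMNS = ["duplex", "position", "base", "partner_mod",
                      "nu1_hz", "r1rho_s", "r1rho_err_s", "T_s"]
CLEANEX_FIT_COLUMNS = ["duplex", "position", "base", "partner_mod",
                       "k1h_s", "k1h_err_s", "ra_s", "ra_err_s", "rb_s", "rb_err_s",
                       "chi2_reduced", "detected", "converged"]
EXCHANGE_FIT_COLUMNS = ["duplex", "position", "base", "partner_mod",
                        "r20_s", "r20_err_s", "kex_s", "kex_err_s", "pb", "pb_err",
                        "dw_rad_s", "dw_err_rad_s", "phi_ex", "phi_ex_err",
                        "chi2_reduced", "mode", "no_rex", "converged"]
SUMMARY_COLUMNS = ["duplex", "position", "base", "partner_mod",
                   "k1h_norm", "k1h_norm_err", "rel_kop", "kclose_approx",
                   "rel_kopen_index", "ex2_ok", "detected", "no_rex"]

_NUMERIC = {
    "tau_m_s", "ratio", "ratio_err", "nu1_hz", "r1rho_s", "r1rho_err_s", "T_s",
    "k1h_s", "k1h_err_s", "ra_s", "ra_err_s", "rb_s", "rb_err_s", "chi2_reduced",
    "r20_s", "r20_err_s", "kex_s", "kex_err_s", "pb", "pb_err", "dw_rad_s",
    "dw_err_rad_s", "phi_ex", "phi_ex_err", "k1h_norm", "k1h_norm_err", "rel_kop",
    "kclose_approx", "rel_kopen_index", "value",
}


def read_table(path, schema: list[str]) -> pd.DataFrame:
    """Read a tab-delimited table and validate it against a column schema.

    Unknown or missing columns, and non-numeric cells in numeric columns, are
    rejected with messages naming the column (and the offending row, 1-based
    over data rows).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     skip_blank_lines=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in schema if c not in df.columns]
    unknown = [c for c in df.columns if c not in schema]
    if missing or unknown:
        raise ValidationError(
            f"table {path} does not match schema: missing columns {missing}, "
            f"unknown columns {unknown}"
        )
    out = pd.DataFrame(index=df.index)
    for col in schema:
        raw = df[col].astype(str).str.strip()
        if col in _NUMERIC:
            vals = pd.to_numeric(raw, errors="coerce")
            bad = vals.isna() & ~raw.str.lower().isin(["nan", ""])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
                raise ValidationError(
                    f"non-numeric value {raw[bad].iloc[0]!r} in column {col!r}, "
                    f"data row {row} of {path}"
                )
            # exact round-trip parsing: element-wise Python float()
            out[col] = raw.where(~raw.str.lower().isin(["nan", ""]),
                                 other="nan").map(float)
        elif col in ("detected", "converged", "no_rex", "ex2_ok"):
            out[col] = raw.str.lower().map({"true": True, "false": False})
        elif col in ("position", "frame"):
            out[col] = raw.astype(int)
        else:
            out[col] = raw.where(raw.str.lower() != "none", other=None)
    return out


def _fmt(x) -> str:
    if isinstance(x, float):
        return repr(x)
    return str(x)


def write_table(path, df: pd.DataFrame, comment: str | None = None) -> None:
    """Write a table tab-delimited at full float precision."""
    path = Path(path)
    buf = io.StringIO()
    if comment:
        for line in comment.splitlines():
            buf.write(f"# {line}\n")
    buf.write("\t".join(df.columns) + "\n")
    for _, row in df.iterrows():
        buf.write("\t".join(_fmt(v) for v in row) + "\n")
    path.write_text(buf.getvalue())


def _site_cols(site: DuplexSite) -> dict:
    d = site.to_dict()
    d["partner_mod"] = d["partner_mod"] if d["partner_mod"] is not None else "none"
    return d


def _site_from_row(row) -> DuplexSite:
    pm = row["partner_mod"]
    return DuplexSite.from_dict({
        "duplex": row["duplex"], "position": int(row["position"]),
        "base": row["base"],
        "partner_mod": None if pm in (None, "none", "") else pm,
    })


# ---------------------------------------------------------------- build-up


def write_buildup_curves(path, curves: list[BuildUpCurve]) -> None:
    rows = []
    for c in curves:
        sc = _site_cols(c.site)
        for tau, r, e in zip(c.mixing_times, c.ratios, c.ratio_errors):
            rows.append({**sc, "tau_m_s": float(tau), "ratio": float(r),
                         "ratio_err": float(e)})
    write_table(path, pd.DataFrame(rows, columns=BUILDUP_COLUMNS))


def read_buildup_curves(path) -> list[BuildUpCurve]:
    df = read_table(path, BUILDUP_COLUMNS)
    neg = df["tau_m_s"] <= 0
    if neg.any():
        row = int(np.flatnonzero(neg.to_numpy())[0]) + 1
        raise ValidationError(f"non-positive mixing time at data row {row} of {path}")
    curves = []
    for _, grp in df.groupby(["duplex", "position"], sort=False):
        grp = grp.sort_values("tau_m_s")
        curves.append(BuildUpCurve(
            site=_site_from_row(grp.iloc[0]),
            mixing_times=grp["tau_m_s"].to_numpy(),
            ratios=grp["ratio"].to_numpy(),
            ratio_errors=grp["ratio_err"].to_numpy(),
        ))
    return curves


# -------------------------------------------------------------- dispersion


def write_dispersion_curves(path, curves: list[DispersionCurve]) -> None:
    rows = []
    for c in curves:
        sc = _site_cols(c.site)
        for nu1, r, e in zip(c.spinlock_nu1, c.r1rho, c.r1rho_errors):
            rows.append({**sc, "nu1_hz": float(nu1), "r1rho_s": float(r),
                         "r1rho_err_s": float(e), "T_s": c.relax_period})
    write_table(path, pd.DataFrame(rows, columns=DISPERSION_COLUMNS))


def read_dispersion_curves(path) -> list[DispersionCurve]:
    df = read_table(path, DISPERSION_COLUMNS)
    curves = []
    for _, grp in df.groupby(["duplex", "position"], sort=False):
        grp = grp.sort_values("nu1_hz")
        curves.append(DispersionCurve(
            site=_site_from_row(grp.iloc[0]),
            spinlock_nu1=grp["nu1_hz"].to_numpy(),
            r1rho=grp["r1rho_s"].to_numpy(),
            r1rho_errors=grp["r1rho_err_s"].to_numpy(),
            relax_period=float(grp["T_s"].iloc[0]),
        ))
    return curves


# -------------------------------------------------------------------- fits


def write_cleanex_fits(path, fits: list[tuple[DuplexSite, CleanexFit]]) -> None:
    rows = []
    for site, f in fits:
        rows.append({**_site_cols(site),
                     "k1h_s": f.k1h, "k1h_err_s": f.k1h_err,
                     "ra_s": f.ra, "ra_err_s": f.ra_err,
                     "rb_s": f.rb, "rb_err_s": f.rb_err,
                     "chi2_reduced": f.chi2_reduced,
                     "detected": f.detected, "converged": f.converged})
    write_table(path, pd.DataFrame(rows, columns=CLEANEX_FIT_COLUMNS))


def read_cleanex_fits(path) -> list[tuple[DuplexSite, CleanexFit]]:
    df = read_table(path, CLEANEX_FIT_COLUMNS)
    out = []
    for _, row in df.iterrows():
        out.append((_site_from_row(row), CleanexFit(
            k1h=row["k1h_s"], ra=row["ra_s"], rb=row["rb_s"],
            k1h_err=row["k1h_err_s"], ra_err=row["ra_err_s"], rb_err=row["rb_err_s"],
            chi2_reduced=row["chi2_reduced"],
            detected=bool(row["detected"]), converged=bool(row["converged"]),
        )))
    return out


def write_exchange_fits(path, fits: list[tuple[DuplexSite, ExchangeFit]]) -> None:
    rows = []
    for site, f in fits:
        rows.append({**_site_cols(site),
                     "r20_s": f.r20, "r20_err_s": f.r20_err,
                     "kex_s": f.kex, "kex_err_s": f.kex_err,
                     "pb": f.pb, "pb_err": f.pb_err,
                     "dw_rad_s": f.dw, "dw_err_rad_s": f.dw_err,
                     "phi_ex": f.phi_ex, "phi_ex_err": f.phi_ex_err,
                     "chi2_reduced": f.chi2_reduced, "mode": f.parameterization_mode,
                     "no_rex": f.no_rex, "converged": f.converged})
    write_table(path, pd.DataFrame(rows, columns=EXCHANGE_FIT_COLUMNS))


def read_exchange_fits(path) -> list[tuple[DuplexSite, ExchangeFit]]:
    df = read_table(path, EXCHANGE_FIT_COLUMNS)
    out = []
    for _, row in df.iterrows():
        out.append((_site_from_row(row), ExchangeFit(
            r20=row["r20_s"], kex=row["kex_s"], pb=row["pb"], dw=row["dw_rad_s"],
            phi_ex=row["phi_ex"], r20_err=row["r20_err_s"], kex_err=row["kex_err_s"],
            pb_err=row["pb_err"], dw_err=row["dw_err_rad_s"],
            phi_ex_err=row["phi_ex_err"], chi2_reduced=row["chi2_reduced"],
            parameterization_mode=row["mode"], no_rex=bool(row["no_rex"]),
            converged=bool(row["converged"]),
        )))
    return out


def write_summaries(path, summaries: list[KineticsSummary]) -> None:
    rows = []
    for s in summaries:
        d = s.to_dict()
        d["partner_mod"] = d["partner_mod"] if d["partner_mod"] is not None else "none"
        rows.append(d)
    write_table(path, pd.DataFrame(rows, columns=SUMMARY_COLUMNS))


# ------------------------------------------------------------------- misc


def read_melting_curve(path):
    """Two-column (temperature_c, absorbance) tab- or whitespace-delimited table."""
    df = pd.read_csv(path, sep=r"\s+", comment="#",
                     names=["temperature_c", "absorbance"], header=None,
                     skiprows=_count_header_rows(path))
    return df["temperature_c"].to_numpy(dtype=float), df["absorbance"].to_numpy(dtype=float)


def _count_header_rows(path) -> int:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            first = line.split()[0]
            try:
                float(first)
                return 0
            except ValueError:
                return 1
    return 0


def read_helical_table(path) -> pd.DataFrame:
    """Long-format helical-parameter table: frame, position, parameter, value."""
    df = read_table(path, ["frame", "position", "parameter", "value"])
    if not math.isfinite(df["value"].astype(float).sum()):
        raise ValidationError("helical table contains non-finite values")
    return df
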