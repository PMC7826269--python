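"""Summaries of per-frame DNA helical-parameter tables (3DNA-style output).

Molecular-dynamics trajectories analysed with 3DNA yield one row of helical
parameters (roll, tilt, inclination, tip, buckle, ...) per base pair or step
per frame.  This module reduces such tables to per-position means and sample
standard deviations — the mean describes the average local geometry, the SD
the amplitude of fluctuation around it — and can difference two duplexes'
summaries.  It never runs MD or 3DNA itself.

The accepted input is a long-format table with columns
``frame, position, parameter, value`` (angles in degrees).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ValidationError

__all__ = ["summarize_helical", "difference_vs_reference"]

REQUIRED_COLUMNS = ("frame", "position", "parameter", "value")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"helical table missing columns: {missing}")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValidationError("helical parameter values must be finite")
    return table


def summarize_helical(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD per (position, parameter) over frames.

    Requires at least 2 frames per cell; cells present for some positions but
    not others are simply absent from the output (never imputed).
    """
    table = _validate(table)
    grouped = table.groupby(["position", "parameter"])["value"]
    out = grouped.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    if (out["n"] < 2).any():
        bad = out.loc[out["n"] < 2, ["position", "parameter"]].to_records(index=False)
        raise ValidationError(f"fewer than 2 frames for cells: {list(bad)}")
    return out


def difference_vs_reference(summary: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD differences of a duplex summary against a reference summary.

    Cells absent from either side are dropped.
    """
    merged = summary.merge(reference, on=["position", "parameter"],
                           suffixes=("", "_ref"), how="inner")
    merged["d_mean"] = merged["mean"] - merged["mean_ref"]
    merged["d_sd"] = merged["sd"] - merged["sd_ref"]
    return merged[["position", "parameter", "mean", "sd", "mean_ref", "sd_ref",
                   "d_mean", "d_sd"]]
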