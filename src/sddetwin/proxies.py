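"""Cross-sectional delay-proxy ratios from tabular biomarker data.

Single-timepoint measurements cannot show a temporal lag directly, but the
imbalance between an upstream marker (neutrophils), a downstream
acute-phase reactant (CRP) and a negative regulator (albumin) acts as a
structural analog of delayed inflammatory dynamics. Two unit-bearing
composites summarize it:

    tau_composite = CRP / (neutrophils + 1)
    delta_ratio   = CRP / albumin

High values indicate amplification (CRP outrunning the neutrophil signal)
or failed compensation (low albumin relative to inflammation). The module
computes both ratios for a CSV table, assigns tertiles, and hooks into the
survival machinery when event/time columns are present.

Missing values are handled per-ratio: a row lacking albumin is excluded
from delta_ratio (and its tertiles) but kept for tau_composite; exclusion
counts are reported, and no row is dropped from the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import SurvivalCurve, kaplan_meier, log_rank, tertile_split

__all__ = [
    "BiomarkerRecord",
    "tau_composite",
    "delta_ratio",
    "proxy_table",
    "proxy_survival_by_tertile",
]

REQUIRED_COLUMNS = ("subject_id", "crp", "neutrophils", "albumin")


@dataclass(frozen=True)
class BiomarkerRecord:
    """One subject's biomarker panel (assay units) and optional follow-up."""

    subject_id: int
    crp: float
    neutrophils: float
    albumin: float
    event: int | None = None
    time: float | None = None


def tau_composite(crp: float, neutrophils: float) -> float:
    """CRP / (neutrophils + 1): upstream-vs-downstream amplification proxy."""
    if crp < 0:
        raise ValueError(f"crp must be >= 0, got {crp}")
    if neutrophils < 0:
        raise ValueError(f"neutrophils must be >= 0, got {neutrophils}")
    return crp / (neutrophils + 1.0)


def delta_ratio(crp: float, albumin: float) -> float:
    """CRP / albumin: inflammation-vs-compensation imbalance proxy."""
    if crp < 0:
        raise ValueError(f"crp must be >= 0, got {crp}")
    if albumin <= 0:
        raise ValueError(f"albumin must be > 0 for delta_ratio, got {albumin}")
    return crp / albumin


def proxy_table(records) -> tuple:
    """Augment a biomarker table with both ratios and their tertiles.

    ``records`` is a DataFrame (columns subject_id, crp, neutrophils,
    albumin [, event, time]) or an iterable of :class:`BiomarkerRecord`.
    Returns ``(table, report)``: the table keeps every input row, with NaN
    ratios where inputs are missing/invalid and tertile labels computed on
    the valid rows only; the report counts per-ratio exclusions.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
        df = df.drop(columns=[c for c in ("event", "time")
                              if c in df and df[c].isna().all()])
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input table lacks required columns: {missing}")
    if len(df) == 0:
        raise ValueError("input table is empty")

    crp = pd.to_numeric(df["crp"], errors="coerce")
    neu = pd.to_numeric(df["neutrophils"], errors="coerce")
    alb = pd.to_numeric(df["albumin"], errors="coerce")
    if ((crp < 0) | (neu < 0)).any():
        raise ValueError("negative crp or neutrophil values in input")

    tau_ok = crp.notna() & neu.notna()
    delta_ok = crp.notna() & alb.notna() & (alb > 0)
    if not (tau_ok.any() or delta_ok.any()):
        raise ValueError("no record has a complete biomarker pair")

    df["tau_composite"] = np.where(tau_ok, crp / (neu + 1.0), np.nan)
    df["delta_ratio"] = np.where(delta_ok, crp / alb, np.nan)

    for col, ok in (("tau_composite", tau_ok), ("delta_ratio", delta_ok)):
        tert = pd.Series(pd.NA, index=df.index, dtype="Int64")
        if ok.any():
            tert[ok] = tertile_split(df.loc[ok, col].to_numpy())
        df[f"{col}_tertile"] = tert

    report = {
        "n_rows": int(len(df)),
        "excluded_tau_composite": int((~tau_ok).sum()),
        "excluded_delta_ratio": int((~delta_ok).sum()),
    }
    return df, report


def proxy_survival_by_tertile(table: pd.DataFrame, ratio: str = "tau_composite"):
    """Kaplan–Meier curves by ratio tertile for a table with event/time columns.

    Returns ``(curves, log-rank comparison)`` over the rows with a valid
    ratio, an event flag and a follow-up time.
    """
    for col in ("event", "time"):
        if col not in table.columns:
            raise ValueError(f"survival analysis needs column {col!r}")
    tcol = f"{ratio}_tertile"
    if tcol not in table.columns:
        raise ValueError(f"table lacks tertile column {tcol!r}; run proxy_table first")
    ok = table[tcol].notna() & table["event"].notna() & table["time"].notna()
    sub = table[ok]
    curves: list[SurvivalCurve] = []
    groups = []
    for g in (1, 2, 3):
        rows = sub[sub[tcol] == g]
        if len(rows) == 0:
            continue
        t = rows["time"].to_numpy(dtype=float)
        e = rows["event"].to_numpy(dtype=int)
        curves.append(kaplan_meier(t, e, label=f"{ratio}-T{g}"))
        groups.append((t, e))
    comparison = log_rank(groups) if len(groups) >= 2 else None
    return curves, comparison
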