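"""Batch verification and storage-dynamics summaries.

Two workflows:

* ``verification_suite`` — the model-verification correlations: ammonia-peak
  pH against sample temperature, peak CBC of the first carbonate window
  against total inorganic carbon (TIC), peak CBC of the ammonia window
  against total ammoniacal nitrogen (TAN), and peak CBC against the acid
  amount spent between pH 7.0 and 5.5. Each pairing yields a Pearson r with
  its two-sided p-value and the linear-regression line used for plotting.
  Outlying samples can be excluded only by explicit id list, never silently.

* ``storage_series`` — per-(slurry, storage, week) means and standard errors
  of initial pH, segment amounts and peak capacities over a storage series,
  with stacked-bar/line figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

PAIRINGS: dict[str, tuple[str, str]] = {
    "peakpH_vs_temperature": ("temperature_c", "peak_ph_nh3"),
    "maxCBC_vs_TIC": ("tic_kg_c_m3", "max_cbc_hco3"),
    "maxCBC_vs_TAN": ("tan_kg_n_m3", "max_cbc_nh3"),
    "maxCBC_vs_acid_amount": ("amount_7_to_5p5", "max_cbc_hco3"),
}

GROUP_KEYS = ["slurry_type", "storage", "week"]

VALUE_COLUMNS = [
    "initial_ph",
    "amount_initial_to_7",
    "amount_7_to_5p5",
    "amount_5p5_to_3",
    "amount_9p5_to_11p5",
    "max_cbc_vfa",
    "max_cbc_hco3",
    "max_cbc_nh3",
    "max_cbc_co3",
]


@dataclass(frozen=True)
class VerificationResult:
    pairing: str
    n: int
    pearson_r: float
    p_value: float
    slope: float
    intercept: float


def pearson(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with two-sided p-value (t-transform, n-2 df)."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if len(xs) != len(ys) or len(xs) < 3:
        raise ParameterError("need >= 3 paired, equal-length observations")
    if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(ys))):
        raise ParameterError("non-finite values in correlation input")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ParameterError("correlation undefined for zero-variance input")
    res = stats.pearsonr(xs, ys)
    return float(res.statistic), float(res.pvalue)


def verification_suite(
    table: pd.DataFrame,
    exclude_ids: Iterable[str] = (),
    log: list[str] | None = None,
) -> list[VerificationResult]:
    """Run the four verification correlations on a per-sample table.

    ``table`` holds one row per sample with whichever of the covariate and
    result columns in :data:`PAIRINGS` are available; each pairing uses the
    rows where both of its columns are present and finite. Pairings with
    fewer than 3 complete pairs are skipped with a notice appended to
    ``log``. Rows whose ``sample_id`` is in ``exclude_ids`` are dropped
    first — exclusions are explicit, by id, never inferred.
    """
    log = log if log is not None else []
    excluded = set(exclude_ids)
    if excluded:
        table = table[~table["sample_id"].isin(excluded)]
        log.append(f"excluded ids: {sorted(excluded)}")
    results = []
    for pairing, (xcol, ycol) in PAIRINGS.items():
        if xcol not in table.columns or ycol not in table.columns:
            log.append(f"{pairing}: skipped (missing column)")
            continue
        sub = table[[xcol, ycol]].dropna()
        if len(sub) < 3:
            log.append(f"{pairing}: skipped ({len(sub)} complete pairs < 3)")
            continue
        r, p = pearson(sub[xcol], sub[ycol])
        reg = stats.linregress(sub[xcol], sub[ycol])
        results.append(
            VerificationResult(pairing, len(sub), r, p, float(reg.slope), float(reg.intercept))
        )
    return results


def verification_table(results: Iterable[VerificationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def storage_series(table: pd.DataFrame) -> pd.DataFrame:
    """Group means and standard errors over a storage series.

    ``table`` has one row per titrated replicate keyed by slurry type,
    storage condition and week; every column of :data:`VALUE_COLUMNS` that is
    present is aggregated to mean, SEM (sd/sqrt(n) over non-missing
    replicates) and n. Weeks absent from the input stay absent — gaps are
    gaps, not zeros.
    """
    value_cols = [c for c in VALUE_COLUMNS if c in table.columns]
    if not value_cols:
        raise ParameterError("no summarisable value columns present")
    grouped = table.groupby(GROUP_KEYS, dropna=False)[value_cols]
    out = grouped.agg(["mean", "sem", "count"])
    out.columns = [f"{col}_{stat}" for col, stat in out.columns]
    return out.reset_index().sort_values(GROUP_KEYS).reset_index(drop=True)


# ---------------------------------------------------------------------------
# figures


def plot_storage_series(summary: pd.DataFrame, slurry_type: str, storage: str):
    """Stacked acid-segment bars with the initial-pH line, one storage series.

    Mirrors the classic presentation: grey = acid from initial pH to 7.0,
    blue = 7.0 to 5.5 (carbonate), red = 5.5 to 3.0 (VFA); the line is the
    initial pH on a secondary axis.
    """
    import matplotlib.pyplot as plt

    sub = summary[
        (summary["slurry_type"] == slurry_type) & (summary["storage"] == storage)
    ].sort_values("week")
    fig, ax = plt.subplots(figsize=(6, 4))
    weeks = sub["week"].to_numpy()
    bottom = np.zeros(len(sub))
    for col, label, color in [
        ("amount_initial_to_7_mean", "initial to 7.0", "0.6"),
        ("amount_7_to_5p5_mean", "7.0 to 5.5", "tab:blue"),
        ("amount_5p5_to_3_mean", "5.5 to 3.0", "tab:red"),
    ]:
        if col not in sub.columns:
            continue
        vals = sub[col].fillna(0).to_numpy()
        ax.bar(weeks, vals, bottom=bottom, label=label, color=color, width=0.6)
        bottom += vals
    ax.set_xlabel("storage week")
    ax.set_ylabel("acid amount (mol HCl kg$^{-1}$ slurry)")
    ax.legend(loc="upper left", fontsize=8)
    if "initial_ph_mean" in sub.columns:
        ax2 = ax.twinx()
        ax2.plot(weeks, sub["initial_ph_mean"], "k.-", label="initial pH")
        ax2.set_ylabel("initial pH")
    ax.set_title(f"{slurry_type}, {storage} storage")
    fig.tight_layout()
    return fig


def plot_buffer_dynamics(summary: pd.DataFrame, slurry_type: str, storage: str):
    """Peak-CBC time series of the buffer systems for one storage series."""
    import matplotlib.pyplot as plt

    sub = summary[
        (summary["slurry_type"] == slurry_type) & (summary["storage"] == storage)
    ].sort_values("week")
    fig, ax = plt.subplots(figsize=(6, 4))
    for col, label in [
        ("max_cbc_vfa_mean", "VFA"),
        ("max_cbc_hco3_mean", "HCO3-"),
        ("max_cbc_co3_mean", "CO3 2-"),
        ("max_cbc_nh3_mean", "NH3"),
    ]:
        if col in sub.columns and sub[col].notna().any():
            err = sub.get(col.replace("_mean", "_sem"))
            ax.errorbar(sub["week"], sub[col], yerr=err, marker="o", label=label)
    ax.set_xlabel("storage week")
    ax.set_ylabel("max CBC (mol kg$^{-1}$ slurry pH$^{-1}$)")
    ax.legend(fontsize=8)
    ax.set_title(f"{slurry_type}, {storage} storage")
    fig.tight_layout()
    return fig
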