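"""Quality control of titration records before modelling.

Real slurry titrations fail in recognisable ways: organic material fouls the
pH sensor (pH readings reverse against the dosing direction or stall), foam
retains titrant (large effective dose gaps), or the run never reaches the
pH window the model fits. In the source protocol such runs were excluded by
visual inspection; here that judgement is operationalised as numeric flags
with configurable thresholds, reported per record so exclusions stay
auditable.

Hard flags (``non_monotone_ph``, ``insufficient_range``) force exclusion;
soft flags (``stalled_ph``, ``large_dose_gap``, ``excess_noise``) inform but
do not exclude on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

from .cbc_model import select_fit_range
from .errors import InsufficientDataError
from .titration_io import Direction, TitrationRecord

HARD_FLAGS = frozenset({"non_monotone_ph", "insufficient_range"})
SOFT_FLAGS = frozenset({"stalled_ph", "large_dose_gap", "excess_noise"})
ALL_FLAGS = tuple(sorted(HARD_FLAGS | SOFT_FLAGS))


class Verdict(str, Enum):
    PASS = "pass"
    EXCLUDE = "exclude"


@dataclass(frozen=True)
class QCThresholds:
    """Numeric surrogates for visual exclusion; all configurable.

    ``tau_reversal``: pH units a reading may move against the titration
    direction before the record counts as non-monotone (sensor fouling).
    ``stall_steps``/``stall_dph``: this many consecutive doses each moving
    pH by less than ``stall_dph`` flags a stalled sensor.
    ``max_step_ml``/``dose_gap_factor``: a single dose increment larger than
    factor x protocol cap flags titrant retention (foam).
    ``tau_noise``: median absolute deviation of residuals from a local
    linear smooth above this flags a noisy electrode.
    """

    tau_reversal: float = 0.3
    stall_steps: int = 5
    stall_dph: float = 0.005
    max_step_ml: float = 0.5
    dose_gap_factor: float = 2.0
    tau_noise: float = 0.05
    smooth_window: int = 11


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    flags: frozenset[str] = field(default_factory=frozenset)
    verdict: Verdict = Verdict.PASS
    details: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return self.verdict is Verdict.PASS


def _running_extreme_reversal(ph: np.ndarray, acidify: bool) -> float:
    """Largest excursion against the titration direction so far."""
    if acidify:
        return float(np.max(ph - np.minimum.accumulate(ph)))
    return float(np.max(np.maximum.accumulate(ph) - ph))


def _local_linear_mad(ph: np.ndarray, window: int) -> float:
    """MAD of residuals from a centred rolling-mean smooth of the pH trace."""
    if len(ph) < window:
        return 0.0
    smooth = pd.Series(ph).rolling(window, center=True, min_periods=1).mean().to_numpy()
    resid = ph - smooth
    return float(np.median(np.abs(resid - np.median(resid))))


def evaluate_qc(record: TitrationRecord, thresholds: QCThresholds | None = None) -> QCReport:
    """Flag a record; never raises on content, only reports.

    Deterministic and independent of batch order: the verdict depends only
    on the record and the thresholds.
    """
    thr = thresholds or QCThresholds()
    ph = record.steps["ph"].to_numpy(float)
    vol = record.steps["volume_ml"].to_numpy(float)
    acidify = record.direction is Direction.ACIDIFY
    flags: set[str] = set()
    details: dict = {}

    reversal = _running_extreme_reversal(ph, acidify)
    details["max_reversal_ph"] = reversal
    if reversal > thr.tau_reversal:
        flags.add("non_monotone_ph")

    dph = np.abs(np.diff(ph))
    dosed = np.diff(vol) > 0
    stalled = (dph < thr.stall_dph) & dosed
    run, longest = 0, 0
    for s in stalled:
        run = run + 1 if s else 0
        longest = max(longest, run)
    details["longest_stall"] = longest
    if longest >= thr.stall_steps:
        flags.add("stalled_ph")

    max_gap = float(np.max(np.diff(vol))) if len(vol) > 1 else 0.0
    details["max_dose_gap_ml"] = max_gap
    if max_gap > thr.dose_gap_factor * thr.max_step_ml:
        flags.add("large_dose_gap")

    try:
        select_fit_range(record)
    except InsufficientDataError:
        flags.add("insufficient_range")

    noise = _local_linear_mad(ph, thr.smooth_window)
    details["residual_mad_ph"] = noise
    if noise > thr.tau_noise:
        flags.add("excess_noise")

    verdict = Verdict.EXCLUDE if flags & HARD_FLAGS else Verdict.PASS
    return QCReport(record.sample_id, frozenset(flags), verdict, details)


def qc_table(batch: Iterable[TitrationRecord], thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """One QC row per record: verdict plus one boolean column per flag."""
    rows = []
    for record in batch:
        report = evaluate_qc(record, thresholds)
        row = {"sample_id": report.sample_id, "verdict": report.verdict.value}
        row.update({flag: flag in report.flags for flag in ALL_FLAGS})
        row.update(report.details)
        rows.append(row)
    return pd.DataFrame(rows)
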