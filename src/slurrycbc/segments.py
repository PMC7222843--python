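"""Titrant amounts between pH bounds, computed on raw dosing data.

The storage-dynamics quantities are segment amounts: how much acid it took
to move a sample from its initial pH to 7.0, from 7.0 to 5.5 (the first
carbonate buffer's territory) and from 5.5 to 3.0 (the VFA buffer), and how
much base the 9.5-11.5 range (second carbonate system) consumed. These are
deliberately computed from the raw (amount, pH) sequence by linear
interpolation — not from the fitted polynomial — so a rejected or wiggly fit
cannot contaminate them. When the pH crosses a bound more than once (noise),
the first crossing counts: dosing is cumulative.

For a clean record the three acid segments are additive:
amount(initial -> 3.0) = sum of the three, whenever the initial pH >= 7.0.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import CoverageError, ParameterError
from .titration_io import Direction, TitrationRecord, normalize_amount

ACID_SEGMENTS = (("initial", 7.0), (7.0, 5.5), (5.5, 3.0))
BASE_SEGMENT = (9.5, 11.5)


def _amount_at_ph(amount: np.ndarray, ph: np.ndarray, bound: float, ascending: bool) -> float:
    """Cumulative amount at the first crossing of ``bound``; linear interp."""
    if ascending:
        hit = (ph[:-1] <= bound) & (ph[1:] >= bound)
    else:
        hit = (ph[:-1] >= bound) & (ph[1:] <= bound)
    idx = np.flatnonzero(hit)
    if len(idx) == 0:
        raise CoverageError(
            f"pH {bound} never crossed; trajectory spans "
            f"{ph.min():.2f}-{ph.max():.2f}",
            deepest_ph=float(ph.max() if ascending else ph.min()),
        )
    i = int(idx[0])
    if ph[i + 1] == ph[i]:
        return float(amount[i])
    frac = (bound - ph[i]) / (ph[i + 1] - ph[i])
    return float(amount[i] + frac * (amount[i + 1] - amount[i]))


def amount_between(record: TitrationRecord, ph_from: float, ph_to: float) -> float:
    """Titrant amount (mol per kg slurry) spent moving pH from ``ph_from``
    to ``ph_to``.

    For acidification ``ph_from > ph_to``; for alkalization the reverse. A
    sample that starts already past ``ph_from`` contributes from amount 0
    (the bound was "crossed" before any dosing). Raises
    :class:`CoverageError` naming the deepest pH attained when ``ph_to`` was
    never reached.
    """
    if ph_from == ph_to:
        raise ParameterError("ph_from and ph_to must differ")
    ascending = ph_to > ph_from
    if (record.direction is Direction.ACIDIFY) == ascending:
        raise ParameterError(
            f"bounds ({ph_from} -> {ph_to}) run against the titration "
            f"direction {record.direction.value}"
        )
    amount = normalize_amount(record)
    ph = record.steps["ph"].to_numpy(float)
    started_past = ph[0] > ph_from if ascending else ph[0] < ph_from
    a_from = 0.0 if started_past else _amount_at_ph(amount, ph, ph_from, ascending)
    a_to = _amount_at_ph(amount, ph, ph_to, ascending)
    return max(a_to - a_from, 0.0)


def _segment_or_nan(record: TitrationRecord, ph_from, ph_to) -> float:
    try:
        return amount_between(record, ph_from, ph_to)
    except CoverageError:
        return math.nan


def build_segment_table(batch: Iterable[TitrationRecord]) -> pd.DataFrame:
    """One row per record with the four segment amounts and the initial pH.

    Acidification records populate the three acid segments (mol HCl/kg);
    alkalization records populate the 9.5-11.5 base segment (mol OH-/kg).
    A segment the trajectory does not cover is NaN, never zero.
    """
    rows = []
    for record in batch:
        row = {
            "sample_id": record.sample_id,
            "slurry_type": record.slurry_type.value,
            "storage": record.storage.value,
            "week": record.week,
            "replicate": record.replicate,
            "direction": record.direction.value,
            "initial_ph": record.initial_ph,
            "amount_initial_to_7": math.nan,
            "amount_7_to_5p5": math.nan,
            "amount_5p5_to_3": math.nan,
            "amount_9p5_to_11p5": math.nan,
        }
        if record.direction is Direction.ACIDIFY:
            row["amount_initial_to_7"] = (
                0.0 if record.initial_ph <= 7.0
                else _segment_or_nan(record, record.initial_ph, 7.0)
            )
            row["amount_7_to_5p5"] = _segment_or_nan(record, 7.0, 5.5)
            row["amount_5p5_to_3"] = _segment_or_nan(record, 5.5, 3.0)
        else:
            row["amount_9p5_to_11p5"] = _segment_or_nan(record, *BASE_SEGMENT)
        rows.append(row)
    return pd.DataFrame(rows)
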