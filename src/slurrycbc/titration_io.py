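"""Reading, validating and writing potentiometric titration logs.

A titration log is a delimited text file with one row per dosing step and
columns for cumulative titrant volume (mL), pH and temperature (°C).
Instrument exports vary in delimiter (comma, semicolon, tab) and may use a
decimal comma; both are handled transparently. Sample- and titrant-level
metadata (slurry type, storage condition, week, replicate, titrant, molarity,
masses, titration direction) travel alongside the step table in a
:class:`TitrationRecord`.

Amounts are normalised to mol titrant per kg *slurry* (the pre-dilution
sample mass); the dilution water added to make the sample stirrable does not
enter the denominator.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DataError,
    FormatError,
    InsufficientDataError,
    ParameterError,
)

MIN_STEPS = 10  # minimum dosing steps for any downstream fit

STEP_COLUMNS = ("volume_ml", "ph", "temperature_c")


class SlurryType(str, Enum):
    FATTENING_PIG = "fattening_pig"
    DAIRY_COW = "dairy_cow"
    SOW = "sow"
    SYNTHETIC = "synthetic"


class Storage(str, Enum):
    COLD = "cold"
    WARM = "warm"
    NONE = "none"


class Direction(str, Enum):
    ACIDIFY = "acidify"
    ALKALIZE = "alkalize"
    ALKALIZE_AFTER_ACID = "alkalize_after_acid"


class Titrant(str, Enum):
    HCL = "HCl"
    NAOH = "NaOH"


@dataclass
class TitrationRecord:
    """One instrument log plus its sample and titrant metadata.

    ``steps`` is a DataFrame with columns ``volume_ml`` (cumulative titrant
    volume), ``ph`` and ``temperature_c``, ordered by volume.
    """

    sample_id: str
    direction: Direction
    titrant: Titrant
    titrant_molarity: float
    sample_mass: float
    diluent_mass: float = 0.0
    slurry_type: SlurryType = SlurryType.SYNTHETIC
    storage: Storage = Storage.NONE
    week: int = 0
    replicate: int = 1
    steps: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.direction = Direction(self.direction)
        self.titrant = Titrant(self.titrant)
        self.slurry_type = SlurryType(self.slurry_type)
        self.storage = Storage(self.storage)

    # -- derived quantities -------------------------------------------------
    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def initial_ph(self) -> float:
        return float(self.steps["ph"].iloc[0])

    @property
    def mean_temperature_c(self) -> float:
        return float(self.steps["temperature_c"].mean())

    @property
    def solution_mass(self) -> float:
        """Total mass in the titration vessel (slurry + dilution water), kg."""
        return self.sample_mass + self.diluent_mass

    def validate(self) -> "TitrationRecord":
        """Check all record invariants; return self for chaining."""
        if self.titrant_molarity <= 0:
            raise ParameterError("titrant_molarity must be > 0")
        if self.sample_mass <= 0:
            raise ParameterError("sample_mass must be > 0")
        if self.diluent_mass < 0:
            raise ParameterError("diluent_mass must be >= 0")
        if self.week < 0:
            raise ParameterError("week must be >= 0")
        if self.replicate < 1:
            raise ParameterError("replicate must be >= 1")
        if self.direction is Direction.ACIDIFY and self.titrant is not Titrant.HCL:
            raise ParameterError("acidification requires HCl titrant")
        if self.direction is not Direction.ACIDIFY and self.titrant is not Titrant.NAOH:
            raise ParameterError("alkalization requires NaOH titrant")
        missing = [c for c in STEP_COLUMNS if c not in self.steps.columns]
        if missing:
            raise FormatError(f"steps missing columns: {missing}")
        vol = self.steps["volume_ml"].to_numpy(float)
        if len(vol) and vol[0] < 0:
            raise DataError("cumulative volume must be >= 0")
        if np.any(np.diff(vol) < 0):
            raise DataError("cumulative volume must be non-decreasing")
        ph = self.steps["ph"].to_numpy(float)
        if np.any((ph <= 0) | (ph >= 14)):
            raise DataError("pH readings must lie in (0, 14)")
        return self


# ---------------------------------------------------------------------------
# reading

_VOLUME_KEYS = ("volume", "vol", "ml", "amount")
_PH_KEYS = ("ph",)
_TEMP_KEYS = ("temp", "temperature", "t")


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def _match_column(columns: Iterable[str], keys: tuple[str, ...]) -> str | None:
    for col in columns:
        low = col.strip().lower()
        if any(low == k or low.startswith(k) or k in low for k in keys):
            return col
    return None


def _parse_table(path: str | Path) -> pd.DataFrame:
    text = Path(path).read_text()
    sep = _sniff_delimiter(text[:8192])
    df = pd.read_csv(io.StringIO(text), sep=sep, comment="#", skip_blank_lines=True)
    # decimal comma (German instrument locale) only unambiguous with ; or tab
    if sep in (";", "\t") and any(df[c].dtype == object for c in df.columns):
        df = pd.read_csv(
            io.StringIO(text), sep=sep, comment="#", decimal=",", skip_blank_lines=True
        )
    return df


def read_titration(file_path: str | Path, metadata: Mapping) -> TitrationRecord:
    """Read a titration log and return a validated :class:`TitrationRecord`.

    ``metadata`` supplies the sample/titrant fields of
    :class:`TitrationRecord` (everything except ``steps``). The file must
    contain columns for cumulative volume (mL), pH and temperature (°C);
    names are matched case-insensitively, with positional fallback when the
    file has exactly three columns.

    Rows must be in dosing order (cumulative volume non-decreasing); rows
    repeating a volume are collapsed keeping the last pH reading, matching
    instrument re-reads at equilibrium.
    """
    df = _parse_table(file_path)
    cols = {}
    for name, keys in (
        ("volume_ml", _VOLUME_KEYS),
        ("ph", _PH_KEYS),
        ("temperature_c", _TEMP_KEYS),
    ):
        match = _match_column(df.columns, keys)
        if match is not None:
            cols[name] = match
    if len(cols) < 3:
        if len(df.columns) == 3:
            cols = dict(zip(STEP_COLUMNS, df.columns))
        else:
            missing = [c for c in STEP_COLUMNS if c not in cols]
            raise FormatError(
                f"{file_path}: could not identify columns {missing} "
                f"among {list(df.columns)}"
            )
    steps = df[[cols[c] for c in STEP_COLUMNS]].copy()
    steps.columns = list(STEP_COLUMNS)
    for c in STEP_COLUMNS:
        steps[c] = pd.to_numeric(steps[c], errors="raise")
    if len(steps) < MIN_STEPS:
        raise InsufficientDataError(
            f"{file_path}: {len(steps)} rows < required {MIN_STEPS}"
        )
    vol = steps["volume_ml"].to_numpy(float)
    if np.any(np.diff(vol) < 0):
        raise DataError(f"{file_path}: cumulative volume decreases between rows")
    # collapse duplicate volumes, keeping the last (equilibrated) reading
    steps = steps.groupby("volume_ml", as_index=False, sort=True).last()
    steps = steps.reset_index(drop=True)
    record = TitrationRecord(steps=steps, **dict(metadata))
    return record.validate()


def read_batch(manifest_path: str | Path) -> list[TitrationRecord]:
    """Read a YAML/JSON batch manifest mapping titration files to metadata.

    The manifest is a list of entries ``{file: <path>, <metadata fields>}``;
    relative paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    entries = yaml.safe_load(manifest_path.read_text())
    if not isinstance(entries, list):
        raise FormatError("manifest must be a list of {file, metadata} entries")
    records = []
    for entry in entries:
        entry = dict(entry)
        try:
            rel = entry.pop("file")
        except KeyError:
            raise FormatError(f"manifest entry missing 'file': {entry}") from None
        path = manifest_path.parent / rel
        records.append(read_titration(path, entry))
    return records


# ---------------------------------------------------------------------------
# normalisation and writing


def normalize_amount(record: TitrationRecord) -> np.ndarray:
    """Cumulative titrant amount in mol per kg slurry at each step.

    amount_i = volume_i [L] x molarity [mol/L] / sample_mass [kg slurry].
    The denominator is the pre-dilution slurry mass; dilution water is
    excluded.
    """
    if record.sample_mass <= 0:
        raise ParameterError("sample_mass must be > 0")
    vol_l = record.steps["volume_ml"].to_numpy(float) / 1000.0
    return vol_l * record.titrant_molarity / record.sample_mass


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    units: Mapping[str, str] | None = None,
    float_format: str = "%.6g",
) -> Path:
    """Write a tidy table as CSV with unit annotations in ``#`` header lines."""
    path = Path(path)
    try:
        with open(path, "w") as fh:
            if units:
                for col, unit in units.items():
                    fh.write(f"# {col}: {unit}\n")
            df.to_csv(fh, index=False, float_format=float_format)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, comment="#")


def write_results(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    units: Mapping[str, Mapping[str, str]] | None = None,
) -> list[Path]:
    """Write a collection of named result tables to ``out_dir`` as CSV files.

    ``results`` maps a table name (file stem) to a DataFrame; ``units``
    optionally maps table names to per-column unit strings emitted as header
    comments. Returns the written paths in stable (sorted-name) order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(results):
        table_units = (units or {}).get(name)
        written.append(write_table(results[name], out_dir / f"{name}.csv", table_units))
    return written


def record_to_frame(record: TitrationRecord) -> pd.DataFrame:
    """Flatten a record's steps with its metadata repeated per row."""
    df = record.steps.copy()
    df.insert(0, "sample_id", record.sample_id)
    df["slurry_type"] = record.slurry_type.value
    df["storage"] = record.storage.value
    df["week"] = record.week
    df["replicate"] = record.replicate
    df["direction"] = record.direction.value
    return df


def with_steps(record: TitrationRecord, steps: pd.DataFrame) -> TitrationRecord:
    """Copy a record with a replacement step table (no validation)."""
    return replace(record, steps=steps.reset_index(drop=True))
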