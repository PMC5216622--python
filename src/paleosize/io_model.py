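"""Data model and delimited-text I/O for cyst size analyses.

Three input tables drive the pipeline, all UTF-8 CSV with one header row:

* observations — ``species,period,diameter`` one row per measured cyst
  (diameter in μm, measured inside the cyst wall);
* assemblage   — ``species,period,count`` counted cysts per taxon per
  climate period, defining relative-abundance weights;
* literature   — ``species,length_min,length_max,width_min,width_max,
  diameter_min,diameter_max`` published size ranges in μm (length/width
  ranges optional when a diameter range is given, and vice versa).

Species names are matched by exact string equality after whitespace
trimming; no synonym resolution is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DuplicateKeyError, RowValidationError, SchemaError

__all__ = [
    "DiameterObservation",
    "AssemblageCount",
    "LiteratureEntry",
    "SpeciesSummary",
    "read_observations",
    "write_observations",
    "read_assemblage",
    "write_assemblage",
    "read_literature",
    "write_literature",
]


@dataclass(frozen=True)
class DiameterObservation:
    """One measured cyst: species and period labels plus diameter in μm."""

    species: str
    period: str
    diameter: float

    def __post_init__(self):
        object.__setattr__(self, "species", self.species.strip())
        object.__setattr__(self, "period", self.period.strip())
        if not self.species or not self.period:
            raise RowValidationError("species and period must be non-empty")
        if not (self.diameter > 0):
            raise RowValidationError(
                f"diameter must be positive, got {self.diameter!r}"
            )


@dataclass(frozen=True)
class AssemblageCount:
    """Counted abundance of one species in one period (whole cysts)."""

    species: str
    period: str
    count: int

    def __post_init__(self):
        object.__setattr__(self, "species", self.species.strip())
        object.__setattr__(self, "period", self.period.strip())
        if not self.species or not self.period:
            raise RowValidationError("species and period must be non-empty")
        if self.count < 0 or int(self.count) != self.count:
            raise RowValidationError(
                f"count must be a non-negative integer, got {self.count!r}"
            )
        object.__setattr__(self, "count", int(self.count))


@dataclass(frozen=True)
class LiteratureEntry:
    """Published size ranges for one species, in μm.

    ``diameter_range`` may be absent only when both ``length_range`` and
    ``width_range`` are present; the diameter range is then derived
    downstream by endpoint averaging (see :mod:`paleosize.litcompare`).
    """

    species: str
    length_range: tuple[float, float] | None = None
    width_range: tuple[float, float] | None = None
    diameter_range: tuple[int, int] | None = None

    def __post_init__(self):
        object.__setattr__(self, "species", self.species.strip())
        if not self.species:
            raise RowValidationError("species must be non-empty")
        if self.diameter_range is None and (
            self.length_range is None or self.width_range is None
        ):
            raise SchemaError(
                f"{self.species}: need a diameter range or both length "
                "and width ranges"
            )
        for name in ("length_range", "width_range", "diameter_range"):
            rng = getattr(self, name)
            if rng is None:
                continue
            lo, hi = rng
            if lo > hi:
                raise RowValidationError(
                    f"{self.species}: {name} minimum {lo} exceeds maximum {hi}"
                )
            if lo <= 0:
                raise RowValidationError(
                    f"{self.species}: {name} endpoints must be positive"
                )


@dataclass(frozen=True)
class SpeciesSummary:
    """Per-(species, period) summary: mean, sample SD, SE = SD/√n, n."""

    species: str
    period: str
    mean: float
    sd: float
    se: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise RowValidationError("sd must be non-negative")
        if self.n < 1:
            raise RowValidationError("n must be a positive integer")


OBS_COLUMNS = ("species", "period", "diameter")
ASM_COLUMNS = ("species", "period", "count")
LIT_COLUMNS = (
    "species",
    "length_min",
    "length_max",
    "width_min",
    "width_max",
    "diameter_min",
    "diameter_max",
)


def _load_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    for column in required:
        if column not in frame.columns:
            raise SchemaError(f"{path}: missing required column '{column}'")
    return frame


def _parse_float(raw, line: int, column: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise RowValidationError(
            f"column '{column}' is not numeric: {raw!r}", line=line
        ) from None
    if math.isnan(value):
        raise RowValidationError(f"column '{column}' is missing", line=line)
    return value


def read_observations(path: str | Path) -> list[DiameterObservation]:
    """Read a cyst-diameter observation table, preserving row order."""
    frame = _load_table(path, OBS_COLUMNS)
    records = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        diameter = _parse_float(row["diameter"], line, "diameter")
        try:
            records.append(
                DiameterObservation(str(row["species"]), str(row["period"]), diameter)
            )
        except RowValidationError as exc:
            raise RowValidationError(str(exc), line=line) from None
    return records


def write_observations(
    records: Iterable[DiameterObservation], path: str | Path
) -> None:
    frame = pd.DataFrame(
        [(r.species, r.period, r.diameter) for r in records], columns=OBS_COLUMNS
    )
    frame.to_csv(path, index=False)


def read_assemblage(path: str | Path) -> list[AssemblageCount]:
    """Read an assemblage count table; (species, period) must be unique."""
    frame = _load_table(path, ASM_COLUMNS)
    records: list[AssemblageCount] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in frame.iterrows():
        line = idx + 2
        count = _parse_float(row["count"], line, "count")
        try:
            record = AssemblageCount(str(row["species"]), str(row["period"]), count)
        except RowValidationError as exc:
            raise RowValidationError(str(exc), line=line) from None
        key = (record.species, record.period)
        if key in seen:
            raise DuplicateKeyError(
                f"line {line}: duplicate (species, period) = {key}"
            )
        seen.add(key)
        records.append(record)
    return records


def write_assemblage(records: Iterable[AssemblageCount], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.species, r.period, r.count) for r in records], columns=ASM_COLUMNS
    )
    frame.to_csv(path, index=False)


def _parse_range(
    row, line: int, lo_col: str, hi_col: str, as_int: bool = False
) -> tuple | None:
    lo_raw, hi_raw = row[lo_col], row[hi_col]
    lo_missing = pd.isna(lo_raw) or str(lo_raw).strip() == ""
    hi_missing = pd.isna(hi_raw) or str(hi_raw).strip() == ""
    if lo_missing and hi_missing:
        return None
    if lo_missing or hi_missing:
        raise RowValidationError(
            f"range columns '{lo_col}'/'{hi_col}' must both be present or both absent",
            line=line,
        )
    lo = _parse_float(lo_raw, line, lo_col)
    hi = _parse_float(hi_raw, line, hi_col)
    if as_int:
        return (int(round(lo)), int(round(hi)))
    return (lo, hi)


def read_literature(path: str | Path) -> list[LiteratureEntry]:
    """Read a literature size table (ranges in μm)."""
    frame = _load_table(path, LIT_COLUMNS)
    records = []
    for idx, row in frame.iterrows():
        line = idx + 2
        length = _parse_range(row, line, "length_min", "length_max")
        width = _parse_range(row, line, "width_min", "width_max")
        diameter = _parse_range(row, line, "diameter_min", "diameter_max", as_int=True)
        try:
            records.append(
                LiteratureEntry(str(row["species"]), length, width, diameter)
            )
        except (RowValidationError, SchemaError) as exc:
            raise type(exc)(f"line {line}: {exc}") from None
    return records


def write_literature(records: Iterable[LiteratureEntry], path: str | Path) -> None:
    rows = []
    for r in records:
        length = r.length_range or (None, None)
        width = r.width_range or (None, None)
        diameter = r.diameter_range or (None, None)
        rows.append((r.species, *length, *width, *diameter))
    pd.DataFrame(rows, columns=LIT_COLUMNS).to_csv(path, index=False)
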