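"""Age-length tables and their delimited-text I/O.

The canonical on-disk schema is a delimited text file (comma or tab, sniffed)
with a header row and columns ``age`` (whole years) and ``length_mm``
(total length, mm), plus an optional ``provenance`` column.  Arbitrary source
files can be ingested by passing a column mapping, so the exact headers of a
third-party export never need to be hard-coded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["AgeLengthTable", "read_age_length", "write_age_length"]


@dataclass(frozen=True)
class AgeLengthTable:
    """Individual fish records: integer age (years, from annulus counts) and
    total length (mm).

    ``provenance`` tags where the records came from: ``"raw"`` (observed),
    ``"bolstered"`` (observed plus simulated fill-in) or ``"synthetic"``
    (fully simulated).  Records are kept in insertion order; bolstering and
    simulation guarantee the original records form an unmodified prefix.
    """

    ages: np.ndarray
    lengths: np.ndarray
    provenance: str = "raw"
    max_age: int = field(default=8, compare=False)

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "lengths", lengths)
        if ages.size == 0:
            raise InputError("age-length table is empty")
        if ages.shape != lengths.shape or ages.ndim != 1:
            raise InputError("ages and lengths must be 1-D and equal length")
        if not np.all(np.isfinite(lengths)) or np.any(lengths <= 0):
            raise InputError("all lengths must be finite and positive")
        if np.any(ages < 1) or np.any(ages > self.max_age):
            raise InputError(f"ages must lie in [1, {self.max_age}]")

    # -- basic summaries -------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.ages.size)

    @property
    def observed_ages(self) -> np.ndarray:
        return np.unique(self.ages)

    @property
    def age_min(self) -> int:
        return int(self.ages.min())

    @property
    def age_max(self) -> int:
        return int(self.ages.max())

    @property
    def length_min(self) -> float:
        return float(self.lengths.min())

    @property
    def length_max(self) -> float:
        return float(self.lengths.max())

    # -- conversion ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "length_mm": self.lengths,
                "provenance": self.provenance,
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, provenance: str | None = None, max_age: int = 8
    ) -> "AgeLengthTable":
        if provenance is None:
            provenance = (
                str(frame["provenance"].iloc[0]) if "provenance" in frame else "raw"
            )
        return cls(
            ages=frame["age"].to_numpy(),
            lengths=frame["length_mm"].to_numpy(),
            provenance=provenance,
            max_age=max_age,
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    if not sample.strip():
        raise InputError(f"{path}: file is empty")
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_age_length(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    max_age: int = 8,
) -> AgeLengthTable:
    """Read an age-length table from delimited text (comma or tab, sniffed).

    ``column_map`` maps the canonical names (``age``, ``length_mm``,
    optionally ``provenance``) to the file's actual column headers, e.g.
    ``{"age": "Age", "length_mm": "TL"}``.  A header row is required.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=delim)
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing = [src for src in column_map.values() if src not in frame.columns]
        if missing:
            raise InputError(f"{path}: mapped columns {missing} not found in header")
        frame = frame.rename(columns=rename)
    for col in ("age", "length_mm"):
        if col not in frame.columns:
            raise InputError(
                f"{path}: required column {col!r} missing "
                f"(header read as {list(frame.columns)})"
            )
    return AgeLengthTable.from_frame(frame, max_age=max_age)


def write_age_length(table: AgeLengthTable, path: str | Path) -> None:
    """Write the canonical schema (age, length_mm, provenance) as CSV."""
    table.to_frame().to_csv(path, index=False)
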