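"""Reading and writing release–recapture tables and result JSON.

The CSV dialect is deliberately strict: comma-separated, UTF-8, ``.``
decimal separator, mandatory header with columns ``distance_m``,
``released``, ``caught`` and optionally ``sem``; lines starting with ``#``
are comments.  Field tables come from heterogeneous sources, and one strict
dialect avoids silent mis-parses.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import DistanceCatchRecord, ReleaseRecaptureDataset

__all__ = [
    "DatasetFormatError",
    "read_dataset",
    "write_dataset",
    "save_json",
]

REQUIRED_COLUMNS = ("distance_m", "released", "caught")


class DatasetFormatError(ValueError):
    """A release–recapture CSV could not be parsed."""


def read_dataset(
    path: str | Path, species: str = "", trap_type: str = "", note: str = ""
) -> ReleaseRecaptureDataset:
    """Parse a release–recapture CSV into a sorted dataset.

    Malformed rows are reported with their (1-based, header-inclusive)
    line position in the file.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetFormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as err:
        raise DatasetFormatError(f"{path}: {err}") from err
    missing = [col for col in REQUIRED_COLUMNS if col not in df.columns]
    if missing:
        raise DatasetFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}; "
            f"found {', '.join(df.columns)}"
        )
    has_sem = "sem" in df.columns
    records = []
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based + header line
        try:
            distance = float(row["distance_m"])
            released = _as_count(row["released"], "released")
            caught = _as_count(row["caught"], "caught")
            sem = None
            if has_sem and not pd.isna(row["sem"]):
                sem = float(row["sem"])
            records.append(
                DistanceCatchRecord(distance, released, caught, sem=sem)
            )
        except (ValueError, TypeError) as err:
            raise DatasetFormatError(f"{path}, row {rowno}: {err}") from err
    if not records:
        raise DatasetFormatError(f"{path}: no data rows")
    return ReleaseRecaptureDataset(
        tuple(records), species=species, trap_type=trap_type, note=note
    )


def _as_count(value, name: str) -> int:
    number = float(value)
    if not number.is_integer():
        raise ValueError(f"{name} must be an integer count, got {value!r}")
    return int(number)


def write_dataset(ds: ReleaseRecaptureDataset, path: str | Path) -> Path:
    """Write a dataset in the same CSV dialect :func:`read_dataset` reads."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "distance_m": ds.distances,
            "released": ds.n_released,
            "caught": ds.n_caught,
            "sem": ds.sems,
        }
    )
    header = []
    if ds.species:
        header.append(f"# species: {ds.species}")
    if ds.trap_type:
        header.append(f"# trap_type: {ds.trap_type}")
    if ds.note:
        header.append(f"# note: {ds.note}")
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(line + "\n")
        df.to_csv(fh, index=False)
    return path


def save_json(obj: dict, path: str | Path) -> Path:
    """Write a result dictionary as pretty-printed JSON (NaN-safe)."""
    path = Path(path)

    def _default(value):
        if isinstance(value, (np.integer,)):
            return int(value)
        if isinstance(value, (np.floating,)):
            return float(value)
        raise TypeError(f"not JSON serializable: {value!r}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
    return path
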