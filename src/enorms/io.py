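"""Reading single-column measurement data and writing result records.

Clinical measurement exports are typically a one-variable column in a
spreadsheet (CSV or XLSX) or a bare one-number-per-line text file.  The
readers here extract every parseable numeric cell of one column, drop
blank/non-numeric cells with a logged count, and infer the decimal
resolution of the instrument from the parsed values (e.g. conduction
velocities recorded to 0.1 m/s).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("enorms")

__all__ = ["RawColumn", "read_column", "write_result", "infer_resolution"]


class EnormsIOError(RuntimeError):
    """Fatal input/output problem (missing file, no numeric data, bad column)."""


@dataclass
class RawColumn:
    """One variable's measurements as read from a file, in file order.

    ``values`` holds every finite numeric cell of the selected column;
    cleaning (blank / non-numeric cells) happens at read time and is
    counted in ``n_dropped``.  Sorting is a separate, explicit step.
    """

    values: list[float]
    label: str = "value"
    source_path: str = ""
    n_dropped: int = 0
    resolution: float | None = field(default=None)

    def __post_init__(self) -> None:
        bad = [v for v in self.values if not math.isfinite(v)]
        if bad:
            raise ValueError(f"RawColumn contains non-finite values: {bad[:3]}")
        if self.resolution is None and self.values:
            self.resolution = infer_resolution(self.values)


def _decimals(text: str) -> int:
    """Number of decimal places in a plain decimal literal ('44.5' -> 1)."""
    text = text.strip().lower()
    if "e" in text:  # scientific notation: fall back to float repr
        return _decimals(repr(float(text)))
    if "." not in text:
        return 0
    return len(text.split(".", 1)[1].rstrip("0"))


def infer_resolution(values: Sequence[float], max_decimals: int = 10) -> float:
    """Smallest meaningful value step, from the maximum decimal count.

    Clinical instruments record at a fixed resolution; the finest decimal
    seen across the column recovers it (44.5, 43.2 -> 0.1).  Integers give
    a resolution of 1.
    """
    if not len(values):
        raise ValueError("cannot infer resolution of an empty column")
    d = max(min(_decimals(repr(float(v))), max_decimals) for v in values)
    return 10.0 ** (-d)


def _parse_cell(cell: Any) -> float | None:
    if cell is None:
        return None
    if isinstance(cell, (int, float)):
        v = float(cell)
        return v if math.isfinite(v) else None
    text = str(cell).strip()
    if not text:
        return None
    try:
        v = float(text)
    except ValueError:
        return None
    return v if math.isfinite(v) else None


def _select_column(df: pd.DataFrame, column: str | int | None, path: Path) -> pd.Series:
    if column is None:
        return df.iloc[:, 0]
    if isinstance(column, int) or (isinstance(column, str) and column.isdigit()):
        idx = int(column)
        if idx >= df.shape[1]:
            raise EnormsIOError(
                f"{path}: column index {idx} out of range (file has {df.shape[1]} columns)"
            )
        return df.iloc[:, idx]
    if column not in df.columns:
        raise EnormsIOError(
            f"{path}: column {column!r} not found; available: {list(df.columns)}"
        )
    return df[column]


def read_column(
    path: str | Path,
    column: str | int | None = None,
    sheet: str | int | None = None,
) -> RawColumn:
    """Read one numeric column from a CSV, XLSX, or plain-text file.

    The first column is used unless ``column`` names or indexes another
    one (dynamic column handling).  If the first cell of the chosen
    column is non-numeric it is treated as a header and becomes the
    column label.  Blank and non-numeric cells are dropped and counted.

    Raises
    ------
    EnormsIOError
        If the file is missing, the named column is absent, or no
        numeric value can be parsed at all.
    """
    path = Path(path)
    if not path.exists():
        raise EnormsIOError(f"input file not found: {path}")

    suffix = path.suffix.lower()
    label = path.stem
    if suffix in {".xlsx", ".xlsm", ".xls"}:
        df = pd.read_excel(path, sheet_name=sheet if sheet is not None else 0, header=None)
        series = _select_column(df, column, path)
        cells: list[Any] = series.tolist()
    elif suffix == ".csv":
        with open(path, newline="", encoding="utf-8-sig") as fh:
            rows = list(csv.reader(fh))
        if not rows:
            raise EnormsIOError(f"{path}: no numeric data (empty file)")
        header = rows[0]
        if isinstance(column, str) and not column.isdigit():
            names = [c.strip() for c in header]
            if column not in names:
                raise EnormsIOError(
                    f"{path}: column {column!r} not found; available: {names}"
                )
            idx = names.index(column)
            cells = [r[idx] if idx < len(r) else None for r in rows[1:]]
            label = column
        else:
            idx = int(column) if column is not None else 0
            cells = [r[idx] if r and idx < len(r) else None for r in rows]
    else:  # plain text, one value per line
        cells = path.read_text(encoding="utf-8-sig").splitlines()

    values: list[float] = []
    n_dropped = 0
    header_label: str | None = None
    for i, cell in enumerate(cells):
        v = _parse_cell(cell)
        if v is not None:
            values.append(v)
            continue
        text = str(cell).strip() if cell is not None else ""
        if i == 0 and text:
            header_label = text  # leading non-numeric cell = column header
        else:
            n_dropped += 1

    if header_label is not None:
        label = header_label
    if not values:
        raise EnormsIOError(f"{path}: no numeric data")
    if n_dropped:
        logger.info("%s: dropped %d blank/non-numeric cell(s)", path, n_dropped)

    # resolution from the source text where available, else from float repr
    text_cells = [str(c).strip() for c in cells if _parse_cell(c) is not None]
    if suffix not in {".xlsx", ".xlsm", ".xls"}:
        d = max(_decimals(t) for t in text_cells)
        resolution = 10.0 ** (-min(d, 10))
    else:
        resolution = infer_resolution(values)

    return RawColumn(
        values=values,
        label=label,
        source_path=str(path),
        n_dropped=n_dropped,
        resolution=resolution,
    )


def read_two_columns(
    path: str | Path, columns: tuple[Any, Any] | None = None
) -> tuple[RawColumn, RawColumn]:
    """Read two side-by-side columns (Method1, Method2), possibly ragged."""
    path = Path(path)
    if not path.exists():
        raise EnormsIOError(f"input file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xlsm", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise EnormsIOError(f"{path}: need at least two columns, found {df.shape[1]}")
    cols = columns if columns is not None else (0, 1)
    out = []
    for c in cols:
        series = _select_column(df, c, path)
        vals = [v for v in (_parse_cell(x) for x in series.tolist()) if v is not None]
        if not vals:
            raise EnormsIOError(f"{path}: column {c!r} has no numeric data")
        out.append(
            RawColumn(
                values=vals,
                label=str(series.name) if series.name is not None else str(c),
                source_path=str(path),
                n_dropped=len(series) - len(vals),
            )
        )
    return out[0], out[1]


def _flatten(record: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for key, val in record.items():
        name = f"{prefix}{key}"
        if isinstance(val, Mapping):
            flat.update(_flatten(val, prefix=f"{name}."))
        else:
            flat[name] = val
    return flat


def write_result(result: Any, path: str | Path, format: str = "json") -> Path:
    """Write a finalized result record as JSON or a flat two-column CSV.

    The written file round-trips: reading it back reproduces every
    numeric field to full float precision (JSON uses shortest-repr
    decimal literals).
    """
    path = Path(path)
    record = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    if format == "json":
        path.write_text(json.dumps(record, indent=2) + "\n", encoding="utf-8")
    elif format == "csv":
        flat = _flatten(record)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["field", "value"])
            for key, val in flat.items():
                if isinstance(val, (list, tuple)):
                    val = ";".join(repr(x) for x in val)
                writer.writerow([key, repr(val) if isinstance(val, float) else val])
    else:
        raise ValueError(f"unsupported format: {format!r} (expected 'json' or 'csv')")
    return path
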