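"""Panel and summary readers/writers, plus run manifests.

The canonical panel format is TSV: an optional ``# sampling_interval_s=``
comment line, a header row of channel labels, then one row per time point.
CSV is accepted on read. Summaries are TSV with a fixed column order and
6-significant-digit formatting.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .panel import TimeSeriesPanel

__all__ = ["read_panel", "write_panel", "read_summary", "write_summary",
           "write_manifest"]

_INTERVAL_KEY = "sampling_interval_s"


def _delimiter(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise InputError(f"format must be 'tsv' or 'csv', got {fmt!r}")
    return "," if fmt == "csv" else "\t"


def read_panel(path, fmt: str | None = None) -> TimeSeriesPanel:
    """Read a panel from TSV/CSV.

    Labels come from the header row when present (a header is any first
    row with a non-numeric token), otherwise ``ch1..chn`` are generated.
    Format errors carry the 1-based row/column location.
    """
    path = Path(path)
    sep = _delimiter(path, fmt)
    interval = None
    rows: list[list[str]] = []
    lineno_of_row: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if body.startswith(_INTERVAL_KEY):
                    try:
                        interval = float(body.split("=", 1)[1])
                    except (IndexError, ValueError):
                        raise InputError(
                            f"malformed sampling-interval comment at line {lineno}"
                        ) from None
                continue
            rows.append([cell.strip() for cell in stripped.split(sep)])
            lineno_of_row.append(lineno)
    if not rows:
        raise InputError(f"{path}: empty file")

    def to_float(cell: str):
        try:
            return float(cell)
        except ValueError:
            return None

    header: list[str] | None = None
    if any(to_float(cell) is None for cell in rows[0]):
        header = rows.pop(0)
        lineno_of_row.pop(0)
    if not rows:
        raise InputError(f"{path}: no data rows")
    width = len(rows[0])
    values = np.empty((len(rows), width))
    for i, row in enumerate(rows):
        if len(row) != width:
            raise InputError(
                f"{path}: row {i + 1} (line {lineno_of_row[i]}) has "
                f"{len(row)} fields, expected {width}"
            )
        for j, cell in enumerate(row):
            v = to_float(cell)
            if v is None or not math.isfinite(v):
                raise InputError(
                    f"{path}: non-numeric cell {cell!r} at row {i + 1}, "
                    f"column {j + 1} (line {lineno_of_row[i]})"
                )
            values[i, j] = v
    if header is not None and len(header) != width:
        raise InputError(f"{path}: header has {len(header)} labels for {width} columns")
    return TimeSeriesPanel(values, header, interval)


def write_panel(panel: TimeSeriesPanel, path, fmt: str | None = None) -> None:
    """Write a panel to TSV/CSV at full double precision (round-trips)."""
    path = Path(path)
    sep = _delimiter(path, fmt)
    with open(path, "w") as fh:
        if panel.sampling_interval_s is not None:
            fh.write(f"# {_INTERVAL_KEY}={panel.sampling_interval_s!r}\n")
        fh.write(sep.join(panel.channel_labels) + "\n")
        for row in panel.values:
            fh.write(sep.join(f"{v:.17g}" for v in row) + "\n")


def write_summary(summary, path) -> None:
    """Write a sweep summary as TSV (6 significant digits, fixed columns).

    Accepts a SweepSummary, RoiSweepSummary, FilteringComparison or a bare
    DataFrame.
    """
    frame = summary.to_frame() if hasattr(summary, "to_frame") else pd.DataFrame(summary)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, frame.columns)) + "\n")
        for _, row in frame.iterrows():
            cells = []
            for v in row:
                if isinstance(v, (int, np.integer)):
                    cells.append(str(int(v)))
                elif isinstance(v, (float, np.floating)):
                    cells.append("nan" if np.isnan(v) else f"{v:.6g}")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_summary(path) -> pd.DataFrame:
    """Read back a summary TSV written by :func:`write_summary`."""
    return pd.read_csv(path, sep="\t")


def write_manifest(path, config: dict) -> None:
    """JSON manifest of a run: full configuration plus library versions."""
    import pathgc

    manifest = {
        "config": config,
        "versions": {
            "pathgc": pathgc.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
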