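"""Delimited-text I/O for ROI time series and analysis results.

Input matrices are plain CSV/TSV, either ROI-per-row (first column = ROI
label) or ROI-per-column (header = ROI labels) — the orientation flag in
the analysis config selects which.  Results are written as long-format
CSV (one row per directed pair per window) and square labeled matrices;
floats round-trip losslessly through the readers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .sliding import RoiTimeSeriesSet

__all__ = [
    "read_roi_timeseries",
    "write_roi_timeseries",
    "write_long_format",
    "read_long_format",
    "write_matrix",
    "read_matrix",
]

# The shortest decimal string that round-trips each float64 exactly, so
# written values survive read-back bit-for-bit.
def _LOSSLESS(v):
    return repr(float(v))

LONG_COLUMNS = [
    "scan_id", "sender", "receiver", "window_index", "window_start_s",
    "capacity", "pcorr", "swc", "duration_trs", "capacity_units",
]


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


def read_roi_timeseries(
    path,
    tr_seconds: float,
    orientation: str = "roi_rows",
    scan_id: str | None = None,
    delimiter: str | None = None,
) -> RoiTimeSeriesSet:
    """Read a delimited ROI x time (or time x ROI) matrix with labels."""
    path = Path(path)
    sep = _sep_for(path, delimiter)
    if orientation == "roi_rows":
        df = pd.read_csv(path, sep=sep, index_col=0, header=None,
                         float_precision="round_trip")
        values = df.to_numpy(float)
        labels = [str(x) for x in df.index]
    elif orientation == "roi_cols":
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        values = df.to_numpy(float).T
        labels = [str(c) for c in df.columns]
    else:
        raise ValueError("orientation must be 'roi_rows' or 'roi_cols'")
    return RoiTimeSeriesSet(
        values=values,
        roi_labels=labels,
        tr_seconds=tr_seconds,
        scan_id=scan_id or path.stem,
    )


def write_roi_timeseries(ts: RoiTimeSeriesSet, path, orientation: str = "roi_rows",
                         delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _sep_for(path, delimiter)
    if orientation == "roi_rows":
        pd.DataFrame(ts.values, index=ts.roi_labels).to_csv(
            path, sep=sep, header=False, float_format=_LOSSLESS
        )
    elif orientation == "roi_cols":
        pd.DataFrame(ts.values.T, columns=ts.roi_labels).to_csv(
            path, sep=sep, index=False, float_format=_LOSSLESS
        )
    else:
        raise ValueError("orientation must be 'roi_rows' or 'roi_cols'")


def write_long_format(frame: pd.DataFrame, path) -> None:
    """Write a long-format result table (lossless float representation)."""
    frame.to_csv(path, index=False, float_format=_LOSSLESS)


def read_long_format(path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LONG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"long-format file {path} lacks columns {missing}")
    return frame


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a square ROI-labeled matrix as CSV."""
    matrix.to_csv(path, float_format=_LOSSLESS)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, float_precision="round_trip")
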