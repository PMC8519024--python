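"""Delimited-text readers and writers for design matrices and responses."""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_matrix", "write_matrix", "read_survival"]


def _detect_sep(path: Path) -> str:
    first = path.open().readline()
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_matrix(path, sep: str | None = None):
    """Read a delimited numeric matrix (rows = samples, cols = predictors).

    Comma/tab dialect is auto-detected unless ``sep`` is given; an
    optional header row and an optional leading row-name column are
    recognized when their cells are non-numeric.

    Returns
    -------
    (values, columns, index) : ndarray, list[str] | None, list[str] | None
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = _detect_sep(path)
    first = path.open().readline().rstrip("\n").split(sep)
    header = 0 if any(not _is_number(t) for t in first if t != "") else None
    df = pd.read_csv(path, sep=sep, header=header, float_precision="round_trip")
    index = None
    first_col = df.iloc[:, 0]
    if first_col.dtype == object and not first_col.map(
        lambda v: _is_number(str(v))
    ).all():
        index = first_col.astype(str).tolist()
        df = df.iloc[:, 1:]
    columns = [str(c) for c in df.columns] if header is not None else None
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        # locate the offending cell for a useful message
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df[col]):
                if not _is_number(str(v)):
                    raise ValueError(
                        f"non-numeric cell at row {i + 1}, column {col!r} in {path}"
                    ) from exc
        raise
    if df.isna().any().any():
        bad = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"ragged or missing cell at row {bad[0] + 1}, column {bad[1] + 1} in {path}"
        )
    return values, columns, index


def write_matrix(path, values, columns=None, sep: str = ",") -> None:
    """Write a matrix as delimited text at full float precision."""
    df = pd.DataFrame(np.asarray(values, dtype=float), columns=columns)
    df.to_csv(path, sep=sep, index=False, header=columns is not None,
              float_format="%.17g")


def read_survival(path, sep: str | None = None):
    """Read a two-column (time, status) survival file into SurvivalData."""
    from .cox import SurvivalData

    values, columns, _ = read_matrix(path, sep=sep)
    if values.shape[1] < 2:
        raise ValueError("survival file needs columns: time, status")
    if columns and "time" in [c.lower() for c in columns]:
        cols = [c.lower() for c in columns]
        t = values[:, cols.index("time")]
        d = values[:, cols.index("status")]
    else:
        t, d = values[:, 0], values[:, 1]
    return SurvivalData(t, d)
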