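"""Reading and writing count tables, metadata and result tables (TSV/CSV)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_count_table", "read_metadata", "write_table"]


def _sep(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_count_table(path, orientation: str = "samples_rows") -> pd.DataFrame:
    """Read a count table and return it with samples in rows.

    ``orientation`` is ``"samples_rows"`` or ``"features_rows"`` (the latter
    is transposed on read).  Cells must be numeric, finite and nonnegative;
    duplicate sample or feature identifiers are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if orientation == "features_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cells in the count table: {exc}")
    bad = ~np.isfinite(values) | (values < 0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{path}: invalid count at sample {df.index[i]!r}, "
            f"feature {df.columns[j]!r} (negative, NaN or infinite)"
        )
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample identifiers")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate feature identifiers")
    return df.astype(float)


def read_metadata(path, sample_col: str | None = None) -> pd.DataFrame:
    """Read sample metadata; the sample-ID column becomes the index."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    if sample_col is None:
        sample_col = df.columns[0]
    if sample_col not in df.columns:
        raise KeyError(f"{path}: no sample-ID column {sample_col!r}")
    df = df.set_index(sample_col)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample identifiers")
    return df


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep(path), index_label=index_label)
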