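"""Minimal BED (0-based half-open) reading/writing on pandas.

All interval tracks inside the package are DataFrames with columns
``chrom, start, end[, name]`` in BED coordinates; conversion to the
1-based inclusive coordinates used by TSV outputs happens here and
nowhere else.
"""

from __future__ import annotations

import pandas as pd

_COLS = ["chrom", "start", "end", "name"]


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=_COLS, usecols=range(4), dtype={0: str, 3: str},
    )
    if df["name"].isna().all():
        df = df.drop(columns=["name"])
    df["start"] = df["start"].astype("int64")
    df["end"] = df["end"].astype("int64")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in _COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def bed_to_inclusive(df: pd.DataFrame) -> pd.DataFrame:
    """BED half-open -> 1-based inclusive (start+1, end)."""
    out = df.copy()
    out["start"] = out["start"] + 1
    return out


def inclusive_to_bed(df: pd.DataFrame) -> pd.DataFrame:
    """1-based inclusive -> BED half-open (start-1, end)."""
    out = df.copy()
    out["start"] = out["start"] - 1
    return out
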