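"""CSV readers/writers for the pipeline's tabular interchange formats.

Documented headers:

* events CSV   — participant_id, session, block, t_s, key
* metadata CSV — participant_id, age_group, break_duration, break_type,
                 sdsc, psqi, source (+ optional corrupted,
                 insufficient_performance flags)
* metrics CSV  — participant_id, session, block, n_keypresses, n_chunks,
                 speed_s_per_key, accuracy_err, gpi, flagged (+ z_gpi after
                 normalization)

Malformed files raise ValueError naming the file, the offending column and,
where determinable, the 1-based data row numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

EVENTS_COLUMNS = ["participant_id", "session", "block", "t_s", "key"]
METADATA_COLUMNS = [
    "participant_id",
    "age_group",
    "break_duration",
    "break_type",
    "sdsc",
    "psqi",
    "source",
]


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def _bad_rows(mask: pd.Series) -> list[int]:
    # +2: 1-based with a header line
    return (np.flatnonzero(mask.to_numpy()) + 2).tolist()[:10]


def read_events_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, EVENTS_COLUMNS, path)
    df["block"] = pd.to_numeric(df["block"], errors="coerce")
    df["t_s"] = pd.to_numeric(df["t_s"], errors="coerce")
    df["key"] = pd.to_numeric(df["key"], errors="coerce")
    for col in ("block", "t_s", "key"):
        bad = df[col].isna()
        if bad.any():
            raise ValueError(
                f"{path}: non-numeric values in column {col!r} at rows {_bad_rows(bad)}"
            )
    bad = ~df["key"].isin([1, 2, 3, 4])
    if bad.any():
        raise ValueError(
            f"{path}: key codes outside 1-4 at rows {_bad_rows(bad)}"
        )
    df["key"] = df["key"].astype(np.int64)
    df["block"] = df["block"].astype(np.int64)
    return df[EVENTS_COLUMNS + [c for c in df.columns if c not in EVENTS_COLUMNS]]


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, METADATA_COLUMNS[:4], path)
    for col in ("sdsc", "psqi"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "source" not in df.columns:
        df["source"] = "new"
    dup = df["participant_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate participant_id at rows {_bad_rows(dup)}"
        )
    return df


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(
        df, ["participant_id", "session", "block", "gpi"], path
    )
    if "flagged" not in df.columns:
        df["flagged"] = False
    return df


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
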