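"""Participant exclusion rules, within-participant Z-normalization of the GPI,
and construction of the long-format design tables for the online (blocks 1-12)
and offline (S1 vs S2 session) analyses.

Exclusion screens: corrupted recordings; insufficient motor performance
(configurable minimum median keypress count, no default threshold); poor sleep
quality — SDSC total > 67 for children, PSQI total > 7 for adults (strict
inequalities). Archival participants carry no questionnaire and bypass the
sleep screens; a missing sleep score retains the participant with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

PARTICIPANT_COLUMNS = [
    "participant_id",
    "age_group",
    "break_duration",
    "break_type",
    "sdsc",
    "psqi",
    "source",
]


@dataclass(frozen=True)
class ExclusionThresholds:
    """Screening thresholds; a participant is excluded on a *strictly greater*
    sleep score and a *strictly smaller* median keypress count."""

    sdsc_max: int = 67
    psqi_max: int = 7
    min_keypresses: int | None = None


def apply_exclusions(
    participants: pd.DataFrame,
    metrics: pd.DataFrame | None = None,
    thresholds: ExclusionThresholds = ExclusionThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split participants into (retained, excluded-with-reasons).

    Optional boolean columns ``corrupted`` and ``insufficient_performance`` on
    ``participants`` mark upstream failures; when ``metrics`` and a
    ``min_keypresses`` threshold are given, insufficient performance is also
    derived from the median per-block keypress count, and blocks flagged by
    the scorer (zero keypresses) exclude their participant.
    """
    missing = set(PARTICIPANT_COLUMNS[:4]) - set(participants.columns)
    if missing:
        raise ValueError(f"participants table missing column(s): {sorted(missing)}")
    df = participants.copy()
    for col in ("sdsc", "psqi"):
        if col not in df.columns:
            df[col] = np.nan
    if "source" not in df.columns:
        df["source"] = "new"

    reasons = pd.Series("", index=df.index, dtype=object)

    def mark(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    if "corrupted" in df.columns:
        mark(df["corrupted"].fillna(False).astype(bool), "corrupted file")

    insufficient = (
        df["insufficient_performance"].fillna(False).astype(bool)
        if "insufficient_performance" in df.columns
        else pd.Series(False, index=df.index)
    )
    if metrics is not None:
        flagged_pids = set(metrics.loc[metrics["flagged"], "participant_id"])
        insufficient |= df["participant_id"].isin(flagged_pids)
        if thresholds.min_keypresses is not None:
            med = metrics.groupby("participant_id")["n_keypresses"].median()
            low = set(med.index[med < thresholds.min_keypresses])
            insufficient |= df["participant_id"].isin(low)
    mark(insufficient, "insufficient motor performance")

    archival = df["source"].eq("archival")
    sdsc = pd.to_numeric(df["sdsc"], errors="coerce")
    psqi = pd.to_numeric(df["psqi"], errors="coerce")
    child = df["age_group"].eq("child")
    adult = ~child
    mark(child & ~archival & (sdsc > thresholds.sdsc_max), "poor sleep quality (SDSC)")
    mark(adult & ~archival & (psqi > thresholds.psqi_max), "poor sleep quality (PSQI)")

    missing_sleep = (
        ~archival
        & (reasons == "")
        & ((child & sdsc.isna()) | (adult & psqi.isna()))
    )
    if missing_sleep.any():
        ids = df.loc[missing_sleep, "participant_id"].tolist()
        warnings.warn(
            f"missing sleep score for retained participant(s): {ids}",
            stacklevel=2,
        )

    excluded = df[reasons != ""].copy()
    excluded["reason"] = reasons[reasons != ""]
    retained = df[reasons == ""].copy()
    retained["included"] = True
    return retained.reset_index(drop=True), excluded.reset_index(drop=True)


def zscore_gpi(
    metrics: pd.DataFrame, *, n_blocks: int = 14
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score the GPI within each participant across all ``n_blocks`` blocks.

    z = (gpi - mean over the 14 blocks) / SD over the 14 blocks (sample SD,
    n-1 denominator), so each retained participant's z-scores have mean 0 and
    SD 1 exactly. Participants with missing blocks or zero SD are flagged
    (z set to NaN), never silently dropped.

    Returns (metrics with added ``z_gpi`` column, flags table).
    """
    df = metrics.copy()
    df["z_gpi"] = np.nan
    flag_rows = []
    for pid, grp in df.groupby("participant_id", sort=False):
        if len(grp) != n_blocks:
            flag_rows.append((pid, f"expected {n_blocks} blocks, found {len(grp)}"))
            continue
        g = grp["gpi"].to_numpy(dtype=float)
        sd = g.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            flag_rows.append((pid, "zero or undefined GPI variance"))
            continue
        df.loc[grp.index, "z_gpi"] = (g - g.mean()) / sd
    flags = pd.DataFrame(flag_rows, columns=["participant_id", "flag"])
    return df, flags


def _merge_meta(zmetrics: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    meta = participants[
        ["participant_id", "age_group", "break_duration", "break_type"]
    ]
    merged = zmetrics.merge(meta, on="participant_id", how="inner")
    return merged


def build_online_table(
    zmetrics: pd.DataFrame,
    participants: pd.DataFrame,
    *,
    n_s1_blocks: int = 12,
    on_incomplete: str = "raise",
) -> pd.DataFrame:
    """Long table (one row per participant x S1 block) for the online-learning
    ANOVA. Restricted to retained participants present in ``participants``.
    Participants with missing S1 blocks raise (default) or are dropped with a
    warning (``on_incomplete='drop'``)."""
    merged = _merge_meta(zmetrics, participants)
    online = merged[merged["session"].eq("S1") & (merged["block"] <= n_s1_blocks)]
    counts = online.groupby("participant_id")["block"].count()
    bad = counts[counts != n_s1_blocks]
    if len(bad):
        if on_incomplete == "drop":
            warnings.warn(f"dropping participants missing S1 blocks: "
                          f"{bad.index.tolist()}", stacklevel=2)
            online = online[~online["participant_id"].isin(bad.index)]
        else:
            raise ValueError(f"participants missing S1 blocks: {bad.index.tolist()}")
    cols = [
        "participant_id",
        "age_group",
        "break_duration",
        "break_type",
        "block",
        "z_gpi",
    ]
    return online[cols].sort_values(["participant_id", "block"]).reset_index(drop=True)


def build_offline_table(
    zmetrics: pd.DataFrame,
    participants: pd.DataFrame,
    *,
    n_s1_blocks: int = 12,
    n_s2_blocks: int = 2,
    on_incomplete: str = "raise",
) -> pd.DataFrame:
    """Two rows per participant: S1 = mean z-GPI of the last two learning
    blocks, S2 = mean z-GPI of the two test blocks. Participants missing any
    of those blocks raise (default) or are dropped with a warning
    (``on_incomplete='drop'``)."""
    merged = _merge_meta(zmetrics, participants)
    s1_blocks = [n_s1_blocks - 1, n_s1_blocks]
    s2_blocks = list(range(n_s1_blocks + 1, n_s1_blocks + n_s2_blocks + 1))
    wanted = merged[merged["block"].isin(s1_blocks + s2_blocks)]
    rows = []
    for pid, grp in wanted.groupby("participant_id", sort=True):
        have = set(grp["block"])
        need = set(s1_blocks + s2_blocks)
        if have != need:
            if on_incomplete == "drop":
                warnings.warn(
                    f"dropping participant {pid!r}: missing block(s) "
                    f"{sorted(need - have)}", stacklevel=2)
                continue
            raise ValueError(
                f"participant {pid!r} missing block(s) {sorted(need - have)}"
            )
        meta = grp.iloc[0]
        s1 = grp.loc[grp["block"].isin(s1_blocks), "z_gpi"].mean()
        s2 = grp.loc[grp["block"].isin(s2_blocks), "z_gpi"].mean()
        for session, val in (("S1", s1), ("S2", s2)):
            rows.append(
                (
                    pid,
                    meta["age_group"],
                    meta["break_duration"],
                    meta["break_type"],
                    session,
                    val,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "age_group",
            "break_duration",
            "break_type",
            "session",
            "z_gpi",
        ],
    )
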