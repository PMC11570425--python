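"""Synthetic enrollment fixture encoding the reference recruitment and
exclusion scenario used by the validation suite.

The table is generated programmatically (no real participant data): 64
children enrolled of whom 3 have corrupted files, 2 show insufficient motor
performance, 1 exceeds the SDSC sleep screen (score 68) and 1 retained child
has a missing SDSC score; 30 newly recruited adults of whom 2 exceed the PSQI
screen (score 8); and 30 archival adults from an earlier active-break study
who carry no questionnaire. Applying the default screens retains
58 children + 28 new adults + 30 archival adults = 116 participants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import PARTICIPANT_COLUMNS


def make_enrollment_table(seed: int = 0) -> pd.DataFrame:
    """Build the synthetic enrollment metadata table (one row per enrollee).

    Extra boolean columns ``corrupted`` and ``insufficient_performance`` mark
    the upstream failures; sleep scores are drawn in their plausible ranges.
    """
    rng = np.random.default_rng(seed)
    rows = []

    child_cells = [
        ("30min", "active"),
        ("30min", "passive"),
        ("4h", "active"),
        ("4h", "passive"),
    ]
    for i in range(64):
        dur, btype = child_cells[i % 4]
        sdsc: float | None = float(int(np.clip(round(rng.normal(36.6, 6.0)), 26, 57)))
        rows.append(
            {
                "participant_id": f"child-{i + 1:02d}",
                "age_group": "child",
                "break_duration": dur,
                "break_type": btype,
                "sdsc": sdsc,
                "psqi": None,
                "source": "new",
                "corrupted": False,
                "insufficient_performance": False,
            }
        )
    for i in (4, 21, 40):  # corrupted recordings
        rows[i]["corrupted"] = True
    for i in (10, 33):  # insufficient motor performance
        rows[i]["insufficient_performance"] = True
    rows[50]["sdsc"] = 68.0  # above the SDSC > 67 screen
    rows[7]["sdsc"] = None  # missing questionnaire, retained with a warning

    adult_cells = [("30min", "passive"), ("4h", "passive")]
    for i in range(30):
        dur, btype = adult_cells[i % 2]
        rows.append(
            {
                "participant_id": f"adult-{i + 1:02d}",
                "age_group": "adult",
                "break_duration": dur,
                "break_type": btype,
                "sdsc": None,
                "psqi": float(int(np.clip(round(rng.normal(4.9, 1.9)), 2, 7))),
                "source": "new",
                "corrupted": False,
                "insufficient_performance": False,
            }
        )
    rows[64 + 3]["psqi"] = 8.0  # above the PSQI > 7 screen
    rows[64 + 18]["psqi"] = 8.0

    archival_cells = [("30min", "active"), ("4h", "active")]
    for i in range(30):
        dur, btype = archival_cells[i % 2]
        rows.append(
            {
                "participant_id": f"arch-{i + 1:02d}",
                "age_group": "adult",
                "break_duration": dur,
                "break_type": btype,
                "sdsc": None,
                "psqi": None,
                "source": "archival",
                "corrupted": False,
                "insufficient_performance": False,
            }
        )

    df = pd.DataFrame(rows)
    return df[PARTICIPANT_COLUMNS + ["corrupted", "insufficient_performance"]]
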