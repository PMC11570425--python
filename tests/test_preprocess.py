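"""Exclusion screens, within-participant z-scoring, design-table building."""

import numpy as np
import pandas as pd
import pytest

from fingertap import (
    apply_exclusions,
    build_offline_table,
    build_online_table,
    make_enrollment_table,
    zscore_gpi,
)
from fingertap.preprocess import ExclusionThresholds


def _participants(**cols):
    base = {
        "participant_id": ["p1"],
        "age_group": ["child"],
        "break_duration": ["30min"],
        "break_type": ["active"],
        "sdsc": [40.0],
        "psqi": [None],
        "source": ["new"],
    }
    base.update(cols)
    n = max(len(v) for v in base.values())
    base = {k: (v * n if len(v) == 1 else v) for k, v in base.items()}
    base["participant_id"] = [f"p{i}" for i in range(n)]
    return pd.DataFrame(base)


class TestExclusions:
    def test_enrollment_fixture_counts(self):
        enrol = make_enrollment_table()
        with pytest.warns(UserWarning):  # one retained child has no SDSC score
            retained, excluded = apply_exclusions(enrol)
        counts = retained.groupby(["age_group", "source"])["participant_id"].count()
        assert counts[("child", "new")] == 58
        assert counts[("adult", "new")] == 28
        assert counts[("adult", "archival")] == 30
        assert len(retained) == 116
        reasons = excluded["reason"].value_counts()
        assert reasons["corrupted file"] == 3
        assert reasons["insufficient motor performance"] == 2
        assert reasons["poor sleep quality (SDSC)"] == 1
        assert reasons["poor sleep quality (PSQI)"] == 2

    def test_sleep_thresholds_are_strict(self):
        df = _participants(sdsc=[67.0, 68.0])
        retained, excluded = apply_exclusions(df)
        assert retained["sdsc"].tolist() == [67.0]
        assert excluded["reason"].tolist() == ["poor sleep quality (SDSC)"]
        df = _participants(age_group=["adult"], sdsc=[None], psqi=[7.0, 8.0])
        retained, excluded = apply_exclusions(df)
        assert retained["psqi"].tolist() == [7.0]

    def test_missing_sleep_score_warns_but_retains(self):
        df = _participants(sdsc=[None])
        with pytest.warns(UserWarning, match="missing sleep score"):
            retained, excluded = apply_exclusions(df)
        assert len(retained) == 1 and excluded.empty

    def test_archival_bypasses_sleep_screen(self):
        df = _participants(age_group=["adult"], psqi=[99.0], source=["archival"])
        retained, excluded = apply_exclusions(df)
        assert len(retained) == 1 and excluded.empty

    def test_metrics_based_performance_screen(self):
        df = _participants(sdsc=[40.0, 40.0])
        metrics = pd.DataFrame(
            {
                "participant_id": ["p0"] * 2 + ["p1"] * 2,
                "session": ["S1"] * 4,
                "block": [1, 2] * 2,
                "n_keypresses": [50, 60, 5, 4],
                "flagged": [False] * 4,
            }
        )
        retained, excluded = apply_exclusions(
            df, metrics, ExclusionThresholds(min_keypresses=20)
        )
        assert retained["participant_id"].tolist() == ["p0"]
        assert excluded["reason"].tolist() == ["insufficient motor performance"]

    def test_flagged_block_excludes_participant(self):
        df = _participants(sdsc=[40.0, 40.0])
        metrics = pd.DataFrame(
            {
                "participant_id": ["p0", "p1"],
                "session": ["S1"] * 2,
                "block": [1, 1],
                "n_keypresses": [50, 0],
                "flagged": [False, True],
            }
        )
        retained, _ = apply_exclusions(df, metrics)
        assert retained["participant_id"].tolist() == ["p0"]


def _metrics_one(pid="p1", gpis=None):
    gpis = gpis if gpis is not None else np.linspace(0.1, 0.6, 14)
    return pd.DataFrame(
        {
            "participant_id": [pid] * 14,
            "session": ["S1"] * 12 + ["S2"] * 2,
            "block": range(1, 15),
            "gpi": gpis,
            "flagged": False,
        }
    )


class TestZScore:
    def test_mean_zero_sd_one(self, demo_zmetrics):
        g = demo_zmetrics.groupby("participant_id")["z_gpi"]
        assert np.all(np.abs(g.mean()) < 1e-10)
        assert np.allclose(g.std(ddof=1), 1.0, atol=1e-10)

    def test_affine_invariance(self):
        m = _metrics_one()
        z1, _ = zscore_gpi(m)
        m2 = m.assign(gpi=3.7 * m["gpi"] + 1.2)
        z2, _ = zscore_gpi(m2)
        assert np.allclose(z1["z_gpi"], z2["z_gpi"], atol=1e-12)

    def test_idempotence(self):
        m = _metrics_one()
        z1, _ = zscore_gpi(m)
        z2, _ = zscore_gpi(z1.assign(gpi=z1["z_gpi"]))
        assert np.allclose(z1["z_gpi"], z2["z_gpi"], atol=1e-12)

    def test_zero_variance_flagged(self):
        m = _metrics_one(gpis=np.full(14, 0.5))
        z, flags = zscore_gpi(m)
        assert flags["flag"].str.contains("variance").all()
        assert z["z_gpi"].isna().all()

    def test_wrong_block_count_flagged(self):
        m = _metrics_one().iloc[:10]
        z, flags = zscore_gpi(m)
        assert len(flags) == 1
        assert "10" in flags.loc[0, "flag"]


class TestDesignTables:
    def test_shapes(self, demo_bundle, demo_tables):
        online, offline = demo_tables
        n = len(demo_bundle.participants)
        assert len(online) == 12 * n
        assert len(offline) == 2 * n
        assert set(offline["session"]) == {"S1", "S2"}

    def test_offline_values_are_block_means(self, demo_zmetrics, demo_bundle,
                                            demo_tables):
        _, offline = demo_tables
        pid = offline["participant_id"].iloc[0]
        sub = demo_zmetrics[demo_zmetrics["participant_id"] == pid]
        s1 = sub.loc[sub["block"].isin([11, 12]), "z_gpi"].mean()
        s2 = sub.loc[sub["block"].isin([13, 14]), "z_gpi"].mean()
        got = offline[offline["participant_id"] == pid].set_index("session")["z_gpi"]
        assert got["S1"] == pytest.approx(s1)
        assert got["S2"] == pytest.approx(s2)

    def test_missing_block_raises_or_drops(self, demo_zmetrics, demo_bundle):
        broken = demo_zmetrics[
            ~(
                demo_zmetrics["participant_id"].eq(
                    demo_zmetrics["participant_id"].iloc[0]
                )
                & demo_zmetrics["block"].eq(13)
            )
        ]
        with pytest.raises(ValueError, match="missing block"):
            build_offline_table(broken, demo_bundle.participants)
        with pytest.warns(UserWarning, match="dropping participant"):
            off = build_offline_table(
                broken, demo_bundle.participants, on_incomplete="drop"
            )
        assert len(off) == 2 * (len(demo_bundle.participants) - 1)

    def test_online_restricted_to_retained(self, demo_zmetrics, demo_bundle):
        keep = demo_bundle.participants.iloc[:10]
        online = build_online_table(demo_zmetrics, keep)
        assert set(online["participant_id"]) == set(keep["participant_id"])
        assert len(online) == 120

    def test_empty_input(self, demo_bundle):
        empty = pd.DataFrame(
            columns=["participant_id", "session", "block", "gpi", "z_gpi"]
        )
        out = build_online_table(empty, demo_bundle.participants)
        assert out.empty
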