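"""Mixed ANOVA: df arithmetic, reference agreement, sphericity, post hocs,
inclusion Bayes factors."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from statsmodels.stats.anova import AnovaRM

from fingertap import (
    AnovaSpec,
    fit_mixed_anova,
    gg_epsilon,
    inclusion_bf,
    inclusion_bfs,
    mauchly_test,
    posthoc_contrasts,
)
from fingertap.contrasts import cohen_d_paired

from conftest import make_offline_like


def random_mixed_design(rng, n_groups, n_within, n_per_group, effect=0.4):
    rows = []
    for g in range(n_groups):
        for i in range(n_per_group):
            sid = f"g{g}s{i}"
            base = rng.normal()
            for w in range(n_within):
                y = base + effect * w + 0.2 * g + rng.normal()
                rows.append((sid, f"g{g}", f"w{w}", y))
    return pd.DataFrame(rows, columns=["subj", "grp", "time", "y"])


class TestMixedAnova:
    def test_df_arithmetic(self):
        rng = np.random.default_rng(0)
        # w within levels, N subjects, c cells -> df = (w-1, (w-1)(N-c))
        df = random_mixed_design(rng, n_groups=2, n_within=4, n_per_group=6)
        res = fit_mixed_anova(
            df, AnovaSpec(dv="y", within="time", subject="subj", between=["grp"])
        )
        e = res.get("time")
        assert (e.df_num, e.df_den) == (3, 3 * (12 - 2))
        assert res.get("grp").df_den == 12 - 2

    @pytest.mark.parametrize("seed", range(5))
    def test_agreement_with_pingouin(self, seed):
        rng = np.random.default_rng(seed)
        n_groups = int(rng.integers(2, 4))
        n_within = int(rng.integers(2, 6))
        n_per = int(rng.integers(4, 9))
        df = random_mixed_design(rng, n_groups, n_within, n_per)
        ours = fit_mixed_anova(
            df, AnovaSpec(dv="y", within="time", subject="subj", between=["grp"])
        )
        ref = pg.mixed_anova(
            data=df, dv="y", within="time", subject="subj", between="grp"
        ).set_index("Source")
        assert ours.get("grp").F == pytest.approx(ref.loc["grp", "F"], abs=1e-6)
        assert ours.get("time").F == pytest.approx(ref.loc["time", "F"], abs=1e-6)
        assert ours.get("time:grp").F == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-6
        )

    def test_agreement_with_anova_rm_pure_within(self):
        rng = np.random.default_rng(3)
        df = random_mixed_design(rng, 1, 5, 12)
        ours = fit_mixed_anova(df, AnovaSpec(dv="y", within="time", subject="subj"))
        ref = AnovaRM(df, "y", "subj", within=["time"]).fit().anova_table
        assert ours.get("time").F == pytest.approx(
            float(ref.loc["time", "F Value"]), abs=1e-8
        )

    def test_two_level_within_equals_squared_t(self, demo_tables):
        _, offline = demo_tables
        spec = AnovaSpec(between=["age_group", "break_duration", "break_type"])
        res = fit_mixed_anova(offline, spec)
        wide = offline.pivot_table(
            index=["participant_id", "age_group", "break_duration", "break_type"],
            columns="session",
            values="z_gpi",
        ).reset_index()
        d = (wide["S2"] - wide["S1"]).to_numpy()
        X = np.column_stack(
            [
                np.ones(len(d)),
                np.where(wide.age_group == "adult", 1, -1),
                np.where(wide.break_duration == "30min", 1, -1),
                np.where(wide.break_type == "active", 1, -1),
            ]
        )
        X = np.column_stack(
            [X, X[:, 1] * X[:, 2], X[:, 1] * X[:, 3], X[:, 2] * X[:, 3],
             X[:, 1] * X[:, 2] * X[:, 3]]
        )
        beta, *_ = np.linalg.lstsq(X, d, rcond=None)
        r = d - X @ beta
        s2 = (r @ r) / (len(d) - X.shape[1])
        t = beta[0] / np.sqrt(s2 * np.linalg.inv(X.T @ X)[0, 0])
        assert res.get("session").F == pytest.approx(t**2, abs=1e-8)

    def test_group_relabel_symmetry(self):
        rng = np.random.default_rng(4)
        df = random_mixed_design(rng, 2, 2, 8, effect=0.0)
        res1 = fit_mixed_anova(
            df, AnovaSpec(dv="y", within="time", subject="subj", between=["grp"])
        )
        swapped = df.assign(grp=df["grp"].map({"g0": "g1", "g1": "g0"}))
        res2 = fit_mixed_anova(
            swapped, AnovaSpec(dv="y", within="time", subject="subj", between=["grp"])
        )
        for e1, e2 in zip(res1.effects, res2.effects):
            assert e1.F == pytest.approx(e2.F, abs=1e-10)

    def test_partial_eta_identity(self, demo_tables):
        online, offline = demo_tables
        spec = AnovaSpec(
            within="block", between=["age_group", "break_duration", "break_type"]
        )
        for e in fit_mixed_anova(online, spec):
            expected = e.df_num * e.F / (e.df_num * e.F + e.df_den)
            assert e.partial_eta_sq == pytest.approx(expected, abs=1e-9)

    def test_empty_cell_error_names_cell(self):
        rng = np.random.default_rng(5)
        df = random_mixed_design(rng, 2, 2, 6)
        # grp2 observed in both levels overall, but never as (g1, y)
        df["grp2"] = "x"
        df.loc[df["subj"].isin(["g0s0", "g0s1", "g0s2"]), "grp2"] = "y"
        with pytest.raises(ValueError, match="empty between cell: g1|y"):
            fit_mixed_anova(
                df,
                AnovaSpec(dv="y", within="time", subject="subj",
                          between=["grp", "grp2"]),
            )

    def test_incomplete_within_design_rejected(self):
        rng = np.random.default_rng(6)
        df = random_mixed_design(rng, 2, 3, 5)
        df = df.drop(df.index[0])
        with pytest.raises(ValueError, match="incomplete"):
            fit_mixed_anova(
                df, AnovaSpec(dv="y", within="time", subject="subj", between=["grp"])
            )


class TestSphericity:
    def test_two_level_epsilon_is_one(self, demo_tables):
        _, offline = demo_tables
        res = fit_mixed_anova(
            offline,
            AnovaSpec(between=["age_group", "break_duration", "break_type"]),
        )
        assert res.get("session").gg_epsilon == 1.0

    def test_epsilon_bounds_and_limits(self):
        w = 12
        # spherical covariance -> epsilon exactly 1
        assert gg_epsilon(np.eye(w)) == pytest.approx(1.0)
        # rank-one (maximally non-spherical) -> lower bound 1/(w-1)
        c = np.arange(1.0, w + 1.0)
        S = np.outer(c, c)
        assert gg_epsilon(S) == pytest.approx(1.0 / (w - 1))

    def test_epsilon_near_one_for_compound_symmetry(self):
        # compound symmetry satisfies sphericity; estimate -> 1 as n grows
        rng = np.random.default_rng(7)
        n, w = 400, 6
        Y = rng.normal(size=(n, 1)) + rng.normal(size=(n, w))
        S = np.cov(Y, rowvar=False)
        assert gg_epsilon(S) > 0.95

    def test_mauchly_detects_violation(self):
        rng = np.random.default_rng(8)
        n, w = 60, 4
        spherical = rng.normal(size=(n, w))
        W, chi2, df, p = mauchly_test(np.cov(spherical, rowvar=False), n - 1)
        assert p > 0.01
        shaped = spherical * np.array([0.2, 1.0, 2.0, 4.0])
        W2, _, _, p2 = mauchly_test(np.cov(shaped, rowvar=False), n - 1)
        assert p2 < 1e-4 and W2 < W

    def test_gg_correction_applied_when_violated(self, demo_tables):
        online, _ = demo_tables
        spec = AnovaSpec(
            within="block", between=["age_group", "break_duration", "break_type"]
        )
        res = fit_mixed_anova(online, spec)
        block = res.get("block")
        if res.mauchly_p < 0.05:
            assert block.gg_applied
            assert block.p_gg >= block.p_uncorrected * 0  # defined
            assert 1.0 / 11 <= block.gg_epsilon <= 1.0


class TestPosthocs:
    def test_single_comparison_unadjusted(self):
        rng = np.random.default_rng(9)
        tbl = make_offline_like(rng, {("a",): 10}, lambda c: 0.5,
                                between_names=["f1"])
        res = posthoc_contrasts(tbl, by=[], adjustment="bonferroni")
        assert len(res) == 1
        assert res[0].p_adjusted == pytest.approx(res[0].p_uncorrected)

    def test_identical_samples_give_zero_d(self):
        a = np.arange(10.0)
        assert cohen_d_paired(a, a) == 0.0

    def test_bonferroni_caps_and_orders(self):
        rng = np.random.default_rng(10)
        tbl = make_offline_like(
            rng, {("a",): 8, ("b",): 8}, lambda c: 0.1, between_names=["f1"]
        )
        res = posthoc_contrasts(tbl, by=["f1"], adjustment="bonferroni")
        assert len(res) == 2
        for c in res:
            assert c.p_uncorrected <= c.p_adjusted <= 1.0

    def test_tukey_adjustment_monotone(self):
        rng = np.random.default_rng(11)
        tbl = make_offline_like(
            rng, {("a",): 12, ("b",): 12}, lambda c: 0.8, between_names=["f1"]
        )
        res = posthoc_contrasts(tbl, by=["f1"], adjustment="tukey")
        for c in res:
            assert c.p_adjusted >= c.p_uncorrected

    def test_unknown_adjustment_rejected(self):
        rng = np.random.default_rng(12)
        tbl = make_offline_like(rng, {("a",): 5}, lambda c: 0.0,
                                between_names=["f1"])
        with pytest.raises(ValueError, match="adjustment"):
            posthoc_contrasts(tbl, by=["f1"], adjustment="scheffe")

    def test_sign_convention_improvement_negative(self):
        # improvement at S2 => estimate (S1 - S2) and d negative
        rng = np.random.default_rng(13)
        tbl = make_offline_like(rng, {("a",): 40}, lambda c: 1.0,
                                between_names=["f1"], noise=0.3)
        c = posthoc_contrasts(tbl, by=[], adjustment="bonferroni")[0]
        assert c.level_a == "S1" and c.level_b == "S2"
        assert c.estimate < 0 and c.cohen_d < 0


class TestInclusionBF:
    def spec(self, k=2):
        return AnovaSpec(between=["f1", "f2"][:k])

    def test_strong_effect_supported(self):
        rng = np.random.default_rng(14)
        hits = 0
        for _ in range(10):
            tbl = make_offline_like(
                rng,
                {(a, b): 30 for a in "xy" for b in "pq"},
                lambda c: 1.5,
                between_names=["f1", "f2"],
                noise=1.0,
            )
            if inclusion_bf(tbl, self.spec(), "session") > 3:
                hits += 1
        assert hits >= 9

    def test_null_effect_median_below_one(self):
        rng = np.random.default_rng(15)
        bfs = []
        for _ in range(11):
            tbl = make_offline_like(
                rng,
                {(a, b): 12 for a in "xy" for b in "pq"},
                lambda c: 0.0,
                between_names=["f1", "f2"],
            )
            bfs.append(inclusion_bf(tbl, self.spec(), "session:f1"))
        assert np.median(bfs) < 1.0

    def test_interaction_pattern_detected(self):
        rng = np.random.default_rng(16)
        tbl = make_offline_like(
            rng,
            {(a, b): 25 for a in "xy" for b in "pq"},
            lambda c: 1.5 if c[0] == "x" else 0.0,
            between_names=["f1", "f2"],
            noise=0.8,
        )
        bfs = inclusion_bfs(tbl, self.spec())
        assert bfs["session:f1"] > 3
        assert bfs["session:f2"] < 3

    def test_unknown_effect_rejected(self):
        rng = np.random.default_rng(17)
        tbl = make_offline_like(rng, {("a",): 6}, lambda c: 0.0,
                                between_names=["f1"])
        with pytest.raises(ValueError, match="not in the design"):
            inclusion_bf(tbl, AnovaSpec(between=["f1"]), "session:f9")

    def test_all_effects_positive_finite_or_inf(self, demo_tables):
        _, offline = demo_tables
        spec = AnovaSpec(between=["age_group", "break_duration", "break_type"])
        bfs = inclusion_bfs(offline, spec)
        assert len(bfs) == 15
        for v in bfs.values():
            assert v > 0
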