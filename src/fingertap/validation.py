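"""Monte-Carlo validation studies of the full pipeline.

These run the actual generator -> scorer -> normalizer -> inference chain on
replicate synthetic cohorts to measure (a) type-I error calibration of the
Session effect under a null cohort and (b) recovery of the designed offline
boost pattern under the default study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anova import AnovaSpec, fit_mixed_anova
from .contrasts import posthoc_contrasts
from .preprocess import build_offline_table, zscore_gpi
from .scoring import score_cohort
from .simulate import SimulationConfig, all_cells, cell_key, simulate_cohort

OFFLINE_SPEC = AnovaSpec(
    dv="z_gpi",
    within="session",
    between=["age_group", "break_duration", "break_type"],
)


def null_config(n_per_cell: int = 4) -> SimulationConfig:
    """Default study conditions with every cell's offline boost set to zero."""
    return SimulationConfig(
        n_per_cell=n_per_cell,
        session_offset={cell_key(c): 0.0 for c in all_cells()},
    )


def _offline_table(config: SimulationConfig, seed: int):
    bundle = simulate_cohort(config, seed=seed)
    metrics = score_cohort(bundle.blocks)
    zm, flags = zscore_gpi(metrics)
    ok = zm[~zm["participant_id"].isin(flags["participant_id"])]
    return build_offline_table(ok, bundle.participants)


def session_type1_error(
    n_reps: int = 1000,
    n_per_cell: int = 4,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Fraction of null-cohort replicates in which the Session main effect of
    the offline mixed ANOVA rejects at ``alpha``."""
    cfg = null_config(n_per_cell)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) >> 1
    hits = 0
    for s in seeds:
        table = _offline_table(cfg, int(s))
        res = fit_mixed_anova(table, OFFLINE_SPEC)
        if res.get("session").p < alpha:
            hits += 1
    return hits / n_reps


@dataclass
class RecoveryResult:
    """Per-cell boost-recovery rates over replicate default-condition cohorts."""

    n_reps: int
    adult_30min_rate: float  # significant S2 improvement, adults after 30 min
    child_active_rate: float  # significant S2 improvement, children, active
    adult_4h_rate: float  # spurious improvement where delta = 0
    child_passive_rate: float
    adult_30min_mean_d: float
    child_active_mean_d: float


def boost_recovery(
    n_reps: int = 200,
    seed: int = 0,
    n_per_cell: int = 14,
    alpha: float = 0.05,
) -> RecoveryResult:
    """Replicate the exploratory per-age analyses on default-condition cohorts.

    For each replicate, adults-only Session post hocs are run by break
    duration and children-only post hocs by break type (Bonferroni within
    each family), mirroring the reported exploratory analyses. 'Improvement'
    means adjusted p < alpha with negative S1-minus-S2 Cohen's d.
    """
    cfg = SimulationConfig(n_per_cell=n_per_cell)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) >> 1
    hits = {k: 0 for k in ("a30", "cact", "a4h", "cpas")}
    ds = {"a30": [], "cact": []}
    for s in seeds:
        table = _offline_table(cfg, int(s))
        adults = table[table["age_group"].eq("adult")]
        children = table[table["age_group"].eq("child")]
        for c in posthoc_contrasts(adults, by=["break_duration"]):
            improved = c.p_adjusted < alpha and c.cohen_d < 0
            if c.label.endswith("30min"):
                hits["a30"] += improved
                ds["a30"].append(c.cohen_d)
            else:
                hits["a4h"] += improved
        for c in posthoc_contrasts(children, by=["break_type"]):
            improved = c.p_adjusted < alpha and c.cohen_d < 0
            if c.label.endswith("=active"):
                hits["cact"] += improved
                ds["cact"].append(c.cohen_d)
            else:
                hits["cpas"] += improved
    return RecoveryResult(
        n_reps=n_reps,
        adult_30min_rate=hits["a30"] / n_reps,
        child_active_rate=hits["cact"] / n_reps,
        adult_4h_rate=hits["a4h"] / n_reps,
        child_passive_rate=hits["cpas"] / n_reps,
        adult_30min_mean_d=float(np.mean(ds["a30"])),
        child_active_mean_d=float(np.mean(ds["cact"])),
    )


def reference_cohort_config() -> SimulationConfig:
    """Cohort with the reference totals: 58 children and 58 adults in
    8 cells (116 participants), the near-balanced split implied by the totals."""
    ns = {
        "child|30min|active": 15,
        "child|30min|passive": 15,
        "child|4h|active": 14,
        "child|4h|passive": 14,
        "adult|30min|active": 14,
        "adult|30min|passive": 14,
        "adult|4h|active": 15,
        "adult|4h|passive": 15,
    }
    return SimulationConfig(n_per_cell=ns)
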