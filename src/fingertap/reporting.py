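"""The protocol's four inferential analyses, bundled into one structured report.

Given the long-format design tables (z-scored GPI), this runs:

(a) online learning — RM-ANOVA across the 12 learning blocks with between
    factors Age group x Break duration x Break type;
(b) offline changes — Session (end-of-S1 vs S2) x Age group x Break duration
    x Break type;
(c) adults only — Session x Break type x Break duration;
(d) children only — Session x Break type x Break duration;

each with Greenhouse-Geisser handling, post hoc contrasts (Bonferroni by
default), paired Cohen's d and BIC-approximate inclusion Bayes factors.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd
from pydantic import BaseModel

from .anova import AnovaSpec, AnovaTable, fit_mixed_anova
from .bayes import inclusion_bfs
from .contrasts import ContrastResult, posthoc_contrasts

BETWEEN_FACTORS = ["age_group", "break_duration", "break_type"]


class EffectModel(BaseModel):
    effect: str
    df_num: float
    df_den: float
    F: float
    p_unc: float
    gg_epsilon: Optional[float] = None
    p_gg: Optional[float] = None
    gg_applied: bool = False
    partial_eta_sq: float
    bf_incl: Optional[float] = None


class ContrastModel(BaseModel):
    group: str
    level_a: str
    level_b: str
    estimate: float
    t: float
    df: float
    p_unc: float
    p_adj: float
    adjustment: str
    cohen_d: float
    n: int


class AnalysisModel(BaseModel):
    name: str
    n_subjects: int
    cell_counts: dict[str, int]
    balanced: bool
    mauchly_w: Optional[float] = None
    mauchly_p: Optional[float] = None
    gg_epsilon: Optional[float] = None
    effects: list[EffectModel]
    contrasts: list[ContrastModel]


class StudyReport(BaseModel):
    """Top-level analysis report written by the pipeline as report.json."""

    seed: Optional[int] = None
    n_participants: int
    n_blocks_scored: int
    exclusions: list[dict]
    flags: list[dict]
    analyses: list[AnalysisModel]


def _effect_models(aov: AnovaTable, bfs: dict[str, float]) -> list[EffectModel]:
    out = []
    for e in aov.effects:
        out.append(
            EffectModel(
                effect=e.effect,
                df_num=e.df_num,
                df_den=e.df_den,
                F=e.F,
                p_unc=e.p_uncorrected,
                gg_epsilon=e.gg_epsilon,
                p_gg=e.p_gg,
                gg_applied=e.gg_applied,
                partial_eta_sq=e.partial_eta_sq,
                bf_incl=bfs.get(e.effect),
            )
        )
    return out


def _contrast_models(contrasts: list[ContrastResult]) -> list[ContrastModel]:
    return [
        ContrastModel(
            group=c.label,
            level_a=c.level_a,
            level_b=c.level_b,
            estimate=c.estimate,
            t=c.t,
            df=c.df,
            p_unc=c.p_uncorrected,
            p_adj=c.p_adjusted,
            adjustment=c.adjustment,
            cohen_d=c.cohen_d,
            n=c.n,
        )
        for c in contrasts
    ]


def _analysis(
    name: str,
    table: pd.DataFrame,
    spec: AnovaSpec,
    posthoc_by: list[list[str]],
    adjustment: str,
    compute_bf: bool,
) -> AnalysisModel:
    aov = fit_mixed_anova(table, spec)
    bfs = inclusion_bfs(table, spec) if compute_bf else {}
    contrasts: list[ContrastResult] = []
    for by in posthoc_by:
        contrasts.extend(
            posthoc_contrasts(
                table,
                dv=spec.dv,
                factor=spec.within,
                subject=spec.subject,
                by=by,
                paired=True,
                adjustment=adjustment,
            )
        )
    return AnalysisModel(
        name=name,
        n_subjects=aov.n_subjects,
        cell_counts=aov.cell_counts,
        balanced=aov.balanced,
        mauchly_w=aov.mauchly_w,
        mauchly_p=aov.mauchly_p,
        gg_epsilon=aov.gg_epsilon,
        effects=_effect_models(aov, bfs),
        contrasts=_contrast_models(contrasts),
    )


def run_reported_analyses(
    offline_table: pd.DataFrame,
    online_table: pd.DataFrame,
    *,
    adjustment: str = "bonferroni",
    compute_bf: bool = True,
    sphericity: str = "when-violated",
    include_online_posthocs: bool = False,
) -> list[AnalysisModel]:
    """Run the four reported ANOVAs and their post hocs.

    Block-by-block post hocs of the online analysis (66 pairs) are off by
    default; the Session post hocs of the offline analyses are always run.
    """
    analyses = []

    online_spec = AnovaSpec(
        dv="z_gpi", within="block", between=BETWEEN_FACTORS, sphericity=sphericity
    )
    online_by: list[list[str]] = [[]] if include_online_posthocs else []
    analyses.append(
        _analysis("online_block", online_table, online_spec, online_by,
                  adjustment, compute_bf)
    )

    offline_spec = AnovaSpec(
        dv="z_gpi", within="session", between=BETWEEN_FACTORS, sphericity=sphericity
    )
    analyses.append(
        _analysis(
            "offline_session",
            offline_table,
            offline_spec,
            [["age_group", "break_duration"], ["break_type"]],
            adjustment,
            compute_bf,
        )
    )

    sub_spec = AnovaSpec(
        dv="z_gpi",
        within="session",
        between=["break_duration", "break_type"],
        sphericity=sphericity,
    )
    for group, name in (("adult", "adults_session"), ("child", "children_session")):
        sub = offline_table[offline_table["age_group"] == group]
        if sub.empty:
            continue
        analyses.append(
            _analysis(
                name,
                sub,
                sub_spec,
                [["break_duration"], ["break_type"]],
                adjustment,
                compute_bf,
            )
        )
    return analyses
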