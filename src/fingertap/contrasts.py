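"""Post hoc pairwise contrasts with Bonferroni or Tukey adjustment.

Within-factor (repeated measures) comparisons are paired t-tests; between-
factor comparisons are Welch t-tests. Cohen's d for paired contrasts is the
mean difference divided by the SD of the differences, signed first-minus-
second level — so an S1-vs-S2 improvement yields a negative d.

Bonferroni multiplies each p by the number of comparisons in the family and
caps at 1. Tukey maps sqrt(2)*|t| through the studentized-range distribution
with the pair's own degrees of freedom (a Games-Howell-style variant, since
a pooled repeated-measures error term is not defined for unbalanced cells).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ADJUSTMENTS = ("bonferroni", "tukey", "none")


@dataclass
class ContrastResult:
    """One pairwise comparison (level_a minus level_b)."""

    label: str
    level_a: str
    level_b: str
    estimate: float
    t: float
    df: float
    p_uncorrected: float
    p_adjusted: float
    adjustment: str
    cohen_d: float
    n: int
    paired: bool


def cohen_d_paired(a: np.ndarray, b: np.ndarray) -> float:
    """Paired Cohen's d: mean(a - b) / sd(a - b) (sample SD)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(d.mean() / sd)


def _pair_test(a: np.ndarray, b: np.ndarray, paired: bool):
    if paired:
        diff = a - b
        n = diff.size
        sd = diff.std(ddof=1)
        if sd == 0:
            return 0.0, float(n - 1), 1.0 if diff.mean() == 0 else 0.0
        t = diff.mean() / (sd / np.sqrt(n))
        df = n - 1
    else:
        t, p, df = _welch(a, b)
        return t, df, p
    return float(t), float(df), float(2 * stats.t.sf(abs(t), df))


def _welch(a: np.ndarray, b: np.ndarray):
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p), float(df)


def posthoc_contrasts(
    table: pd.DataFrame,
    *,
    dv: str = "z_gpi",
    factor: str = "session",
    subject: str = "participant_id",
    by: list[str] | None = None,
    paired: bool = True,
    adjustment: str = "bonferroni",
    n_levels_family: int | None = None,
) -> list[ContrastResult]:
    """All pairwise comparisons of ``factor`` levels, separately within each
    combination of ``by`` factors; the whole call is one multiple-comparison
    family.

    ``n_levels_family`` optionally overrides the Tukey number-of-means
    parameter (defaults to the number of factor levels).
    """
    if adjustment not in ADJUSTMENTS:
        raise ValueError(
            f"unknown adjustment {adjustment!r}; expected one of {ADJUSTMENTS}"
        )
    by = by or []
    levels = sorted(pd.unique(table[factor]))
    k_means = n_levels_family or len(levels)
    groups = table.groupby(by, sort=True) if by else [((), table)]
    raw = []
    for key, grp in groups:
        key = key if isinstance(key, tuple) else (key,)
        label = ", ".join(f"{f}={v}" for f, v in zip(by, key)) or "(all)"
        for la, lb in itertools.combinations(levels, 2):
            if paired:
                wide = grp.pivot(index=subject, columns=factor, values=dv)
                if la not in wide.columns or lb not in wide.columns:
                    continue
                sub = wide[[la, lb]].dropna()
                a, b = sub[la].to_numpy(), sub[lb].to_numpy()
                n = len(sub)
                d = cohen_d_paired(a, b)
            else:
                a = grp.loc[grp[factor] == la, dv].to_numpy(dtype=float)
                b = grp.loc[grp[factor] == lb, dv].to_numpy(dtype=float)
                n = a.size + b.size
                pooled = np.sqrt(
                    ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                    / (n - 2)
                )
                d = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
            t, df, p = _pair_test(a, b, paired)
            raw.append((label, str(la), str(lb), a.mean() - b.mean(), t, df, p, d, n))

    m = len(raw)
    out = []
    for label, la, lb, est, t, df, p, d, n in raw:
        if adjustment == "bonferroni":
            p_adj = min(1.0, p * m)
        elif adjustment == "tukey":
            q = abs(t) * np.sqrt(2.0)
            p_adj = float(stats.studentized_range.sf(q, max(2, k_means), df))
        else:
            p_adj = p
        out.append(
            ContrastResult(
                label=label,
                level_a=la,
                level_b=lb,
                estimate=float(est),
                t=t,
                df=df,
                p_uncorrected=p,
                p_adjusted=max(p, p_adj) if adjustment != "none" else p,
                adjustment=adjustment,
                cohen_d=d,
                n=n,
                paired=paired,
            )
        )
    return out


def contrasts_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": c.label,
                "level_a": c.level_a,
                "level_b": c.level_b,
                "estimate": c.estimate,
                "t": c.t,
                "df": c.df,
                "p_unc": c.p_uncorrected,
                "p_adj": c.p_adjusted,
                "adjustment": c.adjustment,
                "cohen_d": c.cohen_d,
                "n": c.n,
            }
            for c in contrasts
        ]
    )
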