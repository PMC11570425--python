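"""Mixed-design (split-plot) repeated-measures ANOVA.

One within-subject factor (Session with 2 levels, or Block with 12) crossed
with up to three between-subject factors (Age group, Break duration, Break
type). Fitting is done stratum-wise, which is exact for this design:

* between-subject effects are tested on per-subject means, with the
  subjects-within-cells mean square as the error term (df = N - c for c
  between cells);
* within-involving effects are tested on the within-subject deviations
  (each subject's scores minus their mean), with the residual of the full
  within model as the error term (df = (w - 1)(N - c)).

Sums of squares are Type III partial sums of squares under sum-to-zero
(effect) coding; on balanced designs these coincide with Type II. Sphericity
is assessed with Mauchly's test on the pooled within-cell covariance matrix
and handled with the Greenhouse-Geisser correction (both raw and corrected
p-values are always reported for within factors with more than two levels;
the ``sphericity`` policy decides which one is flagged as primary).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel
from scipy import stats


class AnovaSpec(BaseModel):
    """Specification of one mixed ANOVA on a long-format design table."""

    dv: str = "z_gpi"
    within: str = "session"
    subject: str = "participant_id"
    between: list[str] = []
    ss_type: Literal[2, 3] = 3
    sphericity: Literal["never", "always", "when-violated"] = "when-violated"
    alpha_mauchly: float = 0.05


@dataclass
class EffectResult:
    """One ANOVA effect row."""

    effect: str
    df_num: float
    df_den: float
    F: float
    p_uncorrected: float
    partial_eta_sq: float
    ss: float
    ss_error: float
    gg_epsilon: float | None = None
    p_gg: float | None = None
    gg_applied: bool = False
    bf_incl: float | None = None

    @property
    def p(self) -> float:
        """Primary p-value (Greenhouse-Geisser corrected when applied)."""
        return self.p_gg if self.gg_applied and self.p_gg is not None else self.p_uncorrected


@dataclass
class AnovaTable:
    """Fitted mixed ANOVA: effect rows plus design diagnostics."""

    effects: list[EffectResult]
    n_subjects: int
    n_cells: int
    within_levels: list
    balanced: bool
    cell_counts: dict[str, int]
    mauchly_w: float | None = None
    mauchly_chi2: float | None = None
    mauchly_df: float | None = None
    mauchly_p: float | None = None
    gg_epsilon: float | None = None
    spec: AnovaSpec | None = None

    def __iter__(self):
        return iter(self.effects)

    def get(self, effect: str) -> EffectResult:
        for e in self.effects:
            if e.effect == effect:
                return e
        raise KeyError(f"no effect named {effect!r}; have "
                       f"{[e.effect for e in self.effects]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": e.effect,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "F": e.F,
                    "p_unc": e.p_uncorrected,
                    "gg_epsilon": e.gg_epsilon,
                    "p_gg": e.p_gg,
                    "partial_eta_sq": e.partial_eta_sq,
                    "bf_incl": e.bf_incl,
                }
                for e in self.effects
            ]
        )


# ---------------------------------------------------------------------------
# design-matrix helpers


def _sorted_levels(values: pd.Series) -> list:
    levels = pd.unique(values)
    try:
        return sorted(levels)
    except TypeError:
        return list(levels)


def sum_code(values: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero (effect) coding: L levels -> L-1 columns; the last level is
    coded -1 on every column."""
    L = len(levels)
    idx = {lev: i for i, lev in enumerate(levels)}
    pos = np.array([idx[v] for v in values])
    X = np.zeros((len(values), L - 1))
    for j in range(L - 1):
        X[pos == j, j] = 1.0
    X[pos == L - 1, :] = -1.0
    return X


def _between_terms(between: list[str]) -> list[tuple[str, ...]]:
    terms: list[tuple[str, ...]] = []
    for k in range(1, len(between) + 1):
        terms.extend(itertools.combinations(between, k))
    return terms


def _term_matrix(term: tuple[str, ...], coded: dict[str, np.ndarray], n: int) -> np.ndarray:
    M = np.ones((n, 1))
    for f in term:
        C = coded[f]
        M = (M[:, :, None] * C[:, None, :]).reshape(n, -1)
    return M


def _rss(X: np.ndarray | None, y: np.ndarray) -> float:
    if X is None or X.shape[1] == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


# ---------------------------------------------------------------------------
# sphericity


def pooled_within_cov(Y: np.ndarray, cell_codes: np.ndarray) -> np.ndarray:
    """Pooled within-cell covariance of the repeated measures (divisor N - c)."""
    N, w = Y.shape
    cells = np.unique(cell_codes)
    S = np.zeros((w, w))
    for cval in cells:
        sub = Y[cell_codes == cval]
        d = sub - sub.mean(axis=0, keepdims=True)
        S += d.T @ d
    return S / (N - len(cells))


def gg_epsilon(S: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon-hat from a within-subject covariance matrix.

    epsilon = tr(PSP)^2 / ((w-1) * tr((PSP)^2)) with P the centering
    projector; bounded in [1/(w-1), 1].
    """
    S = np.asarray(S, dtype=float)
    w = S.shape[0]
    if w < 2:
        raise ValueError("need at least 2 within levels")
    if w == 2:
        return 1.0
    P = np.eye(w) - np.full((w, w), 1.0 / w)
    T = P @ S @ P
    num = np.trace(T) ** 2
    den = (w - 1) * np.sum(T * T)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / (w - 1), num / den)))


def mauchly_test(S: np.ndarray, n_error_df: int) -> tuple[float, float, float, float]:
    """Mauchly's sphericity test on covariance matrix S with error df n_error_df.

    Returns (W, chi2, df, p). A singular contrast covariance yields W = 0 and
    p = 0 (treated as a violation).
    """
    S = np.asarray(S, dtype=float)
    w = S.shape[0]
    k = w - 1
    if k < 2:
        return 1.0, 0.0, 0.0, 1.0
    # orthonormal contrasts (rows orthogonal to the unit vector)
    M = np.linalg.qr(np.eye(w) - np.full((w, w), 1.0 / w))[0][:, :k].T
    T = M @ S @ M.T
    eig = np.linalg.eigvalsh(T)
    mean_eig = eig.mean()
    df = k * (k + 1) / 2 - 1
    if np.any(eig <= 0) or mean_eig <= 0:
        return 0.0, np.inf, df, 0.0
    W = float(np.exp(np.sum(np.log(eig)) - k * np.log(mean_eig)))
    d = 1 - (2 * k**2 + k + 2) / (6 * k * n_error_df)
    chi2 = -n_error_df * d * np.log(W)
    p = float(stats.chi2.sf(chi2, df))
    return W, float(chi2), float(df), p


# ---------------------------------------------------------------------------
# main fit


def fit_mixed_anova(table: pd.DataFrame, spec: AnovaSpec) -> AnovaTable:
    """Fit the mixed-design RM-ANOVA described by ``spec`` on a long table.

    Requires a complete within design (every subject observed once at every
    within level) and at least two subjects per between cell; a missing or
    singleton cell raises an error naming the cell.
    """
    cols = [spec.subject, spec.within, *spec.between, spec.dv]
    missing = set(cols) - set(table.columns)
    if missing:
        raise ValueError(f"design table missing column(s): {sorted(missing)}")
    df = table[cols].copy()
    if df[spec.dv].isna().any():
        raise ValueError("design table contains missing DV values")

    wide = df.pivot_table(
        index=spec.subject, columns=spec.within, values=spec.dv, aggfunc="count"
    )
    if (wide != 1).any().any() or wide.isna().any().any():
        bad = wide.index[(wide != 1).any(axis=1) | wide.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete or duplicated within design for subjects {bad}")
    wide = df.pivot(index=spec.subject, columns=spec.within, values=spec.dv)
    within_levels = _sorted_levels(df[spec.within])
    wide = wide[within_levels]
    Y = wide.to_numpy(dtype=float)
    N, w = Y.shape

    meta = (
        df.drop_duplicates(spec.subject).set_index(spec.subject).loc[wide.index]
        if spec.between
        else pd.DataFrame(index=wide.index)
    )
    if spec.between:
        consistent = df.groupby(spec.subject)[spec.between].nunique()
        if (consistent > 1).any().any():
            raise ValueError("between-factor labels vary within a subject")

    between_levels = {f: _sorted_levels(df[f]) for f in spec.between}
    coded = {
        f: sum_code(meta[f].to_numpy(), between_levels[f]) for f in spec.between
    }
    # cell bookkeeping
    if spec.between:
        cell_labels = meta[spec.between].astype(str).agg("|".join, axis=1)
        counts = cell_labels.value_counts()
        expected = [
            "|".join(map(str, combo))
            for combo in itertools.product(
                *(between_levels[f] for f in spec.between)
            )
        ]
        for cell in expected:
            n_in = int(counts.get(cell, 0))
            if n_in == 0:
                raise ValueError(f"empty between cell: {cell}")
            if n_in < 2:
                raise ValueError(f"between cell with a single subject: {cell}")
        cell_counts = {c: int(counts[c]) for c in expected}
        _, cell_codes = np.unique(cell_labels.to_numpy(), return_inverse=True)
    else:
        cell_counts = {"(all)": N}
        cell_codes = np.zeros(N, dtype=int)
    n_cells = len(cell_counts)
    balanced = len(set(cell_counts.values())) == 1
    if N - n_cells < 1:
        raise ValueError("no error degrees of freedom (need more subjects)")

    terms = _between_terms(spec.between)
    term_mats = {t: _term_matrix(t, coded, N) for t in terms}

    effects: list[EffectResult] = []

    # ---- between stratum: subject means -----------------------------------
    ybar = Y.mean(axis=1)
    blocks_b = [np.ones((N, 1))] + [term_mats[t] for t in terms]
    Xb_full = np.hstack(blocks_b)
    rss_full_b = _rss(Xb_full, ybar)
    df_err_b = N - Xb_full.shape[1]
    for t in terms:
        keep = [np.ones((N, 1))] + [term_mats[u] for u in terms if u != t]
        ss = max(0.0, _rss(np.hstack(keep), ybar) - rss_full_b)
        df1 = term_mats[t].shape[1]
        F = (ss / df1) / (rss_full_b / df_err_b)
        p = float(stats.f.sf(F, df1, df_err_b))
        effects.append(
            EffectResult(
                effect=":".join(t),
                df_num=df1,
                df_den=df_err_b,
                F=float(F),
                p_uncorrected=p,
                partial_eta_sq=float(ss / (ss + rss_full_b)),
                ss=float(ss * w),
                ss_error=float(rss_full_b * w),
            )
        )

    # ---- within stratum: deviations from subject means --------------------
    D = (Y - ybar[:, None]).ravel()  # subject-major
    Cw = sum_code(np.array(within_levels, dtype=object), within_levels)
    Cw_exp = np.tile(Cw, (N, 1))
    Xb_exp_blocks = {(): np.ones((N * w, 1))}
    for t in terms:
        Xb_exp_blocks[t] = np.repeat(term_mats[t], w, axis=0)

    def within_cols(t: tuple[str, ...]) -> np.ndarray:
        B = Xb_exp_blocks[t]
        return (Cw_exp[:, :, None] * B[:, None, :]).reshape(N * w, -1)

    wterms = [()] + terms
    wmats = {t: within_cols(t) for t in wterms}
    Xw_full = np.hstack([wmats[t] for t in wterms])
    rss_full_w = _rss(Xw_full, D)
    df_err_w = (w - 1) * (N - n_cells)

    eps = mau = None
    if w > 2:
        S = pooled_within_cov(Y, cell_codes)
        eps = gg_epsilon(S)
        mau = mauchly_test(S, N - n_cells)
    violated = mau is not None and mau[3] < spec.alpha_mauchly
    apply_gg = {
        "never": False,
        "always": w > 2,
        "when-violated": w > 2 and violated,
    }[spec.sphericity]

    for t in wterms:
        keep = [wmats[u] for u in wterms if u != t]
        ss = max(0.0, _rss(np.hstack(keep) if keep else None, D) - rss_full_w)
        df1 = wmats[t].shape[1]
        F = (ss / df1) / (rss_full_w / df_err_w)
        p = float(stats.f.sf(F, df1, df_err_w))
        name = spec.within if t == () else ":".join((spec.within,) + t)
        if w == 2:
            e_eps, p_gg = 1.0, p
        elif eps is not None:
            e_eps = eps
            p_gg = float(stats.f.sf(F, df1 * eps, df_err_w * eps))
        else:  # pragma: no cover
            e_eps, p_gg = None, None
        effects.append(
            EffectResult(
                effect=name,
                df_num=df1,
                df_den=df_err_w,
                F=float(F),
                p_uncorrected=p,
                partial_eta_sq=float(ss / (ss + rss_full_w)),
                ss=float(ss),
                ss_error=float(rss_full_w),
                gg_epsilon=e_eps,
                p_gg=p_gg,
                gg_applied=apply_gg,
            )
        )

    return AnovaTable(
        effects=effects,
        n_subjects=N,
        n_cells=n_cells,
        within_levels=list(within_levels),
        balanced=balanced,
        cell_counts=cell_counts,
        mauchly_w=None if mau is None else mau[0],
        mauchly_chi2=None if mau is None else mau[1],
        mauchly_df=None if mau is None else mau[2],
        mauchly_p=None if mau is None else mau[3],
        gg_epsilon=eps,
        spec=spec,
    )
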