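"""Inclusion Bayes factors via a BIC approximation with matched-models
averaging.

For every effect we enumerate the hierarchical (marginality-respecting) model
space, weight each model by exp(-BIC/2) (unit-information prior, uniform
model priors), and form

    BF_incl = sum of weights of models that contain the effect but no
              higher-order interaction involving it
            / sum of weights of the same models with the effect removed.

The enumeration is stratum-wise, mirroring the split-plot fit: between-
subject effects compete on the per-subject means (n = N observations),
within-involving effects on the within-subject deviations (n = N*(w-1)
effective observations). This keeps every model estimable without a random
subject term and is an approximation to (not a replica of) JZS-prior
Bayesian ANOVA; calibration: values > 3 support inclusion, < 1/3 exclusion.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .anova import (
    AnovaSpec,
    _between_terms,
    _rss,
    _sorted_levels,
    _term_matrix,
    sum_code,
)

Term = tuple[str, ...]  # between term; within-involving terms get prefix WITHIN

WITHIN = "__within__"


def _closed(s: frozenset[Term]) -> bool:
    have = {frozenset(t) for t in s}
    for t in s:
        for k in range(1, len(t)):
            for sub in itertools.combinations(t, k):
                if frozenset(sub) not in have:
                    return False
    return True


def hierarchical_models(terms: list[Term]) -> list[frozenset[Term]]:
    """All subsets of ``terms`` closed under marginality (every sub-term of an
    included interaction is also included)."""
    out = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            s = frozenset(combo)
            if _closed(s):
                out.append(s)
    return out


def _bic(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + k * np.log(n)


class _Stratum:
    """One model-selection stratum: a response vector plus candidate term
    column blocks."""

    def __init__(self, y: np.ndarray, blocks: dict[Term, np.ndarray],
                 base: np.ndarray | None, n_eff: int):
        self.y = y
        self.blocks = blocks
        self.base = base  # columns present in every model (intercept), or None
        self.n_eff = n_eff
        self._cache: dict[frozenset[Term], float] = {}

    def bic(self, model: frozenset[Term]) -> float:
        if model not in self._cache:
            cols = [] if self.base is None else [self.base]
            k = 0 if self.base is None else self.base.shape[1]
            for t in sorted(model):
                cols.append(self.blocks[t])
                k += self.blocks[t].shape[1]
            X = np.hstack(cols) if cols else None
            self._cache[model] = _bic(_rss(X, self.y), self.n_eff, k + 2)
        return self._cache[model]


def _strata(table: pd.DataFrame, spec: AnovaSpec) -> tuple[_Stratum, _Stratum, list[Term]]:
    df = table[[spec.subject, spec.within, *spec.between, spec.dv]].copy()
    wide = df.pivot(index=spec.subject, columns=spec.within, values=spec.dv)
    within_levels = _sorted_levels(df[spec.within])
    wide = wide[within_levels]
    if wide.isna().any().any():
        raise ValueError("incomplete within design")
    Y = wide.to_numpy(dtype=float)
    N, w = Y.shape
    meta = (
        df.drop_duplicates(spec.subject).set_index(spec.subject).loc[wide.index]
        if spec.between
        else pd.DataFrame(index=wide.index)
    )
    coded = {
        f: sum_code(meta[f].to_numpy(), _sorted_levels(df[f])) for f in spec.between
    }
    terms = _between_terms(spec.between)
    term_mats = {t: _term_matrix(t, coded, N) for t in terms}

    ybar = Y.mean(axis=1)
    between = _Stratum(ybar, dict(term_mats), np.ones((N, 1)), N)

    D = (Y - ybar[:, None]).ravel()
    Cw = sum_code(np.array(within_levels, dtype=object), within_levels)
    Cw_exp = np.tile(Cw, (N, 1))
    wblocks: dict[Term, np.ndarray] = {}
    for t in [()] + terms:
        B = np.ones((N * w, 1)) if t == () else np.repeat(term_mats[t], w, axis=0)
        key: Term = (WITHIN,) + t
        wblocks[key] = (Cw_exp[:, :, None] * B[:, None, :]).reshape(N * w, -1)
    within = _Stratum(D, wblocks, None, N * (w - 1))
    return between, within, terms


def _effect_term(effect: str, spec: AnovaSpec) -> tuple[Term, bool]:
    parts = tuple(effect.split(":"))
    if parts[0] == spec.within:
        return (WITHIN,) + parts[1:], True
    return parts, False


def inclusion_bfs(
    table: pd.DataFrame, spec: AnovaSpec, effects: list[str] | None = None
) -> dict[str, float]:
    """Inclusion Bayes factors for all (or the named) effects of the design."""
    between, within, terms = _strata(table, spec)
    bmodels = hierarchical_models(terms)
    wterms: list[Term] = [(WITHIN,) + t for t in [()] + terms]

    def wclosed(s: frozenset[Term]) -> bool:
        for t in s:
            bt = t[1:]
            for k in range(0, len(bt)):
                for sub in itertools.combinations(bt, k):
                    if (WITHIN,) + sub not in s:
                        return False
        return True

    wmodels = [
        s
        for r in range(len(wterms) + 1)
        for s in map(frozenset, itertools.combinations(wterms, r))
        if wclosed(s)
    ]

    all_effects = [":".join(t) for t in terms] + [
        spec.within if t == (WITHIN,) else ":".join((spec.within,) + t[1:])
        for t in wterms
    ]
    if effects is None:
        effects = all_effects

    out: dict[str, float] = {}
    for eff in effects:
        term, is_within = _effect_term(eff, spec)
        stratum = within if is_within else between
        models = wmodels if is_within else bmodels
        universe = set(wterms if is_within else terms)
        if term not in universe:
            raise ValueError(f"effect {eff!r} not in the design")
        supersets = {u for u in universe if set(term) < set(u)}
        cands = [m for m in models if term in m and not (m & supersets)]
        if not cands:
            raise ValueError(f"effect {eff!r} absent from all candidate models")
        bics_with = np.array([stratum.bic(m) for m in cands])
        bics_without = np.array([stratum.bic(m - {term}) for m in cands])
        log_bf = logsumexp(-bics_with / 2) - logsumexp(-bics_without / 2)
        with np.errstate(over="ignore"):  # overwhelming evidence -> inf
            out[eff] = float(np.exp(log_bf))
    return out


def inclusion_bf(table: pd.DataFrame, spec: AnovaSpec, effect: str) -> float:
    """Inclusion Bayes factor for one effect (see module docstring)."""
    return inclusion_bfs(table, spec, [effect])[effect]
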