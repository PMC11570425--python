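"""Synthetic finger-tapping cohorts for the two-session mixed design.

The generator emulates a mixed design: 2 age groups (child, adult) x 2 break
durations (30 min, 4 h) x 2 break types (active, passive), each participant
tapping twelve 30-s learning blocks (session S1) and two delayed test blocks
(session S2).

Latent model, per participant i in cell g, block b:

* S1 tapping rate: ``r_ib = R(b) + u_i + e_ib`` with the saturating learning
  curve ``R(b) = r_inf - (r_inf - r_0) * exp(-(b - 1) / tau)``, a
  between-participant offset ``u_i ~ N(0, sd_between)`` and block noise
  ``e_ib ~ N(0, sd_within)``.
* S2 tapping rate: ``r_ib = R_end + delta_g * sigma_diff + u_i + e_ib`` where
  ``R_end`` is the mean of the latent curve over the last two S1 blocks (the
  same blocks the offline contrast averages, so delta_g = 0 is an exact null)
  and ``delta_g`` is the cell's offline boost in SD units of the paired
  session-difference score. ``sigma_diff`` combines the latent block noise
  with the renewal-process keypress-count noise, so the latent paired Cohen's
  d of the S1-vs-S2 contrast equals delta_g by construction.
* Error probability follows its own saturating curve and is frozen at its
  end-of-learning value in S2.

Keypress streams are renewal processes with gamma-distributed inter-press
intervals (shape 4, mean 1/rate — right-skewed like human inter-tap
intervals); each press is the next element of the cyclic target with
probability 1 - p_err, otherwise a uniformly random wrong key.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .scoring import TARGET_SEQUENCE, BlockRecord

AGE_GROUPS = ("child", "adult")
BREAK_DURATIONS = ("30min", "4h")
BREAK_TYPES = ("active", "passive")

Cell = tuple[str, str, str]  # (age_group, break_duration, break_type)


def cell_key(cell: Cell | str) -> str:
    """Canonical string key 'age|duration|type' for a design cell."""
    if isinstance(cell, str):
        return cell
    return "|".join(cell)


def all_cells() -> list[Cell]:
    return [
        (a, d, t)
        for a, d, t in itertools.product(AGE_GROUPS, BREAK_DURATIONS, BREAK_TYPES)
    ]


#: Default offline-boost map (in session-difference SD units), encoding the
#: qualitative result pattern: adults improve after 30 min regardless of break
#: type and not after 4 h; children improve after an active break at both
#: delays and not after a passive one.
DEFAULT_SESSION_OFFSET: dict[str, float] = {
    "adult|30min|active": 1.3,
    "adult|30min|passive": 1.3,
    "adult|4h|active": 0.0,
    "adult|4h|passive": 0.0,
    "child|30min|active": 1.2,
    "child|4h|active": 1.2,
    "child|30min|passive": 0.0,
    "child|4h|passive": 0.0,
}


class LearningCurve(BaseModel):
    """Saturating-exponential latent tapping rate across S1 blocks."""

    rate_initial: float = 2.2  # keypresses/s at block 1
    rate_asymptote: float = 3.3  # keypresses/s plateau
    tau: float = 2.5  # blocks

    @model_validator(mode="after")
    def _check(self) -> "LearningCurve":
        if not (self.rate_asymptote >= self.rate_initial > 0):
            raise ValueError("require rate_asymptote >= rate_initial > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        return self

    def value(self, block) -> np.ndarray:
        b = np.asarray(block, dtype=float)
        return self.rate_asymptote - (self.rate_asymptote - self.rate_initial) * np.exp(
            -(b - 1.0) / self.tau
        )


class ErrorCurve(BaseModel):
    """Saturating-exponential per-keypress error probability across S1 blocks."""

    p_err_initial: float = 0.08
    p_err_asymptote: float = 0.02
    tau_err: float = 3.0

    @model_validator(mode="after")
    def _check(self) -> "ErrorCurve":
        for p in (self.p_err_initial, self.p_err_asymptote):
            if not 0.0 <= p <= 1.0:
                raise ValueError("error probabilities must lie in [0, 1]")
        if self.tau_err <= 0:
            raise ValueError("tau_err must be > 0")
        return self

    def value(self, block) -> np.ndarray:
        b = np.asarray(block, dtype=float)
        return self.p_err_asymptote + (
            self.p_err_initial - self.p_err_asymptote
        ) * np.exp(-(b - 1.0) / self.tau_err)


class SimulationConfig(BaseModel):
    """Full description of one synthetic cohort."""

    seed: int = 0
    n_per_cell: Union[int, dict[str, int]] = 14
    cells: list[Cell] = Field(default_factory=all_cells)
    block_duration_s: float = 30.0
    n_s1_blocks: int = 12
    n_s2_blocks: int = 2
    learning_curve: LearningCurve = Field(default_factory=LearningCurve)
    error_curve: ErrorCurve = Field(default_factory=ErrorCurve)
    session_offset: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_SESSION_OFFSET)
    )
    noise_sd_between: float = 0.35  # keypresses/s
    noise_sd_within: float = 0.15  # keypresses/s
    ipi_shape: float = 4.0  # gamma shape of inter-press intervals (CV = 0.5)
    error_mode: Literal["continue", "restart"] = "continue"
    min_rate: float = 0.2  # floor on the latent rate, keypresses/s

    @field_validator("cells")
    @classmethod
    def _cells_nonempty(cls, v: list[Cell]) -> list[Cell]:
        if not v:
            raise ValueError("cells list must be nonempty")
        for cell in v:
            a, d, t = cell
            if a not in AGE_GROUPS or d not in BREAK_DURATIONS or t not in BREAK_TYPES:
                raise ValueError(f"unknown cell {cell!r}")
        if len(set(v)) != len(v):
            raise ValueError("duplicate cells")
        return v

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        ns = (
            [self.n_per_cell]
            if isinstance(self.n_per_cell, int)
            else list(self.n_per_cell.values())
        )
        if any(n < 2 for n in ns):
            raise ValueError("n_per_cell must be >= 2")
        if isinstance(self.n_per_cell, dict):
            missing = {cell_key(c) for c in self.cells} - set(self.n_per_cell)
            if missing:
                raise ValueError(f"n_per_cell missing cells: {sorted(missing)}")
        if self.block_duration_s <= 0:
            raise ValueError("block_duration_s must be > 0")
        if self.n_s1_blocks < 2 or self.n_s2_blocks < 1:
            raise ValueError("need >= 2 learning blocks and >= 1 test block")
        for sd in (self.noise_sd_between, self.noise_sd_within):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")
        if self.ipi_shape <= 0:
            raise ValueError("ipi_shape must be > 0")
        return self

    def cell_n(self, cell: Cell) -> int:
        if isinstance(self.n_per_cell, int):
            return self.n_per_cell
        return self.n_per_cell[cell_key(cell)]


@dataclass
class CohortBundle:
    """A simulated cohort: metadata, raw keypress blocks, and the latent truth."""

    participants: pd.DataFrame  # participant_id, age_group, break_duration, ...
    blocks: list[BlockRecord]
    truth: pd.DataFrame  # participant_id, session, block, latent_rate, p_err

    def events_frame(self) -> pd.DataFrame:
        """Long keypress-event table (participant_id, session, block, t_s, key)."""
        parts = []
        for b in self.blocks:
            n = b.n_keypresses
            parts.append(
                pd.DataFrame(
                    {
                        "participant_id": np.repeat(b.participant_id, n),
                        "session": np.repeat(b.session, n),
                        "block": np.repeat(b.block_index, n),
                        "t_s": b.times,
                        "key": b.keys,
                    }
                )
            )
        if not parts:
            return pd.DataFrame(
                columns=["participant_id", "session", "block", "t_s", "key"]
            )
        return pd.concat(parts, ignore_index=True)


def simulate_block(
    rate: float,
    p_err: float,
    duration: float,
    target: tuple[int, ...] = TARGET_SEQUENCE,
    rng: np.random.Generator | None = None,
    *,
    ipi_shape: float = 4.0,
    error_mode: str = "continue",
    participant_id: str = "p00",
    session: str = "S1",
    block_index: int = 1,
) -> BlockRecord:
    """Simulate one tapping block as a gamma-renewal keypress stream.

    ``error_mode='continue'`` (default): a wrong key does not reset the
    participant's position in the cyclic target. ``'restart'``: after an
    error the participant restarts the sequence from its first element.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if not 0.0 <= p_err <= 1.0:
        raise ValueError("p_err must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    if duration == 0:
        return BlockRecord(participant_id, session, block_index, duration,
                           np.empty(0), np.empty(0, dtype=np.int64))
    scale = 1.0 / (ipi_shape * rate)
    chunks = []
    total = 0.0
    n_guess = int(duration * rate * 1.3) + 20
    while total < duration:
        iv = rng.gamma(ipi_shape, scale, n_guess)
        cs = total + np.cumsum(iv)
        chunks.append(cs)
        total = cs[-1]
    times = np.concatenate(chunks)
    times = times[times < duration]
    n = times.size
    tarr = np.asarray(target, dtype=np.int64)
    tlen = tarr.size
    if error_mode == "continue":
        keys = tarr[np.arange(n) % tlen].copy()
        err = rng.random(n) < p_err
        n_err = int(err.sum())
        if n_err:
            # wrong key = cyclic shift by 1..3 in key space {1..4}, uniform
            offs = rng.integers(1, 4, size=n_err)
            keys[err] = ((keys[err] - 1 + offs) % 4) + 1
    elif error_mode == "restart":
        keys = np.empty(n, dtype=np.int64)
        pos = 0
        for i in range(n):
            correct = tarr[pos % tlen]
            if rng.random() < p_err:
                keys[i] = ((correct - 1 + rng.integers(1, 4)) % 4) + 1
                pos = 0
            else:
                keys[i] = correct
                pos += 1
    else:
        raise ValueError(f"unknown error_mode {error_mode!r}")
    return BlockRecord(participant_id, session, block_index, duration, times, keys)


def session_diff_sd(config: SimulationConfig) -> float:
    """Analytic SD, in tapping-rate units, of the paired S1-vs-S2
    session-difference score as measured on the (log) GPI scale.

    Each session score averages two blocks, so the difference variance equals
    the per-block measurement variance. On the log-GPI scale
    ``g = -(speed + accuracy)`` three noise sources enter at the
    end-of-learning operating point (rate r, error probability p, n = r*T
    keypresses per block):

    * latent block-to-block rate noise ``sd_within``,
    * renewal keypress-count noise ``var(rate_hat) ~= r / (shape * T)``,
      both mapped through ``speed = 1/rate`` (slope 1/r^2),
    * binomial sequencing-error noise in the accuracy term: each wrong key
      removes up to three overlapping chunk windows, so
      ``var(accuracy) ~= 9 p (1 - p) / n``.

    The total log-GPI SD is mapped back to rate units with the inverse slope
    r^2, so an S2 offset of ``delta * session_diff_sd`` yields a latent
    paired Cohen's d of ``delta`` on the (z-scored) GPI outcome. The accuracy
    term assumes the default 'continue' error mode.
    """
    lc, ec = config.learning_curve, config.error_curve
    last_two = [config.n_s1_blocks - 1, config.n_s1_blocks]
    r_end = float(np.mean(lc.value(last_two)))
    p_end = float(np.mean(ec.value(last_two)))
    n_keys = r_end * config.block_duration_s
    rate_var = config.noise_sd_within**2 + r_end / (
        config.ipi_shape * config.block_duration_s
    )
    g_var = rate_var / r_end**4 + 9.0 * p_end * (1.0 - p_end) / n_keys
    return float(r_end**2 * np.sqrt(g_var))


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> CohortBundle:
    """Generate a full cohort; deterministic given config and seed.

    ``seed`` overrides ``config.seed`` when given.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lc, ec = config.learning_curve, config.error_curve
    ns1, ns2 = config.n_s1_blocks, config.n_s2_blocks
    s1_blocks = np.arange(1, ns1 + 1)
    rate_s1 = lc.value(s1_blocks)
    perr_s1 = ec.value(s1_blocks)
    r_end = float(np.mean(rate_s1[-2:]))
    p_end = float(np.mean(perr_s1[-2:]))
    sd_diff = session_diff_sd(config)

    part_rows = []
    truth_rows = []
    blocks: list[BlockRecord] = []
    for cell in config.cells:
        age, dur, btype = cell
        delta = config.session_offset.get(cell_key(cell), 0.0)
        source = "archival" if (age == "adult" and btype == "active") else "new"
        for i in range(config.cell_n(cell)):
            pid = f"{age}-{dur}-{btype}-{i + 1:02d}"
            u = rng.normal(0.0, config.noise_sd_between)
            if age == "child":
                sdsc = int(np.clip(round(rng.normal(36.6, 6.0)), 26, 57))
                psqi = None
            else:
                sdsc = None
                psqi = (
                    None
                    if source == "archival"
                    else int(np.clip(round(rng.normal(4.9, 1.9)), 2, 7))
                )
            part_rows.append((pid, age, dur, btype, sdsc, psqi, source))
            for b in range(1, ns1 + ns2 + 1):
                if b <= ns1:
                    session, mu, pe = "S1", rate_s1[b - 1], float(perr_s1[b - 1])
                else:
                    session, mu, pe = "S2", r_end + delta * sd_diff, p_end
                r = max(config.min_rate, mu + u + rng.normal(0.0, config.noise_sd_within))
                blocks.append(
                    simulate_block(
                        r,
                        pe,
                        config.block_duration_s,
                        rng=rng,
                        ipi_shape=config.ipi_shape,
                        error_mode=config.error_mode,
                        participant_id=pid,
                        session=session,
                        block_index=b,
                    )
                )
                truth_rows.append((pid, session, b, r, pe))

    participants = pd.DataFrame(
        part_rows,
        columns=[
            "participant_id",
            "age_group",
            "break_duration",
            "break_type",
            "sdsc",
            "psqi",
            "source",
        ],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["participant_id", "session", "block", "latent_rate", "p_err"],
    )
    return CohortBundle(participants=participants, blocks=blocks, truth=truth)
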