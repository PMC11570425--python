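"""Score raw finger-tapping keypress streams into per-block performance metrics.

A block is 30 s of free tapping of the cyclic target sequence 4-1-3-2-4
(1 = index finger ... 4 = little finger). Per block we compute:

* ``speed`` — block duration divided by the number of keypresses
  (seconds per keypress; lower is faster),
* ``accuracy`` — the *error fraction*: (keypresses - correct three-element
  chunks) / keypresses, where a chunk is a run of three consecutive
  keypresses matching the cyclic order of the target (lower is more accurate),
* ``gpi`` — the Global Performance Index ``exp(-speed) * exp(-accuracy)``,
  a speed-accuracy composite in (0, 1]; higher is better.

By default chunks are counted over *overlapping* stride-1 windows, so a
perfect stream of n keypresses contains n - 2 chunks and the seam between
two repetitions of the sequence (the 4 -> 4 transition) counts. A
non-overlapping (greedy, disjoint-triplet) variant is available via
``overlap=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The five-element target sequence typed with the non-dominant hand.
TARGET_SEQUENCE: tuple[int, ...] = (4, 1, 3, 2, 4)

VALID_KEYS = frozenset((1, 2, 3, 4))

METRICS_COLUMNS = [
    "participant_id",
    "session",
    "block",
    "n_keypresses",
    "n_chunks",
    "speed_s_per_key",
    "accuracy_err",
    "gpi",
    "flagged",
]


@dataclass(frozen=True)
class BlockRecord:
    """One 30-s tapping block: ordered, timestamped keypresses.

    ``times`` are seconds from block start, strictly within [0, duration);
    ``keys`` are integers 1-4. Blocks 1..n_s1 belong to session S1, the
    remainder to S2.
    """

    participant_id: str
    session: str
    block_index: int
    duration: float
    times: np.ndarray
    keys: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        k = np.asarray(self.keys, dtype=np.int64)
        if t.shape != k.shape:
            raise ValueError("times and keys must have equal length")
        if t.size:
            if np.any(np.diff(t) < 0):
                raise ValueError("timestamps must be nondecreasing")
            if t[0] < 0 or t[-1] >= self.duration > 0:
                raise ValueError("timestamps must lie in [0, duration)")
            bad = set(np.unique(k)) - VALID_KEYS
            if bad:
                raise ValueError(f"invalid key codes: {sorted(bad)}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "keys", k)
        if self.session not in ("S1", "S2"):
            raise ValueError(f"session must be 'S1' or 'S2', got {self.session!r}")

    @property
    def n_keypresses(self) -> int:
        return int(self.keys.size)


@dataclass(frozen=True)
class BlockMetrics:
    """Per-block performance summary (see module docstring for definitions)."""

    n_keypresses: int
    n_chunks: int
    speed: float  # seconds per keypress; +inf for an empty block
    accuracy: float  # error fraction in [0, 1]
    gpi: float  # exp(-speed) * exp(-accuracy); 0.0 sentinel for empty blocks
    flagged: bool = False  # True => needs exclusion review (e.g. empty block)


def _cyclic_triples(target: tuple[int, ...]) -> np.ndarray:
    """Base-5 codes of every length-3 substring of the infinite cyclic target."""
    ext = list(target) + list(target[:2])
    codes = {
        ext[i] * 25 + ext[i + 1] * 5 + ext[i + 2] for i in range(len(target))
    }
    return np.fromiter(sorted(codes), dtype=np.int64)


_TRIPLES_CACHE: dict[tuple[int, ...], np.ndarray] = {}


def count_correct_chunks(
    keys,
    target: tuple[int, ...] = TARGET_SEQUENCE,
    *,
    overlap: bool = True,
) -> int:
    """Count correct three-element chunks in a keypress stream.

    A window of three consecutive keypresses is *correct* when it matches some
    length-3 substring of the infinite cyclic repetition of ``target``. With
    ``overlap=True`` (default) every stride-1 window is tested; with
    ``overlap=False`` correct windows are consumed greedily left-to-right so
    counted triplets are disjoint.
    """
    if not target:
        raise ValueError("target sequence must be nonempty")
    k = np.asarray(keys, dtype=np.int64)
    n = k.size
    if n < 3:
        return 0
    tkey = tuple(target)
    triples = _TRIPLES_CACHE.get(tkey)
    if triples is None:
        triples = _TRIPLES_CACHE[tkey] = _cyclic_triples(tkey)
    codes = k[:-2] * 25 + k[1:-1] * 5 + k[2:]
    ok = np.isin(codes, triples)
    if overlap:
        return int(ok.sum())
    count = 0
    i = 0
    m = ok.size
    while i < m:
        if ok[i]:
            count += 1
            i += 3
        else:
            i += 1
    return count


def score_block(
    block: BlockRecord,
    target: tuple[int, ...] = TARGET_SEQUENCE,
    *,
    overlap: bool = True,
) -> BlockMetrics:
    """Compute speed, accuracy (error fraction) and GPI for one block.

    A block with zero keypresses cannot be scored meaningfully: it returns the
    sentinel ``speed=inf, accuracy=1, gpi=0`` and is flagged for exclusion
    review rather than raising.
    """
    if block.duration <= 0:
        raise ValueError("block duration must be positive")
    n = block.n_keypresses
    if n == 0:
        return BlockMetrics(0, 0, math.inf, 1.0, 0.0, flagged=True)
    chunks = count_correct_chunks(block.keys, target, overlap=overlap)
    speed = block.duration / n
    accuracy = (n - chunks) / n
    gpi = math.exp(-speed) * math.exp(-accuracy)
    return BlockMetrics(n, chunks, speed, accuracy, gpi)


def score_cohort(
    blocks: list[BlockRecord],
    target: tuple[int, ...] = TARGET_SEQUENCE,
    *,
    overlap: bool = True,
) -> pd.DataFrame:
    """Score every block and return a long metrics table (one row per block).

    Order-preserving and pure; duplicate (participant, session, block) keys
    are rejected.
    """
    seen: set[tuple[str, str, int]] = set()
    rows = []
    for b in blocks:
        key = (b.participant_id, b.session, b.block_index)
        if key in seen:
            raise ValueError(f"duplicate block key {key}")
        seen.add(key)
        m = score_block(b, target, overlap=overlap)
        rows.append(
            (
                b.participant_id,
                b.session,
                b.block_index,
                m.n_keypresses,
                m.n_chunks,
                m.speed,
                m.accuracy,
                m.gpi,
                m.flagged,
            )
        )
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def score_events_frame(
    events: pd.DataFrame,
    *,
    duration: float = 30.0,
    target: tuple[int, ...] = TARGET_SEQUENCE,
    overlap: bool = True,
) -> pd.DataFrame:
    """Score a long keypress-event table (columns participant_id, session,
    block, t_s, key) into the per-block metrics table."""
    required = {"participant_id", "session", "block", "t_s", "key"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing column(s): {sorted(missing)}")
    blocks = []
    for (pid, session, blk), grp in events.groupby(
        ["participant_id", "session", "block"], sort=True
    ):
        blocks.append(
            BlockRecord(
                participant_id=str(pid),
                session=str(session),
                block_index=int(blk),
                duration=duration,
                times=grp["t_s"].to_numpy(dtype=float),
                keys=grp["key"].to_numpy(dtype=np.int64),
            )
        )
    return score_cohort(blocks, target, overlap=overlap)
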