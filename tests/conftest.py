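import numpy as np
import pandas as pd
import pytest

from fingertap import (
    SimulationConfig,
    build_offline_table,
    build_online_table,
    score_cohort,
    simulate_cohort,
    zscore_gpi,
)


@pytest.fixture(scope="session")
def demo_bundle():
    """One default-condition cohort (8 cells x 14 participants), shared."""
    return simulate_cohort(SimulationConfig(), seed=42)


@pytest.fixture(scope="session")
def demo_metrics(demo_bundle):
    return score_cohort(demo_bundle.blocks)


@pytest.fixture(scope="session")
def demo_zmetrics(demo_metrics):
    zm, flags = zscore_gpi(demo_metrics)
    assert flags.empty
    return zm


@pytest.fixture(scope="session")
def demo_tables(demo_bundle, demo_zmetrics):
    online = build_online_table(demo_zmetrics, demo_bundle.participants)
    offline = build_offline_table(demo_zmetrics, demo_bundle.participants)
    return online, offline


def make_offline_like(
    rng: np.random.Generator,
    ns: dict[tuple, int],
    effect: callable,
    between_names: list[str] | None = None,
    noise: float = 1.0,
) -> pd.DataFrame:
    """Latent-level offline design table: one S1/S2 pair per subject, session
    gain given by ``effect(cell)``, subject and block noise standard normal."""
    between_names = between_names or ["f1", "f2", "f3"][: len(next(iter(ns)))]
    rows = []
    for cell, n in ns.items():
        for i in range(n):
            sid = "_".join(map(str, cell)) + f"_{i}"
            base = rng.normal()
            s1 = base + rng.normal(0, noise)
            s2 = base + effect(cell) + rng.normal(0, noise)
            for sess, y in (("S1", s1), ("S2", s2)):
                rows.append((sid, *cell, sess, y))
    return pd.DataFrame(
        rows, columns=["participant_id", *between_names, "session", "z_gpi"]
    )
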