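"""Optional matplotlib figures: per-group block trajectories and session
means. Kept out of the core pipeline (off by default) so it stays headless."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_GROUP = ["age_group", "break_duration", "break_type"]


def _agg(table: pd.DataFrame, x: str) -> pd.DataFrame:
    g = table.groupby(_GROUP + [x])["z_gpi"]
    out = g.mean().rename("mean").to_frame()
    out["sem"] = g.sem()
    return out.reset_index()


def plot_block_trajectories(online_table: pd.DataFrame, path: str | Path) -> None:
    """Mean +/- SEM z-GPI across the 12 learning blocks, one line per cell."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = _agg(online_table, "block")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for (a, d, t), grp in agg.groupby(_GROUP):
        ax.errorbar(grp["block"], grp["mean"], yerr=grp["sem"],
                    label=f"{a}/{d}/{t}", capsize=2)
    ax.set_xlabel("learning block")
    ax.set_ylabel("z-scored GPI")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_session_means(offline_table: pd.DataFrame, path: str | Path) -> None:
    """End-of-learning (S1) vs test (S2) mean z-GPI per cell."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = _agg(offline_table, "session")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for (a, d, t), grp in agg.groupby(_GROUP):
        ax.errorbar(grp["session"], grp["mean"], yerr=grp["sem"],
                    label=f"{a}/{d}/{t}", marker="o")
    ax.set_xlabel("session")
    ax.set_ylabel("z-scored GPI")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
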