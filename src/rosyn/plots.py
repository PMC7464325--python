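"""Figure output: hockey-stick plot, heatmap, profile, FA-CI and isobologram."""

from __future__ import annotations

from pathlib import Path


import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .differential import SignalMatrix, profile_summary
from .enhancers import EnhancerRanking
from .synergy import Isobologram


def plot_hockey_stick(ranking: EnhancerRanking, path: str | Path) -> None:
    """Rank vs. signal with the super-enhancer cutoff marked."""
    signals = [r.signal for r in ranking.regions]
    ranks = [r.rank for r in ranking.regions]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ranks, signals, ".", ms=3, color="steelblue")
    ax.axhline(ranking.cutoff_signal, ls="--", color="firebrick", lw=1)
    ax.axvline(ranking.cutoff_index, ls=":", color="gray", lw=1)
    ax.set_xlabel("enhancer rank (1 = lowest signal)")
    ax.set_ylabel("region signal (area units)")
    ax.set_title(f"{len(signals)} regions, {ranking.n_super} super-enhancers")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heatmap(matrix: SignalMatrix, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(
        matrix.values,
        aspect="auto",
        interpolation="nearest",
        extent=(-matrix.window / 1e3, matrix.window / 1e3, matrix.values.shape[0], 0),
        cmap="viridis",
    )
    ax.set_xlabel("distance from center (kb)")
    ax.set_ylabel("region (by total signal)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="mean density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_profile(
    matrices: dict[str, SignalMatrix], path: str | Path
) -> None:
    """Mean +/- SD profile per condition on a shared axis."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, m in matrices.items():
        mean, sd = profile_summary(m)
        x = (m.bin_offsets + m.bin_size / 2) / 1e3
        ax.plot(x, mean, label=label)
        ax.fill_between(x, mean - sd, mean + sd, alpha=0.2)
    ax.set_xlabel("distance from center (kb)")
    ax.set_ylabel("mean density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fa_ci(ci_table: pd.DataFrame, path: str | Path) -> None:
    """Combination index versus fraction affected; dotted line = additivity."""
    fig, ax = plt.subplots(figsize=(5, 4))
    if len(ci_table):
        ax.plot(ci_table["fa"], ci_table["ci"], "o", color="black")
    ax.axhline(1.0, ls=":", color="gray")
    ax.set_xlabel("fraction affected (FA)")
    ax.set_ylabel("combination index (CI)")
    ax.set_xlim(0, 1)
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_isobologram(iso: Isobologram, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    if iso.normalized:
        ax.plot([1, 0], [0, 1], "-", color="gray", label="additivity")
        ax.set_xlabel("D1 / Dx1")
        ax.set_ylabel("D2 / Dx2")
    else:
        dx1, dx2 = iso.axis_intercepts
        ax.plot([dx1, 0], [0, dx2], "-", color="gray", label="additivity")
        ax.set_xlabel("drug 1 dose")
        ax.set_ylabel("drug 2 dose")
    if iso.combo_points:
        xs, ys = zip(*iso.combo_points)
        ax.plot(xs, ys, "o", color="firebrick", label="combination")
    ax.set_title(f"effect level fa = {iso.effect_level:g}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
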