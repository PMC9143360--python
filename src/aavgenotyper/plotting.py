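"""Static plot exports for scan results (PNG/SVG via matplotlib Agg)."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_pddm(grid, path: str | Path) -> None:
    """Heatmap of the window-pair RMSE grid."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(grid.rmse, cmap="RdYlBu_r", origin="lower")
    ticks = range(grid.n_windows)
    names = [str(w) for w in grid.windows]
    ax.set_xticks(ticks, names, rotation=90, fontsize=7)
    ax.set_yticks(ticks, names, fontsize=7)
    ax.set_title(f"PDDM (window {grid.window}, step {grid.step})")
    fig.colorbar(im, ax=ax, label="PDCP RMSE")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pdcp(result, path: str | Path) -> None:
    """Distance-vs-distance scatter with the fitted regression line."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(result.d_a, result.d_b, s=6, alpha=0.4, edgecolors="none")
    xs = np.linspace(float(np.min(result.d_a)), float(np.max(result.d_a)), 50)
    ax.plot(xs, result.slope * xs + result.intercept, color="crimson", lw=1)
    ax.set_xlabel(f"p-distance {result.region_a}")
    ax.set_ylabel(f"p-distance {result.region_b}")
    ax.set_title(f"PDCP, RMSE = {result.rmse:.4f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_similarity(track, path: str | Path) -> None:
    """Per-window similarity of the query against each panel sequence."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(8, 4))
    for c, pid in enumerate(track.panel_ids):
        ax.plot(track.centers, track.similarity[:, c], lw=1, label=pid)
    ax.set_xlabel("alignment position (window center)")
    ax.set_ylabel("similarity")
    ax.set_title(f"similarity scan: {track.query_id} "
                 f"(window {track.window}, step {track.step})")
    ax.set_ylim(0, 1.02)
    if len(track.panel_ids) <= 12:
        ax.legend(fontsize=6, ncols=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
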