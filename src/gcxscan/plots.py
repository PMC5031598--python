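"""Figure analogues: GC density plots, class-overlap scatters, motif GC profiles."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .codon_gc import gc_density


def density_panel(
    value_sets: dict[str, Sequence[float]], path, cutoff: Optional[float] = None, title: str = ""
) -> None:
    """One KDE panel per named value set (gene GC, CDS GC, or GC_x)."""
    n = len(value_sets)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.2), squeeze=False)
    for ax, (name, values) in zip(axes[0], value_sets.items()):
        vals = [v for v in values if v is not None]
        if len(vals) >= 2:
            grid, dens = gc_density(vals)
            ax.plot(grid, dens, lw=1.5)
            ax.fill_between(grid, dens, alpha=0.2)
        if cutoff is not None:
            ax.axvline(cutoff, color="tab:blue", ls="--", lw=1)
        ax.set_xlabel(name)
        ax.set_ylabel("density")
        ax.set_xlim(0, 1)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def overlap_scatter(scatter: dict, path, cutoff: float = 0.80) -> None:
    """Pairwise GC_x scatter with cutoff guide lines (class-overlap view)."""
    pairs = list(scatter)
    fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3.6), squeeze=False)
    for ax, pair in zip(axes[0], pairs):
        pts = np.asarray(scatter[pair], dtype=float)
        if pts.size:
            ax.scatter(pts[:, 0], pts[:, 1], s=4, alpha=0.4)
        ax.axvline(cutoff, color="tab:blue", lw=1)
        ax.axhline(cutoff, color="tab:blue", lw=1)
        a, b = pair
        ax.set_xlabel(f"GC{a}")
        ax.set_ylabel(f"GC{b}")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def periodicity_plot(groups: dict[int, np.ndarray], path, title: str = "") -> None:
    """Per-position GC values by 3-nt periodicity group."""
    fig, ax = plt.subplots(figsize=(4.5, 3.4))
    for g, vals in groups.items():
        x = np.full(len(vals), g) + np.linspace(-0.12, 0.12, len(vals))
        ax.plot(x, vals, "o", ms=5, label=f"nt{g}")
        ax.hlines(np.mean(vals), g - 0.2, g + 0.2, color="k", lw=1.5)
    ax.set_xticks([1, 2, 3], ["nt1", "nt2", "nt3"])
    ax.set_ylabel("GC fraction")
    ax.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
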