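"""Figure rendering: metagene line plots, heatmaps, fill plots, box plots, PCA scatters.

Figures are presentation artifacts; every numeric claim they carry is computed
by (and tested on) the underlying tables. Rendering uses the Agg backend so
output is reproducible without a display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .coverage import FlankMatrix
from .io_formats import ValidationError
from .stats import MetageneProfile, PcaResult

FIGURE_KINDS = ("metagene", "heatmap", "fillplot", "boxplot", "pca_scatter")


@dataclass
class FigureSpec:
    """What to draw and where to put it."""

    kind: str
    output: str
    title: str = ""
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FIGURE_KINDS:
            raise ValidationError(f"unknown figure kind {self.kind!r}")


def plot_metagene(
    profiles: Sequence[MetageneProfile], output, title: str = "", separate_scales: bool = True
):
    """Sense/antisense metagene line plot; the two orientations get independent y-scales."""
    fig, ax = plt.subplots(figsize=(7, 4))
    axes = [ax]
    if separate_scales and len(profiles) > 1:
        axes.append(ax.twinx())
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for i, prof in enumerate(profiles):
        a = axes[min(i, len(axes) - 1)] if separate_scales else ax
        x = prof.offsets + prof.bin_size / 2
        a.plot(x, prof.mean, color=colors[i % len(colors)], label=prof.label)
        a.fill_between(
            x, prof.mean - prof.sem, prof.mean + prof.sem,
            color=colors[i % len(colors)], alpha=0.25, linewidth=0,
        )
        a.set_ylabel(f"{prof.label} CPM")
    ax.axvline(0, color="grey", linestyle=":", linewidth=0.8)
    ax.set_xlabel("distance from DSB (bp)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(output)
    plt.close(fig)
    return output


def heatmap_row_order(site_ids: Sequence[str], efficiency_rank: pd.Series) -> list[str]:
    """Rows in ascending cleavage-efficiency order (stable for ties)."""
    ranked = [sid for sid in site_ids if sid in efficiency_rank.index]
    missing = [sid for sid in site_ids if sid not in efficiency_rank.index]
    if missing:
        raise ValidationError(f"no efficiency ranking for sites {missing[:5]}")
    return sorted(ranked, key=lambda sid: efficiency_rank[sid])


def plot_heatmap(
    matrix: FlankMatrix,
    efficiency_rank: pd.Series,
    output,
    title: str = "",
    clip_percentiles: tuple[float, float] = (1.0, 99.0),
):
    """Sites x bins heatmap with rows in ascending cleavage-efficiency order.

    Color limits are clipped to per-matrix percentiles (default 1st-99th); the
    clip values are recorded in the figure metadata text.
    """
    order = heatmap_row_order(matrix.site_ids, efficiency_rank)
    sub = matrix.subset(order)
    lo, hi = np.percentile(sub.values, clip_percentiles)
    if hi <= lo:
        hi = lo + 1e-9
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(
        sub.values, aspect="auto", cmap="viridis", vmin=lo, vmax=hi,
        extent=(-matrix.flank, matrix.flank, len(order), 0), interpolation="nearest",
    )
    fig.colorbar(im, ax=ax, label="CPM")
    ax.set_xlabel("distance from DSB (bp)")
    ax.set_ylabel(f"sites (ascending cleavage efficiency; clip {lo:.3g}-{hi:.3g})")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(output)
    plt.close(fig)
    return order


def plot_fillplot(matrix: FlankMatrix, site_id: str, output, title: str = ""):
    """Per-bin coverage of one site drawn as a filled area (an IGV-snapshot stand-in)."""
    row = matrix.row(site_id)
    x = np.arange(-matrix.flank, matrix.flank, matrix.bin_size) + matrix.bin_size / 2
    fig, ax = plt.subplots(figsize=(7, 2.5))
    ax.fill_between(x, 0, row, step="mid", color="#3b6ea5")
    ax.axvline(0, color="grey", linestyle=":", linewidth=0.8)
    ax.set_xlabel("distance from DSB (bp)")
    ax.set_ylabel("CPM")
    ax.set_title(title or site_id)
    fig.tight_layout()
    fig.savefig(output)
    plt.close(fig)
    return output


def plot_boxplot(groups: dict[str, Sequence[float]], output, title: str = "", ylabel: str = "log2 fold change"):
    fig, ax = plt.subplots(figsize=(1.2 + 1.2 * len(groups), 4))
    labels = list(groups)
    ax.boxplot([np.asarray(groups[k], dtype=float) for k in labels], tick_labels=labels)
    ax.axhline(0, color="grey", linestyle=":", linewidth=0.8)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(output)
    plt.close(fig)
    return output


def plot_pca(result: PcaResult, output, title: str = ""):
    fig, ax = plt.subplots(figsize=(5, 4))
    coords = result.coordinates
    ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1] if coords.shape[1] > 1 else 0 * coords.iloc[:, 0])
    for name, row in coords.iterrows():
        ax.annotate(str(name), (row.iloc[0], row.iloc[1] if coords.shape[1] > 1 else 0))
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    if coords.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(output)
    plt.close(fig)
    return output


def render_figures(spec: FigureSpec, data: dict):
    """Dispatch a :class:`FigureSpec` to the matching plot function.

    ``data`` supplies the referenced inputs: ``profiles`` for metagene,
    ``matrix`` + ``efficiency_rank`` for heatmap, ``matrix`` + ``site_id`` for
    fillplot, ``groups`` for boxplot, ``pca`` for pca_scatter.
    """
    if spec.kind == "metagene":
        return plot_metagene(data["profiles"], spec.output, spec.title, **spec.options)
    if spec.kind == "heatmap":
        if "efficiency_rank" not in data:
            raise ValidationError("heatmap requires an efficiency ranking")
        return plot_heatmap(data["matrix"], data["efficiency_rank"], spec.output, spec.title, **spec.options)
    if spec.kind == "fillplot":
        return plot_fillplot(data["matrix"], data["site_id"], spec.output, spec.title)
    if spec.kind == "boxplot":
        return plot_boxplot(data["groups"], spec.output, spec.title, **spec.options)
    if spec.kind == "pca_scatter":
        return plot_pca(data["pca"], spec.output, spec.title)
    raise ValidationError(f"unknown figure kind {spec.kind!r}")
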