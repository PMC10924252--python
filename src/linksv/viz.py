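"""Heatmaps of barcode sharing and decay-model diagnostics.

The heatmap is the method's primary exploratory output: an upper-left-origin
image of the Jaccard matrix with genomic coordinates on both axes.  SVs have
recognisable signatures -- an inversion shows a "bowtie" of excess sharing
between loci flanking its opposite breakpoints, a large deletion a depleted
square over its footprint plus a triangle of excess between the breakpoints.
Split-triangle plots put one population's matrix above the diagonal and a
second below, so group-specific structure stands out.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
from matplotlib import patches

from .detect import CandidateSV, DecayModel, DistanceStats, OutlierCell
from .sharing import SharingMatrix


def _region_slice(matrix: SharingMatrix, region: Optional[Tuple[int, int]]):
    if region is None:
        return 0, matrix.grid.n_windows
    start, end = region
    m = matrix.grid.window_size
    w0, w1 = start // m, -(-end // m)
    w0 = max(0, w0)
    w1 = min(matrix.grid.n_windows, w1)
    if w1 <= w0:
        raise ValueError("region contains no windows")
    return w0, w1


def plot_heatmap(
    matrix: SharingMatrix,
    out: Optional[str] = None,
    region: Optional[Tuple[int, int]] = None,
    vmax_quantile: float = 0.99,
    candidates: Optional[Sequence[CandidateSV]] = None,
    cmap: str = "viridis",
    ax: Optional[plt.Axes] = None,
):
    """Render a barcode-sharing heatmap; returns the matplotlib Axes.

    The colour scale is clipped at the ``vmax_quantile`` of off-diagonal
    values (default 0.99) so the unit diagonal does not wash out off-diagonal
    signal.  ``region`` is a (start, end) bp pair; ``candidates`` are drawn
    as outline rectangles over their breakpoint-window blocks.  For a
    two-population comparison pass a merged split-triangle matrix.
    """
    if not 0.5 < vmax_quantile <= 1.0:
        raise ValueError("vmax_quantile must be in (0.5, 1]")
    w0, w1 = _region_slice(matrix, region)
    sub = matrix.values[w0:w1, w0:w1]
    m = matrix.grid.window_size
    off_diag = sub[~np.eye(sub.shape[0], dtype=bool)]
    vmax = float(np.quantile(off_diag, vmax_quantile)) if off_diag.size else 1.0
    vmax = max(vmax, 1e-6)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    extent = (w0 * m, w1 * m, w1 * m, w0 * m)  # upper-left origin
    im = ax.imshow(sub, cmap=cmap, vmin=0.0, vmax=vmax, extent=extent, interpolation="nearest")
    ax.figure.colorbar(im, ax=ax, label="Jaccard barcode sharing")
    title = matrix.grid.chrom
    if matrix.populations:
        title += f"  (upper: {matrix.populations[0]}, lower: {matrix.populations[1]})"
    ax.set_title(title)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("position (bp)")
    for c in candidates or []:
        a0, a1 = c.breakpoint_a
        b0, b1 = c.breakpoint_b
        rect = patches.Rectangle(
            (b0 * m, a0 * m), (b1 - b0) * m, (a1 - a0) * m,
            fill=False, edgecolor="red", linewidth=1.0,
        )
        ax.add_patch(rect)
    if out:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
    return ax


def plot_fit_diagnostics(
    matrix: SharingMatrix,
    model: DecayModel,
    stats: DistanceStats,
    outliers: Optional[Sequence[OutlierCell]] = None,
    alpha: float = 0.05,
    out: Optional[str] = None,
    max_points: int = 50_000,
    seed: int = 0,
    ax: Optional[plt.Axes] = None,
):
    """Scatter of sharing vs diagonal distance with the fitted decay curve,
    the alpha prediction band and any outlier cells highlighted."""
    n = matrix.grid.n_windows
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for x in range(1, n):
        d = np.diagonal(matrix.values, offset=x)
        xs.append(np.full(d.size, x))
        ys.append(d)
    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)
    if x_all.size > max_points:
        pick = rng.choice(x_all.size, max_points, replace=False)
        x_all, y_all = x_all[pick], y_all[pick]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    ax.scatter(x_all, y_all, s=2, alpha=0.2, color="grey", label="window pairs", rasterized=True)
    grid_x = np.arange(1, n)
    lo, hi = model.prediction_band(grid_x, alpha)
    ax.plot(grid_x, model.predict(grid_x), color="C0", label="fitted decay")
    ax.fill_between(grid_x, lo, hi, color="C0", alpha=0.2,
                    label=f"prediction band (alpha={alpha:g})")
    if outliers:
        ox = np.array([c.j - c.i for c in outliers])
        oy = np.array([matrix.values[c.i, c.j] for c in outliers])
        ax.scatter(ox, oy, s=8, color="red", label="outlier cells")
    ax.set_xlabel("distance to diagonal (windows)")
    ax.set_ylabel("Jaccard barcode sharing")
    ax.legend(loc="upper right", fontsize=8)
    if out:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
    return ax
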