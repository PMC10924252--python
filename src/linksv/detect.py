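"""Background decay model, outlier cells and candidate-SV calls.

Barcode sharing between windows i and j depends, in the absence of
rearrangement, only on their diagonal distance x = |j - i| and decays as a
double exponential

    y(x) = exp(a + b * exp(-c * x)),

where ``a`` sets the asymptotic (log) background level, ``b`` the
near-diagonal amplitude (both tied to coverage) and ``c`` the decay rate per
window, inversely related to molecule length.  The model is fitted to all
upper-triangle cells by nonlinear least squares; cells outside the normal
prediction band y(x) +/- z_{1-alpha/2} * sigma AND extreme within their own
distance class (|Z| above a threshold, default 2) are outlier cells.  The
conjunction suppresses false positives near the diagonal, where sharing is
intrinsically noisy.  Connected outlier cells are clustered into candidate SV
calls with window-resolution breakpoint intervals; candidates are not typed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.stats import norm

from .sharing import SharingMatrix, WindowGrid

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    """Outlier-detection settings; the defaults are the method's canonical ones
    (prediction band at alpha = 0.05, per-distance |Z| threshold 2, excess
    sharing only)."""

    alpha: float = 0.05
    z_threshold: float = 2.0
    min_distance_x: int = 1
    cluster_gap: int = 1
    direction: str = "excess"  # excess | depletion | both

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if self.direction not in ("excess", "depletion", "both"):
            raise ValueError("direction must be excess, depletion or both")


@dataclass
class DistanceStats:
    """Mean, standard deviation and count of matrix entries per diagonal offset."""

    offsets: np.ndarray  # 0 .. n-1
    mean: np.ndarray
    sd: np.ndarray  # population sd; 0 when a single entry (documented convention)
    count: np.ndarray


@dataclass
class DecayModel:
    """Fitted double-exponential background y(x) = exp(a + b * exp(-c * x))."""

    a: float
    b: float
    c: float
    residual_sd: float
    n_points_fit: int
    converged: bool

    def predict(self, x: Union[float, np.ndarray]) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        return np.exp(self.a + self.b * np.exp(-self.c * x))

    def prediction_band(
        self, x: Union[float, np.ndarray], alpha: float = 0.05
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Lower/upper normal prediction band at level alpha around y(x)."""
        half = norm.ppf(1.0 - alpha / 2.0) * self.residual_sd
        y = self.predict(x)
        return y - half, y + half


class OutlierCell(NamedTuple):
    """One flagged matrix cell: upper-triangle indices, per-distance Z, and
    observed minus predicted sharing."""

    i: int
    j: int
    z: float
    excess: float


@dataclass
class CandidateSV:
    """A clustered candidate structural variant, BED-style half-open."""

    chrom: str
    start: int
    end: int
    breakpoint_a: Tuple[int, int]  # window range [first, last+1) along rows
    breakpoint_b: Tuple[int, int]  # window range along columns
    n_cells: int
    peak_z: float
    mean_excess: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("candidate interval must be non-empty")


class FitError(RuntimeError):
    """Decay-model fit failed to converge; carries best-effort parameters."""

    def __init__(self, message: str, model: DecayModel):
        super().__init__(message)
        self.model = model


def compute_distance_stats(matrix: SharingMatrix) -> DistanceStats:
    """Per-offset mean/sd/count of matrix entries (offset x has n - x cells)."""
    v = matrix.values
    n = v.shape[0]
    offsets = np.arange(n)
    mean = np.empty(n)
    sd = np.empty(n)
    count = (n - offsets).astype(np.int64)
    for x in range(n):
        d = np.diagonal(v, offset=x)
        mean[x] = d.mean()
        sd[x] = d.std() if d.size > 1 else 0.0
    return DistanceStats(offsets, mean, sd, count)


def _weighted_curve_fit(
    x: np.ndarray, mean: np.ndarray, count: np.ndarray, c_starts: Sequence[float]
) -> Tuple[np.ndarray, bool]:
    """Count-weighted least squares of exp(a + b e^{-cx}) to per-offset means.

    Minimising sum_x n_x (mean_x - f(x))^2 yields exactly the cell-level
    least-squares estimate, because the within-offset scatter contributes a
    parameter-free constant to the cell-level objective.
    """
    sw = np.sqrt(count.astype(np.float64))
    eps = 1e-9
    tail = max(1, x.size // 10)
    tail_mean = float(mean[-tail:].mean())
    near_mean = float(mean[: max(1, tail)].mean())
    a0 = np.log(max(tail_mean, 0.0) + eps)
    b0 = np.log((max(near_mean, 0.0) + eps) / (max(tail_mean, 0.0) + eps))

    def resid(p: np.ndarray) -> np.ndarray:
        a, b, c = p
        return sw * (mean - np.exp(a + b * np.exp(-c * x)))

    def jac(p: np.ndarray) -> np.ndarray:
        a, b, c = p
        e = np.exp(-c * x)
        y = np.exp(a + b * e)
        g = np.empty((x.size, 3))
        g[:, 0] = -sw * y
        g[:, 1] = -sw * y * e
        g[:, 2] = sw * y * b * x * e
        return g

    best = None
    for c0 in c_starts:
        try:
            res = optimize.least_squares(
                resid,
                x0=np.array([a0, max(b0, 1e-3), c0]),
                jac=jac,
                bounds=([-50.0, -50.0, 1e-9], [10.0, 60.0, 50.0]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=2000,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all decay-model starts failed")
    return best.x, bool(best.status > 0)


def fit_decay_model(
    matrix: SharingMatrix, config: DetectionConfig = DetectionConfig()
) -> DecayModel:
    """Fit the double-exponential background to all upper-triangle cells with
    x >= ``min_distance_x`` (the unit diagonal is always excluded).

    Multi-start initialisation covers decay rates for molecule lengths of
    roughly 25, 50 and 100 kb.  Raises :class:`FitError` carrying best-effort
    parameters when no start converges.
    """
    stats = compute_distance_stats(matrix)
    lo = config.min_distance_x
    x = stats.offsets[lo:].astype(np.float64)
    mean = stats.mean[lo:]
    count = stats.count[lo:]
    if x.size < 3:
        raise ValueError("need at least 3 distinct diagonal distances to fit")
    m = matrix.grid.window_size
    c_starts = [m / 25_000.0, m / 50_000.0, m / 100_000.0]

    params, ok = _weighted_curve_fit(x, mean, count, c_starts)
    a, b, c = (float(p) for p in params)
    pred = np.exp(a + b * np.exp(-c * x))
    n_cells = int(count.sum())
    # cell-level residual variance = weighted curve misfit + within-offset scatter
    sd_cells = stats.sd[lo:]
    ss = float(np.sum(count * (mean - pred) ** 2) + np.sum(count * sd_cells**2))
    residual_sd = float(np.sqrt(ss / max(n_cells - 3, 1)))
    model = DecayModel(a, b, c, residual_sd, n_cells, ok)
    if not ok:
        raise FitError("decay-model fit did not converge", model)
    return model


def detect_outlier_cells(
    matrix: SharingMatrix,
    model: DecayModel,
    stats: DistanceStats,
    config: DetectionConfig = DetectionConfig(),
    apply_z_filter: bool = True,
) -> List[OutlierCell]:
    """Flag upper-triangle cells outside the prediction band (alpha) that are
    also extreme within their own distance class (|Z| > threshold).

    A cell (i, j) at offset x = j - i >= ``min_distance_x`` is an excess
    outlier iff observed > y(x) + q_{1-alpha/2} * sigma and
    (observed - mean_x) / sd_x > z_threshold (strict inequalities; a cell on
    the band boundary is not an outlier).  Depletion mirrors both conditions
    below.  With ``apply_z_filter=False`` only the band condition applies --
    the pre-filter stage used for calibration checks.  Offsets with sd_x = 0
    satisfy the Z condition only in the direction of their deviation.
    """
    v = matrix.values
    n = v.shape[0]
    q = norm.ppf(1.0 - config.alpha / 2.0)
    # floor guards the degenerate noise-free case against float dust
    band_sd = max(model.residual_sd, 1e-12)
    want_excess = config.direction in ("excess", "both")
    want_depl = config.direction in ("depletion", "both")
    cells: List[OutlierCell] = []
    sd_zero_logged = False
    for x in range(config.min_distance_x, n):
        d = np.diagonal(v, offset=x)
        pred = model.predict(float(x))
        upper = pred + q * band_sd
        lower = pred - q * band_sd
        sd_x = stats.sd[x]
        mean_x = stats.mean[x]
        if sd_x > 0:
            z = (d - mean_x) / sd_x
        else:
            if not sd_zero_logged:
                log.info("offset with sd=0 encountered; Z condition falls back to sign of excess")
                sd_zero_logged = True
            z = np.zeros_like(d)
            z[d > pred] = np.inf
            z[d < pred] = -np.inf
        masks = []
        if want_excess:
            cond = d > upper
            if apply_z_filter:
                cond &= z > config.z_threshold
            masks.append(cond)
        if want_depl:
            cond = d < lower
            if apply_z_filter:
                cond &= z < -config.z_threshold
            masks.append(cond)
        mask = np.logical_or.reduce(masks)
        for i in np.nonzero(mask)[0]:
            zi = float(z[i]) if np.isfinite(z[i]) else float(np.sign(d[i] - pred) * np.inf)
            cells.append(OutlierCell(int(i), int(i + x), zi, float(d[i] - pred)))
    return cells


def cluster_candidates(
    cells: Iterable[OutlierCell],
    grid: WindowGrid,
    config: DetectionConfig = DetectionConfig(),
) -> List[CandidateSV]:
    """Merge outlier cells within ``cluster_gap`` in both matrix axes
    (8-connectivity at gap 1) into candidate SV calls.

    Each cluster reports its row-window range (breakpoint A), column-window
    range (breakpoint B) and the covering genomic interval
    [min window start, max window end); calls are sorted by coordinate.
    """
    cells = list(cells)
    if not cells:
        return []
    n = grid.n_windows
    mask = np.zeros((n, n), dtype=bool)
    ii = np.array([c.i for c in cells])
    jj = np.array([c.j for c in cells])
    mask[ii, jj] = True
    if config.cluster_gap > 1:
        size = 2 * config.cluster_gap - 1
        grown = ndimage.binary_dilation(mask, structure=np.ones((size, size), dtype=bool))
    else:
        grown = mask
    labels, _ = ndimage.label(grown, structure=np.ones((3, 3), dtype=int))
    cell_labels = labels[ii, jj]

    calls: List[CandidateSV] = []
    for lab in np.unique(cell_labels):
        sel = cell_labels == lab
        rows, cols = ii[sel], jj[sel]
        zs = np.array([c.z for c in cells])[sel]
        exc = np.array([c.excess for c in cells])[sel]
        lo_win = int(min(rows.min(), cols.min()))
        hi_win = int(max(rows.max(), cols.max()))
        start = grid.window_bounds(lo_win)[0]
        end = grid.window_bounds(hi_win)[1]
        peak = zs[np.argmax(np.abs(zs))] if np.any(np.isfinite(zs)) else zs[0]
        calls.append(
            CandidateSV(
                chrom=grid.chrom,
                start=start,
                end=end,
                breakpoint_a=(int(rows.min()), int(rows.max()) + 1),
                breakpoint_b=(int(cols.min()), int(cols.max()) + 1),
                n_cells=int(sel.sum()),
                peak_z=float(peak),
                mean_excess=float(exc.mean()),
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    return calls


def call_candidate_svs(
    matrix: SharingMatrix, config: DetectionConfig = DetectionConfig()
) -> Tuple[List[CandidateSV], DecayModel, DistanceStats, List[OutlierCell]]:
    """Convenience pipeline: fit the background, flag outlier cells, cluster."""
    model = fit_decay_model(matrix, config)
    stats = compute_distance_stats(matrix)
    cells = detect_outlier_cells(matrix, model, stats, config)
    return cluster_candidates(cells, matrix.grid, config), model, stats, cells


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def intersect_reciprocal(
    calls_a: Sequence[CandidateSV],
    calls_b: Sequence[CandidateSV],
    min_fraction: float = 0.8,
) -> dict:
    """Partition ``calls_a`` into shared/specific by reciprocal overlap with
    ``calls_b``.

    A call in A is shared iff some call in B on the same chromosome overlaps
    at least ``min_fraction`` of A's length AND of B's length (bedtools
    ``-f 0.8 -F 0.8 -u`` semantics: each A call reported once).
    """
    shared: List[CandidateSV] = []
    specific: List[CandidateSV] = []
    for a in calls_a:
        la = a.end - a.start
        hit = any(
            b.chrom == a.chrom
            and (ov := _overlap(a.start, a.end, b.start, b.end)) >= min_fraction * la
            and ov >= min_fraction * (b.end - b.start)
            for b in calls_b
        )
        (shared if hit else specific).append(a)
    return {"shared": shared, "specific": specific}


def write_calls_bed(
    calls: Sequence[CandidateSV],
    path: Union[str, Path],
    model: Optional[DecayModel] = None,
) -> None:
    """Write BED6 calls plus a TSV sidecar with breakpoint windows and scores.

    BED score is peak |Z| x 10 capped at 1000; the sidecar (``<path>.tsv``)
    carries breakpoint window ranges, cell counts, mean excess and the fitted
    model parameters.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for k, c in enumerate(calls):
            score = int(min(abs(c.peak_z) * 10 if np.isfinite(c.peak_z) else 1000, 1000))
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tSV{k + 1}\t{score}\t.\n")
    rows = [
        {
            "name": f"SV{k + 1}",
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "bkpt_a_first": c.breakpoint_a[0],
            "bkpt_a_last": c.breakpoint_a[1],
            "bkpt_b_first": c.breakpoint_b[0],
            "bkpt_b_last": c.breakpoint_b[1],
            "n_cells": c.n_cells,
            "peak_z": c.peak_z,
            "mean_excess": c.mean_excess,
        }
        for k, c in enumerate(calls)
    ]
    pd.DataFrame(rows).to_csv(path.with_suffix(path.suffix + ".tsv"), sep="\t", index=False)
    if model is not None:
        report = {
            "a": model.a,
            "b": model.b,
            "c": model.c,
            "residual_sd": model.residual_sd,
            "n_points_fit": model.n_points_fit,
            "converged": model.converged,
        }
        path.with_suffix(".fit.json").write_text(json.dumps(report, indent=2))


def read_calls_bed(path: Union[str, Path]) -> List[CandidateSV]:
    """Read a BED3+ file into minimal :class:`CandidateSV` records."""
    calls: List[CandidateSV] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        calls.append(
            CandidateSV(
                chrom=chrom,
                start=start,
                end=end,
                breakpoint_a=(0, 0),
                breakpoint_b=(0, 0),
                n_cells=0,
                peak_z=float(parts[4]) / 10 if len(parts) > 4 and parts[4] != "." else 0.0,
                mean_excess=0.0,
            )
        )
    return calls
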