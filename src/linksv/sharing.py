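"""Window partitioning and Jaccard barcode-sharing matrices.

A chromosome is cut into ``n = ceil(length / m)`` fixed-size windows
(default m = 10 kb; the final truncated window is kept).  Every filtered
alignment contributes its molecule barcode to the window containing its
leftmost coordinate, and the similarity between two windows A and B is the
Jaccard index J(A, B) = |A n B| / |A u B| of their barcode sets.  Because
molecules (40-60 kb here) span several windows, J is large near the diagonal
and decays with distance; rearrangements show up as off-diagonal departures
from that background.
"""

from __future__ import annotations

import json
import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
from scipy import sparse

from .haplotag import TaggedAlignment

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowGrid:
    """Fixed-size window partition of one chromosome.

    Window ``i`` spans ``[i*m, min((i+1)*m, chrom_length))``, 0-based
    half-open; the last window may be truncated.
    """

    chrom: str
    chrom_length: int
    window_size: int = 10_000

    def __post_init__(self) -> None:
        if self.chrom_length <= 0 or self.window_size <= 0:
            raise ValueError("chromosome length and window size must be positive")

    @property
    def n_windows(self) -> int:
        return math.ceil(self.chrom_length / self.window_size)

    def window_of(self, pos: int) -> int:
        if not 0 <= pos < self.chrom_length:
            raise ValueError(f"position {pos} outside chromosome of length {self.chrom_length}")
        return pos // self.window_size

    def window_bounds(self, i: int) -> Tuple[int, int]:
        if not 0 <= i < self.n_windows:
            raise IndexError(f"window {i} out of range")
        start = i * self.window_size
        return start, min(start + self.window_size, self.chrom_length)


@dataclass
class WindowBarcodeSets:
    """Per-window sets of distinct molecule barcodes for one chromosome."""

    grid: WindowGrid
    sets: List[Set[Hashable]]

    def __post_init__(self) -> None:
        if len(self.sets) != self.grid.n_windows:
            raise ValueError("one barcode set per window is required")


@dataclass
class SharingMatrix:
    """Symmetric n x n matrix of pairwise Jaccard indices between windows.

    ``populations`` labels the (upper, lower) triangles of a two-group merged
    matrix; it is None for a single-population matrix.
    """

    grid: WindowGrid
    values: np.ndarray
    populations: Optional[Tuple[str, str]] = None

    def __post_init__(self) -> None:
        n = self.grid.n_windows
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} windows")


def collect_window_barcodes(
    alignments: Union[Iterable[TaggedAlignment], "object"],
    grid: WindowGrid,
) -> WindowBarcodeSets:
    """Assign each alignment's barcode to the window containing its start.

    Accepts any iterable of :class:`TaggedAlignment`, or an array-backed read
    set exposing ``starts`` and ``barcode_ids`` (the simulator's container),
    which takes a vectorised path.  Alignments beyond the chromosome end are
    rejected with a warning; duplicates within a window collapse.
    """
    sets: List[Set[Hashable]] = [set() for _ in range(grid.n_windows)]
    m = grid.window_size
    if hasattr(alignments, "starts") and hasattr(alignments, "barcode_ids"):
        starts = np.asarray(alignments.starts)
        bcs = np.asarray(alignments.barcode_ids)
        ok = (starts >= 0) & (starts < grid.chrom_length)
        if not ok.all():
            log.warning("%d reads beyond chromosome end rejected", int((~ok).sum()))
        pairs = np.unique(np.stack([starts[ok] // m, bcs[ok]], axis=1), axis=0)
        for w, b in pairs:
            sets[int(w)].add(int(b))
        return WindowBarcodeSets(grid, sets)

    n_rejected = 0
    for aln in alignments:
        if aln.start >= grid.chrom_length:
            n_rejected += 1
            continue
        if aln.bx is not None:
            sets[aln.start // m].add(aln.bx)
    if n_rejected:
        log.warning("%d alignments beyond chromosome end rejected", n_rejected)
    return WindowBarcodeSets(grid, sets)


def jaccard(a: Set[Hashable], b: Set[Hashable]) -> float:
    """Jaccard index |A n B| / |A u B|; 0.0 when both sets are empty."""
    if not a and not b:
        return 0.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def _incidence(sets: Sequence[Set[Hashable]]) -> sparse.csr_matrix:
    """Binary window x barcode incidence matrix with a stable barcode order."""
    barcode_index: dict[Hashable, int] = {}
    rows: List[int] = []
    cols: List[int] = []
    for w, s in enumerate(sets):
        for b in s:
            j = barcode_index.setdefault(b, len(barcode_index))
            rows.append(w)
            cols.append(j)
    n, k = len(sets), max(len(barcode_index), 1)
    return sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)), shape=(n, k)
    )


def build_matrix(
    sets: WindowBarcodeSets,
    threads: int = 1,
    max_memory_gb: float = 6.0,
) -> SharingMatrix:
    """Compute the full pairwise Jaccard matrix for one chromosome.

    The computation runs block-wise over rows (optionally across ``threads``
    workers against the shared read-only incidence matrix) with a
    deterministic reduction, so the result is bit-identical for any thread
    count.  Refuses to allocate more than ``max_memory_gb`` for the dense
    result; enlarge the window size m for very long chromosomes.
    """
    if threads < 1:
        raise ValueError("threads must be >= 1")
    n = sets.grid.n_windows
    needed = 3 * n * n * 8 / 1e9
    if needed > max_memory_gb:
        raise MemoryError(
            f"{n} windows need ~{needed:.1f} GB (> {max_memory_gb} GB cap); "
            "increase the window size m or raise max_memory_gb"
        )
    w = _incidence(sets.sets)
    counts = np.asarray([len(s) for s in sets.sets], dtype=np.int64)
    values = np.zeros((n, n), dtype=np.float64)

    block = max(64, math.ceil(n / max(threads * 4, 1)))
    starts = range(0, n, block)

    def _fill(row0: int) -> None:
        row1 = min(row0 + block, n)
        inter = np.asarray((w[row0:row1] @ w.T).todense(), dtype=np.float64)
        union = counts[row0:row1, None] + counts[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            j = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        values[row0:row1] = j

    if threads == 1:
        for r in starts:
            _fill(r)
    else:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            list(pool.map(_fill, starts))
    return SharingMatrix(sets.grid, values)


def merge_group_matrices(
    matrix_a: SharingMatrix,
    matrix_b: SharingMatrix,
    labels: Tuple[str, str] = ("A", "B"),
) -> SharingMatrix:
    """Merge two per-population matrices into one split-triangle matrix.

    The upper triangle (and diagonal) holds ``matrix_a``, the lower triangle
    ``matrix_b`` -- the convention used for side-by-side comparison of two
    groups in a single heatmap.
    """
    if matrix_a.grid != matrix_b.grid:
        raise ValueError("matrices to merge must share the same window grid")
    merged = np.triu(matrix_a.values)
    merged += np.tril(matrix_b.values, k=-1)
    return SharingMatrix(matrix_a.grid, merged, populations=labels)


def split_group_matrix(merged: SharingMatrix) -> Tuple[SharingMatrix, SharingMatrix]:
    """Recover the two symmetric per-population matrices from a merged one."""
    up = np.triu(merged.values)
    lo = np.tril(merged.values, k=-1)
    a = up + np.triu(merged.values, k=1).T
    b = lo + lo.T
    np.fill_diagonal(b, np.diag(merged.values))
    return (
        SharingMatrix(merged.grid, a),
        SharingMatrix(merged.grid, b),
    )


def save_matrix(matrix: SharingMatrix, path: Union[str, Path]) -> None:
    """Persist a matrix plus grid metadata as a .npz container."""
    meta = {
        "chrom": matrix.grid.chrom,
        "chrom_length": matrix.grid.chrom_length,
        "window_size": matrix.grid.window_size,
        "populations": list(matrix.populations) if matrix.populations else None,
    }
    np.savez_compressed(str(path), values=matrix.values, meta=json.dumps(meta))


def load_matrix(path: Union[str, Path]) -> SharingMatrix:
    with np.load(str(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        values = np.asarray(data["values"], dtype=np.float64)
    grid = WindowGrid(meta["chrom"], meta["chrom_length"], meta["window_size"])
    pops = tuple(meta["populations"]) if meta["populations"] else None
    return SharingMatrix(grid, values, populations=pops)
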