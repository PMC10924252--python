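"""End-to-end simulation benchmark: genome -> SVs -> reads -> matrix -> calls.

This is the validation harness the package runs against itself: generate a
random chromosome, splice known SVs into it, simulate barcoded molecules over
the rearranged genome, build the barcode-sharing matrix on the *reference*
frame, call candidate SVs and score them against truth.  Detection here runs
direction="both": simulated insertions carry sequence absent from the
reference, so their only footprint in the matrix is a depletion of sharing
across the insertion point, while deletions and inversions additionally
produce excess sharing between their breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .benchmark import EvaluationConfig, EvaluationRecord, match_and_score, overall_sensitivity
from .detect import (
    CandidateSV,
    DecayModel,
    DetectionConfig,
    DistanceStats,
    OutlierCell,
    call_candidate_svs,
)
from .sharing import SharingMatrix, WindowGrid, build_matrix, collect_window_barcodes
from .simulate import (
    MoleculeModel,
    SimulatedSV,
    SimulationConfig,
    TaggedReadSet,
    induce_svs,
    random_genome,
    simulate_tagged_reads,
)


@dataclass
class StudyResult:
    """Everything one simulation study produced, for inspection and plots."""

    truth: List[SimulatedSV]
    calls: List[CandidateSV]
    records: List[EvaluationRecord]
    sensitivity: pd.DataFrame
    matrix: SharingMatrix
    model: DecayModel
    stats: DistanceStats
    outlier_cells: List[OutlierCell]
    reads: TaggedReadSet

    def overall_sensitivity(self, threshold: int = 20) -> float:
        return overall_sensitivity(self.records, threshold)


def run_simulation_study(
    genome_length: int = 20_000_000,
    sv_sizes: Sequence[int] = (50_000, 100_000),
    sv_types: Sequence[str] = ("insertion", "deletion", "inversion"),
    window_size: int = 10_000,
    seed: int = 0,
    spacing_mean: float = 333_333.0,
    molecule_model: Optional[MoleculeModel] = None,
    detection: Optional[DetectionConfig] = None,
    evaluation: Optional[EvaluationConfig] = None,
    threads: int = 1,
) -> StudyResult:
    """Run the full simulate -> matrix -> detect -> benchmark pipeline.

    Sub-seeds for genome, SV placement and molecule simulation are derived
    deterministically from ``seed``.  The defaults reproduce the large-SV
    benchmark conditions: a 20-Mb chromosome, 50/100-kb events of all three
    types at Exp(1/3 Mb) spacing, 40-60 kb molecules, 10-kb windows,
    alpha = 0.05 and Z threshold 2.
    """
    model_cfg = molecule_model or MoleculeModel()
    det = detection or DetectionConfig(direction="both")
    ev = evaluation or EvaluationConfig(window_size=window_size)
    if ev.window_size != window_size:
        ev = replace(ev, window_size=window_size)

    genome = random_genome(genome_length, seed=seed * 3 + 1)
    sim_cfg = SimulationConfig(
        sv_sizes=tuple(sv_sizes), sv_types=tuple(sv_types),
        spacing_mean=spacing_mean, seed=seed * 3 + 2,
    )
    _, truth, maps = induce_svs(genome, sim_cfg)
    chrom = next(iter(genome))
    reads = simulate_tagged_reads(maps[chrom], model=model_cfg, seed=seed * 3 + 3, chrom=chrom)

    grid = WindowGrid(chrom, genome_length, window_size)
    sets = collect_window_barcodes(reads, grid)
    matrix = build_matrix(sets, threads=threads)
    calls, model, stats, cells = call_candidate_svs(matrix, det)
    records, table = match_and_score(truth, calls, ev)
    return StudyResult(truth, calls, records, table, matrix, model, stats, cells, reads)
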