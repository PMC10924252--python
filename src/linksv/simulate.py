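"""SV-induction genome simulator and synthetic linked-read generator.

The validation protocol needs datasets with known truth: a reference genome
into which non-overlapping insertions, deletions and inversions of chosen
sizes are spliced (gaps between consecutive events drawn from an exponential
distribution, mean 1/3 Mb), and barcoded molecules simulated over the
rearranged ("derived") genome.  Instead of running an aligner, every read's
derived-genome interval is lifted through an exact coordinate map back to
reference coordinates: reads falling inside novel (inserted) sequence are
unmappable and dropped, reads inside inversions come back reverse-oriented at
the mirrored position, and reads downstream of indels are shifted.  The
emitted records carry the molecule's BX tag and MAPQ 60, so they pass the
package's alignment filters and drive the full matrix -> detect -> benchmark
pipeline with no external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .haplotag import TaggedAlignment

log = logging.getLogger(__name__)

SV_TYPES = ("insertion", "deletion", "inversion")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_genome(
    length: int,
    seed: int = 0,
    chrom: str = "chr1",
    n_chromosomes: int = 1,
) -> Dict[str, str]:
    """Generate i.i.d. uniform A/C/G/T chromosome sequences."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome: Dict[str, str] = {}
    for k in range(n_chromosomes):
        name = chrom if n_chromosomes == 1 else f"{chrom.rstrip('0123456789')}{k + 1}"
        seq = bases[rng.integers(0, 4, size=length)]
        genome[name] = seq.tobytes().decode("ascii")
    return genome


@dataclass(frozen=True)
class SimulationConfig:
    """SV-induction settings.

    ``sv_sizes`` spans 1-100 kb by default; consecutive events are separated
    by Exp(``spacing_mean``) gaps (mean 1/3 Mb), which guarantees
    non-overlap.  Type and size are drawn uniformly and independently per
    event unless ``type_weights`` is given.
    """

    sv_sizes: Tuple[int, ...] = (1_000, 5_000, 10_000, 50_000, 100_000)
    sv_types: Tuple[str, ...] = SV_TYPES
    spacing_mean: float = 333_333.0
    seed: int = 0
    type_weights: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.spacing_mean <= 0:
            raise ValueError("spacing_mean must be positive")
        if any(s <= 0 for s in self.sv_sizes):
            raise ValueError("sv_sizes must be positive")
        if any(t not in SV_TYPES for t in self.sv_types):
            raise ValueError(f"sv_types must be a subset of {SV_TYPES}")


@dataclass(frozen=True)
class SimulatedSV:
    """One truth event on the reference.

    Deletions and inversions occupy ``[ref_start, ref_end)``; insertions are
    breakpoints with ``ref_start == ref_end`` and carry the novel sequence.
    """

    chrom: str
    ref_start: int
    ref_end: int
    type: str
    size: int
    inserted_sequence: str = ""

    def __post_init__(self) -> None:
        if self.type == "insertion":
            if self.ref_start != self.ref_end or len(self.inserted_sequence) != self.size:
                raise ValueError("insertion must have a zero-length footprint and its sequence")
        elif self.ref_end - self.ref_start != self.size:
            raise ValueError("deletion/inversion footprint must equal its size")


@dataclass(frozen=True)
class MapSegment:
    """One piece of the derived genome: maps to the reference with orientation
    '+'/'-', or is novel (insertion-origin, ``ref_start`` None)."""

    derived_start: int
    length: int
    ref_start: Optional[int]
    strand: Optional[str]  # '+', '-' or None for novel


class CoordinateMap:
    """Exact segment map between a derived (rearranged) genome and its reference.

    Segments partition the derived genome; lifting composed with projection is
    the identity on all mappable positions.
    """

    def __init__(self, segments: Sequence[MapSegment], ref_length: int):
        self.segments = list(segments)
        self.ref_length = ref_length
        if not self.segments:
            raise ValueError("a coordinate map needs at least one segment")
        pos = 0
        for seg in self.segments:
            if seg.derived_start != pos:
                raise ValueError("segments must partition the derived genome")
            pos += seg.length
        self.derived_length = pos
        self._d_starts = np.array([s.derived_start for s in self.segments], dtype=np.int64)
        self._lengths = np.array([s.length for s in self.segments], dtype=np.int64)
        self._ref_starts = np.array(
            [-1 if s.ref_start is None else s.ref_start for s in self.segments], dtype=np.int64
        )
        self._strand = np.array(
            [0 if s.strand is None else (1 if s.strand == "+" else -1) for s in self.segments],
            dtype=np.int64,
        )

    @classmethod
    def identity(cls, length: int, _chrom: str = "chr1") -> "CoordinateMap":
        return cls([MapSegment(0, length, 0, "+")], ref_length=length)

    @classmethod
    def from_truth(cls, truth: Sequence[SimulatedSV], ref_length: int) -> "CoordinateMap":
        """Build the derived->reference map implied by a sorted truth list."""
        segs: List[MapSegment] = []
        dpos = rpos = 0
        for sv in truth:
            pre = sv.ref_start - rpos
            if pre < 0:
                raise ValueError("truth events must be sorted and non-overlapping")
            if pre > 0:
                segs.append(MapSegment(dpos, pre, rpos, "+"))
                dpos += pre
                rpos += pre
            if sv.type == "deletion":
                rpos += sv.size
            elif sv.type == "insertion":
                segs.append(MapSegment(dpos, sv.size, None, None))
                dpos += sv.size
            elif sv.type == "inversion":
                segs.append(MapSegment(dpos, sv.size, sv.ref_start, "-"))
                dpos += sv.size
                rpos += sv.size
        if rpos < ref_length:
            segs.append(MapSegment(dpos, ref_length - rpos, rpos, "+"))
        return cls(segs, ref_length=ref_length)

    def _segment_of(self, derived_pos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self._d_starts, derived_pos, side="right") - 1

    def lift_point(self, derived_pos: int) -> Optional[int]:
        """Reference coordinate of one derived-genome position (None if novel)."""
        seg = int(self._segment_of(np.asarray([derived_pos]))[0])
        if not 0 <= derived_pos < self.derived_length:
            raise ValueError("derived position out of range")
        s = self.segments[seg]
        if s.strand is None:
            return None
        o = derived_pos - s.derived_start
        if s.strand == "+":
            return s.ref_start + o
        return s.ref_start + s.length - 1 - o

    def project_point(self, ref_pos: int) -> Optional[int]:
        """Derived coordinate of one reference position (None if deleted)."""
        if not 0 <= ref_pos < self.ref_length:
            raise ValueError("reference position out of range")
        for s in self.segments:
            if s.ref_start is None:
                continue
            if s.ref_start <= ref_pos < s.ref_start + s.length:
                o = ref_pos - s.ref_start
                if s.strand == "+":
                    return s.derived_start + o
                return s.derived_start + s.length - 1 - o
        return None

    def lift_reads(
        self, starts: np.ndarray, read_length: int
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised liftover of read intervals ``[start, start+read_length)``.

        Each read is assigned to the segment containing its midpoint (reads
        straddling a boundary take that segment's frame -- a documented
        approximation), reads inside novel segments are dropped, and the
        returned arrays are (kept_mask, reference_starts, reverse_flags).
        """
        starts = np.asarray(starts, dtype=np.int64)
        mid = starts + read_length // 2
        seg = self._segment_of(np.clip(mid, 0, self.derived_length - 1))
        strand = self._strand[seg]
        keep = strand != 0
        o = starts - self._d_starts[seg]
        ref = np.where(
            strand > 0,
            self._ref_starts[seg] + o,
            self._ref_starts[seg] + self._lengths[seg] - o - read_length,
        )
        ref = np.clip(ref, 0, max(self.ref_length - read_length, 0))
        return keep, ref, strand < 0

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write(f"#ref_length={self.ref_length}\n")
            fh.write("derived_start\tlength\tref_start\tstrand\n")
            for s in self.segments:
                fh.write(
                    f"{s.derived_start}\t{s.length}\t"
                    f"{'.' if s.ref_start is None else s.ref_start}\t"
                    f"{'.' if s.strand is None else s.strand}\n"
                )

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "CoordinateMap":
        lines = Path(path).read_text().splitlines()
        ref_length = int(lines[0].split("=")[1])
        segs = []
        for line in lines[2:]:
            d, ln, r, st = line.split("\t")
            segs.append(
                MapSegment(
                    int(d), int(ln), None if r == "." else int(r), None if st == "." else st
                )
            )
        return cls(segs, ref_length=ref_length)


def induce_svs(
    genome: Mapping[str, str], config: SimulationConfig
) -> Tuple[Dict[str, str], List[SimulatedSV], Dict[str, CoordinateMap]]:
    """Splice non-overlapping SVs into a genome, left to right.

    Each event starts one Exp(``spacing_mean``) gap after the previous event's
    end; type and size are drawn uniformly from the configured sets (or with
    ``type_weights``).  Returns the derived genome, the sorted truth list, and
    a per-chromosome :class:`CoordinateMap`.  A chromosome exhausted
    mid-placement simply stops accumulating events (no partial events).
    """
    rng = np.random.default_rng(config.seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    truth: List[SimulatedSV] = []
    derived: Dict[str, str] = {}
    maps: Dict[str, CoordinateMap] = {}
    weights = None
    if config.type_weights is not None:
        w = np.asarray(config.type_weights, dtype=float)
        weights = w / w.sum()

    for chrom in genome:
        ref = genome[chrom]
        length = len(ref)
        events: List[SimulatedSV] = []
        prev_end = 0
        while True:
            gap = rng.exponential(config.spacing_mean)
            start = prev_end + max(1, int(round(gap)))
            sv_type = str(rng.choice(config.sv_types, p=weights))
            size = int(rng.choice(config.sv_sizes))
            footprint = 0 if sv_type == "insertion" else size
            if start + footprint >= length:
                break  # chromosome exhausted; drop the partial event
            if sv_type == "insertion":
                ins = bases[rng.integers(0, 4, size=size)].tobytes().decode("ascii")
                events.append(SimulatedSV(chrom, start, start, sv_type, size, ins))
            else:
                events.append(SimulatedSV(chrom, start, start + size, sv_type, size))
            prev_end = start + footprint
        truth.extend(events)
        cmap = CoordinateMap.from_truth(events, length)
        maps[chrom] = cmap
        # assemble the derived sequence segment by segment
        parts: List[str] = []
        novel_iter = iter([sv.inserted_sequence for sv in events if sv.type == "insertion"])
        for seg in cmap.segments:
            if seg.strand == "+":
                parts.append(ref[seg.ref_start : seg.ref_start + seg.length])
            elif seg.strand == "-":
                parts.append(revcomp(ref[seg.ref_start : seg.ref_start + seg.length]))
            else:
                parts.append(next(novel_iter))
        derived[chrom] = "".join(parts)
    return derived, truth, maps


def apply_svs(genome: Mapping[str, str], truth: Sequence[SimulatedSV]) -> Dict[str, str]:
    """Independently re-apply a truth list to a reference by in-place splicing.

    Events are applied right-to-left so reference coordinates stay valid;
    used to cross-check that the simulator's segment assembly and its truth
    records agree byte-for-byte.
    """
    out: Dict[str, str] = {}
    for chrom, seq in genome.items():
        events = sorted(
            (sv for sv in truth if sv.chrom == chrom), key=lambda s: s.ref_start, reverse=True
        )
        for sv in events:
            if sv.type == "deletion":
                seq = seq[: sv.ref_start] + seq[sv.ref_end :]
            elif sv.type == "insertion":
                seq = seq[: sv.ref_start] + sv.inserted_sequence + seq[sv.ref_start :]
            elif sv.type == "inversion":
                seq = seq[: sv.ref_start] + revcomp(seq[sv.ref_start : sv.ref_end]) + seq[sv.ref_end :]
        out[chrom] = seq
    return out


@dataclass(frozen=True)
class MoleculeModel:
    """Linked-molecule and read-sampling parameters.

    Molecule lengths are uniform on ``molecule_length_range`` (40-60 kb, the
    typical haplotagging range); ``molecule_coverage`` is the mean number of
    molecules overlapping a position and ``target_read_coverage`` the mean
    short-read depth.  Each molecule draws one barcode uniformly from
    ``barcode_space`` (96^3 combinatorial beads by default), so occasional
    barcode collisions between molecules occur at a realistic rate.
    """

    molecule_length_range: Tuple[int, int] = (40_000, 60_000)
    molecules_per_barcode: int = 1
    read_length: int = 150
    target_read_coverage: float = 10.0
    molecule_coverage: float = 25.0
    barcode_space: int = 884_736

    def __post_init__(self) -> None:
        lo, hi = self.molecule_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("molecule_length_range must be positive and ordered")
        if self.target_read_coverage <= 0 or self.molecule_coverage <= 0:
            raise ValueError("coverages must be positive")


def barcode_string(code: int, width: int = 2) -> str:
    """Render a barcode integer as a four-segment BX string (base-96 digits)."""
    digits = []
    c = code
    for _ in range(4):
        digits.append(c % 96 + 1)
        c //= 96
    a, b, c_, d = digits[::-1]
    return f"A{a:0{width}d}C{c_:0{width}d}B{b:0{width}d}D{d:0{width}d}"


class TaggedReadSet:
    """Array-backed container of simulated BX-tagged single-end alignments.

    Iterating yields :class:`~linksv.haplotag.TaggedAlignment` records in
    coordinate order; ``to_sam`` writes an equivalent coordinate-sorted SAM
    with ``BX:Z`` tags (MAPQ 60, no mismatches).
    """

    def __init__(
        self,
        chrom: str,
        chrom_length: int,
        starts: np.ndarray,
        barcode_ids: np.ndarray,
        reverse: Optional[np.ndarray] = None,
        read_length: int = 150,
        mapq: int = 60,
    ):
        order = np.argsort(starts, kind="stable")
        self.chrom = chrom
        self.chrom_length = int(chrom_length)
        self.starts = np.asarray(starts, dtype=np.int64)[order]
        self.barcode_ids = np.asarray(barcode_ids, dtype=np.int64)[order]
        self.reverse = (
            np.zeros(len(self.starts), dtype=bool)
            if reverse is None
            else np.asarray(reverse, dtype=bool)[order]
        )
        self.read_length = read_length
        self.mapq = mapq

    def __len__(self) -> int:
        return len(self.starts)

    def barcode(self, idx: int) -> str:
        return barcode_string(int(self.barcode_ids[idx]))

    def __iter__(self) -> Iterator[TaggedAlignment]:
        for k in range(len(self)):
            yield TaggedAlignment(
                chrom=self.chrom,
                start=int(self.starts[k]),
                mapq=self.mapq,
                is_duplicate=False,
                bx=self.barcode(k),
            )

    def read_coverage(self) -> float:
        return len(self) * self.read_length / self.chrom_length

    def to_sam(
        self, path: Union[str, Path], reference: Optional[str] = None
    ) -> None:
        """Write a coordinate-sorted SAM; read sequences are taken from the
        ``reference`` string when given, else omitted."""
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": self.chrom, "LN": self.chrom_length}],
        }
        rl = self.read_length
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for k in range(len(self)):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = f"mol{int(self.barcode_ids[k])}_{k}"
                rec.flag = 16 if self.reverse[k] else 0
                rec.reference_id = 0
                rec.reference_start = int(self.starts[k])
                rec.mapping_quality = self.mapq
                rec.cigartuples = [(0, rl)]
                if reference is not None:
                    seq = reference[self.starts[k] : self.starts[k] + rl]
                    if self.reverse[k]:
                        seq = revcomp(seq)
                    rec.query_sequence = seq
                    rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                rec.set_tag("BX", self.barcode(k), "Z")
                out.write(rec)


def simulate_tagged_reads(
    cmap: CoordinateMap,
    model: MoleculeModel = MoleculeModel(),
    seed: int = 0,
    chrom: str = "chr1",
) -> TaggedReadSet:
    """Simulate barcoded molecules on the derived genome and lift their reads.

    Molecules are placed uniformly at ``molecule_coverage``; each draws a
    barcode (unique per molecule up to the finite barcode space) and a
    Poisson number of uniformly placed reads matching
    ``target_read_coverage``.  Reads lifted into novel (inserted) sequence
    are dropped as unmappable; the rest are emitted at their reference
    coordinate and orientation, coordinate-sorted.
    """
    rng = np.random.default_rng(seed)
    g = cmap.derived_length
    lo, hi = model.molecule_length_range
    mean_len = (lo + hi) / 2.0
    n_mol = max(1, int(round(model.molecule_coverage * g / mean_len)))
    lengths = rng.integers(lo, hi + 1, size=n_mol)
    mol_starts = rng.integers(0, np.maximum(g - lengths, 1))

    if model.molecules_per_barcode > 1:
        n_codes = max(1, n_mol // model.molecules_per_barcode)
        barcodes = rng.integers(0, model.barcode_space, size=n_codes)
        mol_bc = barcodes[rng.integers(0, n_codes, size=n_mol)]
    else:
        mol_bc = rng.integers(0, model.barcode_space, size=n_mol)

    reads_per_bp = model.target_read_coverage / (model.read_length * model.molecule_coverage)
    n_reads = rng.poisson(lengths * reads_per_bp)
    total = int(n_reads.sum())
    mol_of_read = np.repeat(np.arange(n_mol), n_reads)
    span = np.maximum(lengths[mol_of_read] - model.read_length, 1)
    read_starts = mol_starts[mol_of_read] + (rng.random(total) * span).astype(np.int64)

    keep, ref_starts, rev = cmap.lift_reads(read_starts, model.read_length)
    return TaggedReadSet(
        chrom=chrom,
        chrom_length=cmap.ref_length,
        starts=ref_starts[keep],
        barcode_ids=mol_bc[mol_of_read][keep],
        reverse=rev[keep],
        read_length=model.read_length,
    )


def make_null_dataset(
    genome_length: int,
    model: MoleculeModel = MoleculeModel(),
    seed: int = 0,
    chrom: str = "chr1",
) -> TaggedReadSet:
    """Simulated reads over an SV-free genome (identity coordinate map)."""
    return simulate_tagged_reads(
        CoordinateMap.identity(genome_length), model=model, seed=seed, chrom=chrom
    )


def write_truth_bed(
    truth: Sequence[SimulatedSV],
    path: Union[str, Path],
    insertions_fasta: Optional[Union[str, Path]] = None,
) -> None:
    """Write truth events as BED (0-based half-open; insertions zero-length
    with their size in column 5); inserted sequences optionally to FASTA."""
    with open(path, "w") as fh:
        for k, sv in enumerate(truth):
            fh.write(f"{sv.chrom}\t{sv.ref_start}\t{sv.ref_end}\t{sv.type}_{k + 1}\t{sv.size}\t.\n")
    if insertions_fasta is not None:
        with open(insertions_fasta, "w") as fh:
            for k, sv in enumerate(truth):
                if sv.type == "insertion":
                    fh.write(f">{sv.type}_{k + 1}\n{sv.inserted_sequence}\n")


def read_truth_bed(path: Union[str, Path]) -> List[SimulatedSV]:
    truth: List[SimulatedSV] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, start, end, name, size = line.split("\t")[:5]
        sv_type = name.rsplit("_", 1)[0]
        truth.append(
            SimulatedSV(
                chrom,
                int(start),
                int(end),
                sv_type,
                int(size),
                inserted_sequence="N" * int(size) if sv_type == "insertion" else "",
            )
        )
    return truth


def write_fasta(genome: Mapping[str, str], path: Union[str, Path], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    genome: Dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            genome[entry.name] = entry.sequence.upper()
    return genome
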