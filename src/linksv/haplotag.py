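"""Haplotagging barcode parsing and tagged-alignment input.

Haplotagging attaches one of ~885k combinatorial bead barcodes to every short
read derived from the same long DNA molecule.  The barcode is sequenced as four
6-bp segments spread over the two index reads (13 nt and 12 nt); after
demultiplexing it travels with each read as a ``BX:Z`` tag.  This module
resolves raw index reads against a segment whitelist (with single-mismatch
error correction to an unambiguous closest match), renders canonical BX
strings, and streams BX-tagged alignments from SAM/BAM with the alignment
filters used throughout the package (MAPQ >= 10, duplicates dropped,
untagged reads dropped).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

log = logging.getLogger(__name__)

#: Rendering order of the four segment classes in a BX string, e.g. A07C22B11D90.
SEGMENT_CLASSES: Tuple[str, str, str, str] = ("A", "C", "B", "D")

#: Default 0-based offsets of the two 6-bp segments within each index read:
#: (A, C) in the 13-nt index-1 read, (B, D) in the 12-nt index-2 read.
DEFAULT_INDEX1_OFFSETS: Tuple[int, int] = (0, 7)
DEFAULT_INDEX2_OFFSETS: Tuple[int, int] = (0, 6)

SEGMENT_LENGTH = 6
_VALID_BASES = frozenset("ACGT")
_BX_RE = re.compile(r"([ACBD])(\d+)")


class MalformedReadError(ValueError):
    """An index read is too short to contain the expected barcode segments."""


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class BarcodeWhitelist:
    """Per-segment-class whitelists of 6-nt barcode sequences.

    ``segments`` holds the four ordered entry lists in BX rendering order
    (A, C, B, D).  ``max_correction_distance`` is the number of substitutions
    tolerated per segment when correcting a sequencing error; a segment is
    corrected only when a *unique* whitelist entry attains the minimal
    Hamming distance.
    """

    segments: Tuple[Tuple[str, ...], Tuple[str, ...], Tuple[str, ...], Tuple[str, ...]]
    max_correction_distance: int = 1

    def __post_init__(self) -> None:
        if len(self.segments) != 4:
            raise ValueError("whitelist needs exactly four segment classes")
        for cls, entries in zip(SEGMENT_CLASSES, self.segments):
            if not entries:
                raise ValueError(f"segment class {cls} has no whitelist entries")
            if len(set(entries)) != len(entries):
                raise ValueError(f"segment class {cls} has duplicate entries")
            for e in entries:
                if len(e) != SEGMENT_LENGTH or not set(e) <= _VALID_BASES:
                    raise ValueError(f"bad whitelist entry {e!r} in class {cls}")
        # exact-match lookup tables, built once
        object.__setattr__(
            self,
            "_exact",
            tuple({e: i + 1 for i, e in enumerate(entries)} for entries in self.segments),
        )

    @property
    def index_width(self) -> int:
        """Zero-padding width of segment indices in rendered BX strings."""
        return max(2, len(str(max(len(s) for s in self.segments))))

    def match_segment(self, class_index: int, observed: str) -> int:
        """Resolve one observed 6-mer to a 1-based whitelist index (0 = unresolved).

        Exact hits win; otherwise the unique entry at minimal Hamming distance
        <= ``max_correction_distance`` is taken.  Ties at the minimal distance,
        or no entry within range, leave the segment unresolved.
        """
        code = self._exact[class_index].get(observed)  # type: ignore[attr-defined]
        if code is not None:
            return code
        best, best_code, tie = SEGMENT_LENGTH + 1, 0, False
        for i, entry in enumerate(self.segments[class_index]):
            d = hamming(observed, entry)
            if d < best:
                best, best_code, tie = d, i + 1, False
            elif d == best:
                tie = True
        if best > self.max_correction_distance or tie:
            return 0
        return best_code

    @classmethod
    def from_tsv(cls, path: Union[str, Path], max_correction_distance: int = 1) -> "BarcodeWhitelist":
        """Read a two-column TSV of ``segment_class<TAB>sequence`` rows."""
        buckets: dict[str, list[str]] = {c: [] for c in SEGMENT_CLASSES}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cls_name, seq = line.split("\t")[:2]
            buckets[cls_name].append(seq.upper())
        return cls(
            tuple(tuple(buckets[c]) for c in SEGMENT_CLASSES),  # type: ignore[arg-type]
            max_correction_distance=max_correction_distance,
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for cls_name, entries in zip(SEGMENT_CLASSES, self.segments):
                for seq in entries:
                    fh.write(f"{cls_name}\t{seq}\n")


def synthetic_whitelist(n_per_segment: int = 12, seed: int = 0,
                        min_pairwise_distance: int = 3) -> BarcodeWhitelist:
    """Generate a small synthetic whitelist for tests and simulations.

    Entries within a class are kept at pairwise Hamming distance
    >= ``min_pairwise_distance`` so that single-substitution errors always
    correct unambiguously.  Synthetic stand-in: real haplotagging whitelists
    are bead-batch specific and not bundled here.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    classes = []
    for _ in range(4):
        entries: list[str] = []
        while len(entries) < n_per_segment:
            cand = "".join(rng.choice(bases, SEGMENT_LENGTH))
            if all(hamming(cand, e) >= min_pairwise_distance for e in entries):
                entries.append(cand)
        classes.append(tuple(entries))
    return BarcodeWhitelist(tuple(classes))  # type: ignore[arg-type]


@dataclass(frozen=True)
class BxTag:
    """A resolved four-segment molecule barcode.

    ``segment_codes`` are 1-based whitelist indices in rendering order
    (A, C, B, D); 0 marks an unresolvable segment and invalidates the tag.
    """

    segment_codes: Tuple[int, int, int, int]
    index_width: int = 2

    @property
    def valid(self) -> bool:
        return all(c > 0 for c in self.segment_codes)

    def render(self) -> str:
        return "".join(
            f"{cls}{code:0{self.index_width}d}"
            for cls, code in zip(SEGMENT_CLASSES, self.segment_codes)
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def bx_tag_is_valid(bx: str) -> bool:
    """True when every segment of a rendered BX string has a nonzero index."""
    parts = _BX_RE.findall(bx)
    if len(parts) != 4:
        return False
    return all(int(idx) > 0 for _, idx in parts)


def demultiplex_read_pair(
    index1: str,
    index2: str,
    whitelist: BarcodeWhitelist,
    index1_offsets: Tuple[int, int] = DEFAULT_INDEX1_OFFSETS,
    index2_offsets: Tuple[int, int] = DEFAULT_INDEX2_OFFSETS,
) -> BxTag:
    """Resolve the four 6-bp barcode segments of one read pair into a BxTag.

    Segments A and C sit in ``index1`` (13 nt), B and D in ``index2`` (12 nt),
    at the configured offsets.  Each segment is matched exactly against the
    whitelist or corrected to the unique closest entry within the whitelist's
    ``max_correction_distance``; a tie or out-of-range segment leaves its code
    at 0, marking the whole tag invalid.
    """
    index1 = index1.upper()
    index2 = index2.upper()
    spans = [
        (index1, index1_offsets[0]),
        (index1, index1_offsets[1]),
        (index2, index2_offsets[0]),
        (index2, index2_offsets[1]),
    ]
    codes = []
    for class_index, (read, off) in enumerate(spans):
        if len(read) < off + SEGMENT_LENGTH:
            raise MalformedReadError(
                f"index read of length {len(read)} cannot hold a segment at offset {off}"
            )
        codes.append(whitelist.match_segment(class_index, read[off:off + SEGMENT_LENGTH]))
    return BxTag(tuple(codes), index_width=whitelist.index_width)  # type: ignore[arg-type]


@dataclass(frozen=True)
class AlignmentFilterConfig:
    """Alignment-level filters applied before barcode collection.

    Defaults drop reads with MAPQ < 10, duplicate-flagged reads, and reads
    without a (valid) BX tag.
    """

    min_mapq: int = 10
    drop_duplicates: bool = True
    drop_untagged: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


@dataclass(frozen=True)
class TaggedAlignment:
    """Minimal view of a barcode-tagged alignment record."""

    chrom: str
    start: int  # 0-based leftmost reference coordinate
    mapq: int
    is_duplicate: bool = False
    bx: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("alignment start must be >= 0")
        if not 0 <= self.mapq <= 255:
            raise ValueError("mapq must be in [0, 255]")


def _parse_region(region: str) -> Tuple[str, Optional[int], Optional[int]]:
    """Parse ``chrom`` or ``chrom:start-end`` (1-based inclusive, samtools style)."""
    if ":" not in region:
        return region, None, None
    chrom, span = region.rsplit(":", 1)
    start_s, end_s = span.replace(",", "").split("-")
    return chrom, int(start_s) - 1, int(end_s)


def passes_filters(aln: TaggedAlignment, filters: AlignmentFilterConfig) -> bool:
    if aln.mapq < filters.min_mapq:
        return False
    if filters.drop_duplicates and aln.is_duplicate:
        return False
    if filters.drop_untagged and (aln.bx is None or not bx_tag_is_valid(aln.bx)):
        return False
    return True


def stream_tagged_alignments(
    source: Union[str, Path, pysam.AlignmentFile],
    region: Optional[str] = None,
    filters: AlignmentFilterConfig = AlignmentFilterConfig(),
) -> Iterator[TaggedAlignment]:
    """Yield filtered :class:`TaggedAlignment` records in coordinate order.

    Secondary, supplementary and unmapped records are always skipped so each
    read contributes its barcode once per locus.  With a region on an indexed
    BAM the index is used; on plain SAM a linear scan with coordinate
    filtering is performed instead.  An unknown chromosome yields nothing
    (with a warning).
    """
    owns = not isinstance(source, pysam.AlignmentFile)
    afile = pysam.AlignmentFile(str(source)) if owns else source
    try:
        records: Iterable[pysam.AlignedSegment]
        if region is not None:
            chrom, start, end = _parse_region(region)
            if chrom not in afile.references:
                log.warning("region chromosome %s not in alignment header; nothing to yield", chrom)
                return
            use_index = afile.is_bam or afile.is_cram
            if use_index:
                if not afile.has_index():
                    raise FileNotFoundError(
                        f"{afile.filename!r} has no index; run samtools index, or pass a SAM "
                        "for a linear scan"
                    )
                records = afile.fetch(chrom, start, end)
            else:
                def _scan() -> Iterator[pysam.AlignedSegment]:
                    for rec in afile.fetch(until_eof=True):
                        if rec.is_unmapped or rec.reference_name != chrom:
                            continue
                        if start is not None and rec.reference_start < start:
                            continue
                        if end is not None and rec.reference_start >= end:
                            continue
                        yield rec
                records = _scan()
        else:
            records = afile.fetch(until_eof=True)

        for rec in records:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            bx = rec.get_tag("BX") if rec.has_tag("BX") else None
            aln = TaggedAlignment(
                chrom=rec.reference_name,
                start=rec.reference_start,
                mapq=rec.mapping_quality,
                is_duplicate=rec.is_duplicate,
                bx=bx,
            )
            if passes_filters(aln, filters):
                yield aln
    finally:
        if owns:
            afile.close()


def demultiplex_fastq(
    r1: Union[str, Path],
    r2: Union[str, Path],
    i1: Union[str, Path],
    i2: Union[str, Path],
    whitelist: BarcodeWhitelist,
    out_prefix: Union[str, Path],
) -> dict:
    """Demultiplex four FASTQ streams into BX-annotated paired FASTQ files.

    Writes ``<prefix>_R1.fastq`` / ``<prefix>_R2.fastq`` with the rendered BX
    tag appended to the read comment as ``BX:Z:<tag>`` (invalid tags are still
    rendered, with 00 segments, so downstream filters can drop them).  Returns
    counts of total/valid/corrected read pairs.
    """
    stats = {"pairs": 0, "valid": 0, "invalid": 0}
    out_prefix = str(out_prefix)
    with pysam.FastxFile(str(r1)) as f1, pysam.FastxFile(str(r2)) as f2, \
            pysam.FastxFile(str(i1)) as fi1, pysam.FastxFile(str(i2)) as fi2, \
            open(out_prefix + "_R1.fastq", "w") as o1, open(out_prefix + "_R2.fastq", "w") as o2:
        for e1, e2, x1, x2 in zip(f1, f2, fi1, fi2):
            tag = demultiplex_read_pair(x1.sequence, x2.sequence, whitelist)
            stats["pairs"] += 1
            stats["valid" if tag.valid else "invalid"] += 1
            comment = f"BX:Z:{tag.render()}"
            for entry, out in ((e1, o1), (e2, o2)):
                qual = entry.quality if entry.quality is not None else "I" * len(entry.sequence)
                out.write(f"@{entry.name} {comment}\n{entry.sequence}\n+\n{qual}\n")
    return stats
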