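"""Read-depth extraction from BAM at sampled transcript positions.

Depth is taken from aligned (M/=/X) reference bases only: deletions and
splice gaps in a read's CIGAR contribute nothing, and both mates of a pair
contribute independently. The default read filter mirrors the
"uniquely mapped, high quality" convention: mapq >= 30, no secondary,
supplementary, duplicate or QC-fail alignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam

from .gene_models import CoordinateMap, TranscriptModel

__all__ = [
    "ReadFilter",
    "DEFAULT_FILTER",
    "CoveragePoints",
    "sample_positions",
    "depth_at",
    "spliced_coverage",
    "count_overlapping_reads",
    "aligned_reference_blocks",
    "open_bam",
]

# CIGAR operations that consume the reference
_REF_ALIGNED = {0, 7, 8}  # M, =, X contribute coverage
_REF_SKIP = {2, 3}  # D, N advance without coverage


@dataclass(frozen=True)
class ReadFilter:
    """Alignment-level filters applied before counting a read."""

    min_mapq: int = 30
    drop_secondary: bool = True
    drop_supplementary: bool = True
    drop_duplicates: bool = True
    drop_qcfail: bool = True

    def __post_init__(self):
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")

    def passes(self, read: pysam.AlignedSegment) -> bool:
        if read.is_unmapped:
            return False
        if read.mapping_quality < self.min_mapq:
            return False
        if self.drop_secondary and read.is_secondary:
            return False
        if self.drop_supplementary and read.is_supplementary:
            return False
        if self.drop_duplicates and read.is_duplicate:
            return False
        if self.drop_qcfail and read.is_qcfail:
            return False
        return True


DEFAULT_FILTER = ReadFilter()


@dataclass
class CoveragePoints:
    """Depths at the sampled transcript offsets of one transcript."""

    transcript: str
    offsets: np.ndarray  # strictly increasing transcript offsets
    depths: np.ndarray  # non-negative read depth per offset

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.offsets.shape != self.depths.shape:
            raise ValueError("offsets and depths must have the same length")
        if len(self.offsets) and (np.diff(self.offsets) <= 0).any():
            raise ValueError("offsets must be strictly increasing")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def m(self) -> int:
        """Number of distinct evaluated positions."""
        return len(self.offsets)


def sample_positions(model: TranscriptModel, k: int = 100) -> np.ndarray:
    """The k equally spaced transcript offsets plus all exon-exon junction
    offsets, deduplicated and sorted.

    The grid spans [0, spliced_length - 1] inclusive with nearest-integer
    (half-up) rounding, so both transcript ends are always evaluated.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    length = model.spliced_length
    if length < 1:
        raise ValueError(f"{model.name}: empty transcript")
    grid = np.floor(np.arange(k) * (length - 1) / (k - 1) + 0.5).astype(np.int64)
    cmap = CoordinateMap(model)
    return np.union1d(grid, cmap.junction_offsets)


def aligned_reference_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference intervals covered by aligned bases (M/=/X) of one read.

    Splice gaps (N) and deletions (D) split blocks and contribute nothing.
    """
    blocks: list[tuple[int, int]] = []
    pos = read.reference_start
    for op, n in read.cigartuples or ():
        if op in _REF_ALIGNED:
            blocks.append((pos, pos + n))
            pos += n
        elif op in _REF_SKIP:
            pos += n
    return blocks


def open_bam(bam, *, require_index: bool = True) -> tuple[pysam.AlignmentFile, bool]:
    """Return (AlignmentFile, whether_we_opened_it); verifies the index."""
    if isinstance(bam, pysam.AlignmentFile):
        af, opened = bam, False
    else:
        af, opened = pysam.AlignmentFile(str(bam), "rb"), True
    if require_index:
        try:
            af.check_index()
        except (ValueError, AttributeError, OSError):
            if opened:
                af.close()
            raise FileNotFoundError(
                f"{af.filename.decode() if af.filename else bam}: no BAM index found; "
                "create one with 'samtools index <bam>'"
            ) from None
    return af, opened


def _span_depth(af: pysam.AlignmentFile, model: TranscriptModel,
                read_filter: ReadFilter) -> np.ndarray | None:
    """Read depth over the genomic span [tx_start, tx_end); None if the
    contig is absent from the BAM header."""
    if model.chrom not in af.references:
        return None
    tx0, tx1 = model.tx_start, model.tx_end
    delta = np.zeros(tx1 - tx0 + 1, dtype=np.int64)
    for read in af.fetch(model.chrom, tx0, tx1):
        if not read_filter.passes(read):
            continue
        for bs, be in aligned_reference_blocks(read):
            bs, be = max(bs, tx0), min(be, tx1)
            if be > bs:
                delta[bs - tx0] += 1
                delta[be - tx0] -= 1
    return np.cumsum(delta)[: tx1 - tx0]


def depth_at(
    bam,
    model: TranscriptModel,
    offsets: Sequence[int] | np.ndarray,
    read_filter: ReadFilter = DEFAULT_FILTER,
) -> CoveragePoints:
    """Depth of filter-passing reads at the given transcript offsets."""
    af, opened = open_bam(bam)
    try:
        depth = _span_depth(af, model, read_filter)
    finally:
        if opened:
            af.close()
    offsets = np.asarray(offsets, dtype=np.int64)
    if depth is None:
        warnings.warn(
            f"{model.name}: contig {model.chrom!r} absent from BAM; depths set to 0"
        )
        return CoveragePoints(model.name, offsets, np.zeros(len(offsets), dtype=np.int64))
    g = CoordinateMap(model).transcript_to_genome(offsets)
    return CoveragePoints(model.name, offsets, depth[g - model.tx_start])


def spliced_coverage(
    bam,
    model: TranscriptModel,
    read_filter: ReadFilter = DEFAULT_FILTER,
) -> np.ndarray:
    """Base-resolution depth along the spliced transcript, oriented 5'->3'."""
    af, opened = open_bam(bam)
    try:
        depth = _span_depth(af, model, read_filter)
    finally:
        if opened:
            af.close()
    if depth is None:
        warnings.warn(
            f"{model.name}: contig {model.chrom!r} absent from BAM; coverage set to 0"
        )
        return np.zeros(model.spliced_length, dtype=np.int64)
    tx0 = model.tx_start
    idx = np.concatenate([np.arange(s - tx0, e - tx0) for s, e in model.exons])
    cov = depth[idx]
    return cov[::-1] if model.strand == "-" else cov


def count_overlapping_reads(
    bam,
    chrom: str,
    blocks: Iterable[tuple[int, int]],
    read_filter: ReadFilter = DEFAULT_FILTER,
) -> int:
    """Number of filter-passing reads whose aligned bases overlap any of the
    genomic ``blocks``; each read counts once."""
    blocks = sorted(blocks)
    if not blocks:
        return 0
    starts = np.asarray([b[0] for b in blocks])
    ends = np.asarray([b[1] for b in blocks])
    af, opened = open_bam(bam)
    try:
        if chrom not in af.references:
            return 0
        n = 0
        for read in af.fetch(chrom, blocks[0][0], blocks[-1][1]):
            if not read_filter.passes(read):
                continue
            for rs, re in aligned_reference_blocks(read):
                # any region block with start < re and end > rs?
                i = np.searchsorted(starts, re, side="left")
                if (ends[:i] > rs).any():
                    n += 1
                    break
        return n
    finally:
        if opened:
            af.close()
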