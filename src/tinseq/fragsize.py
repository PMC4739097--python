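"""RNA fragment-size estimation from mapped read pairs.

The size of a sequenced RNA fragment is recovered from its read pair as the
genomic span between the outermost aligned ends of the two mates, minus any
introns of the transcript model that lie fully inside that span - i.e. the
spliced (mRNA-scale) length of the fragment. Degraded libraries carry
shorter fragments, so the per-transcript and per-sample means of these sizes
track RNA integrity.

Only uniquely mapped, high-quality (mapq >= 30 by default) pairs in proper
forward/reverse orientation whose aligned bases lie entirely within the
transcript's exons are used; everything else is rejected with a categorized
reason.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .coverage import aligned_reference_blocks, open_bam
from .gene_models import TranscriptModel

from ._util import atomic_write

__all__ = [
    "SingleEndError",
    "FragmentSizeEstimate",
    "pair_fragment_size",
    "transcript_fragment_size",
    "sample_fragment_size",
    "write_fragsize_table",
]

#: rejection categories reported in the counters
REASONS = ("low-mapq", "orientation", "off-model", "nonpositive")


class SingleEndError(ValueError):
    """Raised for single-end input: fragment sizes need read pairs."""


@dataclass
class FragmentSizeEstimate:
    level: str  # 'pair', 'transcript' or 'sample'
    transcript: str | None
    n_pairs: int
    mean_size: float
    median_size: float
    sizes: np.ndarray | None = None
    rejections: dict[str, int] = field(default_factory=dict)


def _blocks_within_exons(blocks: Sequence[tuple[int, int]], model: TranscriptModel) -> bool:
    for bs, be in blocks:
        inside = False
        for es, ee in model.exons:
            if bs >= es and be <= ee:
                inside = True
                break
        if not inside:
            return False
    return True


def pair_fragment_size(
    r1: pysam.AlignedSegment,
    r2: pysam.AlignedSegment,
    model: TranscriptModel,
    *,
    min_mapq: int = 30,
) -> tuple[int | None, str | None]:
    """Spliced fragment size of one read pair, or (None, reason).

    The size is (rightmost aligned end - leftmost aligned start) minus the
    total length of model introns fully contained in that genomic span.
    """
    if min(r1.mapping_quality, r2.mapping_quality) < min_mapq:
        return None, "low-mapq"
    if r1.reference_name != model.chrom or r2.reference_name != model.chrom:
        return None, "off-model"
    if r1.is_reverse == r2.is_reverse:
        return None, "orientation"
    fwd, rev = (r2, r1) if r1.is_reverse else (r1, r2)
    if fwd.reference_start > rev.reference_start:
        return None, "orientation"
    b1 = aligned_reference_blocks(r1)
    b2 = aligned_reference_blocks(r2)
    if not b1 or not b2:
        return None, "off-model"
    if not (_blocks_within_exons(b1, model) and _blocks_within_exons(b2, model)):
        return None, "off-model"
    lo = min(b1[0][0], b2[0][0])
    hi = max(b1[-1][1], b2[-1][1])
    intron_sum = sum(ie - istart for istart, ie in model.introns if istart >= lo and ie <= hi)
    size = hi - lo - intron_sum
    if size <= 0:
        return None, "nonpositive"
    return size, None


def _iter_pairs(
    af: pysam.AlignmentFile, model: TranscriptModel
) -> Iterator[tuple[pysam.AlignedSegment, pysam.AlignedSegment]]:
    """Primary, non-duplicate mate pairs with both reads inside the
    transcript's genomic span."""
    pending: dict[str, pysam.AlignedSegment] = {}
    if model.chrom not in af.references:
        return
    for read in af.fetch(model.chrom, model.tx_start, model.tx_end):
        if (
            read.is_unmapped
            or not read.is_paired
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.is_qcfail
        ):
            continue
        mate = pending.pop(read.query_name, None)
        if mate is None:
            pending[read.query_name] = read
        else:
            yield mate, read


def _collect_sizes(
    af: pysam.AlignmentFile,
    model: TranscriptModel,
    *,
    min_mapq: int,
    seen: set[str] | None = None,
) -> tuple[list[int], Counter]:
    sizes: list[int] = []
    rejections: Counter = Counter()
    for r1, r2 in _iter_pairs(af, model):
        if seen is not None and r1.query_name in seen:
            continue
        size, reason = pair_fragment_size(r1, r2, model, min_mapq=min_mapq)
        if size is None:
            rejections[reason] += 1
        else:
            sizes.append(size)
            if seen is not None:
                seen.add(r1.query_name)
    return sizes, rejections


def transcript_fragment_size(
    bam,
    model: TranscriptModel,
    *,
    min_pairs: int = 30,
    min_mapq: int = 30,
    keep_sizes: bool = False,
) -> FragmentSizeEstimate | None:
    """Mean fragment size over pairs mapping within one transcript, or None
    if fewer than ``min_pairs`` pairs were accepted."""
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    af, opened = open_bam(bam)
    try:
        sizes, rejections = _collect_sizes(af, model, min_mapq=min_mapq)
    finally:
        if opened:
            af.close()
    if len(sizes) < min_pairs:
        return None
    arr = np.asarray(sizes, dtype=float)
    return FragmentSizeEstimate(
        level="transcript",
        transcript=model.name,
        n_pairs=len(sizes),
        mean_size=float(arr.mean()),
        median_size=float(np.median(arr)),
        sizes=arr if keep_sizes else None,
        rejections=dict(rejections),
    )


def _check_paired(af: pysam.AlignmentFile, probe: int = 2000) -> None:
    saw_read = False
    for read in af.head(probe):
        saw_read = True
        if read.is_paired:
            return
    if saw_read:
        raise SingleEndError(
            "input looks single-end: fragment sizes can only be estimated "
            "from paired-end data"
        )


def sample_fragment_size(
    bam,
    models: Iterable[TranscriptModel],
    *,
    min_mapq: int = 30,
    keep_sizes: bool = False,
) -> FragmentSizeEstimate:
    """Pooled mean fragment size over all accepted pairs of all transcripts.

    ``models`` should already be reduced to one (longest) isoform per gene.
    Each pair is counted once even if it fits several transcripts. Raises
    :class:`SingleEndError` for single-end input and ``ValueError`` when no
    pair is accepted.
    """
    af, opened = open_bam(bam)
    try:
        _check_paired(af)
        seen: set[str] = set()
        all_sizes: list[int] = []
        rejections: Counter = Counter()
        for model in models:
            sizes, rej = _collect_sizes(af, model, min_mapq=min_mapq, seen=seen)
            all_sizes.extend(sizes)
            rejections.update(rej)
    finally:
        if opened:
            af.close()
    if not all_sizes:
        raise ValueError(
            f"no read pair was accepted for fragment-size estimation "
            f"(rejections: {dict(rejections)})"
        )
    arr = np.asarray(all_sizes, dtype=float)
    return FragmentSizeEstimate(
        level="sample",
        transcript=None,
        n_pairs=len(arr),
        mean_size=float(arr.mean()),
        median_size=float(np.median(arr)),
        sizes=arr if keep_sizes else None,
        rejections=dict(rejections),
    )


def write_fragsize_table(estimates: Iterable[FragmentSizeEstimate], path) -> None:
    with atomic_write(path) as fh:
        fh.write("transcript\tn_pairs\tmean_fragment_size\tmedian_fragment_size\n")
        for est in estimates:
            name = est.transcript if est.transcript is not None else "(sample)"
            fh.write(
                f"{name}\t{est.n_pairs}\t{est.mean_size:.2f}\t{est.median_size:.2f}\n"
            )
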