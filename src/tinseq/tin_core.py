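"""The transcript integrity number (TIN) and its sample-level median.

TIN measures how uniformly RNA-seq reads cover a transcript. With depths
C_i at m sampled positions the relative coverage is P_i = C_i / sum(C),
coverage evenness is Shannon entropy H = -sum(P_i ln P_i), the effective
number of uniformly covered positions is U = exp(H), and

    TIN = 100 * U / m

so 100 means perfectly uniform coverage and small values mean coverage
concentrated on a few positions. Natural logarithms are used throughout:
U = exp(H) is the effective-support count (the "numbers equivalent" of the
entropy) only under ln, which is what makes TIN a percentage of positions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .coverage import DEFAULT_FILTER, CoveragePoints, ReadFilter, depth_at, open_bam, sample_positions
from .gene_models import TranscriptModel

from ._util import atomic_write

__all__ = [
    "ZeroCoverageError",
    "TinRecord",
    "SampleTinSummary",
    "relative_coverage",
    "shannon_entropy",
    "tin_score",
    "med_tin",
    "score_transcripts",
    "write_tin_table",
    "write_summary",
]


class ZeroCoverageError(ValueError):
    """Signals an all-zero depth vector (TIN is 0 by convention)."""


def relative_coverage(depths) -> np.ndarray:
    """P_i = C_i / sum(C). Raises :class:`ZeroCoverageError` on all zeros."""
    d = np.asarray(depths, dtype=float)
    if (d < 0).any():
        raise ValueError("depths must be non-negative")
    total = d.sum()
    if total <= 0:
        raise ZeroCoverageError("no coverage at any sampled position")
    return d / total


def shannon_entropy(p) -> float:
    """H = -sum(P_i ln P_i) in nats, with 0 * ln 0 = 0."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass
class TinRecord:
    """Per-transcript TIN plus the quantities that produced it.

    ``entropy`` and ``uniformity`` are ``None`` when the transcript was below
    the coverage threshold (TIN reported as 0 but excluded from medTIN by
    default).
    """

    transcript: str
    chrom: str
    tx_start: int
    tx_end: int
    spliced_length: int
    m: int
    mean_sampled_depth: float
    entropy: float | None
    uniformity: float | None
    tin: float

    @property
    def scored(self) -> bool:
        return self.entropy is not None


@dataclass
class SampleTinSummary:
    sample: str
    n_scored: int
    n_skipped: int
    med_tin: float | None
    mean_tin: float | None
    sd_tin: float | None


def tin_score(
    points: CoveragePoints,
    min_mean_depth: float = 10.0,
    model: TranscriptModel | None = None,
) -> TinRecord:
    """TIN of one transcript from its sampled depths.

    Transcripts whose mean sampled depth is below ``min_mean_depth`` get
    TIN = 0 with entropy and uniformity recorded as absent.
    """
    d = points.depths
    m = points.m
    mean_depth = float(d.mean()) if m else 0.0
    chrom = model.chrom if model else "."
    tx_start = model.tx_start if model else 0
    tx_end = model.tx_end if model else 0
    length = model.spliced_length if model else (int(points.offsets[-1]) + 1 if m else 0)
    if mean_depth <= 0 or mean_depth < min_mean_depth:
        return TinRecord(
            points.transcript, chrom, tx_start, tx_end, length, m,
            mean_depth, None, None, 0.0,
        )
    h = shannon_entropy(relative_coverage(d))
    u = math.exp(h)
    tin = min(100.0, max(0.0, 100.0 * u / m))
    return TinRecord(
        points.transcript, chrom, tx_start, tx_end, length, m,
        mean_depth, h, u, tin,
    )


def med_tin(
    records: Sequence[TinRecord],
    *,
    sample: str = "sample",
    include_skipped: bool = False,
) -> SampleTinSummary:
    """Median / mean / sd of TIN across one sample's transcripts.

    Below-threshold transcripts are counted as skipped and excluded from the
    statistics unless ``include_skipped`` is set, in which case their TIN of
    0 enters the median (the alternative reading of "all transcripts").
    """
    if not records:
        raise ValueError("med_tin requires at least one TinRecord")
    n_scored = sum(1 for r in records if r.scored)
    n_skipped = len(records) - n_scored
    if include_skipped:
        values = np.asarray([r.tin for r in records], dtype=float)
    else:
        values = np.asarray([r.tin for r in records if r.scored], dtype=float)
    if len(values) == 0:
        warnings.warn(f"{sample}: no transcript passed the coverage threshold")
        return SampleTinSummary(sample, n_scored, n_skipped, None, None, None)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return SampleTinSummary(
        sample,
        n_scored,
        n_skipped,
        float(np.median(values)),
        float(values.mean()),
        sd,
    )


def score_transcripts(
    bam,
    models: Iterable[TranscriptModel],
    *,
    k: int = 100,
    read_filter: ReadFilter = DEFAULT_FILTER,
    min_mean_depth: float = 10.0,
) -> list[TinRecord]:
    """TIN for every transcript in ``models`` against one BAM."""
    af, opened = open_bam(bam)
    try:
        records = []
        for model in models:
            offsets = sample_positions(model, k)
            points = depth_at(af, model, offsets, read_filter)
            records.append(tin_score(points, min_mean_depth, model))
        return records
    finally:
        if opened:
            af.close()


_TIN_HEADER = (
    "transcript\tchrom\ttx_start\ttx_end\tspliced_length\tmean_sampled_depth\tTIN\n"
)


def write_tin_table(records: Iterable[TinRecord], path) -> None:
    with atomic_write(path) as fh:
        fh.write(_TIN_HEADER)
        for r in records:
            fh.write(
                f"{r.transcript}\t{r.chrom}\t{r.tx_start}\t{r.tx_end}\t"
                f"{r.spliced_length}\t{r.mean_sampled_depth:.2f}\t{r.tin:.2f}\n"
            )


def write_summary(summary: SampleTinSummary, path) -> None:
    def fmt(x):
        return "NA" if x is None else f"{x:.2f}"

    with atomic_write(path) as fh:
        fh.write("sample\tn_scored\tn_skipped\tmedTIN\tmeanTIN\tsdTIN\n")
        fh.write(
            f"{summary.sample}\t{summary.n_scored}\t{summary.n_skipped}\t"
            f"{fmt(summary.med_tin)}\t{fmt(summary.mean_tin)}\t{fmt(summary.sd_tin)}\n"
        )
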