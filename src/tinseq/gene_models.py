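"""BED12 gene models and genomic <-> transcript coordinate arithmetic.

All genomic coordinates are 0-based, half-open (BED convention).
Transcript coordinates always run 5'->3' of the mRNA: offset 0 is the
transcription start site, so on the minus strand it maps to the genomic
position ``tx_end - 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Bed12Error",
    "TranscriptModel",
    "CoordinateMap",
    "read_bed12",
    "write_bed12",
    "read_gene_map",
    "longest_isoform_per_gene",
]


class Bed12Error(ValueError):
    """A malformed BED12 record; carries the 1-based file line number."""

    def __init__(self, message: str, lineno: int | None = None):
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)
        self.lineno = lineno


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered, disjoint set of exons on one strand.

    Parameters
    ----------
    name : str
        Transcript identifier (BED12 ``name`` field).
    chrom : str
        Reference sequence name.
    strand : str
        ``'+'`` or ``'-'``.
    exons : tuple of (int, int)
        Genomic exon intervals, 0-based half-open, ascending and disjoint.
    """

    name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.name}: transcript must have at least one exon")
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"{self.name}: empty or inverted exon ({start}, {end})")
            if start < prev_end:
                raise ValueError(f"{self.name}: exons overlap or are out of order")
            prev_end = end

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intervals between consecutive exons."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @classmethod
    def from_bed12_line(cls, line: str, lineno: int | None = None) -> "TranscriptModel":
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 12:
            raise Bed12Error(f"expected >= 12 tab-separated fields, got {len(fields)}", lineno)
        try:
            chrom_start = int(fields[1])
            chrom_end = int(fields[2])
            block_count = int(fields[9])
        except ValueError as exc:
            raise Bed12Error(f"non-integer coordinate field: {exc}", lineno) from None
        name = fields[3]
        strand = fields[5]
        sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x != ""]
        starts = [int(x) for x in fields[11].rstrip(",").split(",") if x != ""]
        if len(sizes) != block_count or len(starts) != block_count:
            raise Bed12Error(
                f"record {name!r}: blockCount={block_count} but "
                f"{len(sizes)} blockSizes / {len(starts)} blockStarts",
                lineno,
            )
        exons = tuple(
            (chrom_start + bs, chrom_start + bs + sz) for bs, sz in zip(starts, sizes)
        )
        try:
            model = cls(name=name, chrom=fields[0], strand=strand, exons=exons)
        except ValueError as exc:
            raise Bed12Error(str(exc), lineno) from None
        if model.tx_start != chrom_start or model.tx_end != chrom_end:
            raise Bed12Error(
                f"record {name!r}: blocks do not span chromStart..chromEnd", lineno
            )
        return model

    def to_bed12_line(self) -> str:
        sizes = ",".join(str(n) for n in self.exon_lengths)
        starts = ",".join(str(s - self.tx_start) for s, _ in self.exons)
        return "\t".join(
            [
                self.chrom,
                str(self.tx_start),
                str(self.tx_end),
                self.name,
                "0",
                self.strand,
                str(self.tx_start),
                str(self.tx_end),
                "0",
                str(self.n_exons),
                sizes,
                starts,
            ]
        )


class CoordinateMap:
    """Bidirectional map between transcript offsets and genomic positions.

    Transcript offsets are 0-based from the 5' end of the mRNA. The map is
    strictly monotonic in genomic order (decreasing on the minus strand).
    """

    def __init__(self, model: TranscriptModel):
        self.model = model
        self._starts = np.asarray([s for s, _ in model.exons], dtype=np.int64)
        self._ends = np.asarray([e for _, e in model.exons], dtype=np.int64)
        lens = self._ends - self._starts
        # cumulative spliced coordinate in *genomic* order
        self._cum = np.concatenate(([0], np.cumsum(lens)))
        self.spliced_length = int(self._cum[-1])

    @property
    def junction_offsets(self) -> np.ndarray:
        """Transcript offsets of the first base of each downstream exon."""
        internal = self._cum[1:-1]
        if self.model.strand == "+":
            return internal.copy()
        return np.sort(self.spliced_length - internal)

    def transcript_to_genome(self, offsets):
        """Map transcript offset(s) to genomic position(s)."""
        t = np.asarray(offsets, dtype=np.int64)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        if ((t < 0) | (t >= self.spliced_length)).any():
            raise ValueError(
                f"{self.model.name}: transcript offset out of range "
                f"[0, {self.spliced_length})"
            )
        tg = t if self.model.strand == "+" else self.spliced_length - 1 - t
        i = np.searchsorted(self._cum, tg, side="right") - 1
        g = self._starts[i] + (tg - self._cum[i])
        return int(g[0]) if scalar else g

    def genome_to_transcript(self, positions):
        """Map genomic position(s) back to transcript offset(s).

        Raises ``ValueError`` for intronic or out-of-transcript positions.
        """
        g = np.asarray(positions, dtype=np.int64)
        scalar = g.ndim == 0
        g = np.atleast_1d(g)
        i = np.searchsorted(self._starts, g, side="right") - 1
        bad = (i < 0) | (g >= self._ends[np.clip(i, 0, len(self._ends) - 1)])
        if bad.any():
            raise ValueError(f"{self.model.name}: genomic position not exonic")
        tg = self._cum[i] + (g - self._starts[i])
        t = tg if self.model.strand == "+" else self.spliced_length - 1 - tg
        return int(t[0]) if scalar else t

    def region_blocks(self, t_start: int, t_end: int) -> list[tuple[int, int]]:
        """Genomic blocks (ascending, half-open) of transcript interval
        ``[t_start, t_end)``."""
        if not (0 <= t_start < t_end <= self.spliced_length):
            raise ValueError(
                f"{self.model.name}: bad transcript interval [{t_start}, {t_end})"
            )
        if self.model.strand == "+":
            a, b = t_start, t_end
        else:
            a, b = self.spliced_length - t_end, self.spliced_length - t_start
        i0 = int(np.searchsorted(self._cum, a, side="right") - 1)
        i1 = int(np.searchsorted(self._cum, b - 1, side="right") - 1)
        blocks = []
        for i in range(i0, i1 + 1):
            gs = int(self._starts[i] + max(0, a - self._cum[i]))
            ge = int(self._starts[i] + min(self._cum[i + 1] - self._cum[i], b - self._cum[i]))
            blocks.append((gs, ge))
        return blocks


def read_bed12(path, on_error: str = "raise") -> list[TranscriptModel]:
    """Read a BED12 file into a list of :class:`TranscriptModel`.

    Parameters
    ----------
    path : path-like
    on_error : {'raise', 'skip'}
        Fail fast on a malformed line, or log it and continue.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            try:
                models.append(TranscriptModel.from_bed12_line(line, lineno))
            except Bed12Error as exc:
                if on_error == "raise":
                    raise
                log.warning("skipping malformed BED12 record: %s", exc)
    return models


def write_bed12(models: Iterable[TranscriptModel], path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for m in models:
            fh.write(m.to_bed12_line() + "\n")


def read_gene_map(path) -> dict[str, str]:
    """Read a 2-column TSV mapping transcript name -> gene name."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            mapping[parts[0]] = parts[1]
    return mapping


def longest_isoform_per_gene(
    models: Sequence[TranscriptModel],
    gene_of: Mapping[str, str] | Callable[[str], str] | None = None,
    *,
    separator: str | None = None,
) -> list[TranscriptModel]:
    """Keep one transcript per gene: the longest spliced isoform.

    Ties are broken by the lexicographically smallest transcript name so the
    result is deterministic. Gene grouping comes from ``gene_of`` (a mapping
    or callable on the transcript name), or from the name prefix before
    ``separator``; with neither, each transcript is its own gene and the
    input is returned unchanged (deduplicated by name).
    """
    if gene_of is not None and separator is not None:
        raise ValueError("pass either gene_of or separator, not both")

    def key(name: str) -> str:
        if callable(gene_of):
            return gene_of(name)
        if gene_of is not None:
            try:
                return gene_of[name]
            except KeyError:
                raise KeyError(f"gene_of has no entry for transcript {name!r}") from None
        if separator is not None:
            return name.split(separator)[0]
        return name

    best: dict[str, TranscriptModel] = {}
    order: list[str] = []
    for m in models:
        g = key(m.name)
        cur = best.get(g)
        if cur is None:
            best[g] = m
            order.append(g)
        elif m.spliced_length > cur.spliced_length or (
            m.spliced_length == cur.spliced_length and m.name < cur.name
        ):
            best[g] = m
    return [best[g] for g in order]
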