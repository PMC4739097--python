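"""Synthetic degraded RNA-seq libraries with per-transcript ground truth.

The generator emulates a poly-A RNA-seq experiment on a synthetic multi-exon
transcriptome:

1. a genome with one contig per gene, each carrying one multi-exon
   transcript on a random strand;
2. per-transcript expression weights drawn log-normally;
3. in vitro degradation: hydrolysis cuts arrive along each molecule at
   rate ``degradation_rate`` (cuts per nucleotide), and oligo-dT selection
   keeps only the 3'-terminal piece, so every molecule is truncated at a
   single decay point and the surviving 3'-anchored piece has exponential
   length min(Exp(rate), L). Longer transcripts therefore retain a smaller
   fraction of their body - the length susceptibility degraded libraries
   show in practice;
4. fragmentation of the surviving molecule by a random-phase circular
   tiling: every piece carries an exact draw from the configured
   fragment-size distribution, the final piece's tail overlapping territory
   already tiled. The random phase makes base-level coverage of the
   retained region stationary - no artificial dips at molecule ends - and
   by Wald's identity the pooled piece mean equals the configured fragment
   mean. A piece whose arc crosses the molecule boundary is emitted as a
   discordant (non-proper) pair clipped at the boundary: its reads
   contribute coverage but fragment-size estimators reject it, just as
   discordant pairs are rejected on real data, so accepted proper pairs
   follow the configured size distribution;
5. paired-end read emission with splice-aware CIGARs, written directly as a
   coordinate-sorted, indexed BAM (no aligner: coverage truth is exact).

Every random draw comes from one seeded generator, so a fixed config yields
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .gene_models import CoordinateMap, TranscriptModel, write_bed12

from ._util import atomic_write

__all__ = ["SimConfig", "SimResult", "simulate_library", "expected_retained_fraction"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic library.

    ``degradation_rate`` is the hydrolysis intensity in cut events per
    nucleotide: 0 means intact RNA; 4e-3 (mean surviving 3' piece of 250 nt)
    is severe degradation. Fragment sizes are in nucleotides of the spliced
    molecule.
    """

    n_genes: int = 200
    exon_count_range: tuple[int, int] = (2, 8)  # inclusive
    exon_length_log_mean: float = math.log(300.0)
    exon_length_log_sd: float = 0.6
    exon_length_min: int = 50
    exon_length_max: int = 5000
    intron_length_log_mean: float = math.log(800.0)
    intron_length_log_sd: float = 0.8
    intron_length_min: int = 60
    intron_length_max: int = 20000
    expression_log_sd: float = 1.0
    degradation_rate: float = 0.0
    oligo_dt: bool = True
    fragment_mean: float = 250.0
    fragment_sd: float = 50.0
    read_length: int = 50
    n_read_pairs: int = 200_000
    min_molecule_length: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.degradation_rate < 0:
            raise ValueError("degradation_rate must be >= 0")
        for name in ("fragment_mean", "fragment_sd", "read_length", "n_read_pairs",
                     "n_genes", "min_molecule_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SimResult:
    bed_path: Path
    bam_path: Path
    truth_path: Path
    models: list[TranscriptModel]
    config: SimConfig


def expected_retained_fraction(rate: float, length: int, oligo_dt: bool = True) -> float:
    """Expected surviving fraction of a transcript whose 3'-anchored piece
    has length min(Exp(rate), length): (1 - exp(-rate*L)) / (rate*L).
    Without oligo-dT selection both pieces remain, so the fraction is 1."""
    if rate <= 0 or not oligo_dt:
        return 1.0
    u = rate * length
    return (1.0 - math.exp(-u)) / u


def _build_transcriptome(cfg: SimConfig, rng: np.random.Generator):
    models = []
    lo, hi = cfg.exon_count_range
    for g in range(cfg.n_genes):
        n_ex = int(rng.integers(lo, hi + 1))
        ex = np.clip(
            np.rint(rng.lognormal(cfg.exon_length_log_mean, cfg.exon_length_log_sd, n_ex)),
            cfg.exon_length_min, cfg.exon_length_max,
        ).astype(int)
        inr = np.clip(
            np.rint(rng.lognormal(cfg.intron_length_log_mean, cfg.intron_length_log_sd,
                                  max(n_ex - 1, 0))),
            cfg.intron_length_min, cfg.intron_length_max,
        ).astype(int)
        exons = []
        pos = 100
        for i in range(n_ex):
            exons.append((pos, pos + int(ex[i])))
            pos += int(ex[i])
            if i < n_ex - 1:
                pos += int(inr[i])
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(
            TranscriptModel(
                name=f"tx{g:04d}", chrom=f"chr{g:04d}", strand=strand,
                exons=tuple(exons),
            )
        )
    return models


def _tile_molecule(lr: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Piece lengths tiling a molecule of length ``lr`` on a circle.

    Pieces are drawn from the configured fragment-size distribution until the
    running total first exceeds ``lr`` (a stopping time), every piece keeping
    its exact drawn length: the final piece's tail simply overlaps territory
    already tiled. By Wald's identity the pooled piece mean over many
    molecules equals ``fragment_mean`` exactly. Pieces are clipped into
    [20, lr]; at the default settings the lower clip is a < 1e-5 tail event
    and the upper clip only fires for molecules shorter than a fragment.
    """
    fm, fs = cfg.fragment_mean, cfg.fragment_sd
    pieces: list[int] = []
    tot = 0
    while tot <= lr:
        f = int(min(max(round(rng.normal(fm, fs)), 20), lr))
        pieces.append(f)
        tot += f
    return np.array(pieces, dtype=int)


def simulate_library(config: SimConfig, out_dir, *, emit_fasta: bool = False) -> SimResult:
    """Generate (BED12 gene model, coordinate-sorted indexed BAM, truth TSV).

    Raises ``ValueError`` when the configuration yields no sequenceable
    fragment (for example, extreme degradation of a short transcriptome).
    """
    cfg = config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    models = _build_transcriptome(cfg, rng)
    lengths = np.array([m.spliced_length for m in models], dtype=int)
    weights = rng.lognormal(0.0, cfg.expression_log_sd, cfg.n_genes)
    weights = weights / weights.sum()

    lam = cfg.degradation_rate
    read_len = cfg.read_length

    # truth accumulators
    n_mol = np.zeros(cfg.n_genes, dtype=int)
    retained_sum = np.zeros(cfg.n_genes)
    decile_pos = np.array(
        [[(length - 1) * d // 9 for d in range(10)] for length in lengths], dtype=int
    )
    surv = np.zeros((cfg.n_genes, 10), dtype=int)

    # read records: (gene, t0, t1, mate2_t0, mate2_t1, proper)
    pair_genes: list[int] = []
    pairs: list[tuple[int, int, int, int, bool]] = []

    target = cfg.n_read_pairs
    batch = max(1024, target // 16)
    attempts = 0
    max_attempts = 200 * target + 100_000
    done = False
    while not done:
        gi = rng.choice(cfg.n_genes, size=batch, p=weights)
        length_b = lengths[gi]
        if lam > 0:
            x = rng.exponential(1.0 / lam, size=batch)
        else:
            x = np.full(batch, np.inf)
        u_piece = rng.random(batch)  # piece choice when oligo_dt is off
        # random hydrolysis at rate lam: the 3'-anchored surviving piece has
        # length min(Exp(lam), L), i.e. one truncation at the most-3' cut
        retained = np.minimum(np.ceil(x), length_b).astype(int)
        cut = length_b - retained  # transcript offset of the truncation; 0 = intact

        # truth bookkeeping (degradation only, independent of sequencing)
        s_truth = cut
        np.add.at(n_mol, gi, 1)
        if cfg.oligo_dt:
            np.add.at(retained_sum, gi, (length_b - s_truth) / length_b)
            for d in range(10):
                np.add.at(surv[:, d], gi, (decile_pos[gi, d] >= s_truth).astype(int))
        else:
            np.add.at(retained_sum, gi, 1.0)
            surv_all = np.ones(batch, dtype=int)
            for d in range(10):
                np.add.at(surv[:, d], gi, surv_all)

        for b in range(batch):
            attempts += 1
            g = int(gi[b])
            length = int(length_b[b])
            c = int(cut[b])
            if cfg.oligo_dt or c == 0:
                m0, m1 = c, length
            else:
                # no poly-A selection: both pieces of the cut molecule stay
                # in the pool, sampled in proportion to their length
                if u_piece[b] * length < c:
                    m0, m1 = 0, c
                else:
                    m0, m1 = c, length
            lr = m1 - m0
            if lr < cfg.min_molecule_length:
                continue
            plens = _tile_molecule(lr, cfg, rng)
            # Circular tiling phase: the molecule boundary (seam) is placed
            # inside a piece chosen uniformly among pieces - a uniform phase
            # would pick the seam piece length-biased and skew the sizes of
            # the surviving proper pairs - at a uniform offset within it.
            j = int(rng.integers(0, len(plens)))
            seam_off = int(rng.random() * plens[j])
            w = (lr - seam_off - int(plens[:j].sum())) % lr
            off = 0
            for plen in plens:
                a0 = (w + off) % lr
                off += int(plen)
                a1 = a0 + int(plen)
                if a1 <= lr:  # ordinary linear piece: proper pair
                    t0 = m0 + a0
                    rl = min(read_len, int(plen))
                    pairs.append((t0, t0 + rl, t0 + int(plen) - rl, t0 + int(plen), True))
                else:  # piece wrapping the molecule boundary: discordant pair
                    p1 = lr - a0
                    p2 = a1 - lr
                    r1 = (m0 + a0, m0 + a0 + min(read_len, p1))
                    r2 = (m0 + max(0, p2 - read_len), m0 + p2)
                    pairs.append((r1[0], r1[1], r2[0], r2[1], False))
                pair_genes.append(g)
                if len(pairs) >= target:
                    done = True
                    break
            if done:
                break
        if not done and attempts >= max_attempts:
            if not pairs:
                raise ValueError(
                    "simulation produced no sequenceable fragment; check "
                    f"degradation_rate={lam}, min_molecule_length="
                    f"{cfg.min_molecule_length} against the transcript lengths"
                )
            break

    bed_path = out_dir / "sim.bed"
    bam_path = out_dir / "sim.bam"
    truth_path = out_dir / "sim_truth.tsv"
    write_bed12(models, bed_path)

    _write_bam(bam_path, models, pair_genes, pairs, cfg)
    pysam.index(str(bam_path))

    with atomic_write(truth_path) as fh:
        fh.write(
            "transcript\tchrom\tstrand\tspliced_length\texpression_weight\t"
            "degradation_rate\texpected_retained_fraction\tn_molecules\t"
            "realized_retained_fraction\t"
            + "\t".join(f"survival_q{d}" for d in range(10))
            + "\n"
        )
        for g, m in enumerate(models):
            exp_frac = expected_retained_fraction(lam, int(lengths[g]), cfg.oligo_dt)
            if n_mol[g] > 0:
                realized = retained_sum[g] / n_mol[g]
                sq = [f"{surv[g, d] / n_mol[g]:.4f}" for d in range(10)]
            else:
                realized = float("nan")
                sq = ["NA"] * 10
            fh.write(
                f"{m.name}\t{m.chrom}\t{m.strand}\t{lengths[g]}\t"
                f"{weights[g]:.6g}\t{lam:.6g}\t{exp_frac:.4f}\t{n_mol[g]}\t"
                f"{realized:.4f}\t" + "\t".join(sq) + "\n"
            )

    if emit_fasta:
        _write_fasta(out_dir / "sim_genome.fa", models, cfg)

    return SimResult(bed_path, bam_path, truth_path, models, cfg)


def _cigar_and_pos(cmap: CoordinateMap, t0: int, t1: int):
    blocks = cmap.region_blocks(t0, t1)
    cig = []
    for i, (bs, be) in enumerate(blocks):
        if i > 0:
            cig.append((3, bs - blocks[i - 1][1]))  # N gap
        cig.append((0, be - bs))  # M
    return blocks[0][0], blocks[-1][1], cig


def _write_bam(bam_path, models, pair_genes, pairs, cfg: SimConfig):
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": m.chrom, "LN": m.tx_end + 200} for m in models
        ],
    }
    cmaps = [CoordinateMap(m) for m in models]
    plus = [m.strand == "+" for m in models]

    recs = []  # (tid, pos, pair_idx, mate_idx, flag, cigar, end, mpos, tlen)
    for idx, (g, (a0, a1, b0, b1, proper)) in enumerate(zip(pair_genes, pairs)):
        cm = cmaps[g]
        p1, e1, c1 = _cigar_and_pos(cm, a0, a1)
        p2, e2, c2 = _cigar_and_pos(cm, b0, b1)
        # the transcript-5' read is genome-forward on '+' and reverse on '-';
        # CIGARs are always in genomic order
        if plus[g]:
            rev1, rev2 = False, True
        else:
            rev1, rev2 = True, False
        lo = min(p1, p2)
        hi = max(e1, e2)
        span = hi - lo
        t1 = span if p1 <= p2 else -span
        t2 = -t1 if t1 != 0 else 0
        f1 = 1 | 64 | (2 if proper else 0) | (16 if rev1 else 0) | (32 if rev2 else 0)
        f2 = 1 | 128 | (2 if proper else 0) | (16 if rev2 else 0) | (32 if rev1 else 0)
        recs.append((g, p1, idx, 0, f1, c1, p2, t1))
        recs.append((g, p2, idx, 1, f2, c2, p1, t2))

    recs.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bf:
        hdr = bf.header
        for tid, pos, idx, mate, flag, cig, mpos, tlen in recs:
            a = pysam.AlignedSegment(hdr)
            a.query_name = f"p{idx}"
            a.flag = flag
            a.reference_id = tid
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = cig
            a.next_reference_id = tid
            a.next_reference_start = mpos
            a.template_length = tlen
            bf.write(a)


def _write_fasta(path, models, cfg: SimConfig):
    # sequence content is never read back by the pipeline; emitted only for
    # external tools, deterministically from the config seed
    rng = np.random.default_rng(cfg.seed + 1)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    with atomic_write(path) as fh:
        for m in models:
            n = m.tx_end + 200
            seq = rng.integers(0, 4, size=n)
            fh.write(f">{m.chrom}\n")
            s = b"".join(alphabet[seq]).decode()
            for i in range(0, n, 80):
                fh.write(s[i : i + 80] + "\n")
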