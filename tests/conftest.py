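"""Shared fixtures: hand-built BAMs and session-scoped simulated libraries."""

from __future__ import annotations

import pysam
import pytest

from tinseq.gene_models import TranscriptModel
from tinseq.simulate import SimConfig, simulate_library


def build_bam(path, contigs: dict[str, int], reads: list[dict]) -> str:
    """Write a coordinate-sorted, indexed BAM from read dicts.

    Each read dict needs ``chrom``, ``pos``, ``cigar``; optional ``qname``,
    ``flag``, ``mapq``, ``mpos`` (mate position, defaults to pos).
    """
    path = str(path)
    names = list(contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": contigs[n]} for n in names],
    }
    reads = sorted(reads, key=lambda r: (names.index(r["chrom"]), r["pos"]))
    with pysam.AlignmentFile(path, "wb", header=header) as bf:
        for i, rd in enumerate(reads):
            a = pysam.AlignedSegment(bf.header)
            a.query_name = rd.get("qname", f"r{i}")
            a.flag = rd.get("flag", 0)
            a.reference_id = names.index(rd["chrom"])
            a.reference_start = rd["pos"]
            a.mapping_quality = rd.get("mapq", 60)
            a.cigarstring = rd["cigar"]
            if a.is_paired:
                a.next_reference_id = a.reference_id
                a.next_reference_start = rd.get("mpos", rd["pos"])
            bf.write(a)
    pysam.index(path)
    return path


def proper_pair(qname, chrom, pos1, cigar1, pos2, cigar2, mapq=60):
    """Two read dicts forming a forward/reverse proper pair (mate1 leftmost)."""
    return [
        dict(qname=qname, chrom=chrom, pos=pos1, cigar=cigar1, mapq=mapq,
             flag=99, mpos=pos2),
        dict(qname=qname, chrom=chrom, pos=pos2, cigar=cigar2, mapq=mapq,
             flag=147, mpos=pos1),
    ]


@pytest.fixture
def bam_factory(tmp_path):
    counter = {"n": 0}

    def make(contigs, reads, name=None):
        counter["n"] += 1
        return build_bam(tmp_path / (name or f"t{counter['n']}.bam"), contigs, reads)

    return make


@pytest.fixture
def two_exon_model():
    """Spliced length 900: exons (100, 500) + (1500, 2000), 1000 nt intron."""
    return TranscriptModel("txA", "chr1", "+", ((100, 500), (1500, 2000)))


# ---------------------------------------------------------------------------
# session-scoped simulated libraries (shared by acceptance + module tests)

DEGRADATION_GRID = (0.0, 0.5e-3, 1e-3, 2e-3, 4e-3)


@pytest.fixture(scope="session")
def sim_grid(tmp_path_factory):
    """Five libraries over the degradation grid: 200 genes, 200k pairs each."""
    root = tmp_path_factory.mktemp("sim_grid")
    results = []
    for i, lam in enumerate(DEGRADATION_GRID):
        cfg = SimConfig(
            n_genes=200, n_read_pairs=200_000, degradation_rate=lam, seed=100 + i
        )
        results.append(simulate_library(cfg, root / f"lam{i}"))
    return results


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """One small intact library for CLI / geometry tests."""
    root = tmp_path_factory.mktemp("small_sim")
    cfg = SimConfig(n_genes=25, n_read_pairs=6000, degradation_rate=0.0, seed=42)
    return simulate_library(cfg, root)
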