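"""Fragment-size estimation: pair geometry, intron subtraction, filters."""

import pysam
import pytest

from tinseq.fragsize import (
    SingleEndError,
    pair_fragment_size,
    sample_fragment_size,
    transcript_fragment_size,
)
from tinseq.gene_models import TranscriptModel
from conftest import proper_pair


def fetch_pair(bam, qname):
    reads = [r for r in pysam.AlignmentFile(bam).fetch() if r.query_name == qname]
    assert len(reads) == 2
    return reads


class TestPairFragmentSize:
    def test_same_exon_plain_span(self, bam_factory, two_exon_model):
        bam = bam_factory(
            {"chr1": 2200}, proper_pair("p", "chr1", 100, "50M", 276, "50M")
        )
        size, reason = pair_fragment_size(*fetch_pair(bam, "p"), two_exon_model)
        assert (size, reason) == (226, None)

    def test_intron_subtracted_across_exons(self, bam_factory):
        # genomic span 100..1326 = 1226; minus the 1000 nt intron -> 226
        model = TranscriptModel("txB", "chr1", "+", ((100, 276), (1276, 2000)))
        bam = bam_factory(
            {"chr1": 2200}, proper_pair("p", "chr1", 100, "50M", 1276, "50M")
        )
        size, reason = pair_fragment_size(*fetch_pair(bam, "p"), model)
        assert (size, reason) == (226, None)

    def test_spliced_mate_gap_handled_by_same_rule(self, bam_factory, two_exon_model):
        # mate 2 itself crosses the junction with an N gap
        bam = bam_factory(
            {"chr1": 2200},
            proper_pair("p", "chr1", 300, "50M", 470, "30M1000N20M"),
        )
        size, reason = pair_fragment_size(*fetch_pair(bam, "p"), two_exon_model)
        assert (size, reason) == ((1520 - 300) - 1000, None)

    def test_low_mapq_rejected(self, bam_factory, two_exon_model):
        bam = bam_factory(
            {"chr1": 2200}, proper_pair("p", "chr1", 100, "50M", 276, "50M", mapq=20)
        )
        size, reason = pair_fragment_size(*fetch_pair(bam, "p"), two_exon_model)
        assert (size, reason) == (None, "low-mapq")

    def test_same_strand_pair_rejected(self, bam_factory, two_exon_model):
        reads = [
            dict(qname="p", chrom="chr1", pos=100, cigar="50M", flag=65, mpos=276),
            dict(qname="p", chrom="chr1", pos=276, cigar="50M", flag=129, mpos=100),
        ]
        bam = bam_factory({"chr1": 2200}, reads)
        size, reason = pair_fragment_size(*fetch_pair(bam, "p"), two_exon_model)
        assert (size, reason) == (None, "orientation")

    def test_reverse_before_forward_rejected(self, bam_factory, two_exon_model):
        reads = [
            dict(qname="p", chrom="chr1", pos=100, cigar="50M", flag=83, mpos=276),
            dict(qname="p", chrom="chr1", pos=276, cigar="50M", flag=163, mpos=100),
        ]
        bam = bam_factory({"chr1": 2200}, reads)
        size, reason = pair_fragment_size(*fetch_pair(bam, "p"), two_exon_model)
        assert (size, reason) == (None, "orientation")

    def test_intronic_alignment_rejected_off_model(self, bam_factory, two_exon_model):
        bam = bam_factory(
            {"chr1": 2200}, proper_pair("p", "chr1", 100, "50M", 600, "50M")
        )
        size, reason = pair_fragment_size(*fetch_pair(bam, "p"), two_exon_model)
        assert (size, reason) == (None, "off-model")


def pairs_of_size(chrom, exon_start, sizes, start_step=3):
    """Proper pairs inside one exon with the requested spliced sizes."""
    reads = []
    for i, s in enumerate(sizes):
        pos = exon_start + (i * start_step) % 50
        reads += proper_pair(f"q{i}", chrom, pos, "50M", pos + s - 50, "50M")
    return reads


class TestTranscriptLevel:
    def test_min_pairs_filter(self, bam_factory):
        model = TranscriptModel("tx", "chr1", "+", ((0, 1000),))
        bam29 = bam_factory({"chr1": 1100}, pairs_of_size("chr1", 0, [200] * 29))
        assert transcript_fragment_size(bam29, model, min_pairs=30) is None
        bam30 = bam_factory({"chr1": 1100}, pairs_of_size("chr1", 0, [200] * 30))
        est = transcript_fragment_size(bam30, model, min_pairs=30)
        assert est.n_pairs == 30 and est.mean_size == pytest.approx(200.0)

    def test_mean_of_mixture(self, bam_factory):
        model = TranscriptModel("tx", "chr1", "+", ((0, 1000),))
        bam = bam_factory(
            {"chr1": 1100}, pairs_of_size("chr1", 0, [100] * 30 + [300] * 30)
        )
        est = transcript_fragment_size(bam, model, min_pairs=30)
        assert est.mean_size == pytest.approx(200.0)
        assert est.n_pairs == 60


class TestSampleLevel:
    def test_pair_weighted_pooling(self, bam_factory):
        m1 = TranscriptModel("t1", "chr1", "+", ((0, 1000),))
        m2 = TranscriptModel("t2", "chr2", "+", ((0, 1000),))
        reads = pairs_of_size("chr1", 0, [200])
        reads += [
            r
            for i, s in enumerate([400, 400])
            for r in proper_pair(f"w{i}", "chr2", 10 * i, "50M", 10 * i + s - 50, "50M")
        ]
        bam = bam_factory({"chr1": 1100, "chr2": 1100}, reads)
        est = sample_fragment_size(bam, [m1, m2])
        assert est.n_pairs == 3
        assert est.mean_size == pytest.approx(1000 / 3)

    def test_single_end_input_unsupported(self, bam_factory):
        m = TranscriptModel("t", "chr1", "+", ((0, 1000),))
        reads = [dict(chrom="chr1", pos=10 * i, cigar="50M") for i in range(20)]
        bam = bam_factory({"chr1": 1100}, reads)
        with pytest.raises(SingleEndError):
            sample_fragment_size(bam, [m])

    def test_no_accepted_pairs_is_an_error(self, bam_factory):
        m = TranscriptModel("t", "chr1", "+", ((0, 1000),))
        bam = bam_factory(
            {"chr1": 1100}, proper_pair("p", "chr1", 0, "50M", 150, "50M", mapq=5)
        )
        with pytest.raises(ValueError, match="no read pair"):
            sample_fragment_size(bam, [m])

    def test_rejection_counters_reported(self, bam_factory):
        m = TranscriptModel("t", "chr1", "+", ((0, 1000),))
        reads = proper_pair("ok", "chr1", 0, "50M", 150, "50M")
        reads += proper_pair("bad", "chr1", 0, "50M", 150, "50M", mapq=5)
        bam = bam_factory({"chr1": 1100}, reads)
        est = sample_fragment_size(bam, [m])
        assert est.n_pairs == 1
        assert est.rejections == {"low-mapq": 1}


def test_sample_mean_is_pair_weighted_mean_of_transcript_means(sim_grid):
    """On simulated data the pooled sample mean equals the pair-count-weighted
    mean of transcript-level means computed from the same accepted pairs."""
    res = sim_grid[0]
    models = res.models[:40]
    ests = []
    for m in models:
        e = transcript_fragment_size(str(res.bam_path), m, min_pairs=1)
        if e is not None:
            ests.append(e)
    pooled = sample_fragment_size(str(res.bam_path), models)
    weighted = sum(e.mean_size * e.n_pairs for e in ests) / sum(e.n_pairs for e in ests)
    assert pooled.n_pairs == sum(e.n_pairs for e in ests)
    assert pooled.mean_size == pytest.approx(weighted, abs=1e-9)
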