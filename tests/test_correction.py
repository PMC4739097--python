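"""Loess fitting, TIN-based count correction, and 3' tag counting."""

import numpy as np
import pandas as pd
import pytest

from tinseq.correction import (
    correct_table,
    loess_correct,
    loess_fit,
    three_prime_region,
    three_prime_tag_count,
)
from tinseq.gene_models import TranscriptModel
from conftest import proper_pair


class TestLoessFit:
    def test_matches_statsmodels_local_linear(self):
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(0)
        for n, frac in [(201, 0.37), (157, 0.5), (99, 0.66)]:
            x = np.sort(rng.uniform(0, 10, n))
            y = np.sin(x) + rng.normal(0, 0.3, n)
            sm = lowess(y, x, frac=frac, it=0, return_sorted=False)
            assert np.allclose(loess_fit(x, y, span=frac, degree=1), sm, atol=1e-10)

    def test_matches_wls_oracle_degree_two(self):
        """At each point the loess value must equal an explicit tricube-
        weighted quadratic least-squares fit (statsmodels WLS oracle)."""
        import statsmodels.api as smapi

        rng = np.random.default_rng(1)
        n, span = 120, 0.6
        x = np.sort(rng.uniform(0, 5, n))
        y = x ** 2 - 3 * x + rng.normal(0, 0.2, n)
        fitted = loess_fit(x, y, span=span, degree=2)
        q = int(span * n)
        for i in rng.choice(n, 12, replace=False):
            d = np.abs(x - x[i])
            h = np.sort(d)[q - 1]
            w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
            design = np.column_stack([np.ones(n), x - x[i], (x - x[i]) ** 2])
            res = smapi.WLS(y, design, weights=w).fit()
            assert fitted[i] == pytest.approx(res.params[0], abs=1e-8)

    def test_exact_on_quadratic_data(self):
        x = np.linspace(0, 1, 60)
        y = 2 + 3 * x - 5 * x ** 2
        assert np.allclose(loess_fit(x, y, span=0.5, degree=2), y, atol=1e-10)

    def test_bad_span_rejected(self):
        with pytest.raises(ValueError):
            loess_fit(np.arange(10.0), np.arange(10.0), span=0.0)


def synthetic_sample(rng, n=2000, slope=0.05, noise=0.5, intercept=5.0):
    tins = rng.uniform(20, 95, n)
    log_counts = intercept + slope * tins + rng.normal(0, noise, n)
    counts = np.exp2(log_counts) - 1
    return counts, tins


class TestLoessCorrect:
    def test_tin_independent_counts_pass_nearly_unchanged(self):
        rng = np.random.default_rng(2)
        counts, tins = synthetic_sample(rng, n=1000, slope=0.0)
        res = loess_correct(counts, tins)
        ratio = np.abs(res.log_corrected - np.log2(counts + 1))
        assert ratio.mean() < 0.05

    def test_linear_trend_removed(self):
        rng = np.random.default_rng(3)
        counts, tins = synthetic_sample(rng, n=1000, slope=0.05)
        res = loess_correct(counts, tins)
        r_after = np.corrcoef(res.log_corrected[res.fitted], tins[res.fitted])[0, 1]
        assert abs(res.diagnostics["r_before"]) > 0.5
        assert abs(r_after) < 0.05

    def test_log_scale_median_preserved(self):
        rng = np.random.default_rng(4)
        counts, tins = synthetic_sample(rng, n=800, slope=0.03)
        res = loess_correct(counts, tins)
        before = np.median(np.log2(counts[res.fitted] + 1))
        after = np.median(res.log_corrected[res.fitted])
        assert after == pytest.approx(before, abs=1e-6)

    def test_rank_order_preserved_among_equal_tin_genes(self):
        rng = np.random.default_rng(5)
        tins = np.repeat(rng.uniform(30, 90, 40), 10)
        counts = np.exp2(4 + 0.05 * tins + rng.normal(0, 1, 400)) - 1
        res = loess_correct(counts, tins)
        for t in np.unique(tins):
            grp = tins == t
            order_in = np.argsort(counts[grp])
            order_out = np.argsort(res.corrected[grp])
            assert (order_in == order_out).all()

    def test_constant_tin_degenerate_warns_and_passes_through(self):
        counts = np.arange(1.0, 101.0)
        tins = np.full(100, 70.0)
        with pytest.warns(UserWarning, match="constant"):
            res = loess_correct(counts, tins)
        assert np.array_equal(res.corrected, counts)

    def test_too_few_fit_genes_rejected(self):
        rng = np.random.default_rng(6)
        counts, tins = synthetic_sample(rng, n=20)
        with pytest.raises(ValueError, match="at least 30"):
            loess_correct(counts, tins)

    def test_zero_count_and_zero_tin_genes_pass_through(self):
        rng = np.random.default_rng(7)
        counts, tins = synthetic_sample(rng, n=200)
        counts[:5] = 0.0
        tins[5:10] = 0.0
        res = loess_correct(counts, tins)
        assert not res.fitted[:10].any()
        assert np.array_equal(res.corrected[:10], counts[:10])


class TestCorrectTable:
    def _tables(self, rng, n=200, samples=("s1", "s2")):
        counts = {}
        tins = {}
        for s in samples:
            c, t = synthetic_sample(rng, n=n, slope=0.04)
            counts[s], tins[s] = c, t
        genes = [f"g{i}" for i in range(n)]
        return (pd.DataFrame(counts, index=genes), pd.DataFrame(tins, index=genes))

    def test_per_sample_diagnostics(self):
        rng = np.random.default_rng(8)
        counts, tins = self._tables(rng)
        corrected, diag = correct_table(counts, tins)
        assert corrected.shape == counts.shape
        assert set(diag.index) == {"s1", "s2"}
        assert (diag["n_fit"] > 0).all()

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        counts, tins = self._tables(rng)
        with pytest.raises(ValueError, match="share"):
            correct_table(counts, tins.iloc[::-1])

    def test_integerize_yields_integers(self):
        rng = np.random.default_rng(10)
        counts, tins = self._tables(rng, samples=("s1",))
        corrected, _ = correct_table(counts, tins, integerize=True)
        assert (corrected["s1"] == corrected["s1"].round()).all()


class TestThreePrimeRegion:
    def spliced_walk_oracle(self, model, n):
        """Independent oracle: list exonic genomic positions in transcript
        order, take the last min(n, L), return as a position set."""
        positions = []
        for s, e in model.exons:
            positions.extend(range(s, e))
        if model.strand == "-":
            positions = positions[::-1]
        tail = positions[-min(n, len(positions)):]
        return set(tail)

    @pytest.mark.parametrize(
        "exons,strand,n",
        [
            (((0, 100), (900, 1100)), "+", 250),
            (((0, 100), (900, 1100)), "-", 250),
            (((0, 150),), "+", 250),  # window clamps to whole transcript
            (((10, 60), (100, 220), (500, 800)), "-", 137),
            (((10, 60), (100, 220), (500, 800)), "+", 1),
        ],
    )
    def test_matches_coordinate_walk(self, exons, strand, n):
        model = TranscriptModel("t", "chr1", strand, exons)
        blocks = three_prime_region(model, n)
        got = set()
        for s, e in blocks:
            got.update(range(s, e))
        assert got == self.spliced_walk_oracle(model, n)

    def test_plus_strand_worked_example(self):
        model = TranscriptModel("t", "chr1", "+", ((0, 100), (900, 1100)))
        assert three_prime_region(model, 250) == [(50, 100), (900, 1100)]

    def test_n_must_be_positive(self):
        model = TranscriptModel("t", "chr1", "+", ((0, 100),))
        with pytest.raises(ValueError):
            three_prime_region(model, 0)


class TestTagCount:
    def test_five_prime_read_not_counted(self, bam_factory):
        model = TranscriptModel("t", "chr1", "+", ((0, 1000),))
        reads = proper_pair("five", "chr1", 10, "50M", 200, "50M")
        reads += proper_pair("three", "chr1", 800, "50M", 940, "50M")
        bam = bam_factory({"chr1": 1100}, reads)
        assert three_prime_tag_count(bam, model, n=250) == 2  # both 3' mates
        assert three_prime_tag_count(bam, model, n=1000) == 4

    def test_monotone_in_n_up_to_total(self, small_sim):
        from tinseq.coverage import DEFAULT_FILTER, count_overlapping_reads

        model = small_sim.models[0]
        prev = 0
        for n in (50, 250, 500, 1000, model.spliced_length):
            c = three_prime_tag_count(str(small_sim.bam_path), model, n=n)
            assert c >= prev
            prev = c
        total = count_overlapping_reads(
            str(small_sim.bam_path), model.chrom,
            list(model.exons), DEFAULT_FILTER,
        )
        assert prev == total
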