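# Methods

This note documents the models, conventions and tunable parameters behind
`tinseq`, the reasoning for the choices that were genuinely open, and what
the synthetic libraries do and do not establish about real data.

## Coordinates and gene models

All genomic coordinates are 0-based, half-open (BED convention), the only
standard format the package consumes. Transcript coordinates always run
5′→3′ of the mRNA: offset 0 is the transcription start site, which on the
minus strand is genomic position `tx_end − 1`. Junction offsets are the
transcript offset of the first base of each downstream exon; a transcript
with `e` exons contributes `e − 1` junctions. BED12 carries no gene
identifier, so isoform grouping for the longest-isoform rule defaults to
"each transcript is its own gene" unless a transcript→gene map (2-column
TSV) or a name-prefix separator is supplied. Length ties break to the
lexicographically smallest transcript name so the reduction is
deterministic.

## TIN

TIN is computed from read depths at `k` equally spaced transcript positions
(default **k = 100**, nearest-integer half-up rounding over
`[0, L−1]`, so both transcript ends are always evaluated) united with all
junction offsets. The denominator is `m`, the number of *distinct*
evaluated positions: the k-grid and junctions can collide (and the grid
collapses entirely for transcripts shorter than k), and using `m` avoids
double-counting coincident positions.

Logarithms are natural. The uniformity `U = e^H` is the "numbers
equivalent" of the entropy — the effective count of equally covered
positions — only under `ln`, and that is what makes `TIN = 100·U/m` a
percentage of positions. TIN is clipped into `[0, 100]` against rounding
overshoot; with any positive depth it is mathematically confined to
`[100/m, 100]`.

Depth comes from aligned (M/=/X) reference bases only; deletions and splice
gaps contribute nothing, per SAM semantics. Both mates of a pair count
independently (no pair collapsing). The default read filter — mapq ≥ 30, no
secondary/supplementary/duplicate/QC-fail alignments — mirrors the
"uniquely mapped, high quality" convention used for fragment sizes; no
separate coverage filter is defined anywhere, and using one filter
everywhere keeps the modules consistent. Soft-clipped bases never count
(they are not aligned).

Transcripts whose mean sampled depth falls below **min_mean_depth = 10**
are reported with TIN 0 but flagged unscored: entropy on near-zero counts
is noise, and a default medTIN over expressed transcripts is the more
stable sample summary. Whether unexpressed transcripts belong in the median
is genuinely ambiguous, so both policies are implemented
(`include_skipped`); the default excludes them. An even number of scored
transcripts takes the mean of the two central values.

## Fragment sizes

A pair's fragment size is the half-open genomic span from the leftmost
aligned start to the rightmost aligned end, minus every model intron fully
contained in that span — i.e. the spliced length of the sequenced fragment.
A mate whose own alignment crosses a junction needs no special case: its N
gap is a model intron inside the span. Sizes are recomputed from aligned
coordinates rather than taken from TLEN, because TLEN knows nothing about
introns.

Pairs are accepted only when both mates pass mapq ≥ 30, are on the model's
contig in forward/reverse orientation with the forward mate leftmost, and
every aligned block lies inside the transcript's exons ("specifically
mapped to a transcript"); rejections are counted by reason (`low-mapq`,
`orientation`, `off-model`, `nonpositive`). Transcript-level estimates
require **min_pairs = 30** accepted pairs. The sample-level estimate pools
accepted pairs over all supplied transcripts (callers should reduce to one
longest isoform per gene first), counting each pair once; it is therefore
the pair-count-weighted mean of the transcript means. Single-end input
raises an explicit unsupported-input error — fragment sizes need pairs.
Restricting the sample level to on-model pairs (rather than raw TLEN of all
pairs) is a design choice: it is the definition under which the intron
subtraction is meaningful.

## Count correction

Within one sample, `y = log₂(count + 1)` is regressed on TIN by loess and
replaced with `y′ = (y − ŷ) − median(y − ŷ) + median(y)`, then
back-transformed to `2^{y′} − 1`, floored at 0 (count-based consumers need
non-negative values; `--integerize` rounds for strict count models,
`--log-output` skips the back-transform). Subtracting the residual median
makes median preservation exact rather than approximate; since the median
loess residual is itself ≈ 0, this coincides with the plain
`y − ŷ + median(y)` form to within ~10⁻² log₂ units.

The loess is a local quadratic with tricube weights, **span 0.75**, no
robustness iterations — the common defaults of the reference `loess`
implementations. The neighbourhood holds `floor(span·n)` points (the
R/statsmodels convention; the degree-1 special case reproduces statsmodels
`lowess` to machine precision, which the tests check). Genes with zero
count or TIN 0 (unscored) are excluded from the fit and pass through
unchanged; fewer than 30 fit genes is an error, and a near-constant TIN
vector (variance < 10⁻⁸) is degenerate — counts are returned unchanged
with a warning. Log scale with pseudocount 1 keeps the fit robust to
outliers and invertible at zero. Differential expression itself is out of
scope: the output is a corrected count matrix any DE tool can consume.

## 3′ tag counting and gene-body profiles

The 3′ window is the 3′-most `min(N, L)` *spliced* nucleotides (default
**N = 250**), mapped to genomic blocks strand-aware — on the minus strand
it is the leftmost genomic region. A read counts once if any aligned block
overlaps any window block; the count is non-decreasing in N and reaches the
total overlapping reads at N = L.

Gene-body profiles come in two anchors. Percentile mode averages each
transcript's spliced coverage into 100 equal-width bins (5′→3′), normalizes
the binned vector to sum 1 so every transcript contributes equal mass, and
averages across transcripts; transcripts shorter than **min_length = 100**
are excluded to avoid bin aliasing, and zero-coverage transcripts are
skipped. Base mode aligns the last **window = 1000** spliced bases of every
transcript at the transcription end site, normalizes per transcript, and
averages per offset — the view used to choose the 3′-tag window. The exact
normalization behind published profile figures is never stated anywhere;
the per-transcript-normalized mean is this package's documented choice, and
it makes the profile invariant to read-depth scaling (doubling every read
changes nothing).

## The simulator

The generator emulates a poly-A RNA-seq experiment well enough to exercise
every estimator against known truth, with alignments constructed directly
(no aligner, no sequencing errors), so coverage truth is exact.

* **Transcriptome** — one contig per gene; 2–8 exons with log-normal
  lengths (median 300 nt, log-sd 0.6, clipped to [50, 5000]), log-normal
  introns (median 800 nt), random strand. Spliced lengths land mostly in
  0.5–6 kb, a realistic mRNA range. Expression weights are log-normal
  (log-sd 1.0).
* **Degradation** — hydrolysis cuts arrive at `degradation_rate` λ (cuts
  per nucleotide); oligo-dT selection keeps the 3′-terminal piece, so each
  molecule survives as a 3′-anchored piece of length `min(Exp(λ), L)`. The
  expected retained fraction `(1 − e^{−λL})/(λL)` shrinks with transcript
  length — the mechanism behind both the 3′-skewed gene-body profile and
  the negative length–TIN correlation in degraded samples. λ = 4×10⁻³
  (mean surviving piece 250 nt) is severe degradation. With `oligo_dt`
  off, both pieces of the cut molecule stay in the pool (sampled by
  length), which reproduces the flat profiles of rRNA-depletion protocols.
* **Fragmentation** — the surviving molecule is tiled on a circle with
  pieces drawn *exactly* from the configured size distribution (default
  N(250, 50) nt), the final piece's tail overlapping already-tiled
  territory (a stopping-time construction: by Wald's identity the pooled
  piece mean equals the configured mean). The tiling phase places the
  molecule-boundary "seam" inside a piece chosen uniformly among pieces —
  a uniform phase would select it length-biased and shift the surviving
  sizes. Consequences, verified by the tests: base-level coverage of the
  retained region is stationary (no artificial end dips that would fake a
  length–TIN correlation in intact libraries), and the piece that wraps
  the molecule boundary is emitted as a discordant (non-proper) pair
  clipped at the boundary — its reads still contribute coverage, but
  geometry-based fragment-size estimation rejects it, exactly as
  discordant pairs are rejected on real data. Molecules shorter than
  **min_molecule_length = 100** nt are lost, as in real size selection.
* **Reads** — 50 nt from each fragment end, splice-aware CIGARs, mapq 60,
  proper-pair flags, written directly as a coordinate-sorted indexed BAM.
  All randomness flows from one seeded generator; a fixed config is
  byte-reproducible.
* **Truth table** — per transcript: expression weight, analytic and
  realized retained fraction, and the realized survival profile at ten
  body deciles.

What the simulator does *not* model: sequencing errors and quality strings,
GC/hexamer/mappability bias, multi-mapping, isoform mixtures within a
locus, or multiple independent cuts per molecule (a single effective 3′
truncation is the oligo-dT-visible summary of any number of cuts). Passing
tests therefore establish the estimators' correctness and the direction and
rough magnitude of degradation effects under idealized coverage — not
performance under real-library artefacts.

## Problem sizes and numerical conventions

The property tests and the acceptance script run the degradation grid
λ ∈ {0, 0.5, 1, 2, 4}×10⁻³ cuts/nt at 200 genes × 200 000 read pairs per
library, fragment-size recovery at 60 genes × 15 000 pairs, and the
correction benchmark on 2 000 synthetic genes with an imposed slope of 0.05
log₂ units per TIN point and noise sd 0.5 — sizes at which each effect is
measured with comfortable margin while a full run stays in the
single-minute range. TIN values are written with 2 decimals (doubles
internally); TSVs use '.' decimals regardless of locale; outputs are
written atomically (temp file + rename) and manifests carry no timestamps,
so identical inputs and parameters give byte-identical outputs.

## Known limitations

* TIN on very short transcripts (spliced length below k) evaluates every
  base; the score is still defined but `m < k`.
* The mean-depth threshold makes medTIN depend mildly on sequencing depth
  through which transcripts clear it.
* Fragment sizes are only defined for paired-end data, and the sample-level
  mean ignores pairs that fall outside the supplied gene models.
* The loess correction assumes a smooth count–TIN trend shared across the
  sample; gene-specific degradation responses orthogonal to TIN remain.
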