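"""Gene-body coverage diagnostics.

Two aggregate coverage views over a transcriptome:

* ``five_prime_percentile`` - each transcript's spliced coverage is averaged
  into 100 equal-width bins from the 5' end to the 3' end, normalized so the
  transcript contributes total mass 1, then averaged across transcripts.
  A 3'-skewed profile is the signature of degradation under oligo-dT
  selection.
* ``three_prime_base`` - base-resolution coverage of the last ``window``
  spliced nucleotides, all transcripts anchored at the transcription end
  site; used to choose the window for 3' tag counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .coverage import DEFAULT_FILTER, ReadFilter, open_bam, spliced_coverage
from .gene_models import TranscriptModel

from ._util import atomic_write

__all__ = ["BodyProfile", "gene_body_profile", "write_profile"]

ANCHORS = ("five_prime_percentile", "three_prime_base")


@dataclass
class BodyProfile:
    anchor: str
    x: np.ndarray  # percentile bin index 1..n_bins, or base offset 1..W from the 3' end
    y: np.ndarray  # mean normalized coverage
    n_transcripts: int


def gene_body_profile(
    bam,
    models: Iterable[TranscriptModel],
    anchor: str = "five_prime_percentile",
    *,
    read_filter: ReadFilter = DEFAULT_FILTER,
    min_length: int = 100,
    window: int = 1000,
    n_bins: int = 100,
) -> BodyProfile:
    """Aggregate normalized coverage profile over transcripts with nonzero
    coverage. Raises ``ValueError`` if no transcript qualifies."""
    if anchor not in ANCHORS:
        raise ValueError(f"anchor must be one of {ANCHORS}")
    if anchor == "three_prime_base" and window < 1:
        raise ValueError("window must be >= 1")
    af, opened = open_bam(bam)
    try:
        if anchor == "five_prime_percentile":
            acc = np.zeros(n_bins)
            n_used = 0
            for model in models:
                length = model.spliced_length
                if length < min_length:
                    continue
                cov = spliced_coverage(af, model, read_filter).astype(float)
                total = cov.sum()
                if total <= 0:
                    continue
                idx = (np.arange(length) * n_bins) // length
                sums = np.bincount(idx, weights=cov, minlength=n_bins)
                cnts = np.bincount(idx, minlength=n_bins)
                binmean = sums / np.maximum(cnts, 1)
                acc += binmean / binmean.sum()
                n_used += 1
            if n_used == 0:
                raise ValueError("no transcript passed the profile filters")
            return BodyProfile(anchor, np.arange(1, n_bins + 1), acc / n_used, n_used)

        sums = np.zeros(window)
        cnts = np.zeros(window)
        n_used = 0
        for model in models:
            cov = spliced_coverage(af, model, read_filter).astype(float)
            tail = cov[-window:][::-1]  # tail[0] = 3'-terminal base
            total = tail.sum()
            if total <= 0:
                continue
            sums[: len(tail)] += tail / total
            cnts[: len(tail)] += 1
            n_used += 1
        if n_used == 0:
            raise ValueError("no transcript passed the profile filters")
        y = sums / np.maximum(cnts, 1)
        return BodyProfile(anchor, np.arange(1, window + 1), y, n_used)
    finally:
        if opened:
            af.close()


def write_profile(profile: BodyProfile, path) -> None:
    xlab = "percentile" if profile.anchor == "five_prime_percentile" else "bases_from_3p_end"
    with atomic_write(path) as fh:
        fh.write(f"{xlab}\tmean_normalized_coverage\tn_transcripts\n")
        for xi, yi in zip(profile.x, profile.y):
            fh.write(f"{xi}\t{yi:.6g}\t{profile.n_transcripts}\n")
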