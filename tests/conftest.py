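"""Shared fixtures and per-base oracle helpers.

The oracles work on explicit boolean base masks of a toy chromosome:
an O(L) representation where every interval operation is a trivial
array operation.  They are deliberately independent of the sweep-line
implementations they check.
"""

import numpy as np
import pytest
from scipy.ndimage import binary_dilation

from captureseq.intervals import GenomicInterval


def mask_of(intervals, length, chrom=None):
    """Boolean per-base coverage mask of an interval collection."""
    m = np.zeros(length, dtype=bool)
    for iv in intervals:
        if chrom is None or iv.chrom == chrom:
            m[iv.start : iv.end] = True
    return m


def dilate_mask(mask, margin):
    """Grow every covered run by ``margin`` bases on each side."""
    if margin == 0 or not mask.any():
        return mask.copy()
    return binary_dilation(mask, structure=np.ones(2 * margin + 1, dtype=bool))


def mask_to_intervals(mask, chrom="c1"):
    """Maximal runs of True as intervals (the canonical merged form)."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)]


def min_gap(a, b):
    """Brute-force gap between two intervals on one chromosome."""
    return max(a.start - b.end, b.start - a.end, 0)


def random_intervals(rng, n, length, chrom="c1", max_len=500, named=False):
    out = []
    for i in range(n):
        s = int(rng.integers(0, length - 1))
        ln = int(rng.integers(1, min(max_len, length - s) + 1))
        out.append(
            GenomicInterval(chrom, s, s + ln, ".", f"iv{i}" if named else None)
        )
    return out


@pytest.fixture(scope="session")
def toy_annotation():
    from captureseq.simulate import generate_annotation

    return generate_annotation(n_genes=40, chrom_len=1_000_000, seed=11)
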