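"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from loopkit.core import GenomicInterval, Loop


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, max_width=2_000):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(chrom, start, start + width))
    return out


def random_loops(rng, n, chroms=("chr1", "chr2"), max_pos=500_000, anchor=5_000):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        a = int(rng.integers(0, max_pos)) // anchor * anchor
        b = a + anchor * int(rng.integers(4, 100))
        out.append(
            Loop(
                GenomicInterval(chrom, a, a + anchor),
                GenomicInterval(chrom, b, b + anchor),
                q_value=float(rng.uniform(1e-12, 1.0)),
                resolution=anchor,
            )
        )
    return out


# ---------------------------------------------------------------------------
# O(n*m) brute-force oracles, deliberately independent of the library path
# ---------------------------------------------------------------------------


def brute_overlap(a: GenomicInterval, b: GenomicInterval, slack: int = 0) -> bool:
    if a.chrom != b.chrom:
        return False
    return max(a.start - slack, 0) < b.end and b.start < a.end + slack


def brute_intersect(a_list, b_list, slack=0):
    return sorted(
        (i, j)
        for i, a in enumerate(a_list)
        for j, b in enumerate(b_list)
        if brute_overlap(a, b, slack)
    )


def brute_pair_pair(loops, pairs, slack=0):
    hits = set()
    for li, lp in enumerate(loops):
        for pi, (u, v) in enumerate(pairs):
            fwd = brute_overlap(lp.anchorA, u, slack) and brute_overlap(lp.anchorB, v, slack)
            rev = brute_overlap(lp.anchorA, v, slack) and brute_overlap(lp.anchorB, u, slack)
            if fwd or rev:
                hits.add((li, pi))
    return sorted(hits)
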