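"""Conserved anchors, GC-matched backgrounds, motif-pair bootstrap."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from loopkit.core import GenomicInterval, Loop, Peak
from loopkit.motifs import (
    AnchorUniverse,
    annotate_anchor_motifs,
    bootstrap_pair_enrichment,
    conserved_anchors,
    conserved_threshold,
    cross_sample_summary,
    exclude_blacklisted,
    filter_and_adjust,
    gc_content,
    gc_matched_background,
    observed_pair_counts,
    representative_peaks,
)
from loopkit.synth import SynthConfig, gen_motif_scenario


def _anchor(start, chrom="chr1", width=5000):
    return GenomicInterval(chrom, start, start + width)


def _loop(a, b, chrom="chr1", q=1e-4, sample="s"):
    return Loop(_anchor(a, chrom), _anchor(b, chrom), q_value=q, sample_id=sample)


class TestConservedAnchors:
    @pytest.mark.parametrize("n,expected", [(54, 44), (27, 22), (11, 9)])
    def test_eighty_percent_thresholds(self, n, expected):
        assert conserved_threshold(n, 0.8) == expected

    def test_anchor_below_threshold_excluded(self):
        n = 10  # threshold ceil(8.0) = 8
        shared = _anchor(0)
        near_miss = _anchor(100_000)
        per_sample = {}
        for k in range(n):
            anchors = {shared}
            if k < 7:  # one short of the threshold
                anchors.add(near_miss)
            per_sample[f"s{k}"] = anchors
        conserved, background = conserved_anchors(AnchorUniverse(per_sample), 0.8)
        assert shared in conserved and near_miss not in conserved
        assert near_miss in background

    def test_universe_from_loops(self):
        loops = [_loop(0, 50_000, sample="a"), _loop(0, 100_000, sample="b")]
        u = AnchorUniverse.from_loops(loops)
        assert u.n_samples == 2
        assert _anchor(0) in u.per_sample["a"] and _anchor(0) in u.per_sample["b"]


class TestGcBackground:
    def test_samples_from_matching_bin(self):
        fg = ["GCGC" * 10]  # GC = 1.0... use 0.5 instead
        fg = ["GCAT" * 10]  # GC = 0.5
        pool = ["GCAT" * 10] * 5 + ["GGGC" * 10] * 5  # 0.5 and 1.0 bins
        idx = gc_matched_background(fg * 4, pool, seed=0)
        assert all(j < 5 for j in idx)

    def test_output_size_equals_foreground(self):
        rng = np.random.default_rng(1)
        make = lambda gc, n: [
            "".join(rng.choice(list("GC"), 60)) if rng.random() < gc else
            "".join(rng.choice(list("AT"), 60))
            for _ in range(n)
        ]
        fg = make(0.5, 30)
        pool = make(0.5, 80)
        assert len(gc_matched_background(fg, pool, seed=2)) == 30

    def test_pool_smaller_than_foreground_rejected(self):
        with pytest.raises(ValueError):
            gc_matched_background(["AC"] * 3, ["AC"] * 2)

    def test_sampling_reduces_gc_distance(self):
        """Over 20 seeds, the KS distance between foreground GC and sampled
        background GC is below the distance to the unsampled pool."""
        rng = np.random.default_rng(7)

        def seqs(mean_gc, n):
            out = []
            for _ in range(n):
                gc = np.clip(rng.normal(mean_gc, 0.05), 0.05, 0.95)
                k = int(round(gc * 100))
                out.append("G" * k + "A" * (100 - k))
            return out

        fg = seqs(0.55, 60)
        pool = seqs(0.40, 300)  # pool shifted away from the foreground
        fg_gc = [gc_content(s) for s in fg]
        pool_gc = [gc_content(s) for s in pool]
        d_pool = ks_2samp(fg_gc, pool_gc).statistic
        for seed in range(20):
            idx = gc_matched_background(fg, pool, seed=seed)
            samp_gc = [pool_gc[j] for j in idx]
            assert ks_2samp(fg_gc, samp_gc).statistic < d_pool


class TestRepresentativePeaks:
    def test_highest_signal_wins(self):
        a = _anchor(10_000)
        peaks = [
            Peak(GenomicInterval("chr1", 11_000, 11_500), 5.0, name="low"),
            Peak(GenomicInterval("chr1", 12_000, 12_500), 9.0, name="high"),
        ]
        mapping, dedup = representative_peaks([a], peaks)
        assert mapping[a].name == "high" and len(dedup) == 1

    def test_signal_tie_broken_leftmost(self):
        a = _anchor(10_000)
        peaks = [
            Peak(GenomicInterval("chr1", 12_000, 12_500), 5.0, name="right"),
            Peak(GenomicInterval("chr1", 11_000, 11_500), 5.0, name="left"),
        ]
        mapping, _ = representative_peaks([a], peaks)
        assert mapping[a].name == "left"

    def test_shared_peak_deduplicated(self):
        anchors = [_anchor(10_000), _anchor(15_000)]
        big = Peak(GenomicInterval("chr1", 9_000, 21_000), 3.0, name="wide")
        mapping, dedup = representative_peaks(anchors, [big])
        assert len(mapping) == 2 and len(dedup) == 1

    def test_matches_brute_force(self, rng):
        anchors = [_anchor(int(s) * 5000) for s in rng.integers(0, 100, 40)]
        peaks = [
            Peak(
                GenomicInterval("chr1", int(s), int(s) + 800),
                float(rng.exponential(5)),
                name=f"p{k}",
            )
            for k, s in enumerate(rng.integers(0, 500_000, 120))
        ]
        mapping, _ = representative_peaks(anchors, peaks)
        for a in anchors:
            over = [p for p in peaks if a.overlaps(p.interval)]
            if not over:
                assert a not in mapping
            else:
                best = min(over, key=lambda p: (-p.signal_value, p.interval.start, p.interval.end))
                assert mapping[a] == best


class TestAnnotation:
    def test_occurrence_inside_representative_peak(self):
        a = _anchor(10_000)
        peak = Peak(GenomicInterval("chr1", 11_000, 11_500), 5.0)
        occ = pd.DataFrame(
            [
                {"motif_id": "M1", "chrom": "chr1", "start": 11_100, "end": 11_110},
                {"motif_id": "M2", "chrom": "chr1", "start": 90_000, "end": 90_010},
            ]
        )
        ann = annotate_anchor_motifs([a], occ, via={a: peak})
        assert ann[a] == frozenset({"M1"})

    def test_anchor_without_peak_empty(self):
        a = _anchor(10_000)
        occ = pd.DataFrame(
            [{"motif_id": "M1", "chrom": "chr1", "start": 11_100, "end": 11_110}]
        )
        ann = annotate_anchor_motifs([a], occ, via={})
        assert ann[a] == frozenset()


class TestBlacklist:
    def test_anchor_in_blacklist_dropped(self):
        loops = [_loop(10_000, 100_000), _loop(200_000, 300_000)]
        bl = [GenomicInterval("chr1", 101_000, 102_000)]  # inside anchorB of loop 0
        assert exclude_blacklisted(loops, bl) == [loops[1]]

    def test_touching_halfopen_kept(self):
        loops = [_loop(10_000, 100_000)]
        bl = [GenomicInterval("chr1", 15_000, 16_000)]  # anchorA ends at 15000
        assert exclude_blacklisted(loops, bl) == loops


class TestPairCounts:
    def test_single_pair(self):
        lp = _loop(0, 50_000)
        ann = {lp.anchorA: frozenset({"X"}), lp.anchorB: frozenset({"Y"})}
        assert observed_pair_counts([lp], ann) == Counter({("X", "Y"): 1})

    def test_multi_motif_enumeration(self):
        lp = _loop(0, 50_000)
        ann = {lp.anchorA: frozenset({"X", "Y"}), lp.anchorB: frozenset({"X"})}
        assert observed_pair_counts([lp], ann) == Counter({("X", "X"): 1, ("X", "Y"): 1})

    def test_matches_brute_force(self):
        loops, ann, _ = gen_motif_scenario(SynthConfig(seed=5, n_loops=100, n_motifs=6))
        got = observed_pair_counts(loops, ann)
        expected = Counter()
        for lp in loops:
            pairs = set()
            for a in ann.get(lp.anchorA, frozenset()):
                for b in ann.get(lp.anchorB, frozenset()):
                    pairs.add(tuple(sorted((a, b))))
            expected.update(pairs)
        assert got == expected


class TestBootstrap:
    def test_shuffle_invariant_annotation_gives_p_one(self):
        loops = [_loop(0, 50_000), _loop(100_000, 200_000)]
        ann = {a: frozenset({"X", "Y"}) for lp in loops for a in (lp.anchorA, lp.anchorB)}
        results = bootstrap_pair_enrichment(loops, ann, n_sims=50, seed=0)
        assert results and all(r.p_empirical == 1.0 for r in results)

    def test_same_seed_bit_reproducible(self):
        loops, ann, _ = gen_motif_scenario(SynthConfig(seed=5, n_loops=80, n_motifs=8))
        r1 = bootstrap_pair_enrichment(loops, ann, n_sims=100, seed=42)
        r2 = bootstrap_pair_enrichment(loops, ann, n_sims=100, seed=42)
        assert r1 == r2

    def test_planted_pair_most_significant(self):
        cfg = SynthConfig(seed=13, n_loops=200, n_motifs=10, pair_multiplier=5.0)
        loops, ann, truth = gen_motif_scenario(cfg)
        results = bootstrap_pair_enrichment(loops, ann, n_sims=500, seed=1)
        best = min(results, key=lambda r: (r.p_empirical, -r.observed_count))
        assert best.pair == truth["planted_pair"]
        assert best.p_empirical < 0.01


class TestAdjustment:
    def test_bh_hand_computation(self):
        from loopkit.motifs import MotifPairResult

        ps = [0.001, 0.01, 0.02, 0.8]
        results = [
            MotifPairResult(f"A{k}", f"B{k}", 5, p, 1000) for k, p in enumerate(ps)
        ]
        adjusted = filter_and_adjust(results, top_k=100)
        got = sorted(r.p_adjusted for r in adjusted)
        assert got == pytest.approx([0.004, 0.02, 0.02 * 4 / 3, 0.8])

    def test_all_ones_stay_ones(self):
        from loopkit.motifs import MotifPairResult

        results = [MotifPairResult(f"A{k}", f"B{k}", 1, 1.0, 10) for k in range(4)]
        assert all(r.p_adjusted == 1.0 for r in filter_and_adjust(results, 100))

    def test_top_k_restricts_both_members(self):
        from loopkit.motifs import MotifPairResult

        # M0 appears in 3 pairs, M1 in 2, M2 in 2, M9 in 1
        results = [
            MotifPairResult("M0", "M1", 5, 0.01, 100),
            MotifPairResult("M0", "M2", 5, 0.02, 100),
            MotifPairResult("M1", "M2", 5, 0.03, 100),
            MotifPairResult("M0", "M9", 5, 0.04, 100),
        ]
        kept = filter_and_adjust(results, top_k=3)  # top 3 = M0, M1, M2
        assert {(r.motif_a, r.motif_b) for r in kept} == {
            ("M0", "M1"), ("M0", "M2"), ("M1", "M2")
        }


class TestCrossSample:
    def test_proportions_and_denominators(self):
        from loopkit.motifs import MotifPairResult

        def res(a, b, p):
            return MotifPairResult(a, b, 3, p, 100, p_adjusted=p)

        per_sample = {
            "s1": [res("X", "Y", 0.01), res("X", "Z", 0.5)],
            "s2": [res("X", "Y", 0.02)],
            "s3": [res("X", "Y", 0.9)],
            "s4": [],  # pair never tested here: excluded from denominators
        }
        df = cross_sample_summary(per_sample, alpha=0.05)
        xy = df[(df.motif_a == "X") & (df.motif_b == "Y")].iloc[0]
        assert xy.n_tested == 3 and xy.n_significant == 2
        assert xy.proportion == pytest.approx(2 / 3)
        xz = df[(df.motif_a == "X") & (df.motif_b == "Z")].iloc[0]
        assert xz.n_tested == 1 and xz.proportion == 0.0
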