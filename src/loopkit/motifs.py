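"""Conserved-anchor analysis and motif-pair enrichment at loop anchors.

Conserved anchors are loop anchors called in at least ~80% of a sample set.
For 1D motif enrichment with an external scanner the module constructs a
GC-matched background: non-conserved anchors binned into 0.5% GC quantile
bins and sampled to match the conserved-anchor GC profile, one draw per
foreground sequence.

For motif *pairs*, loop anchors are annotated with motif occurrences falling
within their representative ChIP-seq peak (the highest-signal overlapping
peak), and pair significance is assessed by a block bootstrap: each
simulation redraws every loop's two anchors uniformly with replacement from
the same chromosome's anchor pool (annotations travelling with the anchors),
pair counts are recomputed, and the empirical p-value for a pair is the
add-one fraction of simulations with a count at or above the observed one.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval, Loop, Peak, intersect_with_slack

__all__ = [
    "AnchorUniverse",
    "MotifPairResult",
    "conserved_anchors",
    "gc_content",
    "gc_matched_background",
    "representative_peaks",
    "annotate_anchor_motifs",
    "exclude_blacklisted",
    "observed_pair_counts",
    "bootstrap_pair_enrichment",
    "filter_and_adjust",
    "cross_sample_summary",
]

MotifPair = tuple[str, str]


def _pair(a: str, b: str) -> MotifPair:
    """Canonical unordered pair (self-pairs allowed)."""
    return (a, b) if a <= b else (b, a)


@dataclass
class AnchorUniverse:
    """Per-sample sets of unique loop anchors, all at one resolution."""

    per_sample: dict[str, set[GenomicInterval]]

    @property
    def n_samples(self) -> int:
        return len(self.per_sample)

    @classmethod
    def from_loops(cls, loops: Sequence[Loop]) -> "AnchorUniverse":
        per_sample: dict[str, set[GenomicInterval]] = defaultdict(set)
        for lp in loops:
            per_sample[lp.sample_id].add(lp.anchorA)
            per_sample[lp.sample_id].add(lp.anchorB)
        return cls(dict(per_sample))


def conserved_threshold(n_samples: int, frac: float = 0.8) -> int:
    """Minimum number of samples an anchor must appear in: ceil(frac * n)."""
    if not (0.0 < frac <= 1.0):
        raise ValueError("frac must be in (0, 1]")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    return math.ceil(frac * n_samples)


def conserved_anchors(
    universe: AnchorUniverse, frac: float = 0.8
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Split the anchor universe into conserved anchors (present in
    >= ceil(frac * n) samples) and the non-conserved complement (used as the
    background pool). Both lists are sorted for determinism."""
    threshold = conserved_threshold(universe.n_samples, frac)
    counts: Counter[GenomicInterval] = Counter()
    for anchors in universe.per_sample.values():
        counts.update(anchors)
    conserved = sorted(a for a, c in counts.items() if c >= threshold)
    background = sorted(a for a, c in counts.items() if c < threshold)
    return conserved, background


# ---------------------------------------------------------------------------
# GC-matched background
# ---------------------------------------------------------------------------


def gc_content(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def gc_matched_background(
    foreground: Sequence[str],
    pool: Sequence[str],
    bin_width: float = 0.005,
    seed: int | None = None,
) -> list[int]:
    """Sample one pool sequence per foreground sequence from the matching GC
    quantile bin (0.5% bins by default). Returns indices into ``pool``.

    Draws are with replacement across foreground sequences (a bin may hold
    fewer pool sequences than foreground sequences mapping to it). An empty
    bin falls back to the nearest non-empty bin.
    """
    if not foreground or not pool:
        raise ValueError("foreground and pool must be non-empty")
    if len(pool) < len(foreground):
        raise ValueError("pool must be at least as large as the foreground")
    rng = np.random.default_rng(seed)
    n_bins = int(round(1.0 / bin_width))

    def bin_of(gc: float) -> int:
        return min(int(gc / bin_width), n_bins - 1)

    pool_bins: dict[int, list[int]] = defaultdict(list)
    for j, seq in enumerate(pool):
        pool_bins[bin_of(gc_content(seq))].append(j)
    occupied = sorted(pool_bins)

    chosen = []
    n_fallback = 0
    for seq in foreground:
        b = bin_of(gc_content(seq))
        if b not in pool_bins:
            n_fallback += 1
            b = min(occupied, key=lambda o: (abs(o - b), o))
        idxs = pool_bins[b]
        chosen.append(int(idxs[rng.integers(len(idxs))]))
    if n_fallback:
        import logging

        logging.getLogger(__name__).warning(
            "%d foreground sequences fell in empty GC bins; used nearest bin",
            n_fallback,
        )
    return chosen


# ---------------------------------------------------------------------------
# anchor annotation via representative peaks
# ---------------------------------------------------------------------------


def representative_peaks(
    anchors: Sequence[GenomicInterval],
    peaks: Sequence[Peak],
) -> tuple[dict[GenomicInterval, Peak], list[Peak]]:
    """Per anchor with >= 1 overlapping peak (no slack), the highest-signal
    peak (ties broken by leftmost start, then end). Also returns the
    deduplicated representative peak set — a single peak may represent
    several anchors but appears once."""
    peak_iv = [p.interval for p in peaks]
    best: dict[int, int] = {}
    for ai, pj in intersect_with_slack(list(anchors), peak_iv, slack=0):
        if ai not in best:
            best[ai] = pj
            continue
        cur = peaks[best[ai]]
        cand = peaks[pj]
        key_cur = (-cur.signal_value, cur.interval.start, cur.interval.end)
        key_cand = (-cand.signal_value, cand.interval.start, cand.interval.end)
        if key_cand < key_cur:
            best[ai] = pj
    mapping = {anchors[ai]: peaks[pj] for ai, pj in best.items()}
    dedup_idx = sorted(set(best.values()))
    return mapping, [peaks[j] for j in dedup_idx]


def annotate_anchor_motifs(
    anchors: Sequence[GenomicInterval],
    occurrences: pd.DataFrame,
    via: Mapping[GenomicInterval, Peak] | None = None,
) -> dict[GenomicInterval, frozenset[str]]:
    """Set-valued motif annotation per anchor: motifs whose occurrence
    overlaps the anchor's representative peak (when ``via`` is given) or the
    anchor itself. Anchors without a representative peak get an empty set."""
    occ_iv = [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in occurrences.itertuples(index=False)
    ]
    motif_ids = occurrences["motif_id"].astype(str).tolist()

    targets: list[GenomicInterval] = []
    target_anchor: list[GenomicInterval] = []
    for a in anchors:
        if via is not None:
            peak = via.get(a)
            if peak is None:
                continue
            targets.append(peak.interval)
        else:
            targets.append(a)
        target_anchor.append(a)

    out: dict[GenomicInterval, frozenset[str]] = {a: frozenset() for a in anchors}
    hits: dict[GenomicInterval, set[str]] = defaultdict(set)
    for ti, oj in intersect_with_slack(targets, occ_iv, slack=0):
        hits[target_anchor[ti]].add(motif_ids[oj])
    for a, motifs in hits.items():
        out[a] = frozenset(motifs)
    return out


def exclude_blacklisted(
    loops: Sequence[Loop],
    blacklist: Sequence[GenomicInterval],
) -> list[Loop]:
    """Drop loops where either anchor overlaps any blacklist interval
    (>= 1 bp, no slack)."""
    anchors_a = [lp.anchorA for lp in loops]
    anchors_b = [lp.anchorB for lp in loops]
    bad = {i for i, _ in intersect_with_slack(anchors_a, list(blacklist), 0)}
    bad |= {i for i, _ in intersect_with_slack(anchors_b, list(blacklist), 0)}
    return [lp for i, lp in enumerate(loops) if i not in bad]


# ---------------------------------------------------------------------------
# pair counting and block bootstrap
# ---------------------------------------------------------------------------


def _loop_pairs(
    motifs_a: frozenset[str], motifs_b: frozenset[str]
) -> set[MotifPair]:
    return {_pair(a, b) for a in motifs_a for b in motifs_b}


def observed_pair_counts(
    loops: Sequence[Loop],
    annotation: Mapping[GenomicInterval, frozenset[str]],
) -> Counter:
    """Count, per unordered motif pair (self-pairs allowed), the number of
    loops exhibiting the pair across opposing anchors. Each loop contributes
    at most once per pair."""
    counts: Counter[MotifPair] = Counter()
    empty: frozenset[str] = frozenset()
    for lp in loops:
        ma = annotation.get(lp.anchorA, empty)
        mb = annotation.get(lp.anchorB, empty)
        counts.update(_loop_pairs(ma, mb))
    return counts


@dataclass(frozen=True)
class MotifPairResult:
    motif_a: str
    motif_b: str
    observed_count: int
    p_empirical: float
    n_sims: int
    p_adjusted: float | None = None

    @property
    def pair(self) -> MotifPair:
        return (self.motif_a, self.motif_b)


def bootstrap_pair_enrichment(
    loops: Sequence[Loop],
    annotation: Mapping[GenomicInterval, frozenset[str]],
    n_sims: int = 100_000,
    seed: int | None = None,
    add_one: bool = True,
) -> list[MotifPairResult]:
    """Block-bootstrap enrichment test for motif pairs at loop anchors.

    Each simulation replaces every loop's two anchors with anchors drawn
    uniformly with replacement from the same chromosome's anchor pool (the
    unique anchors of the supplied loops; annotations travel with anchors)
    and recounts pairs. With ``add_one`` the Davison-Hinkley estimator
    ``p = (1 + #{count_sim >= count_obs}) / (1 + n_sims)`` is reported;
    otherwise the plain fraction.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)

    observed = observed_pair_counts(loops, annotation)
    if not observed:
        return []

    # per-chromosome anchor pools as annotation sets
    empty: frozenset[str] = frozenset()
    pool_sets: dict[str, list[frozenset[str]]] = defaultdict(list)
    seen: dict[str, set[GenomicInterval]] = defaultdict(set)
    for lp in loops:
        for a in (lp.anchorA, lp.anchorB):
            if a not in seen[a.chrom]:
                seen[a.chrom].add(a)
                pool_sets[a.chrom].append(annotation.get(a, empty))
    for chrom, pool in pool_sets.items():
        if len(pool) == 1:
            import logging

            logging.getLogger(__name__).warning(
                "chromosome %s has a single anchor; shuffle is degenerate", chrom
            )

    loop_chroms = [lp.chrom for lp in loops]
    chrom_loops: dict[str, int] = Counter(loop_chroms)
    pools = {c: pool_sets[c] for c in chrom_loops}

    exceed: Counter[MotifPair] = Counter()
    for _ in range(n_sims):
        sim_counts: Counter[MotifPair] = Counter()
        for chrom, n_loops_c in chrom_loops.items():
            pool = pools[chrom]
            idx = rng.integers(len(pool), size=2 * n_loops_c)
            for k in range(n_loops_c):
                ma = pool[idx[2 * k]]
                mb = pool[idx[2 * k + 1]]
                if ma and mb:
                    sim_counts.update(_loop_pairs(ma, mb))
        for pair, obs in observed.items():
            if sim_counts.get(pair, 0) >= obs:
                exceed[pair] += 1

    results = []
    for (a, b), obs in sorted(observed.items()):
        k = exceed.get((a, b), 0)
        p = (1 + k) / (1 + n_sims) if add_one else k / n_sims
        results.append(MotifPairResult(a, b, obs, p, n_sims))
    return results


def filter_and_adjust(
    results: Sequence[MotifPairResult],
    top_k: int = 50,
) -> list[MotifPairResult]:
    """Restrict to pairs whose both motifs rank in the sample's top-k motifs
    by frequency of appearance across observed pairs, then Benjamini-Hochberg
    adjust the retained p-values."""
    if not results:
        return []
    freq: Counter[str] = Counter()
    for r in results:
        freq[r.motif_a] += 1
        if r.motif_b != r.motif_a:
            freq[r.motif_b] += 1
    # rank by descending frequency, ties broken alphabetically for determinism
    ranked = sorted(freq, key=lambda m: (-freq[m], m))
    top = set(ranked[:top_k])
    kept = [r for r in results if r.motif_a in top and r.motif_b in top]
    if not kept:
        return []
    pvals = [r.p_empirical for r in kept]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        MotifPairResult(
            r.motif_a, r.motif_b, r.observed_count, r.p_empirical, r.n_sims, float(q)
        )
        for r, q in zip(kept, p_adj)
    ]


def cross_sample_summary(
    per_sample: Mapping[str, Sequence[MotifPairResult]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Proportion of samples in which each motif pair is significant
    (adjusted p <= alpha). A sample enters a pair's denominator only when the
    pair was tested in that sample. Returns a tidy frame with columns
    motif_a, motif_b, n_significant, n_tested, proportion."""
    if not per_sample:
        raise ValueError("need at least one sample")
    tested: Counter[MotifPair] = Counter()
    signif: Counter[MotifPair] = Counter()
    for results in per_sample.values():
        for r in results:
            tested[r.pair] += 1
            p = r.p_adjusted if r.p_adjusted is not None else r.p_empirical
            if p <= alpha:
                signif[r.pair] += 1
    rows = [
        {
            "motif_a": a,
            "motif_b": b,
            "n_significant": signif.get((a, b), 0),
            "n_tested": n,
            "proportion": signif.get((a, b), 0) / n,
        }
        for (a, b), n in sorted(tested.items())
    ]
    return pd.DataFrame(rows)


def pair_matrix(summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot a cross-sample summary into a symmetric motif x motif matrix of
    significant-sample proportions (heatmap-ready)."""
    motifs = sorted(set(summary["motif_a"]) | set(summary["motif_b"]))
    mat = pd.DataFrame(0.0, index=motifs, columns=motifs)
    for r in summary.itertuples(index=False):
        mat.loc[r.motif_a, r.motif_b] = r.proportion
        mat.loc[r.motif_b, r.motif_a] = r.proportion
    return mat
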