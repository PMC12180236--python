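"""Genomic data model and interval/pair intersection primitives.

All coordinates are internally 0-based half-open (BED convention). Inputs in
1-based coordinates (SNP positions) are shifted on parse; a SNP is stored as a
width-1 interval ``[pos-1, pos)``. Overlap means >= 1 shared base pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "ChromSizes",
    "Loop",
    "Peak",
    "SnpRecord",
    "GeneRecord",
    "intersect_with_slack",
    "pair_feature_overlap",
    "pair_pair_overlap",
    "peak_recall",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval", slack: int = 0) -> bool:
        """True iff this interval expanded by ``slack`` on both sides shares
        >= 1 bp with ``other``."""
        if self.chrom != other.chrom:
            return False
        return max(self.start - slack, 0) < other.end and other.start < self.end + slack

    def expanded(self, slack: int) -> "GenomicInterval":
        if slack < 0:
            raise ValueError("slack must be >= 0")
        return GenomicInterval(self.chrom, max(self.start - slack, 0), self.end + slack)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


class ChromSizes(dict):
    """Chromosome name -> length (bp). A thin dict with validation."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(sizes)
        for name, length in self.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")

    def validate(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self:
            raise ValueError(f"unknown chromosome {interval.chrom}")
        if interval.end > self[interval.chrom]:
            raise ValueError(
                f"{interval} extends past end of {interval.chrom} "
                f"({self[interval.chrom]} bp)"
            )


@dataclass(frozen=True)
class Loop:
    """An intra-chromosomal chromatin loop between two anchors.

    ``q_value`` is the loop-call significance (FitHiChIP FDR); ``resolution``
    is the bin size of the loop call. Anchors are stored in canonical order
    (anchorA upstream of anchorB).
    """

    anchorA: GenomicInterval
    anchorB: GenomicInterval
    q_value: float = 1.0
    resolution: int | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.anchorA.chrom != self.anchorB.chrom:
            raise ValueError("loops must be intra-chromosomal")
        if self.anchorA.start > self.anchorB.start:
            # canonicalize: swap so anchorA is the upstream anchor
            a, b = self.anchorA, self.anchorB
            object.__setattr__(self, "anchorA", b)
            object.__setattr__(self, "anchorB", a)
        if not (0.0 < self.q_value <= 1.0):
            raise ValueError(f"q_value must be in (0, 1], got {self.q_value}")

    @property
    def chrom(self) -> str:
        return self.anchorA.chrom

    @property
    def span(self) -> int:
        """Genomic distance between anchor midpoints."""
        return int(self.anchorB.midpoint - self.anchorA.midpoint)


@dataclass(frozen=True)
class Peak:
    """A narrowPeak-style 1D peak with an enrichment signal value."""

    interval: GenomicInterval
    signal_value: float = 0.0
    q_value: float | None = None
    name: str = "."

    def __post_init__(self) -> None:
        if self.signal_value < 0:
            raise ValueError("signal_value must be >= 0")


@dataclass(frozen=True)
class SnpRecord:
    """A (possibly fine-mapped) SNP; ``pos`` is 1-based as in source tables."""

    rsid: str
    chrom: str
    pos: int
    posterior_prob: float | None = None
    study_id: str = ""
    disease: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("SNP positions are 1-based; pos must be >= 1")
        if self.posterior_prob is not None and not (0.0 <= self.posterior_prob <= 1.0):
            raise ValueError("posterior_prob must be in [0, 1]")

    @property
    def interval(self) -> GenomicInterval:
        """Width-1 interval in 0-based half-open coordinates."""
        return GenomicInterval(self.chrom, self.pos - 1, self.pos)


@dataclass(frozen=True)
class GeneRecord:
    """A gene body with strand, as reduced from a GENCODE-style annotation."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start >= self.end:
            raise ValueError("gene start must precede end")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


# ---------------------------------------------------------------------------
# intersection primitives
# ---------------------------------------------------------------------------


def _build_trees(
    intervals: Sequence[GenomicInterval],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    return trees


def intersect_with_slack(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    slack: int = 0,
) -> list[tuple[int, int]]:
    """All pairs ``(i, j)`` where ``a[i]`` expanded by ``slack`` on both sides
    overlaps ``b[j]`` by >= 1 bp. Output is sorted by ``(i, j)``.
    """
    if slack < 0:
        raise ValueError("slack must be >= 0")
    trees = _build_trees(b)
    hits: list[tuple[int, int]] = []
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        lo = max(iv.start - slack, 0)
        hi = iv.end + slack
        for node in tree.overlap(lo, hi):
            hits.append((i, node.data))
    hits.sort()
    return hits


@dataclass
class AnchorHits:
    """Per-loop feature annotation: indices of features hitting each anchor."""

    A_hits: list[int] = field(default_factory=list)
    B_hits: list[int] = field(default_factory=list)


def pair_feature_overlap(
    loops: Sequence[Loop],
    features: Sequence[GenomicInterval],
    slack: int = 0,
) -> list[AnchorHits]:
    """Annotate each loop with the features overlapping each anchor separately
    (bedtools ``pairtobed`` semantics). A feature may hit both anchors.
    """
    anchors_a = [lp.anchorA for lp in loops]
    anchors_b = [lp.anchorB for lp in loops]
    out = [AnchorHits() for _ in loops]
    for i, j in intersect_with_slack(anchors_a, features, slack):
        out[i].A_hits.append(j)
    for i, j in intersect_with_slack(anchors_b, features, slack):
        out[i].B_hits.append(j)
    return out


def pair_pair_overlap(
    loops: Sequence[Loop],
    pairs: Sequence[tuple[GenomicInterval, GenomicInterval]],
    slack: int = 0,
) -> list[tuple[int, int]]:
    """Matches between loops and interval pairs (bedtools ``pairtopair``
    semantics): ``(loop_idx, pair_idx)`` is reported iff one pair member
    overlaps one anchor and the other member overlaps the *opposing* anchor,
    in either orientation. Output sorted, deduplicated.
    """
    first = [p[0] for p in pairs]
    second = [p[1] for p in pairs]
    anchors_a = [lp.anchorA for lp in loops]
    anchors_b = [lp.anchorB for lp in loops]

    a_first = set(intersect_with_slack(anchors_a, first, slack))
    a_second = set(intersect_with_slack(anchors_a, second, slack))
    b_first = set(intersect_with_slack(anchors_b, first, slack))
    b_second = set(intersect_with_slack(anchors_b, second, slack))

    matches = (a_first & b_second) | (a_second & b_first)
    return sorted(matches)


def peak_recall(
    truth: Sequence[Peak],
    test: Sequence[Peak],
    slack: int = 1000,
) -> float:
    """Fraction of ``truth`` peaks overlapped by >= 1 ``test`` peak, allowing
    ``slack`` bp on both sides of the truth peak (1 kb by default)."""
    if not truth:
        raise ValueError("recall is undefined for an empty truth set")
    truth_iv = [p.interval for p in truth]
    test_iv = [p.interval for p in test]
    hit = {i for i, _ in intersect_with_slack(truth_iv, test_iv, slack)}
    return len(hit) / len(truth)
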