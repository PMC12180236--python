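"""SNP-to-gene link (SGL) mapping through chromatin loops.

An SGL is a (SNP, gene, loop, sample) tuple in which the SNP falls in one
loop anchor and the gene's TSS (for GWAS variants: any TSS; for eQTLs: the
TSS of the variant's own paired gene) falls in the *opposing* anchor. A
nearby-gene null — every gene within a fixed window of each SNP — provides
the comparison distribution for a left-sided Mann-Whitney specificity test:
SGL mapping is "specific" when it links fewer genes per SNP than simple
proximity does.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core import (
    GeneRecord,
    GenomicInterval,
    Loop,
    SnpRecord,
    intersect_with_slack,
    pair_feature_overlap,
    pair_pair_overlap,
)

__all__ = [
    "TssRecord",
    "Sgl",
    "SglSummary",
    "tss_from_genes",
    "find_gwas_sgls",
    "find_eqtl_sgls",
    "dedup_sgls",
    "multiplicity_summary",
    "nearby_gene_null",
    "specificity_test",
]


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site as a 1-bp region (0-based half-open)."""

    gene_id: str
    gene_name: str
    chrom: str
    tss_pos: int  # 0-based start of the 1-bp region
    strand: str

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tss_pos, self.tss_pos + 1)


@dataclass(frozen=True)
class Sgl:
    """One SNP-to-gene link: SNP and TSS overlap opposing anchors of a loop."""

    snp: SnpRecord
    gene: TssRecord
    loop: Loop
    sample_id: str = ""
    disease_or_study: str = ""

    @property
    def key(self) -> tuple:
        """Uniqueness key for deduplication: (rsid, gene_id, loop coords,
        resolution, sample)."""
        lp = self.loop
        return (
            self.snp.rsid,
            self.gene.gene_id,
            lp.anchorA.chrom,
            lp.anchorA.start,
            lp.anchorB.start,
            lp.resolution,
            self.sample_id,
        )

    @property
    def distinct_key(self) -> tuple:
        """Key for counting distinct SGLs pooled across samples."""
        return self.key[:-1]


@dataclass
class SglSummary:
    n_sgls: int = 0
    n_unique_sgls: int = 0
    n_snps: int = 0
    n_genes: int = 0
    n_loops: int = 0
    genes_per_snp: dict[str, int] = field(default_factory=dict)
    snps_per_gene: dict[str, int] = field(default_factory=dict)
    median_genes_per_snp: float = 0.0
    median_snps_per_gene: float = 0.0
    singleton_fraction_snps: float = 0.0
    singleton_fraction_genes: float = 0.0


def tss_from_genes(genes: Sequence[GeneRecord]) -> list[TssRecord]:
    """TSS per gene as a 1-bp region: gene start for plus-strand genes, gene
    end for minus-strand genes."""
    out = []
    for g in genes:
        if g.strand == "+":
            pos = g.start
        elif g.strand == "-":
            pos = g.end - 1  # last base of the gene body, width-1 half-open
        else:  # pragma: no cover - GeneRecord validates strand
            raise ValueError(f"gene {g.gene_id} has no valid strand")
        out.append(TssRecord(g.gene_id, g.gene_name, g.chrom, pos, g.strand))
    return out


def find_gwas_sgls(
    loops: Sequence[Loop],
    snps: Sequence[SnpRecord],
    tss: Sequence[TssRecord],
) -> list[Sgl]:
    """GWAS SGLs: every (snp, gene, loop) triple where the SNP overlaps one
    anchor and any TSS overlaps the opposing anchor (both orientations).
    Output deduplicated on (rsid, gene_id, loop coordinates, sample)."""
    snp_iv = [s.interval for s in snps]
    tss_iv = [t.interval for t in tss]
    snp_hits = pair_feature_overlap(loops, snp_iv)
    tss_hits = pair_feature_overlap(loops, tss_iv)

    seen: set[tuple] = set()
    out: list[Sgl] = []
    for lp, sh, th in zip(loops, snp_hits, tss_hits):
        for si, ti in _opposing(sh.A_hits, sh.B_hits, th.A_hits, th.B_hits):
            s, t = snps[si], tss[ti]
            sgl = Sgl(s, t, lp, lp.sample_id, s.disease or s.study_id)
            if sgl.key not in seen:
                seen.add(sgl.key)
                out.append(sgl)
    return out


def _opposing(
    snp_a: list[int], snp_b: list[int], tss_a: list[int], tss_b: list[int]
):
    """(snp_idx, tss_idx) pairs on opposing anchors, both orientations."""
    pairs = set()
    for si in snp_a:
        for ti in tss_b:
            pairs.add((si, ti))
    for si in snp_b:
        for ti in tss_a:
            pairs.add((si, ti))
    return sorted(pairs)


def find_eqtl_sgls(
    loops: Sequence[Loop],
    eqtl_pairs: Sequence[tuple[SnpRecord, str]],
    tss: Sequence[TssRecord],
) -> list[Sgl]:
    """eQTL SGLs: only the eQTL's own paired gene counts — the (SNP, target
    TSS) pair must straddle the loop's opposing anchors (pairtopair
    semantics). eQTL records naming a gene absent from ``tss`` are skipped."""
    tss_by_gene = {t.gene_id: t for t in tss}
    usable: list[tuple[SnpRecord, TssRecord]] = []
    n_skipped = 0
    for snp, gene_id in eqtl_pairs:
        t = tss_by_gene.get(gene_id)
        if t is None:
            n_skipped += 1
            continue
        usable.append((snp, t))
    if n_skipped:
        import logging

        logging.getLogger(__name__).warning(
            "skipped %d eQTL records with unknown gene ids", n_skipped
        )

    iv_pairs = [(s.interval, t.interval) for s, t in usable]
    seen: set[tuple] = set()
    out: list[Sgl] = []
    for li, pi in pair_pair_overlap(loops, iv_pairs):
        snp, t = usable[pi]
        lp = loops[li]
        sgl = Sgl(snp, t, lp, lp.sample_id, snp.study_id)
        if sgl.key not in seen:
            seen.add(sgl.key)
            out.append(sgl)
    return out


def dedup_sgls(sgls: Sequence[Sgl], pooled: bool = True) -> list[Sgl]:
    """Drop duplicate SGLs. With ``pooled=True`` the sample id is ignored, so
    the same link found in several samples counts once (distinct SGLs)."""
    seen: set[tuple] = set()
    out = []
    for s in sgls:
        k = s.distinct_key if pooled else s.key
        if k not in seen:
            seen.add(k)
            out.append(s)
    return out


def multiplicity_summary(sgls: Sequence[Sgl]) -> SglSummary:
    """Multiplicity bookkeeping over a set of SGLs: distinct genes per SNP and
    distinct SNPs per gene, their medians, and singleton fractions."""
    summary = SglSummary()
    summary.n_sgls = len(sgls)
    if not sgls:
        return summary

    distinct = dedup_sgls(sgls, pooled=True)
    summary.n_unique_sgls = len(distinct)

    genes_of_snp: dict[str, set[str]] = defaultdict(set)
    snps_of_gene: dict[str, set[str]] = defaultdict(set)
    loops = set()
    for s in distinct:
        genes_of_snp[s.snp.rsid].add(s.gene.gene_id)
        snps_of_gene[s.gene.gene_id].add(s.snp.rsid)
        loops.add((s.loop.chrom, s.loop.anchorA.start, s.loop.anchorB.start))

    summary.n_snps = len(genes_of_snp)
    summary.n_genes = len(snps_of_gene)
    summary.n_loops = len(loops)
    summary.genes_per_snp = {k: len(v) for k, v in genes_of_snp.items()}
    summary.snps_per_gene = {k: len(v) for k, v in snps_of_gene.items()}
    gps = np.array(list(summary.genes_per_snp.values()))
    spg = np.array(list(summary.snps_per_gene.values()))
    summary.median_genes_per_snp = float(np.median(gps))
    summary.median_snps_per_gene = float(np.median(spg))
    summary.singleton_fraction_snps = float(np.mean(gps == 1))
    summary.singleton_fraction_genes = float(np.mean(spg == 1))
    return summary


def nearby_gene_null(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneRecord],
    window: int = 1_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearby-gene null: link each SNP to every gene whose body overlaps the
    closed window ``[pos - window, pos + window]`` around the SNP. Returns the
    per-SNP gene counts and the per-gene SNP counts (the transpose)."""
    if window <= 0:
        raise ValueError("window must be > 0")
    # closed-boundary window around the 1-based SNP position, expressed in
    # 0-based half-open coordinates
    snp_windows = [
        GenomicInterval(s.chrom, max(s.pos - 1 - window, 0), s.pos + window)
        for s in snps
    ]
    gene_iv = [g.interval for g in genes]
    genes_per_snp = np.zeros(len(snps), dtype=int)
    snps_per_gene = np.zeros(len(genes), dtype=int)
    for i, j in intersect_with_slack(snp_windows, gene_iv, slack=0):
        genes_per_snp[i] += 1
        snps_per_gene[j] += 1
    return genes_per_snp, snps_per_gene


def specificity_test(
    sgl_counts: Sequence[float],
    null_counts: Sequence[float],
) -> float:
    """Left-sided Mann-Whitney U p-value for the alternative that SGL link
    counts are stochastically *smaller* than the nearby-gene null counts
    (i.e. SGL mapping is more specific). Ties are handled by the normal
    approximation with tie correction."""
    x = np.asarray(sgl_counts, dtype=float)
    y = np.asarray(null_counts, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both count distributions must be non-empty")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        # degenerate: both samples constant and identical; U is pure ties
        import logging

        logging.getLogger(__name__).warning(
            "specificity test degenerate: both samples constant and equal"
        )
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="less", method="asymptotic")
    return float(res.pvalue)
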