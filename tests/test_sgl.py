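"""SNP-to-gene link mapping, multiplicity summaries, nearby-gene null."""

import numpy as np
import pytest

from conftest import brute_intersect
from loopkit.core import GeneRecord, GenomicInterval, Loop, SnpRecord
from loopkit.sgl import (
    TssRecord,
    dedup_sgls,
    find_eqtl_sgls,
    find_gwas_sgls,
    multiplicity_summary,
    nearby_gene_null,
    specificity_test,
    tss_from_genes,
)
from loopkit.synth import SynthConfig, gen_sgl_scenario


class TestTss:
    def test_plus_strand_tss_at_start(self):
        (t,) = tss_from_genes([GeneRecord("g", "g", "chr1", 1000, 5000, "+")])
        assert (t.interval.start, t.interval.end) == (1000, 1001)

    def test_minus_strand_tss_at_end(self):
        (t,) = tss_from_genes([GeneRecord("g", "g", "chr1", 1000, 5000, "-")])
        # last base of the half-open body, i.e. the gene's end site
        assert (t.interval.start, t.interval.end) == (4999, 5000)

    def test_mixed_table_matches_strand_rule(self, rng):
        genes = []
        for k in range(50):
            start = int(rng.integers(0, 100_000))
            end = start + int(rng.integers(100, 10_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(f"g{k}", f"g{k}", "chr1", start, end, strand))
        for g, t in zip(genes, tss_from_genes(genes)):
            expected = g.start if g.strand == "+" else g.end - 1
            assert t.tss_pos == expected and t.interval.width == 1


def _loop(a_start, b_start, chrom="chr1", width=5000, q=1e-4, sample="s"):
    return Loop(
        GenomicInterval(chrom, a_start, a_start + width),
        GenomicInterval(chrom, b_start, b_start + width),
        q_value=q,
        sample_id=sample,
    )


class TestGwasSgls:
    def test_opposing_anchor_rule(self):
        lp = _loop(10_000, 100_000)
        snp = SnpRecord("rs1", "chr1", 12_000)
        tss = [TssRecord("g1", "g1", "chr1", 101_000, "+")]
        assert len(find_gwas_sgls([lp], [snp], tss)) == 1
        # SNP and TSS in the same anchor: no SGL
        tss_same = [TssRecord("g1", "g1", "chr1", 13_000, "+")]
        assert find_gwas_sgls([lp], [snp], tss_same) == []

    def test_crosses_all_tss(self):
        """GWAS mapping links a SNP to every TSS in the opposing anchor."""
        lp = _loop(10_000, 100_000)
        snp = SnpRecord("rs1", "chr1", 12_000)
        tss = [
            TssRecord("g1", "g1", "chr1", 101_000, "+"),
            TssRecord("g2", "g2", "chr1", 103_000, "+"),
        ]
        assert {s.gene.gene_id for s in find_gwas_sgls([lp], [snp], tss)} == {"g1", "g2"}

    def test_matches_brute_force(self, rng):
        from conftest import random_loops

        loops = random_loops(rng, 60)
        snps = [
            SnpRecord(f"rs{k}", "chr1" if k % 2 else "chr2", int(rng.integers(1, 500_000)))
            for k in range(60)
        ]
        tss = [
            TssRecord(f"g{k}", f"g{k}", "chr1" if k % 3 else "chr2",
                      int(rng.integers(0, 500_000)), "+")
            for k in range(60)
        ]
        got = {
            (s.snp.rsid, s.gene.gene_id, s.loop.anchorA.start, s.loop.anchorB.start)
            for s in find_gwas_sgls(loops, snps, tss)
        }
        expected = set()
        for lp in loops:
            for snp in snps:
                for t in tss:
                    si, ti = snp.interval, t.interval
                    fwd = lp.anchorA.overlaps(si) and lp.anchorB.overlaps(ti)
                    rev = lp.anchorB.overlaps(si) and lp.anchorA.overlaps(ti)
                    if fwd or rev:
                        expected.add(
                            (snp.rsid, t.gene_id, lp.anchorA.start, lp.anchorB.start)
                        )
        assert got == expected

    @pytest.mark.parametrize("k", [0, 1, 25])
    def test_planted_recovery_exact(self, k):
        cfg = SynthConfig(seed=21, planted_sgl_count=k, n_loops=120)
        loops, snps, genes, truth = gen_sgl_scenario(cfg)
        sgls = find_gwas_sgls(loops, snps, tss_from_genes(genes))
        assert len(sgls) == k
        assert {(s.snp.rsid, s.gene.gene_id) for s in sgls} == {
            (t["rsid"], t["gene_id"]) for t in truth["planted_sgls"]
        }


class TestEqtlSgls:
    def test_pairing_preserved(self):
        lp = _loop(10_000, 100_000)
        snp = SnpRecord("rs1", "chr1", 12_000)
        tss = [
            TssRecord("gX", "gX", "chr1", 101_000, "+"),
            TssRecord("gY", "gY", "chr1", 103_000, "+"),
        ]
        # eQTL names gX: only gX links, even though gY's TSS is also opposite
        got = find_eqtl_sgls([lp], [(snp, "gX")], tss)
        assert [s.gene.gene_id for s in got] == ["gX"]
        # eQTL naming gZ (absent from the TSS table) is skipped
        assert find_eqtl_sgls([lp], [(snp, "gZ")], tss) == []

    def test_wrong_gene_in_opposing_anchor_no_link(self):
        lp = _loop(10_000, 100_000)
        snp = SnpRecord("rs1", "chr1", 12_000)
        tss = [
            TssRecord("gX", "gX", "chr1", 900_000, "+"),  # gX TSS not in anchorB
            TssRecord("gY", "gY", "chr1", 101_000, "+"),
        ]
        assert find_eqtl_sgls([lp], [(snp, "gX")], tss) == []


class TestMultiplicity:
    def test_single_sgl(self):
        lp = _loop(10_000, 100_000)
        s = find_gwas_sgls(
            [lp],
            [SnpRecord("rs1", "chr1", 12_000)],
            [TssRecord("g1", "g1", "chr1", 101_000, "+")],
        )
        summ = multiplicity_summary(s)
        assert summ.median_genes_per_snp == 1 and summ.median_snps_per_gene == 1
        assert summ.singleton_fraction_snps == 1.0

    def test_planted_gene_multiplicity(self):
        lp_set = [_loop(10_000, 100_000 + 10_000 * i) for i in range(5)]
        snps = [SnpRecord(f"rs{i}", "chr1", 12_000 + i) for i in range(5)]
        tss = [TssRecord("g", "g", "chr1", 101_000 + 10_000 * i, "+") for i in range(5)]
        sgls = find_gwas_sgls(lp_set, snps, tss)
        summ = multiplicity_summary(sgls)
        assert summ.snps_per_gene["g"] == 5

    def test_empty_input(self):
        summ = multiplicity_summary([])
        assert summ.n_sgls == 0 and summ.median_genes_per_snp == 0.0

    def test_dedup_idempotent(self):
        cfg = SynthConfig(seed=3, planted_sgl_count=10, n_loops=60)
        loops, snps, genes, _ = gen_sgl_scenario(cfg)
        sgls = find_gwas_sgls(loops, snps, tss_from_genes(genes))
        once = dedup_sgls(sgls)
        assert dedup_sgls(once) == once


class TestNearbyGeneNull:
    def test_counts_genes_in_window(self):
        snp = SnpRecord("rs1", "chr1", 5_000_000)
        genes = [
            GeneRecord("a", "a", "chr1", 4_500_000, 4_510_000, "+"),
            GeneRecord("b", "b", "chr1", 5_400_000, 5_410_000, "+"),
            GeneRecord("c", "c", "chr1", 5_900_000, 5_910_000, "+"),  # body in window
            GeneRecord("d", "d", "chr1", 8_000_000, 8_010_000, "+"),  # outside
        ]
        per_snp, per_gene = nearby_gene_null([snp], genes, window=1_000_000)
        assert per_snp[0] == 3
        assert per_gene.tolist() == [1, 1, 1, 0]

    def test_closed_boundary_gene_at_window_edge(self):
        snp = SnpRecord("rs1", "chr1", 2_000_000)
        # gene body starting exactly at pos + window (1-based closed boundary)
        edge = GeneRecord("e", "e", "chr1", 2_999_999, 3_010_000, "+")
        per_snp, _ = nearby_gene_null([snp], [edge], window=1_000_000)
        assert per_snp[0] == 1

    def test_matches_brute_force(self, rng):
        snps = [SnpRecord(f"rs{k}", "chr1", int(rng.integers(1, 10**7))) for k in range(50)]
        genes = [
            GeneRecord(f"g{k}", f"g{k}", "chr1", s := int(rng.integers(0, 10**7)),
                       s + int(rng.integers(1000, 100_000)), "+")
            for k in range(80)
        ]
        per_snp, per_gene = nearby_gene_null(snps, genes, window=500_000)
        for i, snp in enumerate(snps):
            expected = sum(
                1
                for g in genes
                if g.start <= snp.pos + 500_000 and g.end > snp.pos - 1 - 500_000
            )
            assert per_snp[i] == expected
        assert per_snp.sum() == per_gene.sum()


class TestSpecificityTest:
    def test_fully_separated_small_p(self):
        p = specificity_test([1] * 50, [10] * 50)
        assert p < 1e-6

    def test_sidedness_swapped_near_one(self):
        p = specificity_test([10] * 50, [1] * 50)
        assert p > 1 - 1e-6

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(100):
            x = rng.poisson(20, 50)
            y = rng.poisson(20, 50)
            ps.append(specificity_test(x, y))
        assert abs(np.mean(ps) - 0.5) < 0.1

    def test_degenerate_constant_inputs(self):
        assert specificity_test([3, 3, 3], [3, 3, 3]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            specificity_test([], [1, 2])


def test_sgl_median_below_null_median():
    """Loop-mediated linking is more specific than 1 Mb proximity linking on
    the same synthetic genome (below loop-density saturation)."""
    cfg = SynthConfig(seed=9, planted_sgl_count=25, n_loops=120)
    loops, snps, genes, _ = gen_sgl_scenario(cfg)
    sgls = find_gwas_sgls(loops, snps, tss_from_genes(genes))
    summ = multiplicity_summary(sgls)
    sgl_counts = np.array(list(summ.genes_per_snp.values()))
    null_counts, _ = nearby_gene_null(snps, genes)
    null_counts = null_counts[null_counts > 0]
    assert np.median(sgl_counts) <= np.median(null_counts)
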