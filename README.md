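# loopkit

Downstream analysis of HiChIP chromatin loops: sample quality control,
replicate reproducibility, SNP-to-gene linking, motif-pair enrichment,
regulatory networks, and 2D chromatin embeddings.

HiChIP couples in-situ Hi-C with chromatin immunoprecipitation to profile
protein-anchored chromatin loops — regulatory loops (H3K27ac) joining
enhancers and promoters, and structural loops (CTCF) demarcating domains.
Once loops have been called (FitHiChIP-, HiCCUPS- or Mustache-style BEDPE),
a large amount of the scientific value lives in the *downstream* analysis:
deciding which samples are trustworthy, which replicates to merge, which
non-coding variants the loops connect to which genes, which transcription
factor motif pairs co-occur at loop anchors more often than chance, and how
contact structure and 1D signal organize in space. `loopkit` implements that
downstream layer as a tested, seedable library with a thin `loopkit` CLI,
exercisable end-to-end on synthetic data with planted ground truth — no
downloads required.

## What it computes

**QC scoring and flags** (`loopkit.qc`). Each quality metric χ (mapping %,
valid-pair %, duplicate %, peak and loop counts, NRF/PBC/NSC/RSC, ...) is
scored on a 0–10 scale by piecewise-linear normalization over intervals set
by thresholds t₁ and t₂: [min, t₁]→[0, 6] ("Poor"), [t₁, t₂]→[6, 8]
("Warning"), [t₂, upper]→[8, 10] ("Good"); bounded metrics at their maximum,
or upper outliers past Q₃ + 1.5·IQR, score 10, and "lower is better" metrics
take the complement 10 − score. Stage scores are means,
S_agg = Σ scoreᵢ / m, banded Poor < 6 ≤ Warning < 8 ≤ Good, and the final
per-sample flag is Good only when every stage is Good (worst-of otherwise).

**Replicate reproducibility** (`loopkit.qc.scc`). The stratum-adjusted
correlation coefficient between two contact maps: both matrices smoothed by
a (2h+1)×(2h+1) mean filter, a Pearson correlation r_d per distance stratum
d, combined as SCC = Σ w_d·r_d / Σ w_d with w_d = N_d·σ_{a,d}·σ_{b,d}.
Replicate groups merge only when every pairwise SCC exceeds 0.8.

**SNP-to-gene links** (`loopkit.sgl`). An SGL is a loop with a fine-mapped
GWAS SNP in one anchor and a gene TSS in the opposing anchor (for eQTLs, the
variant's own target promoter — pairtopair semantics). Link multiplicity is
summarized per SNP and per gene, and compared against a nearby-gene null
(every gene within ±1 Mb of each SNP) with a left-sided Mann–Whitney test:
small p means loop-mediated linking is more specific than proximity.

**Motif-pair enrichment** (`loopkit.motifs`). Conserved anchors are those
looping in ≥ ⌈0.8·n⌉ of n samples (44/54, 22/27, 9/11). For external 1D
enrichment tools the module builds GC-matched backgrounds (0.5 % GC quantile
bins). Motif pairs at opposing anchors are tested with a block bootstrap:
every simulation redraws each loop's two anchors uniformly with replacement
from that chromosome's anchor pool (annotations travel with anchors), and
the empirical p is the add-one fraction of simulations with a pair count at
or above the observed one, Benjamini–Hochberg adjusted over pairs within the
top-50 most frequent motifs.

**Regulatory networks** (`loopkit.networks`). Anchors become nodes labelled
promoter (TSS within ±2.5 kb, priority), enhancer (ChIP-seq peak overlap) or
other; loops become edges weighted by −log₁₀(q) capped at 20 and scaled to
[0, 1]. Louvain runs per chromosome at two levels (communities, then
subcommunities inside each), and communities are ranked by a connectivity
score (Borda aggregation of density, conductance complement and internal
strength).

**2D embeddings, Moran's I, APA** (`loopkit.embedding`). A gene-centred
contact window is log₁₀-transformed (assay-specific floor), inverted into
distances, laid out with Kamada–Kawai, and tessellated with Voronoi
polygons; shared Voronoi edges give row-standardized spatial weights W for
global and local Moran's I of an overlaid 1D signal, with permutation
p-values and HH/HL/LH/LL quadrants. Aggregate peak analysis reports the
centre-pixel enrichment of loop calls over a distance-matched corner
background (15–30 kb flanks) and over all non-centre pixels.

**Synthetic data** (`loopkit.synth`). Seeded generators for every input:
loops with power-law spans in [20 kb, 2 Mb] and mixture q-values, planted
SGL triples with rule-violating distractors, motif annotations with planted
co-occurring pairs, contact windows with planted centre enrichment, and
spatially autocorrelated signals — each with a truth record sufficient to
verify the downstream answer.

## Worked example

```python
from loopkit.synth import SynthConfig, gen_sgl_scenario
from loopkit.sgl import (find_gwas_sgls, multiplicity_summary,
                         nearby_gene_null, specificity_test, tss_from_genes)

cfg = SynthConfig(seed=1, planted_sgl_count=25, n_loops=120)
loops, snps, genes, truth = gen_sgl_scenario(cfg)
sgls = find_gwas_sgls(loops, snps, tss_from_genes(genes))
summ = multiplicity_summary(sgls)
null_counts, _ = nearby_gene_null(snps, genes)
p = specificity_test(list(summ.genes_per_snp.values()),
                     null_counts[null_counts > 0])
print(summ.n_sgls, summ.median_genes_per_snp, p)
```

prints

```
25 1.0 4.374545846281354e-15
```

All 25 planted SNP–gene–loop triples are recovered (and nothing else: the
distractor SNPs sharing an anchor with a TSS, or facing an empty anchor, do
not qualify). Each linked SNP reaches a median of 1 gene through loops,
against a median of 19 genes under ±1 Mb proximity linking on the same
genome — the Mann–Whitney p ≈ 4e−15 quantifies that loop-mediated linking
is the more specific of the two.

The same scenarios are available from the shell:

```sh
loopkit synth sgl --seed 1 --out scen/
loopkit sgl gwas --loops scen/loops.bedpe --snps scen/snps.tsv \
    --genes scen/genes.tsv --out sgl.tsv
loopkit sgl nulltest --loops scen/loops.bedpe --snps scen/snps.tsv \
    --genes scen/genes.tsv --out null.json
```

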