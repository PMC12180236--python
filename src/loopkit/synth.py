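"""Seeded synthetic-data generators with planted ground truth.

Every generator is deterministic under a fixed seed and returns, next to the
dataset itself, a truth record sufficient to compute the expected downstream
answer without re-deriving it. The default synthetic genome is two 10-Mb
chromosomes binned at 5 kb: large enough for distance strata and span
sampling, small enough for seconds-scale tests.

Loops follow the conventions of peak-anchored loop callers: anchors on the
bin grid, spans drawn from a truncated power law between 20 kb and 2 Mb, and
a two-component q-value mixture (significant calls near zero, background
uniform).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import ChromSizes, GeneRecord, GenomicInterval, Loop, Peak, SnpRecord
from .embedding import ContactWindow

__all__ = [
    "SynthConfig",
    "gen_loops",
    "gen_peaks",
    "gen_peak_recall_scenario",
    "gen_sgl_scenario",
    "gen_motif_scenario",
    "gen_contact_window",
    "gen_replicate_matrices",
    "gen_autocorrelated_signal",
]


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    chrom_sizes: tuple[tuple[str, int], ...] = (("chr1", 10_000_000), ("chr2", 10_000_000))
    resolution: int = 5000
    n_loops: int = 300
    distance_decay_exponent: float = 1.0
    sig_fraction: float = 0.7  # fraction of loops with "significant" q-values
    sig_lognq: float = 6.0  # mean -log10 q of significant loops
    n_snps: int = 100
    n_genes: int = 80
    planted_sgl_count: int = 25
    n_motifs: int = 20
    motif_freq: float = 0.25  # per-motif presence probability per anchor
    pair_multiplier: float = 1.0
    n_peaks: int = 200
    peak_signal_mean: float = 10.0
    signal_autocorr_bins: float = 5.0
    min_span: int = 20_000
    max_span: int = 2_000_000

    @property
    def sizes(self) -> ChromSizes:
        return ChromSizes(dict(self.chrom_sizes))


def _rng(cfg: SynthConfig, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((cfg.seed, salt))


def _sample_spans(
    rng: np.random.Generator, cfg: SynthConfig, n: int
) -> np.ndarray:
    """Loop spans (bp, multiples of the resolution) from a discrete power law
    p(d) ~ d^-alpha truncated to [min_span, max_span]."""
    res = cfg.resolution
    lo = cfg.min_span // res
    hi = cfg.max_span // res
    d = np.arange(lo, hi + 1, dtype=float)
    p = d ** (-cfg.distance_decay_exponent)
    p /= p.sum()
    return rng.choice(d, size=n, p=p).astype(int) * res


def _sample_q(rng: np.random.Generator, cfg: SynthConfig, n: int) -> np.ndarray:
    sig = rng.random(n) < cfg.sig_fraction
    q = rng.uniform(0.011, 1.0, size=n)  # background: non-significant
    lognq = rng.normal(cfg.sig_lognq, 1.5, size=n).clip(2.1, 300)
    q[sig] = 10.0 ** (-lognq[sig])
    return q


def gen_loops(
    cfg: SynthConfig, sample_id: str = "synth", salt: int = 1
) -> tuple[list[Loop], dict]:
    """Generate ``cfg.n_loops`` loops with power-law spans and mixture
    q-values. Truth records the per-loop span and significance flag."""
    rng = _rng(cfg, salt)
    sizes = cfg.sizes
    res = cfg.resolution
    chroms = list(sizes)
    if cfg.max_span >= max(sizes.values()):
        raise ValueError("max_span must be smaller than the chromosome length")
    spans = _sample_spans(rng, cfg, cfg.n_loops)
    qs = _sample_q(rng, cfg, cfg.n_loops)
    loops = []
    truth_rows = []
    for k in range(cfg.n_loops):
        chrom = chroms[int(rng.integers(len(chroms)))]
        max_start = (sizes[chrom] - spans[k] - res) // res
        a = int(rng.integers(0, max_start)) * res
        b = a + int(spans[k])
        lp = Loop(
            GenomicInterval(chrom, a, a + res),
            GenomicInterval(chrom, b, b + res),
            q_value=float(qs[k]),
            resolution=res,
            sample_id=sample_id,
        )
        loops.append(lp)
        truth_rows.append(
            {"chrom": chrom, "span": int(spans[k]), "significant": bool(qs[k] <= 0.01)}
        )
    return loops, {"n_loops": cfg.n_loops, "loops": truth_rows}


def gen_peaks(
    cfg: SynthConfig, salt: int = 2, n_peaks: int | None = None
) -> list[Peak]:
    """Random narrow peaks (200-1000 bp) with exponential signal values."""
    rng = _rng(cfg, salt)
    sizes = cfg.sizes
    chroms = list(sizes)
    n = cfg.n_peaks if n_peaks is None else n_peaks
    peaks = []
    for k in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        width = int(rng.integers(200, 1000))
        start = int(rng.integers(0, sizes[chrom] - width))
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, start + width),
                signal_value=float(rng.exponential(cfg.peak_signal_mean)),
                q_value=float(10.0 ** -rng.uniform(2, 10)),
                name=f"peak_{k}",
            )
        )
    return peaks


def gen_peak_recall_scenario(
    cfg: SynthConfig, frac_recoverable: float = 0.7, slack: int = 1000, salt: int = 3
) -> tuple[list[Peak], list[Peak], dict]:
    """Truth and test peak sets where exactly ``frac_recoverable`` of truth
    peaks have a test peak within ``slack``; the rest are isolated by more
    than ``slack``."""
    rng = _rng(cfg, salt)
    sizes = cfg.sizes
    chrom = list(sizes)[0]
    n_truth = 100
    gap = 4 * slack + 4000
    truth, test = [], []
    n_rec = int(round(frac_recoverable * n_truth))
    for k in range(n_truth):
        start = 10_000 + k * gap
        iv = GenomicInterval(chrom, start, start + 500)
        truth.append(Peak(iv, signal_value=1.0, name=f"t{k}"))
        if k < n_rec:
            off = int(rng.integers(-slack, slack))  # within reach of the slack
            s = max(start + off, 0)
            test.append(Peak(GenomicInterval(chrom, s, s + 400), 1.0, name=f"x{k}"))
    return truth, test, {"recall": n_rec / n_truth}


# ---------------------------------------------------------------------------
# SGL scenario
# ---------------------------------------------------------------------------


def gen_sgl_scenario(
    cfg: SynthConfig, salt: int = 4
) -> tuple[list[Loop], list[SnpRecord], list[GeneRecord], dict]:
    """Loops, SNPs and genes with *exactly* ``cfg.planted_sgl_count`` (snp,
    gene, loop) triples satisfying the opposing-anchor rule.

    Every loop carrying a feature is built from disjoint anchor bins on the
    first chromosome, so no accidental SGLs can arise from shared or
    overlapping anchors. Distractors violate the rule in each way it can be
    violated: SNP and TSS in the *same* anchor; a SNP with nothing opposite;
    a TSS with nothing opposite; and SNPs on the chromosome tail away from
    every anchor. Feature-free background loops fill the set to
    ``cfg.n_loops`` on the second chromosome.
    """
    if cfg.planted_sgl_count > cfg.n_loops:
        raise ValueError("planted_sgl_count must not exceed n_loops")
    rng = _rng(cfg, salt)
    res = cfg.resolution
    sizes = cfg.sizes
    chroms = list(sizes)
    chrom = chroms[0]
    n_bins = sizes[chrom] // res

    cursor = 2  # next free bin on the feature chromosome; bins never reused
    min_span_bins = max(cfg.min_span // res, 1)

    def alloc_loop(span_bins: int) -> Loop:
        nonlocal cursor
        a = cursor
        b = a + span_bins
        cursor = b + 2
        if cursor >= n_bins:
            raise ValueError("feature chromosome too small for scenario")
        return Loop(
            GenomicInterval(chrom, a * res, (a + 1) * res),
            GenomicInterval(chrom, b * res, (b + 1) * res),
            q_value=float(10.0 ** -rng.uniform(2.5, 10)),
            resolution=res,
            sample_id="sgl_synth",
        )

    def pos_inside(iv: GenomicInterval) -> int:
        """1-based position strictly inside an anchor."""
        return int(rng.integers(iv.start, iv.end)) + 1

    loops: list[Loop] = []
    snps: list[SnpRecord] = []
    genes: list[GeneRecord] = []
    truth: list[dict] = []

    # planted SGL triples, alternating SNP->A / SNP->B orientation
    for k in range(cfg.planted_sgl_count):
        lp = alloc_loop(min_span_bins + int(rng.integers(0, 4)))
        loops.append(lp)
        snp_anchor, tss_anchor = (
            (lp.anchorA, lp.anchorB) if k % 2 == 0 else (lp.anchorB, lp.anchorA)
        )
        rsid, gid = f"rs{1000 + k}", f"GENE{k:04d}"
        snps.append(SnpRecord(rsid, chrom, pos_inside(snp_anchor), 0.9, "studyP", "synthD"))
        tss_pos = pos_inside(tss_anchor) - 1  # 0-based start of the TSS base
        genes.append(GeneRecord(gid, gid, chrom, tss_pos, tss_pos + 40_000, "+"))
        truth.append({"rsid": rsid, "gene_id": gid, "loop_index": len(loops) - 1})

    n_distract = min(8, max(cfg.n_loops - cfg.planted_sgl_count, 0))
    # SNP and TSS inside the SAME anchor -> no SGL
    for k in range(n_distract):
        lp = alloc_loop(min_span_bins + 2)
        loops.append(lp)
        snps.append(
            SnpRecord(f"rs{9000 + k}", chrom, pos_inside(lp.anchorA), 0.5, "studyP", "synthD")
        )
        tss_pos = pos_inside(lp.anchorA) - 1
        genes.append(
            GeneRecord(f"DGENE{k:04d}", f"DGENE{k:04d}", chrom, tss_pos, tss_pos + 30_000, "+")
        )
    # SNP with empty opposing anchor
    for k in range(n_distract):
        if len(loops) >= cfg.n_loops:
            break
        lp = alloc_loop(min_span_bins + 1)
        loops.append(lp)
        snps.append(
            SnpRecord(f"rs{9500 + k}", chrom, pos_inside(lp.anchorB), 0.5, "studyP", "synthD")
        )
    # TSS with empty opposing anchor
    for k in range(n_distract):
        if len(loops) >= cfg.n_loops:
            break
        lp = alloc_loop(min_span_bins + 1)
        loops.append(lp)
        tss_pos = pos_inside(lp.anchorA) - 1
        genes.append(
            GeneRecord(f"EGENE{k:04d}", f"EGENE{k:04d}", chrom, tss_pos, tss_pos + 30_000, "+")
        )

    # SNPs on the chromosome tail, > 1 bin past every allocated anchor
    tail_start = cursor + 4
    k = 0
    while len(snps) < cfg.n_snps and tail_start + k < n_bins - 1:
        pos = (tail_start + k) * res + res // 2
        snps.append(SnpRecord(f"rs{50_000 + k}", chrom, pos + 1, 0.2, "studyP", "synthD"))
        k += 1

    # feature-free background loops on the second chromosome
    if len(loops) < cfg.n_loops and len(chroms) > 1:
        bg_cfg = replace(
            cfg,
            chrom_sizes=((chroms[1], sizes[chroms[1]]),),
            n_loops=cfg.n_loops - len(loops),
        )
        bg_loops, _ = gen_loops(bg_cfg, sample_id="sgl_synth", salt=salt + 100)
        loops.extend(bg_loops)

    return loops, snps, genes, {
        "planted_sgls": truth,
        "n_planted": cfg.planted_sgl_count,
    }


# ---------------------------------------------------------------------------
# motif scenario
# ---------------------------------------------------------------------------


def gen_motif_scenario(
    cfg: SynthConfig,
    salt: int = 5,
    anchors_per_chrom: int = 60,
) -> tuple[list[Loop], dict[GenomicInterval, frozenset[str]], dict]:
    """Loops with per-anchor motif annotations, built under the block
    bootstrap's own sampling model.

    A pool of ``anchors_per_chrom`` grid anchors is laid out per chromosome
    and each of ``cfg.n_motifs`` motifs is present on each pool anchor
    independently with probability ``cfg.motif_freq``. Each loop then draws
    its two anchors uniformly with replacement from one chromosome's pool
    (redrawing only exact self-pairs), so with ``pair_multiplier == 1`` the
    observed pair counts are one draw from the bootstrap null and empirical
    p-values are calibrated. With ``pair_multiplier > 1`` extra loops are
    planted between anchors carrying M0 and M1 respectively, raising that
    pair's expected loop count to roughly the multiplier times the
    independence expectation.
    """
    if cfg.n_motifs < 2:
        raise ValueError("need at least two motifs")
    rng = _rng(cfg, salt)
    res = cfg.resolution
    sizes = cfg.sizes
    chroms = list(sizes)
    motif_ids = [f"M{k}" for k in range(cfg.n_motifs)]

    pools: dict[str, list[GenomicInterval]] = {}
    annotation: dict[GenomicInterval, frozenset[str]] = {}
    for chrom in chroms:
        n_bins = sizes[chrom] // res
        stride = max(n_bins // anchors_per_chrom, 1)
        bins = [b * stride for b in range(anchors_per_chrom) if b * stride < n_bins]
        pool = [GenomicInterval(chrom, b * res, (b + 1) * res) for b in bins]
        pools[chrom] = pool
        presence = rng.random((len(pool), cfg.n_motifs)) < cfg.motif_freq
        for i, a in enumerate(pool):
            annotation[a] = frozenset(
                m for k, m in enumerate(motif_ids) if presence[i, k]
            )

    f = cfg.motif_freq
    # P(unordered pair {M0, M1} across the two anchors of one loop)
    p_pair = 2 * f * f - (f * f) ** 2
    expected = cfg.n_loops * p_pair
    n_extra = 0
    if cfg.pair_multiplier > 1.0:
        n_extra = int(round((cfg.pair_multiplier - 1.0) * expected))

    def draw_pair(chrom: str, sub_a=None, sub_b=None) -> tuple:
        pool_a = sub_a if sub_a else pools[chrom]
        pool_b = sub_b if sub_b else pools[chrom]
        for _ in range(100):
            a = pool_a[int(rng.integers(len(pool_a)))]
            b = pool_b[int(rng.integers(len(pool_b)))]
            if a != b:
                return a, b
        raise ValueError("could not draw two distinct anchors")

    loops: list[Loop] = []
    for _ in range(cfg.n_loops - n_extra):
        chrom = chroms[int(rng.integers(len(chroms)))]
        a, b = draw_pair(chrom)
        loops.append(
            Loop(a, b, q_value=float(10.0 ** -rng.uniform(2.1, 8)),
                 resolution=res, sample_id="motif_synth")
        )

    truth: dict = {"planted_pair": None, "n_motifs": cfg.n_motifs}
    if n_extra:
        for _ in range(n_extra):
            chrom = chroms[int(rng.integers(len(chroms)))]
            with_m0 = [a for a in pools[chrom] if "M0" in annotation[a]]
            with_m1 = [a for a in pools[chrom] if "M1" in annotation[a]]
            if not with_m0 or not with_m1:
                continue
            a, b = draw_pair(chrom, with_m0, with_m1)
            loops.append(
                Loop(a, b, q_value=float(10.0 ** -rng.uniform(2.1, 8)),
                     resolution=res, sample_id="motif_synth")
            )
        truth["planted_pair"] = ("M0", "M1")
        truth["expected_null_count"] = expected
        truth["n_planted_loops"] = n_extra
    return loops, annotation, truth


# ---------------------------------------------------------------------------
# contact windows, replicate matrices, 1D signals
# ---------------------------------------------------------------------------


def gen_contact_window(
    cfg: SynthConfig,
    planted_center_enrichment: float = 1.0,
    n_bins: int = 401,
    n_planted_loops: int = 20,
    noise_sd: float = 0.0,
    gene_id: str = "synthgene",
    salt: int = 6,
) -> tuple[ContactWindow, list[Loop], np.ndarray, dict]:
    """Symmetric contact window with power-law distance decay, planted loop
    pixels multiplied by the enrichment factor, and a companion 1D signal
    with one contiguous high block (for spatial-autocorrelation tests).

    Returns (window, planted loops, signal, truth).
    """
    if planted_center_enrichment < 1.0:
        raise ValueError("enrichment must be >= 1")
    rng = _rng(cfg, salt)
    res = cfg.resolution
    alpha = 0.3  # mild decay so corner backgrounds track the centre pixel
    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    base = 50.0 * (dist + 1.0) ** (-alpha)
    if noise_sd > 0:
        noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=(n_bins, n_bins))
        base *= np.triu(noise) + np.triu(noise, 1).T
    mat = 0.5 * (base + base.T)

    chrom = list(cfg.sizes)[0]
    loops = []
    max_d = min(150, n_bins - 25)
    min_d = min(60, max(5, max_d - 20))
    for k in range(n_planted_loops):
        d = int(rng.integers(min_d, max_d))
        i = int(rng.integers(12, n_bins - d - 12))
        j = i + d
        mat[i, j] *= planted_center_enrichment
        mat[j, i] = mat[i, j]
        loops.append(
            Loop(
                GenomicInterval(chrom, i * res, (i + 1) * res),
                GenomicInterval(chrom, j * res, (j + 1) * res),
                q_value=1e-6,
                resolution=res,
                sample_id="apa_synth",
            )
        )

    bins = [(chrom, int(i * res), int((i + 1) * res)) for i in idx]
    window = ContactWindow(gene_id, bins, mat, res, assay="hichip")

    block_start = n_bins // 3
    block_len = max(n_bins // 10, 3)
    signal = rng.normal(0.0, 1.0, size=n_bins)
    signal[block_start : block_start + block_len] += 4.0
    truth = {
        "enrichment": planted_center_enrichment,
        "block": (block_start, block_start + block_len),
    }
    return window, loops, signal, truth


def gen_replicate_matrices(
    cfg: SynthConfig,
    shared_fraction: float,
    n_bins: int = 200,
    salt: int = 7,
) -> tuple[np.ndarray, np.ndarray]:
    """A pair of replicate contact matrices sharing ``shared_fraction`` of
    their (variance-matched) signal: ``A = s*S + (1-s)*N_A`` with a common
    distance-decay structured field S and independent structured noise
    fields per replicate."""
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValueError("shared_fraction must be in [0, 1]")
    rng = _rng(cfg, salt)

    def structured() -> np.ndarray:
        raw = rng.lognormal(0.0, 1.0, size=(n_bins, n_bins))
        idx = np.arange(n_bins)
        decay = (np.abs(idx[:, None] - idx[None, :]) + 1.0) ** -0.5
        m = raw * decay
        return 0.5 * (m + m.T)

    s = shared_fraction
    shared = structured()
    a = s * shared + (1 - s) * structured()
    b = s * shared + (1 - s) * structured()
    return a, b


def gen_autocorrelated_signal(
    cfg: SynthConfig, n_bins: int = 400, salt: int = 8
) -> np.ndarray:
    """Spatially autocorrelated 1D signal: white noise smoothed with a
    Gaussian kernel of width ``cfg.signal_autocorr_bins``."""
    rng = _rng(cfg, salt)
    white = rng.normal(size=n_bins)
    return gaussian_filter1d(white, sigma=cfg.signal_autocorr_bins, mode="wrap")
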