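"""Readers and writers for the plain-text formats the toolkit consumes.

Formats: BEDPE (loops; FitHiChIP / HiCCUPS / plain dialects), BED, narrowPeak,
chrom.sizes, headered TSV tables for SNPs / genes / eQTLs / motif occurrences,
and triplet-form binned contact matrices with a bins BED.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ChromSizes,
    GeneRecord,
    GenomicInterval,
    Loop,
    Peak,
    SnpRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParseReport",
    "parse_bedpe",
    "parse_bedpe_report",
    "write_bedpe",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_snp_table",
    "write_snp_table",
    "read_gene_table",
    "write_gene_table",
    "read_eqtl_table",
    "read_motif_occurrences",
    "read_contact_matrix",
    "write_contact_matrix",
]

_QVAL_RE = re.compile(r"q[-_. ]?val", re.IGNORECASE)


@dataclass
class ParseReport:
    """Outcome of a BEDPE parse: records plus bookkeeping of rejects."""

    loops: list[Loop] = field(default_factory=list)
    n_interchromosomal: int = 0
    malformed: list[tuple[int, str]] = field(default_factory=list)


def _split(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def _plain_q(fields: list[str]) -> float:
    # plain BEDPE: optional 8th (score) column read as q-value when it parses
    if len(fields) >= 8:
        try:
            q = float(fields[7])
        except ValueError:
            return 1.0
        if 0.0 < q <= 1.0:
            return q
    return 1.0


def parse_bedpe_report(
    path: str | Path,
    dialect: str = "plain",
    sample_id: str = "",
    resolution: int | None = None,
) -> ParseReport:
    """Parse a BEDPE-like loop file into canonical :class:`Loop` records.

    Dialects
    --------
    ``plain``
        6+ tab-separated columns ``chrom1 start1 end1 chrom2 start2 end2``,
        optionally a name column and a q-value in column 8. No header.
    ``fithichip``
        headered table whose first six columns are the anchor coordinates and
        which carries a q-value column (name matching ``q.?val``, e.g.
        ``Q-Value_Bias``); missing q-value column is a format error.
    ``hiccups``
        headered table with columns ``chr1 x1 x2 chr2 y1 y2 ... fdrDonut``;
        ``fdrDonut`` (or a q-value column) supplies significance.
    """
    path = Path(path)
    if dialect not in {"plain", "fithichip", "hiccups"}:
        raise ValueError(f"unknown BEDPE dialect {dialect!r}")
    report = ParseReport()
    with open(path) as fh:
        lines = fh.readlines()

    start_idx = 0
    q_col: int | None = None
    if dialect in {"fithichip", "hiccups"}:
        if not lines:
            raise ValueError(f"{path}: empty {dialect} file (header expected)")
        header = _split(lines[0])
        start_idx = 1
        for k, name in enumerate(header):
            if _QVAL_RE.search(name) or name.lower() == "fdrdonut":
                q_col = k
                break
        if q_col is None:
            raise ValueError(
                f"{path}: no q-value column found in {dialect} header {header!r}"
            )
        if len(header) < 6:
            raise ValueError(f"{path}: {dialect} header has fewer than 6 columns")

    for lineno, line in enumerate(lines[start_idx:], start=start_idx + 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = _split(line)
        if len(fields) < 6:
            report.malformed.append((lineno, "fewer than 6 columns"))
            continue
        try:
            c1, s1, e1, c2, s2, e2 = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                fields[3],
                int(fields[4]),
                int(fields[5]),
            )
        except ValueError as exc:
            report.malformed.append((lineno, f"bad coordinate: {exc}"))
            continue
        if c1 != c2:
            report.n_interchromosomal += 1
            continue
        if dialect == "plain":
            q = _plain_q(fields)
        else:
            try:
                q = float(fields[q_col])  # type: ignore[index]
            except (ValueError, IndexError):
                report.malformed.append((lineno, "bad q-value"))
                continue
            # loop callers may emit q == 0 at float underflow; clamp into (0, 1]
            if q <= 0.0:
                q = np.nextafter(0.0, 1.0)
        try:
            loop = Loop(
                GenomicInterval(c1, s1, e1),
                GenomicInterval(c2, s2, e2),
                q_value=min(q, 1.0),
                resolution=resolution,
                sample_id=sample_id,
            )
        except ValueError as exc:
            report.malformed.append((lineno, str(exc)))
            continue
        report.loops.append(loop)

    if report.n_interchromosomal:
        logger.warning(
            "%s: skipped %d inter-chromosomal records", path, report.n_interchromosomal
        )
    for lineno, reason in report.malformed:
        logger.warning("%s:%d malformed line (%s)", path, lineno, reason)
    return report


def parse_bedpe(
    path: str | Path,
    dialect: str = "plain",
    sample_id: str = "",
    resolution: int | None = None,
) -> list[Loop]:
    return parse_bedpe_report(path, dialect, sample_id, resolution).loops


def write_bedpe(loops: Sequence[Loop], path: str | Path) -> None:
    """Write loops as plain 8-column BEDPE (name '.', q-value in column 8)."""
    with open(path, "w") as fh:
        for lp in loops:
            fh.write(
                f"{lp.anchorA.chrom}\t{lp.anchorA.start}\t{lp.anchorA.end}\t"
                f"{lp.anchorB.chrom}\t{lp.anchorB.start}\t{lp.anchorB.end}\t"
                f".\t{lp.q_value:.6g}\n"
            )


# ---------------------------------------------------------------------------
# BED / narrowPeak / chrom.sizes
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _split(line)
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read a 10-column ENCODE narrowPeak file."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _split(line)
            if len(f) < 10:
                raise ValueError(f"{path}: narrowPeak requires 10 columns, got {len(f)}")
            qv = float(f[8])
            out.append(
                Peak(
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    signal_value=float(f[6]),
                    q_value=None if qv < 0 else 10.0 ** (-qv),
                    name=f[3],
                )
            )
    return out


def write_narrowpeak(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            qcol = -1.0 if p.q_value is None else -np.log10(max(p.q_value, 1e-300))
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.name}\t0\t.\t{p.signal_value:.6g}\t-1\t{qcol:.6g}\t-1\n"
            )


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = _split(line)[:2]
            sizes[name] = int(length)
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """Read a CAUSALdb-style SNP TSV (rsid, chrom, pos, posterior_prob,
    study_id, disease). ``pos`` is 1-based."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        pp = getattr(row, "posterior_prob", None)
        out.append(
            SnpRecord(
                rsid=str(row.rsid),
                chrom=str(row.chrom),
                pos=int(row.pos),
                posterior_prob=None if pp is None or pd.isna(pp) else float(pp),
                study_id=str(getattr(row, "study_id", "")),
                disease=str(getattr(row, "disease", "")),
            )
        )
    return out


def write_snp_table(snps: Sequence[SnpRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "rsid": [s.rsid for s in snps],
            "chrom": [s.chrom for s in snps],
            "pos": [s.pos for s in snps],
            "posterior_prob": [s.posterior_prob for s in snps],
            "study_id": [s.study_id for s in snps],
            "disease": [s.disease for s in snps],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneRecord(
            gene_id=str(r.gene_id),
            gene_name=str(getattr(r, "gene_name", r.gene_id)),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
        )
        for r in df.itertuples(index=False)
    ]


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "gene_name": [g.gene_name for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_eqtl_table(path: str | Path) -> list[tuple[SnpRecord, str]]:
    """Read an eQTL TSV (rsid, chrom, pos, gene_id, study_id) into
    (SNP, target gene id) pairs."""
    df = pd.read_csv(path, sep="\t")
    return [
        (
            SnpRecord(
                rsid=str(r.rsid),
                chrom=str(r.chrom),
                pos=int(r.pos),
                study_id=str(getattr(r, "study_id", "")),
            ),
            str(r.gene_id),
        )
        for r in df.itertuples(index=False)
    ]


def read_motif_occurrences(path: str | Path) -> pd.DataFrame:
    """Read a FIMO-style TSV with columns motif_id, chrom, start, end,
    q_value (coordinates 0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    required = {"motif_id", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: motif table missing columns {sorted(missing)}")
    if "q_value" not in df.columns:
        df["q_value"] = np.nan
    return df


# ---------------------------------------------------------------------------
# binned contact matrices (triplet TSV + bins BED)
# ---------------------------------------------------------------------------


def read_contact_matrix(
    triplet_path: str | Path, n_bins: int | None = None
) -> np.ndarray:
    """Read a symmetric contact matrix from a (bin_i, bin_j, count) TSV."""
    df = pd.read_csv(
        triplet_path, sep="\t", names=["i", "j", "count"], comment="#", header=None
    )
    if n_bins is None:
        n_bins = int(max(df["i"].max(), df["j"].max())) + 1
    mat = np.zeros((n_bins, n_bins))
    mat[df["i"], df["j"]] = df["count"]
    mat[df["j"], df["i"]] = df["count"]
    return mat


def write_contact_matrix(mat: np.ndarray, triplet_path: str | Path) -> None:
    """Write the upper triangle (incl. diagonal) of a symmetric matrix as a
    (bin_i, bin_j, count) TSV, omitting zeros."""
    iu, ju = np.triu_indices_from(mat)
    vals = mat[iu, ju]
    keep = vals != 0
    with open(triplet_path, "w") as fh:
        for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
            fh.write(f"{i}\t{j}\t{v:.10g}\n")
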