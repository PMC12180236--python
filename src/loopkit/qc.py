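"""Sample quality-control scoring, flags, and replicate reproducibility (SCC).

Each QC metric is scored on a 0-10 scale by piecewise-affine normalization of
the raw value over three intervals bounded by thresholds t1 and t2:
[min, t1] -> [0, 6] ("Poor"), [t1, t2] -> [6, 8] ("Warning"),
[t2, upper] -> [8, 10] ("Good"). Metrics where higher raw values indicate
poorer quality (duplicate rates etc.) are scored as the complement 10 - score.
Stage scores are metric-score means; the final flag is Good only when every
stage flag is Good, and otherwise the worst stage flag.

Replicate reproducibility uses the stratum-adjusted correlation coefficient
(SCC): both contact matrices are mean-smoothed, Pearson correlations are taken
per distance stratum (diagonal), and combined with weights
``w_d = N_d * sigma_a,d * sigma_b,d``. Replicate groups merge only when every
pairwise SCC exceeds 0.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "FLAG_ORDER",
    "MetricSpec",
    "MetricScore",
    "StageScore",
    "SccResult",
    "score_metric",
    "aggregate_stage",
    "final_flag",
    "flag_from_score",
    "scc",
    "train_h",
    "merge_decision",
    "select_high_confidence",
    "DEFAULT_METRIC_SPECS",
]

FLAG_ORDER = {"Poor": 0, "Warning": 1, "Good": 2}

IQR_RULE = "iqr"  # upper bound = cohort 75th percentile + 1.5 * IQR


@dataclass(frozen=True)
class MetricSpec:
    """Scoring specification for one QC metric.

    ``upper_bound`` is either a number (bounded metrics: the metric maximum)
    or the string ``"iqr"``, resolved against a cohort of observed values as
    the 75th percentile + 1.5 * IQR (upper-outlier fence).
    """

    name: str
    direction: str  # higher_better | lower_better
    t1: float
    t2: float
    min_value: float = 0.0
    upper_bound: float | str = IQR_RULE

    def __post_init__(self) -> None:
        if self.direction not in {"higher_better", "lower_better"}:
            raise ValueError(f"bad direction {self.direction!r}")
        if not (self.min_value < self.t1 < self.t2):
            raise ValueError(
                f"{self.name}: need min_value < t1 < t2, got "
                f"{self.min_value}, {self.t1}, {self.t2}"
            )
        if isinstance(self.upper_bound, (int, float)) and self.upper_bound <= self.t2:
            raise ValueError(f"{self.name}: upper_bound must exceed t2")

    def resolve_upper(self, cohort: Sequence[float] | None = None) -> float:
        if isinstance(self.upper_bound, (int, float)):
            return float(self.upper_bound)
        if self.upper_bound != IQR_RULE:
            raise ValueError(f"unknown upper-bound rule {self.upper_bound!r}")
        if cohort is None or len(cohort) == 0:
            raise ValueError(
                f"{self.name}: cohort values required to resolve IQR upper bound"
            )
        arr = np.asarray(cohort, dtype=float)
        q1, q3 = np.percentile(arr, [25, 75])
        upper = q3 + 1.5 * (q3 - q1)
        return float(max(upper, np.nextafter(self.t2, np.inf)))


@dataclass(frozen=True)
class MetricScore:
    name: str
    raw_value: float
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 10.0):
            raise ValueError("score must lie in [0, 10]")


@dataclass(frozen=True)
class StageScore:
    stage: str
    s_agg: float
    flag: str


@dataclass(frozen=True)
class SccResult:
    h: int
    scc: float
    strata_used: int
    strata_skipped: int = 0


def _piecewise_score(value: float, lo: float, t1: float, t2: float, hi: float) -> float:
    """Affine interpolation through (lo,0), (t1,6), (t2,8), (hi,10)."""
    if value <= lo:
        return 0.0
    if value >= hi:
        return 10.0
    if value < t1:
        return 6.0 * (value - lo) / (t1 - lo)
    if value < t2:
        return 6.0 + 2.0 * (value - t1) / (t2 - t1)
    return 8.0 + 2.0 * (value - t2) / (hi - t2)


def score_metric(
    value: float,
    spec: MetricSpec,
    cohort: Sequence[float] | None = None,
) -> MetricScore:
    """Score one raw metric value on the 0-10 scale.

    Values at or above the resolved upper bound (the metric maximum for
    bounded metrics, the cohort upper-outlier fence otherwise) score 10;
    values at or below ``min_value`` score 0. For ``lower_better`` metrics
    the complement ``10 - score`` is returned.
    """
    if not math.isfinite(value):
        raise ValueError(f"{spec.name}: non-finite metric value {value}")
    upper = spec.resolve_upper(cohort)
    s = _piecewise_score(value, spec.min_value, spec.t1, spec.t2, upper)
    if spec.direction == "lower_better":
        s = 10.0 - s
    return MetricScore(spec.name, value, min(max(s, 0.0), 10.0))


def flag_from_score(s_agg: float) -> str:
    """QC flag bands: Poor [0,6), Warning [6,8), Good [8,10]."""
    if not (0.0 <= s_agg <= 10.0):
        raise ValueError(f"aggregate score out of range: {s_agg}")
    if s_agg < 6.0:
        return "Poor"
    if s_agg < 8.0:
        return "Warning"
    return "Good"


def aggregate_stage(scores: Sequence[MetricScore], stage: str = "") -> StageScore:
    """Average metric scores for one processing stage and assign its flag."""
    if not scores:
        raise ValueError("cannot aggregate an empty score list")
    s_agg = sum(s.score for s in scores) / len(scores)
    return StageScore(stage, s_agg, flag_from_score(s_agg))


def final_flag(stage_flags: Sequence[str]) -> str:
    """Final QC verdict across processing stages: Good only when every stage
    is Good; otherwise the worst stage flag (any Poor -> Poor, else Warning)."""
    if not stage_flags:
        raise ValueError("need at least one stage flag")
    for f in stage_flags:
        if f not in FLAG_ORDER:
            raise ValueError(f"unknown flag {f!r}")
    return min(stage_flags, key=FLAG_ORDER.__getitem__)


# ---------------------------------------------------------------------------
# stratum-adjusted correlation coefficient
# ---------------------------------------------------------------------------


def _smooth(mat: np.ndarray, h: int) -> np.ndarray:
    if h == 0:
        return np.asarray(mat, dtype=float)
    return uniform_filter(np.asarray(mat, dtype=float), size=2 * h + 1, mode="constant")


def scc(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    h: int = 0,
    max_dist_bins: int | None = None,
) -> SccResult:
    """Stratum-adjusted correlation coefficient between two contact matrices
    on identical bin grids.

    Both matrices are smoothed with a (2h+1) x (2h+1) mean filter; for every
    diagonal stratum d <= max_dist_bins with nonzero variance in both
    matrices, the Pearson correlation r_d is computed, and the SCC is the
    weighted mean ``sum(w_d r_d) / sum(w_d)`` with
    ``w_d = N_d * sigma_a,d * sigma_b,d``.
    """
    a = np.asarray(mat_a, dtype=float)
    b = np.asarray(mat_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and share one bin grid")
    if h < 0:
        raise ValueError("smoothing half-width h must be >= 0")
    n = a.shape[0]
    if max_dist_bins is None:
        max_dist_bins = n - 1
    a = _smooth(a, h)
    b = _smooth(b, h)

    num = 0.0
    den = 0.0
    used = skipped = 0
    for d in range(min(max_dist_bins, n - 1) + 1):
        xa = np.diagonal(a, offset=d)
        xb = np.diagonal(b, offset=d)
        if xa.size < 2:
            continue
        sa = xa.std()
        sb = xb.std()
        if sa == 0.0 or sb == 0.0:
            skipped += 1
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        w = xa.size * sa * sb
        num += w * r
        den += w
        used += 1
    if used == 0:
        raise ValueError("no usable strata (all zero-variance)")
    return SccResult(h=h, scc=num / den, strata_used=used, strata_skipped=skipped)


def train_h(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    h_max: int = 25,
    max_dist_bins: int | None = None,
    tol: float = 0.01,
) -> int:
    """Grid-search the smoothing half-width: return the smallest h whose SCC
    gain over h-1 drops below ``tol`` (diminishing-returns rule), capped at
    ``h_max``."""
    prev = scc(mat_a, mat_b, h=0, max_dist_bins=max_dist_bins).scc
    for h in range(1, h_max + 1):
        cur = scc(mat_a, mat_b, h=h, max_dist_bins=max_dist_bins).scc
        if cur - prev < tol:
            return h - 1
        prev = cur
    return h_max


def merge_decision(
    pairwise: Sequence[SccResult],
    n_replicates: int | None = None,
    threshold: float = 0.8,
) -> bool:
    """True iff every pairwise replicate SCC strictly exceeds ``threshold``.

    When ``n_replicates`` is given, the number of supplied pairwise results
    must equal C(n, 2); a single replicate (no pairs) merges vacuously.
    """
    if n_replicates is not None:
        expected = n_replicates * (n_replicates - 1) // 2
        if len(pairwise) != expected:
            raise ValueError(
                f"expected {expected} pairwise SCCs for {n_replicates} "
                f"replicates, got {len(pairwise)}"
            )
        if expected == 0:
            return True
    if not pairwise:
        return True
    return all(r.scc > threshold for r in pairwise)


def select_high_confidence(
    samples: Iterable[Mapping],
    pulldown: str = "H3K27ac",
    loop_count_key: str = "n_stringent_5kb_fc_loops",
) -> list[Mapping]:
    """High-confidence sample selection: flag Good or Warning and a stringent
    5 kb FC loop count strictly above the pulldown-specific threshold
    (10,000 for H3K27ac / regulatory sets, 2,000 for CTCF / structural)."""
    threshold = 2000 if pulldown.upper() == "CTCF" else 10000
    kept = []
    for s in samples:
        if s.get("pulldown", pulldown) != pulldown:
            continue
        if s["flag"] not in {"Good", "Warning"}:
            continue
        if s[loop_count_key] > threshold:
            kept.append(s)
    return kept


#: Default metric specifications. The thresholds follow field-standard QC
#: guidance (ENCODE library-complexity fences, Hi-C valid-pair expectations);
#: they ship as overridable defaults because deployments differ in depth and
#: protocol. Rates are fractions in [0, 1]; counts are raw integers.
DEFAULT_METRIC_SPECS: dict[str, MetricSpec] = {
    spec.name: spec
    for spec in [
        MetricSpec("n_reads", "higher_better", 1e8, 2e8, 0, IQR_RULE),
        MetricSpec("n_valid_pairs", "higher_better", 5e7, 1e8, 0, IQR_RULE),
        MetricSpec("mean_mapping_pct", "higher_better", 60, 80, 0, 100),
        MetricSpec("valid_pairs_pct", "higher_better", 40, 60, 0, 100),
        MetricSpec("duplicate_pairs_pct", "lower_better", 20, 40, 0, 100),
        MetricSpec("cis_pairs_pct", "higher_better", 40, 60, 0, 100),
        MetricSpec("cis_longrange_pct", "higher_better", 15, 30, 0, 100),
        MetricSpec("n_peaks", "higher_better", 10000, 30000, 0, IQR_RULE),
        MetricSpec("n_loops", "higher_better", 1000, 10000, 0, IQR_RULE),
        MetricSpec("nrf", "higher_better", 0.5, 0.8, 0, 1),
        MetricSpec("pbc1", "higher_better", 0.5, 0.8, 0, 1),
        MetricSpec("pbc2", "higher_better", 1.0, 3.0, 0, IQR_RULE),
        MetricSpec("nsc", "higher_better", 1.05, 1.1, 1.0, IQR_RULE),
        MetricSpec("rsc", "higher_better", 0.8, 1.0, 0, IQR_RULE),
    ]
}


def load_metric_specs(path) -> dict[str, MetricSpec]:
    """Load metric specifications from a YAML mapping
    ``name -> {direction, t1, t2, min_value, upper_bound}``."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = {}
    for name, cfg in raw.items():
        specs[name] = MetricSpec(
            name=name,
            direction=cfg["direction"],
            t1=float(cfg["t1"]),
            t2=float(cfg["t2"]),
            min_value=float(cfg.get("min_value", 0.0)),
            upper_bound=(
                cfg.get("upper_bound", IQR_RULE)
                if isinstance(cfg.get("upper_bound", IQR_RULE), str)
                else float(cfg["upper_bound"])
            ),
        )
    return specs
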