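"""Sample- and gene-level capture enrichment statistics.

The central quantities:

* **on-target fraction** — share of usable reads assigned to panel
  coordinates in one library;
* **sample enrichment factor** — post-capture on-target fraction over
  pre-capture on-target fraction (values of tens to hundreds for a
  successful capture);
* **gene enrichment factor** — per-gene ratio of mean post-capture CPM
  to mean pre-capture CPM, displayed as ``log2(EF + 1)`` so that
  not-enriched genes map into (0, 1);
* **expression cut-off** — the breakpoint of a continuous two-segment
  ("broken-stick") linear regression of gene enrichment on log10
  pre-capture expression, selected against a single line by AICc.  Below
  the cut-off, enrichment estimates inflate because pre-capture
  denominators approach the detection limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .intervals import GenomicInterval, merge_intervals
from .panel import TargetPanel

__all__ = [
    "CountMatrix",
    "EnrichmentResult",
    "GeneEnrichment",
    "SlrFit",
    "cpm_normalize",
    "on_target_fraction",
    "sample_enrichment_factor",
    "gene_enrichment",
    "fit_segmental_linear",
    "expression_threshold",
    "replicate_cv",
    "compare_cv",
    "group_cv",
    "validate_read_balance",
    "stage_correlation",
]

CATEGORIES = ("enriched", "rescued", "not_enriched", "undetected")


@dataclass
class CountMatrix:
    """Gene x sample read counts with per-sample phase metadata.

    ``counts`` is a genes-by-samples integer DataFrame; ``samples`` has
    one row per column of ``counts`` with at least a ``phase`` column
    (``pre``/``post``) and optionally ``capture`` and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        if not self.counts.columns.equals(self.samples.index):
            missing = set(self.counts.columns) ^ set(self.samples.index)
            raise ValueError(f"counts/sample-metadata mismatch: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def library_size(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def phase_samples(self, phase: str) -> list[str]:
        return list(self.samples.index[self.samples["phase"] == phase])


def cpm_normalize(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalisation; every column sums to 1e6."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    libsize = mat.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return mat / libsize * 1e6


def on_target_fraction(
    reads: Iterable[GenomicInterval] | Mapping[str, int] | pd.Series,
    panel: TargetPanel | Sequence[GenomicInterval] | set,
    total_reads: int | None = None,
) -> float:
    """Fraction of reads assigned to panel coordinates.

    BED-mode: ``reads`` are aligned-read intervals and a read is
    on-target when it overlaps any panel base.  Count-mode: ``reads``
    maps gene_id -> count and ``panel`` is the set of targeted gene ids.
    ``total_reads`` defaults to the number/sum of reads supplied.
    """
    if isinstance(reads, (Mapping, pd.Series)):
        series = pd.Series(reads)
        targeted = set(panel)
        on = int(series[series.index.isin(targeted)].sum())
        total = int(series.sum()) if total_reads is None else total_reads
    else:
        reads = list(reads)
        regions = panel.targets if isinstance(panel, TargetPanel) else list(panel)
        regions = merge_intervals(regions)
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        starts = {c: np.array([r.start for r in rs]) for c, rs in by_chrom.items()}
        ends = {c: np.array([r.end for r in rs]) for c, rs in by_chrom.items()}
        on = 0
        for rd in reads:
            if rd.chrom not in starts:
                continue
            i = np.searchsorted(ends[rd.chrom], rd.start, side="right")
            if i < len(starts[rd.chrom]) and starts[rd.chrom][i] < rd.end:
                on += 1
        total = len(reads) if total_reads is None else total_reads
    if total <= 0:
        raise ValueError("total_reads must be positive")
    return on / total


def sample_enrichment_factor(pre_fraction: float, post_fraction: float) -> float:
    """Sample-level enrichment: post on-target share over pre on-target share."""
    for f, label in ((pre_fraction, "pre"), (post_fraction, "post")):
        if not 0 <= f <= 1:
            raise ValueError(f"{label}_fraction must be in [0,1], got {f}")
    if pre_fraction == 0:
        return math.nan
    return post_fraction / pre_fraction


@dataclass(frozen=True)
class EnrichmentResult:
    gene_id: str
    pre_mean: float
    post_mean: float
    ef_raw: float  # nan when pre_mean == 0
    ef_log: float  # log2(ef_raw + pseudocount)
    category: str


@dataclass
class GeneEnrichment:
    """Per-gene enrichment table plus the capture success rate."""

    results: list[EnrichmentResult]
    success_rate: float  # % of genes detected pre-capture that were enriched

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for r in self.results:
            out[r.category] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.gene_id, r.pre_mean, r.post_mean, r.ef_raw, r.ef_log, r.category)
                for r in self.results
            ],
            columns=["gene_id", "pre_mean", "post_mean", "ef_raw", "ef_log", "category"],
        ).set_index("gene_id")


def gene_enrichment(
    counts: CountMatrix,
    targeted_genes: Sequence[str],
    pseudocount: float = 1.0,
) -> GeneEnrichment:
    """Per-gene enrichment factors and categories for the targeted genes.

    Categories partition the panel: *rescued* genes have zero reads in
    every pre-capture replicate but appear post-capture; *undetected*
    genes are absent from both; genes detected pre-capture are *enriched*
    when EF > 1 and *not_enriched* otherwise.
    """
    missing = [g for g in targeted_genes if g not in counts.genes]
    if missing:
        raise KeyError(f"targeted gene(s) absent from count matrix: {missing[:5]}")
    cpm = cpm_normalize(counts)
    pre_cols = counts.phase_samples("pre")
    post_cols = counts.phase_samples("post")
    if not pre_cols or not post_cols:
        raise ValueError("need at least one pre and one post sample")
    pre_mean = cpm[pre_cols].mean(axis=1)
    post_mean = cpm[post_cols].mean(axis=1)
    results = []
    n_pre_detected = n_enriched = 0
    for g in targeted_genes:
        pre, post = float(pre_mean[g]), float(post_mean[g])
        if pre == 0:
            ef = math.nan
            cat = "rescued" if post > 0 else "undetected"
            ef_log = math.nan
        else:
            ef = post / pre
            cat = "enriched" if ef > 1 else "not_enriched"
            ef_log = math.log2(ef + pseudocount)
            n_pre_detected += 1
            n_enriched += cat == "enriched"
        results.append(EnrichmentResult(g, pre, post, ef, ef_log, cat))
    rate = 100.0 * n_enriched / n_pre_detected if n_pre_detected else math.nan
    return GeneEnrichment(results, rate)


# ---------------------------------------------------------------------------
# Segmental (broken-stick) linear regression with AICc model selection


@dataclass
class SlrFit:
    breakpoint: float
    intercept: float
    slope_left: float
    slope_right: float
    rss: float
    rss_linear: float
    aicc_slr: float
    aicc_linear: float
    selected_model: str  # "segmental" | "linear"

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        left = self.intercept + self.slope_left * x
        right = (
            self.intercept
            + self.slope_left * self.breakpoint
            + self.slope_right * (x - self.breakpoint)
        )
        return np.where(x <= self.breakpoint, left, right)


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)  # guard log of a perfect fit
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _slr_rss(x: np.ndarray, y: np.ndarray, x0: float):
    """Conditional OLS of the continuous two-segment model at fixed x0."""
    X = np.column_stack([np.ones_like(x), x, np.where(x > x0, x - x0, 0.0)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def fit_segmental_linear(
    x: Sequence[float],
    y: Sequence[float],
    n_grid: int = 101,
    quantile_range: tuple[float, float] = (0.05, 0.95),
) -> SlrFit:
    """Fit a continuous two-segment regression and select it against a line.

    The breakpoint is grid-searched over ``n_grid`` x-quantiles between
    the 5th and 95th percentile (candidates keeping >= 3 distinct x on
    each side), each candidate solved by conditional OLS, then refined by
    golden-section search around the best grid cell.  Both the segmental
    (K=5: intercept, two slopes, breakpoint, sigma) and single-line
    (K=3) models are scored with small-sample AICc
    ``n ln(RSS/n) + 2K + 2K(K+1)/(n-K-1)`` and the minimiser selected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 8:
        raise ValueError(f"need >= 8 points for segmental regression, got {n}")
    distinct = np.unique(x)
    if len(distinct) < 7:
        raise ValueError("x is too degenerate: need >= 7 distinct values")

    qs = np.quantile(x, np.linspace(*quantile_range, n_grid))
    candidates = []
    for x0 in np.unique(qs):
        if (distinct < x0).sum() >= 3 and (distinct > x0).sum() >= 3:
            candidates.append(x0)
    if not candidates:
        raise ValueError("no admissible breakpoint candidates (x too clustered)")

    rss_grid = [(_slr_rss(x, y, x0)[0], x0) for x0 in candidates]
    best_rss, best_x0 = min(rss_grid)
    i = candidates.index(best_x0)
    lo = candidates[max(0, i - 1)]
    hi = candidates[min(len(candidates) - 1, i + 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda x0: _slr_rss(x, y, x0)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if res.fun <= best_rss:
            best_rss, best_x0 = float(res.fun), float(res.x)
    _, beta = _slr_rss(x, y, best_x0)

    lin = np.polynomial.polynomial.polyfit(x, y, 1)
    resid_lin = y - (lin[0] + lin[1] * x)
    rss_lin = float(resid_lin @ resid_lin)

    aicc_slr = _aicc(best_rss, n, 5)
    aicc_lin = _aicc(rss_lin, n, 3)
    return SlrFit(
        breakpoint=float(best_x0),
        intercept=float(beta[0]),
        slope_left=float(beta[1]),
        slope_right=float(beta[1] + beta[2]),
        rss=best_rss,
        rss_linear=rss_lin,
        aicc_slr=aicc_slr,
        aicc_linear=aicc_lin,
        selected_model="segmental" if aicc_slr < aicc_lin else "linear",
    )


def expression_threshold(
    enrichment: GeneEnrichment,
) -> tuple[float | None, SlrFit]:
    """Expression cut-off (CPM) below which enrichment estimates inflate.

    Fits ``ef_log`` against log10 pre-capture mean CPM over genes
    detected pre-capture; returns ``10**breakpoint`` when the segmental
    model wins on AICc, else ``None`` (no cut-off supported by the data).
    """
    pts = [
        (math.log10(r.pre_mean), r.ef_log)
        for r in enrichment.results
        if r.pre_mean > 0 and math.isfinite(r.ef_log)
    ]
    if len(pts) < 8:
        raise ValueError("too few pre-detected genes for a threshold fit")
    xs, ys = zip(*pts)
    fit = fit_segmental_linear(xs, ys)
    cutoff = 10.0 ** fit.breakpoint if fit.selected_model == "segmental" else None
    return cutoff, fit


# ---------------------------------------------------------------------------
# Replicate variability


def replicate_cv(cpm: pd.DataFrame, group: Sequence[str]) -> pd.Series:
    """Per-gene coefficient of variation (sd/mean, sd with ddof=1) within a
    replicate group; genes with zero group mean are dropped."""
    if len(group) < 2:
        raise ValueError("need >= 2 replicates for a CV")
    sub = cpm[list(group)]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    cv = (sd / mean)[mean > 0]
    cv.name = "cv"
    return cv


def compare_cv(
    pre_cv: pd.Series,
    post_cv: pd.Series,
    zero_method: str = "wilcox",
) -> dict:
    """Two-sided Wilcoxon matched-pairs signed-rank test on paired gene CVs.

    Pairs genes present in both series; exact null distribution for
    n <= 25 pairs, normal approximation with continuity correction above.
    ``zero_method='wilcox'`` drops zero differences (Pratt handling via
    ``'pratt'``).
    """
    shared = pre_cv.index.intersection(post_cv.index)
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes shared between groups")
    a = pre_cv[shared].to_numpy()
    b = post_cv[shared].to_numpy()
    nonzero = int((a != b).sum())
    method = "exact" if nonzero <= 25 else "approx"
    res = stats.wilcoxon(
        a, b, zero_method=zero_method, correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return {
        "n_pairs": int(len(shared)),
        "statistic": float(res.statistic),
        "pvalue": float(res.pvalue),
        "median_pre": float(np.median(a)),
        "median_post": float(np.median(b)),
    }


def group_cv(
    enrichment: GeneEnrichment, threshold_cpm: float
) -> tuple[float, float]:
    """CV of raw enrichment factors above vs below the expression cut-off.

    Strata split strictly: above = pre mean > threshold, below = pre mean
    <= threshold (detected genes only).  A stratum with < 2 genes yields
    NaN.
    """
    if threshold_cpm <= 0:
        raise ValueError("threshold must be positive")
    above, below = [], []
    for r in enrichment.results:
        if r.pre_mean <= 0 or not math.isfinite(r.ef_raw):
            continue
        (above if r.pre_mean > threshold_cpm else below).append(r.ef_raw)

    def _cv(vals: list[float]) -> float:
        if len(vals) < 2:
            return math.nan
        arr = np.array(vals)
        return float(arr.std(ddof=1) / arr.mean())

    return _cv(above), _cv(below)


def validate_read_balance(
    pre_usable: Mapping[str, int], post_on_target: Mapping[str, int]
) -> pd.DataFrame:
    """Pre/post read-balance check per sample pair.

    A pair passes when the pre-capture library's usable reads are >= the
    post-capture library's on-target reads; failing pairs are flagged for
    exclusion rather than downsampled (downsampling the pre library
    would bias read selection).
    """
    pre = pd.Series(pre_usable)
    post = pd.Series(post_on_target)
    unpaired = pre.index.symmetric_difference(post.index)
    if len(unpaired):
        raise ValueError(f"unpaired sample(s): {sorted(unpaired)}")
    df = pd.DataFrame({"pre_usable": pre, "post_on_target": post})
    df["pass"] = df["pre_usable"] >= df["post_on_target"]
    return df


# ---------------------------------------------------------------------------
# Reference-stage correlation


def stage_correlation(
    sample_profiles: pd.DataFrame,
    reference: pd.DataFrame,
    replicate_of: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Correlate samples against reference developmental-stage profiles.

    ``sample_profiles`` is genes x samples expression; ``reference`` is
    genes x reference-columns.  When ``replicate_of`` maps reference
    columns to stage names, replicate profiles are averaged per stage
    first.  Pearson correlation is computed on ``log2(x+1)`` over the
    shared genes; each sample is assigned the argmax stage (ties ->
    earliest reference column order).
    """
    if replicate_of:
        stages: dict[str, list[str]] = {}
        for col, stage in replicate_of.items():
            stages.setdefault(stage, []).append(col)
        reference = pd.DataFrame(
            {s: reference[cols].mean(axis=1) for s, cols in stages.items()}
        )
    shared = sample_profiles.index.intersection(reference.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    s = np.log2(sample_profiles.loc[shared] + 1)
    r = np.log2(reference.loc[shared] + 1)
    corr = pd.DataFrame(index=s.columns, columns=r.columns, dtype=float)
    for sample in s.columns:
        sv = s[sample].to_numpy()
        if np.std(sv) == 0:
            raise ValueError(f"sample {sample!r} has constant profile")
        for stage in r.columns:
            rv = r[stage].to_numpy()
            if np.std(rv) == 0:
                raise ValueError(f"reference stage {stage!r} has constant profile")
            corr.loc[sample, stage] = stats.pearsonr(sv, rv).statistic
    assigned = corr.idxmax(axis=1)  # idxmax takes the first (earliest) on ties
    assigned.name = "assigned_stage"
    return corr, assigned
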