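"""ERCC-style spike-in sensitivity and quantitation QC.

Spike-ins are synthetic RNAs of known concentration (attomoles/µl) added
to each library; a subset is targeted by the capture panel.  Their
dose-response — counts per kilobase per million reads (CPKM) versus
known concentration — calibrates detection sensitivity (the lowest
detectable ladder rung), quantitation linearity (Spearman rho and the
log10-log10 regression slope), and the depletion of non-targeted
spike-ins by capture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpikeInLadder",
    "cpkm",
    "detect",
    "detection_threshold",
    "threshold_improvement",
    "concentration_correlation",
    "loglog_slope",
    "depletion_factor",
    "flag_low_complexity",
]

LADDER_COLUMNS = ["spike_id", "length_nt", "concentration_attomol_ul", "targeted"]


@dataclass
class SpikeInLadder:
    """Known spike-in concentrations, lengths and targeted flags."""

    table: pd.DataFrame  # indexed by spike_id

    def __post_init__(self) -> None:
        t = self.table
        for col in ("length_nt", "concentration_attomol_ul", "targeted"):
            if col not in t.columns:
                raise ValueError(f"ladder table missing column {col!r}")
        if (t["concentration_attomol_ul"] <= 0).any():
            raise ValueError("spike-in concentrations must be positive")
        if (t["length_nt"] <= 0).any():
            raise ValueError("spike-in lengths must be positive")

    @classmethod
    def from_tsv(cls, path) -> "SpikeInLadder":
        df = pd.read_csv(path, sep="\t")
        df["targeted"] = df["targeted"].astype(bool)
        return cls(df.set_index("spike_id"))

    def to_tsv(self, path) -> None:
        out = self.table.reset_index()
        out["targeted"] = out["targeted"].astype(int)
        out.to_csv(path, sep="\t", index=False)

    @property
    def spike_ids(self) -> pd.Index:
        return self.table.index

    @property
    def concentration(self) -> pd.Series:
        return self.table["concentration_attomol_ul"]

    @property
    def targeted_ids(self) -> pd.Index:
        return self.table.index[self.table["targeted"].astype(bool)]

    @property
    def non_targeted_ids(self) -> pd.Index:
        return self.table.index[~self.table["targeted"].astype(bool)]


def cpkm(
    counts: pd.Series | Mapping[str, int],
    lengths: pd.Series | Mapping[str, int],
    total_reads: int,
) -> pd.Series:
    """Counts per kilobase of spike-in length per million total reads.

    ``cpkm = count / (length/1000) / (total_reads/1e6)``.  The denominator
    is the library's total usable reads (not the spike-in subtotal).
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("every spike-in needs a positive length")
    return counts / (lengths / 1e3) / (total_reads / 1e6)


def detect(
    counts: pd.DataFrame | pd.Series, min_reads: int = 1
) -> pd.Series:
    """Detection flags: >= ``min_reads`` in >= 1 replicate (column)."""
    if isinstance(counts, pd.Series):
        return counts >= min_reads
    return (counts >= min_reads).any(axis=1)


def detection_threshold(
    ladder: SpikeInLadder,
    counts: pd.DataFrame | pd.Series,
    min_reads: int = 1,
    targeted_only: bool = True,
) -> float:
    """Lowest known concentration among detected (targeted) spike-ins.

    NaN when nothing is detected.
    """
    flags = detect(counts, min_reads)
    ids = ladder.targeted_ids if targeted_only else ladder.spike_ids
    detected = [s for s in ids if flags.get(s, False)]
    if not detected:
        return math.nan
    return float(ladder.concentration[detected].min())


def threshold_improvement(pre_threshold: float, post_threshold: float) -> float:
    """Fold improvement in detection sensitivity: pre threshold / post."""
    if not (math.isfinite(pre_threshold) and math.isfinite(post_threshold)):
        return math.nan
    if post_threshold <= 0:
        raise ValueError("thresholds must be positive concentrations")
    return pre_threshold / post_threshold


def concentration_correlation(
    cpkm_values: pd.Series,
    ladder: SpikeInLadder,
    targeted_only: bool = True,
) -> tuple[float, float]:
    """Spearman rho (and two-tailed p) of CPKM vs known concentration.

    Computed over detected (CPKM > 0) targeted spike-ins; needs >= 5.
    """
    ids = ladder.targeted_ids if targeted_only else ladder.spike_ids
    vals = cpkm_values.reindex(ids).dropna()
    vals = vals[vals > 0]
    if len(vals) < 5:
        raise ValueError(f"only {len(vals)} detected spike-ins; need >= 5")
    conc = ladder.concentration[vals.index]
    res = stats.spearmanr(conc, vals, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def loglog_slope(
    cpkm_values: pd.Series,
    ladder: SpikeInLadder,
    targeted_only: bool = True,
) -> tuple[float, float]:
    """OLS slope and intercept of log10 CPKM on log10 concentration.

    A perfectly quantitative library has slope 1 (CPKM proportional to
    input concentration); saturation or detection-limit censoring pulls
    the slope away from 1.  Detected spike-ins only; needs >= 3.
    """
    ids = ladder.targeted_ids if targeted_only else ladder.spike_ids
    vals = cpkm_values.reindex(ids).dropna()
    vals = vals[vals > 0]
    if len(vals) < 3:
        raise ValueError(f"only {len(vals)} detected spike-ins; need >= 3")
    x = np.log10(ladder.concentration[vals.index].to_numpy(dtype=float))
    y = np.log10(vals.to_numpy(dtype=float))
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def depletion_factor(
    pre_cpkm: pd.Series,
    post_cpkm: pd.Series,
    ladder: SpikeInLadder,
) -> float:
    """Fold depletion of non-targeted spike-ins by capture.

    Mean pre-capture CPKM over mean post-capture CPKM across the
    non-targeted subset; infinite when they vanish entirely post-capture.
    """
    ids = ladder.non_targeted_ids
    if len(ids) == 0:
        raise ValueError("ladder has no non-targeted spike-ins")
    pre = float(pre_cpkm.reindex(ids).fillna(0).mean())
    post = float(post_cpkm.reindex(ids).fillna(0).mean())
    if post == 0:
        return math.inf
    return pre / post


def flag_low_complexity(
    library_complexity: Mapping[str, float], percentile: float = 10.0
) -> dict[str, bool]:
    """QC flag for poor-quality libraries (complexity below a percentile).

    Returns an explicit per-sample flag; flagged libraries should be
    excluded from spike-in quantification rather than silently dropped.
    """
    s = pd.Series(library_complexity, dtype=float)
    cut = np.percentile(s.to_numpy(), percentile)
    return {k: bool(v < cut) for k, v in s.items()}
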