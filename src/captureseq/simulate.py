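"""Synthetic data generator for capture experiments.

Generates every input the pipeline needs — toy genome annotations with
repeat/EST/SNP/LD-block tracks, pre-/post-capture count matrices from an
explicit generative model, and spike-in dilution ladders — while
retaining the ground truth so parameter-recovery tests can compare
estimates against known values.

The capture generative model
----------------------------

Gene abundances λ_g are log-normal; a library of fixed depth draws read
counts from a multinomial over the (normalised) abundance vector.
Low-input (mini-bulk) pre-capture libraries lose whole transcripts:
gene g drops out with probability ``exp(-λ_g / κ)``, drawn once per
gene (the loss happens in the shared low-input RNA extraction, so the
same genes are missing from every pre-capture replicate).  Capture
multiplies the sampling weight of every targeted gene (and targeted
spike-in) by its efficiency C_g; non-targeted material carries over with
weight 1.  Writing Λ_T and Λ_N for targeted and non-targeted abundance
mass, the expected post-capture on-target share is
``C·Λ_T / (C·Λ_T + Λ_N)`` and the expected sample enrichment factor is
``EF = C / (C·p + 1 - p)`` with ``p = Λ_T/(Λ_T+Λ_N)`` the pre-capture
on-target share — the homogeneous closed form; with per-gene C_g or
pre-only dropout the truth object stores the exact expectation computed
from the weight vectors themselves.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import AnnotationSet, GenomicInterval, TranscriptModel, write_bed, write_gtf
from .spikein import SpikeInLadder

__all__ = [
    "CaptureSimParams",
    "CaptureSimTruth",
    "generate_annotation",
    "generate_spikein_ladder",
    "simulate_pre_capture",
    "simulate_post_capture",
    "simulate_experiment",
    "make_scenario",
    "SCENARIOS",
]

REPEAT_CLASSES = ("rRNA", "tRNA", "7SK", "srpRNA", "LINE", "SINE", "LTR")
RNA_REPEAT_CLASSES = ("rRNA", "tRNA", "7SK", "srpRNA")


# ---------------------------------------------------------------------------
# Toy genome annotation


def generate_annotation(
    n_genes: int = 50,
    chrom_len: int = 1_000_000,
    biotype_mix: dict[str, float] | None = None,
    repeat_density: float = 20e-6,
    est_density: float = 20e-6,
    n_snps: int = 40,
    n_blocks: int = 12,
    seed: int = 0,
    chrom: str = "chrT",
) -> AnnotationSet:
    """Random non-overlapping gene models plus auxiliary tracks.

    Genes have 1–10 exons (100–500 nt) separated by 200–2000 nt introns;
    coding genes carry a CDS inset 30 nt from each end of the exon
    chain.  Tracks: ``repeats`` (classed, includes RNA repeats),
    ``ests``, ``ld_blocks_tier1..3`` and a ``snps`` DataFrame stored on
    the returned object as ``annotation.snps``.  Deterministic under
    ``seed``; raises if the genes cannot be packed onto the chromosome.
    """
    rng = np.random.default_rng(seed)
    mix = biotype_mix or {"coding": 0.55, "lncRNA": 0.35, "other": 0.10}
    biotypes = rng.choice(list(mix), size=n_genes, p=np.array(list(mix.values())))

    transcripts: list[TranscriptModel] = []
    cursor = int(rng.integers(500, 2000))
    for i in range(n_genes):
        n_exons = int(rng.integers(1, 11))
        exons = []
        pos = cursor
        for j in range(n_exons):
            elen = int(rng.integers(100, 501))
            exons.append(GenomicInterval(chrom, pos, pos + elen))
            pos += elen
            if j < n_exons - 1:
                pos += int(rng.integers(200, 2001))
        if pos > chrom_len - 2000:
            raise ValueError(
                f"cannot pack {n_genes} genes onto a {chrom_len} nt chromosome"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        gid, tid = f"G{i:04d}", f"T{i:04d}"
        biotype = str(biotypes[i])
        cds = None
        if biotype == "coding":
            cds = []
            for k, e in enumerate(exons):
                s = e.start + 30 if k == 0 else e.start
                e_ = e.end - 30 if k == len(exons) - 1 else e.end
                if e_ > s:
                    cds.append(GenomicInterval(chrom, s, e_, strand))
        transcripts.append(
            TranscriptModel(tid, gid, biotype, strand,
                            [dataclasses.replace(e, strand=strand) for e in exons],
                            cds)
        )
        cursor = pos + int(rng.integers(1000, 5000))

    # repeats and ESTs in any position (overlaps with genes are realistic)
    def _track(density: float, classed: bool) -> list[GenomicInterval]:
        n = int(density * chrom_len)
        out = []
        for j in range(n):
            s = int(rng.integers(0, chrom_len - 600))
            ln = int(rng.integers(80, 400))
            name = str(rng.choice(REPEAT_CLASSES)) if classed else f"EST{j:04d}"
            out.append(GenomicInterval(chrom, s, s + ln, ".", name))
        return sorted(out, key=GenomicInterval.sort_key)

    repeats = _track(repeat_density, classed=True)
    ests = _track(est_density, classed=False)

    # LD blocks in three preference tiers, and SNPs (some inside blocks)
    tiers: dict[str, list[GenomicInterval]] = {}
    blocks_all: list[GenomicInterval] = []
    for tier in (1, 2, 3):
        n = max(1, n_blocks // (2 ** (tier - 1)))
        tier_blocks = []
        for j in range(n):
            s = int(rng.integers(0, chrom_len - 30_000))
            ln = int(rng.integers(2_000, 25_000))
            tier_blocks.append(
                GenomicInterval(chrom, s, s + ln, ".", f"LD{tier}_{j:03d}")
            )
        tiers[f"ld_blocks_tier{tier}"] = sorted(
            tier_blocks, key=GenomicInterval.sort_key
        )
        blocks_all.extend(tier_blocks)

    snp_rows = []
    phenos = ("parkinsons", "schizophrenia", "epilepsy")
    for j in range(n_snps):
        if j % 2 == 0 and blocks_all:  # half the SNPs land inside a block
            b = blocks_all[int(rng.integers(0, len(blocks_all)))]
            pos = int(rng.integers(b.start, b.end))
        else:
            pos = int(rng.integers(0, chrom_len))
        pval = 10.0 ** float(rng.uniform(-12, -4))
        snp_rows.append(
            (f"rs{j:06d}", chrom, pos, pval, str(rng.choice(phenos)))
        )
    snps = pd.DataFrame(
        snp_rows, columns=["snp_id", "chrom", "pos", "pvalue", "phenotype"]
    )

    ann = AnnotationSet(
        transcripts,
        tracks={"repeats": repeats, "ests": ests, **tiers},
        chrom_sizes={chrom: chrom_len},
    )
    ann.snps = snps  # auxiliary table, not an interval track
    return ann


# ---------------------------------------------------------------------------
# Spike-in ladders


def generate_spikein_ladder(
    n_spikes: int = 24,
    top_conc: float = 30_000.0,
    dilution: float = 2.0,
    targeted_fraction: float = 56 / 92,
    seed: int = 0,
) -> SpikeInLadder:
    """A ``dilution``-fold concentration ladder of synthetic spike-ins.

    Concentrations are ``top_conc / dilution**k`` (attomoles/µl), lengths
    uniform 250–2000 nt, targeted flags Bernoulli(``targeted_fraction``)
    — the default fraction mirrors a 56-of-92 cut-down ERCC set.  At
    least one spike-in on each side of the targeted flag is guaranteed.
    """
    if n_spikes < 4:
        raise ValueError("need at least 4 spike-ins for a useful ladder")
    rng = np.random.default_rng(seed)
    conc = top_conc / dilution ** np.arange(n_spikes)
    lengths = rng.integers(250, 2001, size=n_spikes)
    targeted = rng.random(n_spikes) < targeted_fraction
    if targeted.all():
        targeted[int(rng.integers(0, n_spikes))] = False
    if not targeted.any():
        targeted[int(rng.integers(0, n_spikes))] = True
    table = pd.DataFrame(
        {
            "length_nt": lengths,
            "concentration_attomol_ul": conc,
            "targeted": targeted,
        },
        index=pd.Index([f"SPIKE_{i:03d}" for i in range(n_spikes)], name="spike_id"),
    )
    return SpikeInLadder(table)


# ---------------------------------------------------------------------------
# Count simulation


@dataclass
class CaptureSimParams:
    """Parameters of the capture generative model (defaults: a mini-bulk
    capture of 5% of a 2000-gene transcriptome at 1e6 reads)."""

    n_genes: int = 2000
    targeted_fraction: float = 0.05
    target_low_expression: bool = False  # sample targets from the low-λ half
    expr_mean_log: float = 0.0  # natural-log mean of log-normal abundance
    expr_sigma_log: float = 1.5
    expr_floor: float = 0.05  # abundance floor: keeps every gene detectable
    depth_pre: int = 1_000_000
    depth_post: int = 1_000_000
    capture_efficiency: float = 60.0  # mean per-gene efficiency C
    capture_spread: float = 0.0  # sd of log C across targeted genes
    carryover_weight: float = 1.0  # weight of non-targeted material post-capture
    dropout_kappa: float = 0.16  # P(dropout) = exp(-λ/κ); 0 disables
    dropout_post: bool = False  # also drop out post-capture (library-level loss)
    spike_mass_fraction: float = 0.02  # spike share of total library mass
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.targeted_fraction < 1:
            raise ValueError("targeted_fraction must be in (0,1)")
        if self.depth_pre <= 0 or self.depth_post <= 0:
            raise ValueError("depths must be positive")
        if self.capture_efficiency <= 0:
            raise ValueError("capture_efficiency must be positive")


@dataclass
class CaptureSimTruth:
    """Ground truth of one simulated capture experiment."""

    lam: pd.Series  # true abundance per gene
    dropout: pd.Series  # bool per gene: lost from pre-capture libraries
    capture_eff: pd.Series  # realized C per gene (1 for non-targeted)
    targeted_genes: list[str]
    spike_lam: pd.Series  # abundance assigned to each spike-in
    spike_targeted: pd.Series
    expected_pre_on_target: float
    expected_post_on_target: float
    expected_ef: float  # exact: post share / pre share from the weight vectors
    expected_ef_homogeneous: float  # C/(Cp+1-p) with mass-weighted C
    params: CaptureSimParams

    def expected_rescued(self) -> set[str]:
        """Targeted genes absent pre-capture (dropout) but present post."""
        dropped = set(self.dropout.index[self.dropout])
        return dropped & set(self.targeted_genes)

    def on_target_ids(self) -> list[str]:
        """Every probed id: targeted genes plus targeted spike-ins."""
        spikes = list(self.spike_targeted.index[self.spike_targeted])
        return self.targeted_genes + spikes

    def to_json(self, path) -> None:
        payload = {
            "params": dataclasses.asdict(self.params),
            "lam": self.lam.round(6).to_dict(),
            "dropout": {k: bool(v) for k, v in self.dropout.items()},
            "capture_eff": self.capture_eff.round(6).to_dict(),
            "targeted_genes": self.targeted_genes,
            "spike_lam": self.spike_lam.round(9).to_dict(),
            "spike_targeted": {k: bool(v) for k, v in self.spike_targeted.items()},
            "expected_pre_on_target": self.expected_pre_on_target,
            "expected_post_on_target": self.expected_post_on_target,
            "expected_ef": self.expected_ef,
            "expected_ef_homogeneous": self.expected_ef_homogeneous,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _draw_truth(
    params: CaptureSimParams, ladder: SpikeInLadder | None
) -> CaptureSimTruth:
    rng = np.random.default_rng(params.seed)
    genes = [f"G{i:04d}" for i in range(params.n_genes)]
    lam = np.exp(rng.normal(params.expr_mean_log, params.expr_sigma_log,
                            params.n_genes))
    lam = np.clip(lam, params.expr_floor, None)

    n_targeted = max(1, round(params.targeted_fraction * params.n_genes))
    if params.target_low_expression:
        pool = np.argsort(lam)[: params.n_genes // 2]
    else:
        pool = np.arange(params.n_genes)
    targeted_idx = rng.choice(pool, size=n_targeted, replace=False)
    targeted = np.zeros(params.n_genes, dtype=bool)
    targeted[targeted_idx] = True

    ceff = np.ones(params.n_genes)
    if params.capture_spread > 0:
        draw = rng.lognormal(
            math.log(params.capture_efficiency), params.capture_spread, n_targeted
        )
    else:
        draw = np.full(n_targeted, params.capture_efficiency)
    ceff[targeted_idx] = draw

    if params.dropout_kappa > 0:
        p_drop = np.exp(-lam / params.dropout_kappa)
        dropout = rng.random(params.n_genes) < p_drop
    else:
        dropout = np.zeros(params.n_genes, dtype=bool)

    # spike-ins: weight ∝ concentration × length, scaled to the requested
    # share of total library mass (spikes never drop out)
    if ladder is not None:
        raw = (
            ladder.concentration * ladder.table["length_nt"] / 1e3
        ).to_numpy(dtype=float)
        scale = (
            params.spike_mass_fraction
            / (1 - params.spike_mass_fraction)
            * lam.sum()
            / raw.sum()
        )
        spike_lam = pd.Series(raw * scale, index=ladder.spike_ids)
        spike_targeted = ladder.table["targeted"].astype(bool)
    else:
        spike_lam = pd.Series(dtype=float)
        spike_targeted = pd.Series(dtype=bool)

    lam_s = pd.Series(lam, index=genes)
    drop_s = pd.Series(dropout, index=genes)
    ceff_s = pd.Series(ceff, index=genes)
    targeted_genes = [genes[i] for i in sorted(targeted_idx)]

    # exact expected on-target shares from the weight vectors actually used
    pre_gene = lam * ~dropout
    pre_total = pre_gene.sum() + spike_lam.sum()
    pre_on = pre_gene[targeted].sum() + spike_lam[spike_targeted].sum()
    p_pre = pre_on / pre_total

    post_gene = lam * ceff * (~dropout if params.dropout_post else 1)
    spike_post = spike_lam * np.where(
        spike_targeted, params.capture_efficiency, params.carryover_weight
    )
    post_gene_nt = np.where(targeted, post_gene, post_gene * params.carryover_weight)
    post_total = post_gene_nt.sum() + spike_post.sum()
    post_on = post_gene_nt[targeted].sum() + spike_post[spike_targeted].sum()
    p_post = post_on / post_total

    ef_exact = p_post / p_pre
    # homogeneous closed form EF = C/(Cp+1-p) with the scalar parameter C;
    # equals ef_exact when there is no dropout and no efficiency spread
    c = params.capture_efficiency
    ef_homog = c / (c * p_pre + 1 - p_pre)

    return CaptureSimTruth(
        lam=lam_s,
        dropout=drop_s,
        capture_eff=ceff_s,
        targeted_genes=targeted_genes,
        spike_lam=spike_lam,
        spike_targeted=spike_targeted,
        expected_pre_on_target=float(p_pre),
        expected_post_on_target=float(p_post),
        expected_ef=float(ef_exact),
        expected_ef_homogeneous=float(ef_homog),
        params=params,
    )


def _sample_counts(
    weights: pd.Series, depth: int, n_replicates: int, prefix: str, rng
) -> pd.DataFrame:
    p = weights.to_numpy(dtype=float)
    p = p / p.sum()
    cols = {}
    for r in range(1, n_replicates + 1):
        cols[f"{prefix}{r}"] = rng.multinomial(depth, p)
    return pd.DataFrame(cols, index=weights.index)


def simulate_pre_capture(
    params: CaptureSimParams,
    ladder: SpikeInLadder | None = None,
    truth: CaptureSimTruth | None = None,
):
    """Pre-capture libraries: multinomial reads over dropout-masked abundances.

    Returns ``(CountMatrix, truth)``; pass ``truth`` to reuse an already
    drawn ground truth (the pre and post matrices of one experiment must
    share it).
    """
    from .enrichment import CountMatrix

    if truth is None:
        truth = _draw_truth(params, ladder)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    weights = pd.concat([truth.lam * ~truth.dropout, truth.spike_lam])
    counts = _sample_counts(weights, params.depth_pre, params.n_replicates,
                            "pre_", rng)
    meta = pd.DataFrame(
        {
            "phase": "pre",
            "replicate": [c.split("_")[1] for c in counts.columns],
        },
        index=counts.columns,
    )
    return CountMatrix(counts, meta), truth


def simulate_post_capture(
    truth: CaptureSimTruth,
    params: CaptureSimParams | None = None,
):
    """Post-capture libraries: abundances re-weighted by capture efficiency."""
    from .enrichment import CountMatrix

    params = params or truth.params
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    gene_w = truth.lam * truth.capture_eff
    nt = ~truth.lam.index.isin(truth.targeted_genes)
    gene_w[nt] = gene_w[nt] * params.carryover_weight
    if params.dropout_post:
        gene_w = gene_w * ~truth.dropout
    spike_w = truth.spike_lam * np.where(
        truth.spike_targeted, params.capture_efficiency, params.carryover_weight
    )
    weights = pd.concat([gene_w, spike_w])
    counts = _sample_counts(weights, params.depth_post, params.n_replicates,
                            "post_", rng)
    meta = pd.DataFrame(
        {
            "phase": "post",
            "replicate": [c.split("_")[1] for c in counts.columns],
        },
        index=counts.columns,
    )
    return CountMatrix(counts, meta)


def simulate_experiment(
    params: CaptureSimParams, ladder: SpikeInLadder | None = None
):
    """Full experiment: shared truth, pre and post matrices side by side."""
    from .enrichment import CountMatrix

    pre, truth = simulate_pre_capture(params, ladder)
    post = simulate_post_capture(truth, params)
    counts = pd.concat([pre.counts, post.counts], axis=1)
    meta = pd.concat([pre.samples, post.samples])
    return CountMatrix(counts, meta), truth


# ---------------------------------------------------------------------------
# Scenarios

SCENARIOS = ("ng-like", "tf-like", "low-complexity-minibulk")


def _scenario_params(name: str, seed: int) -> CaptureSimParams:
    if name == "ng-like":
        # small, lowly expressed target set (noncoding loci): <1% of
        # transcriptome mass, strong enrichment
        return CaptureSimParams(
            n_genes=2000,
            targeted_fraction=0.02,
            target_low_expression=True,
            capture_efficiency=200.0,
            seed=seed,
        )
    if name == "tf-like":
        # ~5% of genes targeted at ordinary expression levels
        return CaptureSimParams(
            n_genes=2000,
            targeted_fraction=0.05,
            capture_efficiency=60.0,
            seed=seed,
        )
    if name == "low-complexity-minibulk":
        # poorer library: heavier dropout
        return CaptureSimParams(
            n_genes=2000,
            targeted_fraction=0.05,
            capture_efficiency=60.0,
            dropout_kappa=0.32,
            seed=seed,
        )
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")


@dataclass
class ScenarioBundle:
    name: str
    annotation: AnnotationSet
    params: CaptureSimParams
    ladder: SpikeInLadder
    counts: "object"  # CountMatrix
    truth: CaptureSimTruth


def make_scenario(
    name: str, seed: int = 0, outdir: str | Path | None = None
) -> ScenarioBundle:
    """Build a named end-to-end fixture; optionally write all files.

    Written files (deterministic, byte-identical under one seed):
    ``annotation.gtf``, ``repeats.bed``, ``ests.bed``,
    ``ld_blocks_tier{1..3}.bed``, ``snps.tsv``, ``counts.tsv``,
    ``samples.tsv``, ``ladder.tsv``, ``truth.json``.
    """
    params = _scenario_params(name, seed)
    ladder = generate_spikein_ladder(seed=seed)
    annotation = generate_annotation(n_genes=50, seed=seed)
    counts, truth = simulate_experiment(params, ladder)
    bundle = ScenarioBundle(name, annotation, params, ladder, counts, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(annotation, outdir / "annotation.gtf")
        for track in ("repeats", "ests", "ld_blocks_tier1",
                      "ld_blocks_tier2", "ld_blocks_tier3"):
            write_bed(annotation.tracks[track], outdir / f"{track}.bed")
        annotation.snps.to_csv(outdir / "snps.tsv", sep="\t", index=False)
        counts.counts.to_csv(outdir / "counts.tsv", sep="\t",
                             index_label="gene_id")
        counts.samples.to_csv(outdir / "samples.tsv", sep="\t",
                              index_label="sample_id")
        ladder.to_tsv(outdir / "ladder.tsv")
        truth.to_json(outdir / "truth.json")
    return bundle
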