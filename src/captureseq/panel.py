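"""Capture panel target-region design rules.

Implements the two design procedures of a neural CaptureSeq experiment:

* **NG (NeuroGWAS) design** — genome-wide-significant disease SNPs are
  assigned to precomputed LD blocks (tiered by estimation stringency),
  blocks containing protein-coding transcripts are discarded, exons of
  lncRNA genes near the remaining blocks are pulled in, and everything is
  trimmed away from coding transcripts and highly expressed RNA repeats.

* **TF (transcription-factor) design** — DNA-binding TF genes are probed
  in full unless they are predicted to dominate the captured library, in
  which case only diagnostic 3'-end fragments are probed; each gene also
  gets a repeat-free intronic control region, and spike-in regions are
  length-filtered and padded.

All rules delegate their interval arithmetic to
:mod:`captureseq.intervals`, which fixes the boundary conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import (
    AnnotationSet,
    GenomicInterval,
    IntervalError,
    TranscriptModel,
    gap_distance,
    merge_intervals,
    subtract_with_margin,
    within_distance,
)

__all__ = [
    "TargetPanel",
    "ProbingClass",
    "DesignError",
    "filter_gwas_snps",
    "assign_snps_to_blocks",
    "coding_free_blocks",
    "proximal_lncrna_exons",
    "trim_near_coding",
    "rna_repeat_filter",
    "classify_tf_probing",
    "partial_probe_targets",
    "design_intronic_controls",
    "prepare_spikein_targets",
    "assemble_panel",
    "design_ng_panel",
    "design_tf_panel",
]


class DesignError(ValueError):
    """A design rule could not be applied."""


@dataclass
class TargetPanel:
    """A named, merged set of capture target regions.

    ``targets`` is always merged (sorted, disjoint); ``total_bases`` is
    the summed length; ``gene_attribution`` maps each region (by its
    ``(chrom, start, end)`` key) to the gene ids whose annotation it
    overlaps; ``design_log`` records per-rule region/base counts.
    """

    name: str
    targets: list[GenomicInterval]
    gene_attribution: dict[tuple, list[str]] = field(default_factory=dict)
    design_log: dict[str, int | float | str] = field(default_factory=dict)

    @property
    def total_bases(self) -> int:
        return sum(t.length for t in self.targets)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for gids in self.gene_attribution.values():
            for g in gids:
                seen.setdefault(g, None)
        return sorted(seen)


@dataclass(frozen=True)
class ProbingClass:
    """Full vs partial probing decision for one TF gene."""

    gene_id: str
    probing: str  # "full" | "partial"
    predicted_share_neuronal: float
    predicted_share_encode_max: float


# ---------------------------------------------------------------------------
# NG design rules

SNP_COLUMNS = ["snp_id", "chrom", "pos", "pvalue", "phenotype"]


def filter_gwas_snps(
    snps: pd.DataFrame, p_threshold: float = 5e-8
) -> pd.DataFrame:
    """Keep genome-wide-significant SNPs (pvalue strictly below threshold).

    Duplicate (snp_id, phenotype) associations collapse to one row, so
    the result counts unique SNP–phenotype associations.
    """
    missing = [c for c in ("snp_id", "pvalue") if c not in snps.columns]
    if missing:
        raise DesignError(f"SNP table missing column(s): {', '.join(missing)}")
    kept = snps[snps["pvalue"] < p_threshold]
    subset = ["snp_id", "phenotype"] if "phenotype" in kept.columns else ["snp_id"]
    return kept.drop_duplicates(subset=subset).reset_index(drop=True)


def assign_snps_to_blocks(
    snps: pd.DataFrame,
    block_sets: Sequence[Sequence[GenomicInterval]],
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[dict[str, list[GenomicInterval]], list[str]]:
    """Assign each SNP to LD blocks, trying block sets in preference order.

    A SNP lands in the first (most preferred) block set containing a
    block that overlaps its position; within that set it is assigned to
    every overlapping block.  Returns ``(snp_id -> blocks, unassigned
    snp_ids)``.  ``pos`` is a 0-based coordinate.
    """
    if not block_sets:
        raise DesignError("block_sets must be non-empty")
    assigned: dict[str, list[GenomicInterval]] = {}
    unassigned: list[str] = []
    for row in snps.itertuples(index=False):
        sid, chrom, pos = str(row.snp_id), str(row.chrom), int(row.pos)
        if chrom_sizes is not None and (
            chrom not in chrom_sizes or not 0 <= pos < chrom_sizes[chrom]
        ):
            unassigned.append(sid)
            continue
        hits: list[GenomicInterval] = []
        for tier in block_sets:
            hits = [b for b in tier if b.chrom == chrom and b.start <= pos < b.end]
            if hits:
                break
        if hits:
            assigned.setdefault(sid, [])
            for h in hits:
                if h not in assigned[sid]:
                    assigned[sid].append(h)
        else:
            unassigned.append(sid)
    return assigned, unassigned


def coding_free_blocks(
    blocks: Iterable[GenomicInterval],
    annotation: AnnotationSet,
    extent: str = "transcript",
) -> list[GenomicInterval]:
    """Drop LD blocks that overlap any protein-coding transcript.

    Overlap of a single base disqualifies a block.  By default the full
    transcript genomic extent (introns included) is used, since capture
    probes in introns still pull pre-mRNA; ``extent="exon"`` restricts
    to exons.
    """
    if extent not in ("transcript", "exon"):
        raise DesignError(f"extent must be 'transcript' or 'exon', got {extent!r}")
    coding = annotation.transcripts_of_biotype("coding")
    if extent == "transcript":
        spans = [t.span for t in coding]
    else:
        spans = [e for t in coding for e in t.exons]
    spans = merge_intervals(spans)
    kept = []
    for b in blocks:
        if not any(b.overlaps(s) for s in spans):
            kept.append(b)
    return kept


def proximal_lncrna_exons(
    blocks: Iterable[GenomicInterval],
    annotation: AnnotationSet,
    window: int = 50_000,
) -> list[GenomicInterval]:
    """All exons of lncRNA genes overlapping or within ``window`` of a block.

    The trigger is gene-level: one qualifying exon of one transcript
    pulls in every exon of every transcript of that gene.
    """
    blocks = list(blocks)
    out: list[GenomicInterval] = []
    for gene_id, txs in sorted(annotation.by_gene().items()):
        lnc = [t for t in txs if t.biotype == "lncRNA"]
        if not lnc:
            continue
        exons = [e for t in lnc for e in t.exons]
        if within_distance(exons, blocks, window):
            out.extend(
                GenomicInterval(e.chrom, e.start, e.end, e.strand, gene_id)
                for e in exons
            )
    return out


def trim_near_coding(
    targets: Iterable[GenomicInterval],
    annotation: AnnotationSet,
    margin: int = 50,
) -> list[GenomicInterval]:
    """Trim target bases within ``margin`` nt of any coding transcript extent."""
    exclusions = [t.span for t in annotation.transcripts_of_biotype("coding")]
    return subtract_with_margin(targets, exclusions, margin)


def rna_repeat_filter(
    targets: Iterable[GenomicInterval],
    repeats: Iterable[GenomicInterval],
    margin: int,
    classes: Sequence[str] | None = None,
) -> list[GenomicInterval]:
    """Trim targets near RNA repeats of the selected classes.

    Repeat intervals carry their class in ``name`` (e.g. ``rRNA``,
    ``tRNA``, ``7SK``, ``srpRNA``).  ``classes=None`` uses every repeat.
    """
    repeats = list(repeats)
    if classes is not None:
        available = {r.name for r in repeats if r.name}
        unknown = [c for c in classes if c not in available]
        if unknown:
            raise DesignError(
                f"unknown repeat class(es) requested: {', '.join(sorted(unknown))}"
            )
        repeats = [r for r in repeats if r.name in set(classes)]
    return subtract_with_margin(targets, repeats, margin)


# ---------------------------------------------------------------------------
# TF design rules


def classify_tf_probing(
    expression_shares: pd.DataFrame,
    neuronal_thresh: float = 0.005,
    encode_thresh: float = 0.05,
    neuronal_col: str = "neuronal",
) -> list[ProbingClass]:
    """Decide full vs partial probing per TF gene from predicted read shares.

    A gene is probed only in part when it is predicted to take 0.5% or
    more of captured reads in neuronal cells (``>=``) or over 5% of
    targeted reads in any ENCODE context (strict ``>``).  The table must
    be indexed by gene id with a neuronal column; all other columns are
    treated as ENCODE contexts.
    """
    if neuronal_col not in expression_shares.columns:
        raise DesignError(f"shares table missing column {neuronal_col!r}")
    encode_cols = [c for c in expression_shares.columns if c != neuronal_col]
    vals = expression_shares[[neuronal_col] + encode_cols]
    if ((vals < 0) | (vals > 1)).any().any():
        raise DesignError("expression shares must lie in [0, 1]")
    out = []
    for gene_id, row in expression_shares.iterrows():
        neuro = float(row[neuronal_col])
        enc_max = float(row[encode_cols].max()) if encode_cols else 0.0
        partial = neuro >= neuronal_thresh or enc_max > encode_thresh
        out.append(
            ProbingClass(str(gene_id), "partial" if partial else "full", neuro, enc_max)
        )
    return out


def _transcript_end_slice(
    exon: GenomicInterval, n: int, strand: str, which: str
) -> GenomicInterval:
    """First/last ``n`` nt of a feature in transcript orientation."""
    n = min(n, exon.length)
    take_high = (which == "last") == (strand != "-")
    if take_high:
        return GenomicInterval(exon.chrom, exon.end - n, exon.end, strand, exon.name)
    return GenomicInterval(exon.chrom, exon.start, exon.start + n, strand, exon.name)


def partial_probe_targets(
    transcript: TranscriptModel,
    cds_tail: int = 200,
    penult_len: int = 100,
    final_head: int = 150,
) -> list[GenomicInterval]:
    """Diagnostic 3'-end probe regions for a partially probed transcript.

    Mono-exonic transcripts contribute the last ``cds_tail`` nt of the
    CDS; multi-exonic transcripts contribute the last ``penult_len`` nt
    of the penultimate exon and the first ``final_head`` nt of the final
    exon (whole exon when shorter).  "First"/"last" follow transcript
    orientation, so on the minus strand "last N nt" sits at the lowest
    genomic coordinates.
    """
    strand = transcript.strand
    if len(transcript.exons) == 1:
        if not transcript.cds:
            raise DesignError(
                f"mono-exonic transcript {transcript.transcript_id} has no CDS; "
                "cannot design CDS-tail probes"
            )
        cds_span = GenomicInterval(
            transcript.chrom,
            transcript.cds[0].start,
            transcript.cds[-1].end,
            strand,
            transcript.transcript_id,
        )
        return [_transcript_end_slice(cds_span, cds_tail, strand, "last")]
    ordered = transcript.exons_in_transcript_order()
    penult, final = ordered[-2], ordered[-1]
    return [
        _transcript_end_slice(penult, penult_len, strand, "last"),
        _transcript_end_slice(final, final_head, strand, "first"),
    ]


def design_intronic_controls(
    genes: Sequence[str],
    annotation: AnnotationSet,
    repeats: Iterable[GenomicInterval],
    ests: Iterable[GenomicInterval],
    ann_margin: int = 500,
    repeat_margin: int = 100,
    est_margin: int = 50,
    min_piece: int = 200,
    control_len: int = 200,
    ann_anchor: str = "exon",
) -> list[GenomicInterval]:
    """One repeat-free intronic control region per gene.

    Per gene, candidate pieces are the gene's introns (per-transcript
    exon gaps unioned per gene) trimmed away from annotation
    (``ann_margin``), repeats (``repeat_margin``) and ESTs
    (``est_margin``).  Pieces strictly longer than ``min_piece`` survive;
    the longest (ties: leftmost) yields its centred ``control_len``
    window.  Genes with no surviving piece are omitted.

    ``ann_anchor='exon'`` trims relative to all exons (the default —
    anchoring on whole gene extents would erase every intron of its own
    host gene); ``'transcript'`` uses transcript extents of *other*
    genes only.
    """
    if control_len > min_piece:
        raise DesignError(
            f"control_len ({control_len}) must be <= min_piece ({min_piece})"
        )
    repeats = list(repeats)
    ests = list(ests)
    by_gene = annotation.by_gene()
    all_exons = [e for t in annotation.transcripts for e in t.exons]
    out = []
    for gene_id in genes:
        txs = by_gene.get(gene_id)
        if not txs:
            continue
        introns = merge_intervals(iv for t in txs for iv in t.introns())
        if not introns:
            continue
        if ann_anchor == "exon":
            ann_excl = all_exons
        else:
            ann_excl = [
                t.span for g, ts in by_gene.items() if g != gene_id for t in ts
            ]
        pieces = subtract_with_margin(introns, ann_excl, ann_margin)
        pieces = subtract_with_margin(pieces, repeats, repeat_margin)
        pieces = subtract_with_margin(pieces, ests, est_margin)
        pieces = [p for p in pieces if p.length > min_piece]
        if not pieces:
            continue
        best = max(pieces, key=lambda p: (p.length, -p.start))
        off = (best.length - control_len) // 2
        out.append(
            GenomicInterval(
                best.chrom,
                best.start + off,
                best.start + off + control_len,
                txs[0].strand,
                gene_id,
            )
        )
    return out


def prepare_spikein_targets(
    regions: Iterable[GenomicInterval],
    seq_lengths: Mapping[str, int],
    min_len: int = 30,
    pad_to: int = 50,
) -> list[GenomicInterval]:
    """Length-filter and pad spike-in target regions.

    Regions under ``min_len`` nt are dropped; regions between ``min_len``
    and ``pad_to - 1`` nt are padded symmetrically to ``pad_to`` nt
    (odd deficits put the extra base downstream), never extending past
    the spike-in sequence bounds — a clipped pad is shifted to the other
    side.  Regions already >= ``pad_to`` pass through unchanged.
    """
    out = []
    for r in regions:
        if r.chrom not in seq_lengths:
            raise DesignError(f"unknown spike-in sequence {r.chrom!r}")
        seqlen = seq_lengths[r.chrom]
        if r.end > seqlen:
            raise IntervalError(
                f"region {r.chrom}:{r.start}-{r.end} exceeds sequence length {seqlen}"
            )
        if r.length < min_len:
            continue
        if r.length >= pad_to:
            out.append(r)
            continue
        if seqlen < pad_to:
            raise DesignError(
                f"spike-in sequence {r.chrom} ({seqlen} nt) shorter than pad_to"
            )
        deficit = pad_to - r.length
        left = deficit // 2
        start = r.start - left
        end = r.end + (deficit - left)
        if start < 0:
            end -= start
            start = 0
        if end > seqlen:
            start -= end - seqlen
            end = seqlen
        out.append(GenomicInterval(r.chrom, start, end, r.strand, r.name))
    return out


# ---------------------------------------------------------------------------
# Panel assembly and end-to-end designs


def assemble_panel(
    name: str,
    region_groups: Mapping[str, Iterable[GenomicInterval]],
    annotation: AnnotationSet | None = None,
    design_log: Mapping[str, int | float | str] | None = None,
) -> TargetPanel:
    """Merge named region groups into a final :class:`TargetPanel`.

    Gene attribution is by overlap of each merged region with the
    annotation's transcript extents.  ``design_log`` entries are carried
    over and augmented with per-group and total base counts.
    """
    log: dict[str, int | float | str] = dict(design_log or {})
    all_regions: list[GenomicInterval] = []
    for group, regions in region_groups.items():
        regions = list(regions)
        log[f"group_{group}_regions"] = len(regions)
        log[f"group_{group}_bases"] = sum(r.length for r in regions)
        all_regions.extend(regions)
    targets = merge_intervals(all_regions)
    if not targets:
        raise DesignError(f"panel {name!r} is empty after merging")
    attribution: dict[tuple, list[str]] = {}
    if annotation is not None:
        spans = [(t.span, t.gene_id) for t in annotation.transcripts]
        for region in targets:
            hit = sorted({g for s, g in spans if region.overlaps(s)})
            attribution[(region.chrom, region.start, region.end)] = hit
    panel = TargetPanel(name, targets, attribution, log)
    panel.design_log["total_regions"] = len(targets)
    panel.design_log["total_bases"] = panel.total_bases
    return panel


def design_ng_panel(
    snps: pd.DataFrame,
    block_sets: Sequence[Sequence[GenomicInterval]],
    annotation: AnnotationSet,
    repeats: Sequence[GenomicInterval],
    p_threshold: float = 5e-8,
    lncrna_window: int = 50_000,
    coding_margin: int = 50,
    repeat_margin: int = 50,
    repeat_classes: Sequence[str] | None = ("rRNA", "tRNA", "7SK", "srpRNA"),
    intronic_controls_for: Sequence[str] | None = None,
    ests: Sequence[GenomicInterval] | None = None,
) -> TargetPanel:
    """End-to-end NG (GWAS/lncRNA) panel design.

    SNP filtering -> tiered LD-block assignment -> coding-free block
    selection -> proximal lncRNA exon pull-in -> coding-proximity trim ->
    RNA-repeat trim -> merge.  Optionally adds 500 nt intronic control
    regions for the given genes.
    """
    sig = filter_gwas_snps(snps, p_threshold)
    assigned, unassigned = assign_snps_to_blocks(sig, block_sets)
    hit_blocks = merge_intervals(b for blocks in assigned.values() for b in blocks)
    clean_blocks = coding_free_blocks(hit_blocks, annotation)
    lnc_exons = proximal_lncrna_exons(clean_blocks, annotation, lncrna_window)
    raw_targets = list(clean_blocks) + lnc_exons
    trimmed = trim_near_coding(raw_targets, annotation, coding_margin)
    classes = repeat_classes
    if classes is not None:
        present = {r.name for r in repeats if r.name}
        classes = [c for c in classes if c in present] or None
    if repeats and classes is not None:
        trimmed = rna_repeat_filter(trimmed, repeats, repeat_margin, classes)
    elif repeats:
        trimmed = rna_repeat_filter(trimmed, repeats, repeat_margin)
    groups: dict[str, list[GenomicInterval]] = {"ld_blocks_and_lncrna": trimmed}
    if intronic_controls_for:
        groups["intronic_controls"] = design_intronic_controls(
            intronic_controls_for,
            annotation,
            repeats,
            ests or [],
            min_piece=500,
            control_len=500,
        )
    log = {
        "snps_significant": len(sig),
        "snps_assigned": len(assigned),
        "snps_unassigned": len(unassigned),
        "blocks_hit": len(hit_blocks),
        "blocks_coding_free": len(clean_blocks),
        "lncrna_exons": len(lnc_exons),
    }
    return assemble_panel("NG", groups, annotation, log)


def design_tf_panel(
    tf_genes: Sequence[str],
    annotation: AnnotationSet,
    expression_shares: pd.DataFrame,
    repeats: Sequence[GenomicInterval],
    ests: Sequence[GenomicInterval],
    probe_repeat_margin: int = 120,
    spikein_regions: Sequence[GenomicInterval] | None = None,
    spikein_lengths: Mapping[str, int] | None = None,
) -> TargetPanel:
    """End-to-end TF panel design.

    Full-probed genes contribute every exon of every transcript; partial
    genes contribute 3'-end diagnostic fragments of coding transcripts.
    Exonic targets are trimmed away from RNA repeats; intronic controls
    and (optionally) spike-in regions are added.
    """
    classes = {
        pc.gene_id: pc.probing for pc in classify_tf_probing(expression_shares)
    }
    by_gene = annotation.by_gene()
    exonic: list[GenomicInterval] = []
    n_partial = 0
    for gene in tf_genes:
        txs = by_gene.get(gene)
        if not txs:
            continue
        if classes.get(gene, "full") == "partial":
            n_partial += 1
            for t in txs:
                if t.biotype != "coding":
                    continue
                try:
                    exonic.extend(partial_probe_targets(t))
                except DesignError:
                    continue
        else:
            exonic.extend(e for t in txs for e in t.exons)
    rna_repeats = [r for r in repeats if r.name in ("rRNA", "tRNA", "7SK", "srpRNA")]
    if rna_repeats:
        exonic = subtract_with_margin(exonic, rna_repeats, probe_repeat_margin)
    groups: dict[str, list[GenomicInterval]] = {
        "tf_exons": exonic,
        "intronic_controls": design_intronic_controls(
            tf_genes, annotation, repeats, ests
        ),
    }
    if spikein_regions:
        groups["spikeins"] = prepare_spikein_targets(
            spikein_regions, spikein_lengths or {}
        )
    log = {
        "tf_genes": len(tf_genes),
        "tf_genes_partial": n_partial,
    }
    return assemble_panel("TF", groups, annotation, log)
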