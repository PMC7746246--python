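"""Genomic interval arithmetic and BED/GTF I/O.

All internal coordinates are 0-based half-open (BED convention); GTF's
1-based inclusive coordinates are converted at the boundary.  Distances
between intervals are gap distances: the number of bases strictly between
the two intervals on the same chromosome (overlapping or book-ended
intervals are at distance 0).  Distance is never computed across
chromosomes, and strand is ignored by all distance/trim operations —
hybridization capture is strand-agnostic.  Strand matters only where
transcript orientation does (see :mod:`captureseq.panel`).

Boundary conventions, fixed here because the design rules they serve do
not define them:

* "within N nt" for *trimming* rules forbids gap < N and keeps bases at
  gap >= N (:func:`subtract_with_margin`);
* "within N nt" for *inclusion* rules keeps gap <= N
  (:func:`within_distance`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "AnnotationSet",
    "IntervalError",
    "merge_intervals",
    "subtract_with_margin",
    "within_distance",
    "gap_distance",
    "read_bed",
    "write_bed",
    "read_gtf",
    "write_gtf",
]


class IntervalError(ValueError):
    """Invalid interval, malformed record or inconsistent annotation."""


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on ``chrom``.

    ``strand`` is one of ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    Empty intervals are rejected: ``0 <= start < end`` must hold.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise IntervalError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
                f"{' (' + self.name + ')' if self.name else ''}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise IntervalError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        # ties broken by name for deterministic output
        return (self.chrom, self.start, self.end, self.name or "")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap in nt between two intervals; 0 if they overlap or touch.

    Returns ``None`` when the intervals are on different chromosomes
    (distance is undefined across chromosomes).
    """
    if a.chrom != b.chrom:
        return None
    return max(a.start - b.end, b.start - a.end, 0)


def _validated(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    out = []
    for iv in intervals:
        if not isinstance(iv, GenomicInterval):
            raise IntervalError(f"not a GenomicInterval: {iv!r}")
        out.append(iv)
    return out


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge overlapping and book-ended (end == start) intervals.

    Output is sorted by (chrom, start, end) and pairwise disjoint; the
    union of covered bases is exactly that of the input.  Names and
    strands are dropped on merged output (a merged region has no single
    source).
    """
    ivs = sorted(_validated(intervals), key=GenomicInterval.sort_key)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def subtract_with_margin(
    targets: Iterable[GenomicInterval],
    exclusions: Iterable[GenomicInterval],
    margin: int = 0,
) -> list[GenomicInterval]:
    """Remove from ``targets`` every base within ``margin`` nt of an exclusion.

    A target base at gap >= ``margin`` from the nearest exclusion base is
    kept; gap < ``margin`` is trimmed (with ``margin=0`` this is plain
    subtraction).  Zero-length leftovers are dropped.  Idempotent.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    targets = _validated(targets)
    grown = []
    for ex in _validated(exclusions):
        grown.append(
            GenomicInterval(ex.chrom, max(0, ex.start - margin), ex.end + margin)
        )
    blocked = merge_intervals(grown)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for b in blocked:
        by_chrom.setdefault(b.chrom, []).append(b)

    out: list[GenomicInterval] = []
    for t in sorted(targets, key=GenomicInterval.sort_key):
        pieces = [(t.start, t.end)]
        for b in by_chrom.get(t.chrom, ()):
            if b.start >= t.end:
                break
            nxt = []
            for s, e in pieces:
                if b.end <= s or b.start >= e:
                    nxt.append((s, e))
                    continue
                if b.start > s:
                    nxt.append((s, b.start))
                if b.end < e:
                    nxt.append((b.end, e))
            pieces = nxt
        for s, e in pieces:
            if e > s:
                out.append(GenomicInterval(t.chrom, s, e, t.strand, t.name))
    return sorted(out, key=GenomicInterval.sort_key)


def within_distance(
    query: Iterable[GenomicInterval],
    reference: Iterable[GenomicInterval],
    max_dist: int,
) -> list[GenomicInterval]:
    """Subset of ``query`` with gap <= ``max_dist`` to some same-chrom reference.

    Overlap counts as distance 0, so ``max_dist=0`` selects intervals that
    overlap or touch a reference interval.
    """
    if max_dist < 0:
        raise ValueError(f"max_dist must be >= 0, got {max_dist}")
    refs = merge_intervals(reference)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in refs:
        by_chrom.setdefault(r.chrom, []).append(r)
    kept = []
    for q in _validated(query):
        for r in by_chrom.get(q.chrom, ()):
            d = gap_distance(q, r)
            if d is not None and d <= max_dist:
                kept.append(q)
                break
    return kept


# ---------------------------------------------------------------------------
# Transcript models and annotation containers


@dataclass
class TranscriptModel:
    """Ordered exon structure of one transcript.

    Exons are stored in genomic order (sorted by start, non-overlapping);
    "first"/"last"/"penultimate" exon are defined in *transcript*
    orientation, i.e. reversed on the minus strand.
    """

    transcript_id: str
    gene_id: str
    biotype: str  # {"coding", "lncRNA", "other"}
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=GenomicInterval.sort_key)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.chrom != b.chrom:
                raise IntervalError(
                    f"transcript {self.transcript_id}: exons on multiple chromosomes"
                )
            if b.start < a.end:
                raise IntervalError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        if self.cds:
            self.cds = sorted(self.cds, key=GenomicInterval.sort_key)
            exon_cover = merge_intervals(self.exons)
            leftover = subtract_with_margin(self.cds, exon_cover, 0)
            if leftover:
                raise IntervalError(
                    f"transcript {self.transcript_id}: CDS outside exons"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        """Full genomic extent, first exon start to last exon end."""
        return GenomicInterval(
            self.chrom,
            self.exons[0].start,
            self.exons[-1].end,
            self.strand,
            self.transcript_id,
        )

    def exons_in_transcript_order(self) -> list[GenomicInterval]:
        return list(reversed(self.exons)) if self.strand == "-" else list(self.exons)

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass
class AnnotationSet:
    """Transcript collection plus named auxiliary interval tracks.

    ``tracks`` holds repeats, ESTs, LD blocks etc. keyed by track name;
    interval ``name`` fields carry class labels where relevant (repeat
    classes such as ``rRNA``).  ``chrom_sizes``, when provided, declares
    the sequence universe and every transcript's chrom must be in it.
    """

    transcripts: list[TranscriptModel] = field(default_factory=list)
    tracks: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.chrom_sizes is not None:
            for t in self.transcripts:
                if t.chrom not in self.chrom_sizes:
                    raise IntervalError(
                        f"transcript {t.transcript_id} on undeclared chrom {t.chrom}"
                    )

    def by_gene(self) -> dict[str, list[TranscriptModel]]:
        genes: dict[str, list[TranscriptModel]] = {}
        for t in self.transcripts:
            genes.setdefault(t.gene_id, []).append(t)
        return genes

    def transcripts_of_biotype(self, biotype: str) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.biotype == biotype]


# ---------------------------------------------------------------------------
# BED I/O (BED3/BED6, native 0-based half-open)


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals; malformed lines raise with line number."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise IntervalError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise IntervalError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand, name))
            except IntervalError as exc:
                raise IntervalError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write BED6 (score column fixed at 0); lossless round-trip with read_bed."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# GTF input (1-based inclusive -> internal half-open)

_BIOTYPE_MAP = {
    "protein_coding": "coding",
    "coding": "coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
}

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(
    path,
    biotype_attr: str = "gene_biotype",
    chrom_sizes: Mapping[str, int] | None = None,
) -> AnnotationSet:
    """Parse a GTF into an :class:`AnnotationSet`.

    Exon and CDS features are assembled per ``transcript_id``; start is
    shifted by -1 to the internal half-open convention.  The biotype is
    read from ``biotype_attr`` (falling back to ``gene_type``) and mapped
    to {coding, lncRNA, other}.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        attrs = feat.attributes
        tids = attrs.get("transcript_id")
        if not tids:
            raise IntervalError(
                f"{feat.featuretype} at {feat.seqid}:{feat.start}-{feat.end} "
                "lacks transcript_id"
            )
        tid = tids[0]
        gene = (attrs.get("gene_id") or [tid])[0]
        raw_bt = (attrs.get(biotype_attr) or attrs.get("gene_type") or ["other"])[0]
        biotype = _BIOTYPE_MAP.get(raw_bt, "other")
        meta[tid] = (gene, biotype, feat.strand if feat.strand in "+-" else ".")
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)

    transcripts = []
    for tid in sorted(exons):
        gene, biotype, strand = meta[tid]
        transcripts.append(
            TranscriptModel(tid, gene, biotype, strand, exons[tid], cds.get(tid))
        )
    for tid in cds:
        if tid not in exons:
            raise IntervalError(f"transcript {tid} has CDS but no exons")
    return AnnotationSet(
        transcripts,
        chrom_sizes=dict(chrom_sizes) if chrom_sizes else None,
    )


_BIOTYPE_UNMAP = {"coding": "protein_coding", "lncRNA": "lncRNA", "other": "misc_RNA"}


def write_gtf(annotation: AnnotationSet, path, source: str = "captureseq") -> None:
    """Write exon/CDS GTF records (1-based inclusive); read_gtf round-trips."""
    with open(path, "w") as fh:
        for t in annotation.transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_biotype "{_BIOTYPE_UNMAP.get(t.biotype, t.biotype)}";'
            )
            for feat, ivs in (("exon", t.exons), ("CDS", t.cds or [])):
                for iv in ivs:
                    fh.write(
                        f"{iv.chrom}\t{source}\t{feat}\t{iv.start + 1}\t{iv.end}"
                        f"\t.\t{t.strand}\t.\t{attrs}\n"
                    )
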