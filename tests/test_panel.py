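"""Design rules: unit examples plus oracle-backed end-to-end invariants."""

import numpy as np
import pandas as pd
import pytest

from captureseq.intervals import GenomicInterval, TranscriptModel, merge_intervals
from captureseq.panel import (
    DesignError,
    assemble_panel,
    assign_snps_to_blocks,
    classify_tf_probing,
    coding_free_blocks,
    design_intronic_controls,
    design_ng_panel,
    filter_gwas_snps,
    partial_probe_targets,
    prepare_spikein_targets,
    proximal_lncrna_exons,
    rna_repeat_filter,
    trim_near_coding,
)
from captureseq.simulate import generate_annotation
from conftest import dilate_mask, mask_of


def iv(s, e, chrom="c1", strand=".", name=None):
    return GenomicInterval(chrom, s, e, strand, name)


def snp_table(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "pvalue", "phenotype"])


class TestGwasSnpFilter:
    def test_strict_threshold(self):
        t = snp_table(
            [
                ("a", "c1", 10, 1e-9, "pd"),
                ("b", "c1", 20, 5e-8, "pd"),
                ("c", "c1", 30, 1e-7, "pd"),
            ]
        )
        assert list(filter_gwas_snps(t)["snp_id"]) == ["a"]

    def test_empty_table(self):
        assert filter_gwas_snps(snp_table([])).empty

    def test_duplicate_snp_phenotype_collapses(self):
        t = snp_table(
            [("a", "c1", 10, 1e-9, "pd"), ("a", "c1", 10, 1e-10, "pd"),
             ("a", "c1", 10, 1e-9, "scz")]
        )
        got = filter_gwas_snps(t)
        assert len(got) == 2  # unique (snp, phenotype) associations

    def test_missing_column_is_schema_error(self):
        with pytest.raises(DesignError, match="pvalue"):
            filter_gwas_snps(pd.DataFrame({"snp_id": ["a"]}))


class TestBlockAssignment:
    tiers = [
        [iv(0, 1000, name="t1a")],
        [iv(0, 5000, name="t2a"), iv(6000, 7000, name="t2b")],
        [iv(0, 9000, name="t3a")],
    ]

    def test_first_tier_wins(self):
        snps = snp_table([("a", "c1", 500, 1e-9, "pd")])
        assigned, un = assign_snps_to_blocks(snps, self.tiers)
        assert [b.name for b in assigned["a"]] == ["t1a"] and not un

    def test_rescue_by_lower_tier(self):
        snps = snp_table([("a", "c1", 6500, 1e-9, "pd")])
        assigned, _ = assign_snps_to_blocks(snps, self.tiers)
        assert [b.name for b in assigned["a"]] == ["t2b"]

    def test_unassigned_reported(self):
        snps = snp_table([("a", "c1", 9500, 1e-9, "pd")])
        assigned, un = assign_snps_to_blocks(snps, self.tiers)
        assert not assigned and un == ["a"]

    def test_multiple_blocks_within_one_tier(self):
        tiers = [[iv(0, 100, name="x"), iv(50, 200, name="y")]]
        assigned, _ = assign_snps_to_blocks(
            snp_table([("a", "c1", 60, 1e-9, "pd")]), tiers
        )
        assert sorted(b.name for b in assigned["a"]) == ["x", "y"]

    def test_position_outside_universe_counted_unassigned(self):
        snps = snp_table([("a", "cX", 10, 1e-9, "pd")])
        _, un = assign_snps_to_blocks(snps, self.tiers, chrom_sizes={"c1": 10_000})
        assert un == ["a"]


def make_tx(tid, gene, biotype, strand, exon_pairs, cds_pairs=None, chrom="c1"):
    return TranscriptModel(
        tid,
        gene,
        biotype,
        strand,
        [iv(s, e, chrom=chrom, strand=strand) for s, e in exon_pairs],
        [iv(s, e, chrom=chrom, strand=strand) for s, e in cds_pairs]
        if cds_pairs
        else None,
    )


class TestCodingFreeBlocks:
    def make_ann(self):
        from captureseq.intervals import AnnotationSet

        coding = make_tx("t1", "g1", "coding", "+", [(1000, 1200), (2000, 2200)])
        lnc = make_tx("t2", "g2", "lncRNA", "+", [(5000, 5200)])
        return AnnotationSet([coding, lnc])

    def test_one_base_overlap_removes_block(self):
        ann = self.make_ann()
        # block overlaps the coding transcript's *intron* by one base
        assert coding_free_blocks([iv(2199, 3000)], ann) == []
        assert coding_free_blocks([iv(1500, 1600)], ann) == []  # intron only

    def test_lncrna_overlap_is_allowed(self):
        ann = self.make_ann()
        b = iv(5100, 5300)
        assert coding_free_blocks([b], ann) == [b]

    def test_exon_only_mode(self):
        ann = self.make_ann()
        b = iv(1500, 1600)  # intron of the coding gene
        assert coding_free_blocks([b], ann, extent="exon") == [b]


class TestProximalLncrnaExons:
    def make_ann(self):
        from captureseq.intervals import AnnotationSet

        near = make_tx("t1", "gN", "lncRNA", "+", [(9000, 9100), (12_000, 12_100)])
        far = make_tx("t2", "gF", "lncRNA", "+", [(80_000, 80_100)])
        return AnnotationSet([near, far])

    def test_gene_level_trigger_pulls_all_exons(self):
        got = proximal_lncrna_exons([iv(0, 1000)], self.make_ann(), window=9000)
        assert [(g.start, g.end) for g in got] == [(9000, 9100), (12_000, 12_100)]
        assert all(g.name == "gN" for g in got)

    def test_gene_outside_window_excluded(self):
        got = proximal_lncrna_exons([iv(0, 1000)], self.make_ann(), window=50_000)
        assert {g.name for g in got} == {"gN"}

    def test_no_lncrna_genes(self):
        from captureseq.intervals import AnnotationSet

        ann = AnnotationSet([make_tx("t", "g", "coding", "+", [(0, 100)])])
        assert proximal_lncrna_exons([iv(0, 1000)], ann) == []


class TestTrimNearCoding:
    def test_boundary_convention(self):
        from captureseq.intervals import AnnotationSet

        ann = AnnotationSet([make_tx("t", "g", "coding", "+", [(1000, 2000)])])
        # target ending 50 nt before the transcript is untouched
        t_far = iv(0, 950)
        assert trim_near_coding([t_far], ann, margin=50) == [t_far]
        # target reaching into the margin is trimmed back to gap 50
        assert trim_near_coding([iv(0, 980)], ann, margin=50) == [iv(0, 950)]


class TestRnaRepeatFilter:
    repeats = [iv(1000, 1100, name="rRNA"), iv(5000, 5100, name="LINE")]

    def test_only_selected_classes_trim(self):
        t = [iv(4900, 5300)]  # overlaps the LINE repeat only
        got = rna_repeat_filter(t, self.repeats, margin=50, classes=["rRNA"])
        assert got == t

    def test_margin_applies(self):
        got = rna_repeat_filter([iv(900, 990)], self.repeats, 50, ["rRNA"])
        assert got == [iv(900, 950)]

    def test_unknown_class_rejected(self):
        with pytest.raises(DesignError, match="7SK"):
            rna_repeat_filter([iv(0, 10)], self.repeats, 50, ["7SK"])


class TestClassifyTfProbing:
    def shares(self, neuronal, encode):
        return pd.DataFrame(
            {"neuronal": [neuronal], "encode_a": [encode]},
            index=pd.Index(["g1"], name="gene_id"),
        )

    @pytest.mark.parametrize(
        "neuronal,encode,expected",
        [
            (0.006, 0.01, "partial"),  # neuronal clause, >= 0.5%
            (0.005, 0.01, "partial"),  # boundary: 0.5% "or more"
            (0.001, 0.051, "partial"),  # encode clause, strict "over 5%"
            (0.001, 0.05, "full"),  # boundary: exactly 5% is not "over"
            (0.004, 0.05, "full"),
        ],
    )
    def test_thresholds(self, neuronal, encode, expected):
        (pc,) = classify_tf_probing(self.shares(neuronal, encode))
        assert pc.probing == expected

    def test_share_out_of_range_rejected(self):
        with pytest.raises(DesignError):
            classify_tf_probing(self.shares(1.2, 0.0))


class TestPartialProbeTargets:
    def test_short_penultimate_exon_taken_whole(self):
        t = make_tx("t", "g", "coding", "+", [(1000, 1080), (2000, 2500)])
        penult, final = partial_probe_targets(t)
        assert (penult.start, penult.end) == (1000, 1080)
        assert (final.start, final.end) == (2000, 2150)

    def test_minus_strand_orientation_flip(self):
        # on '-': final exon is the genomically-first; "first 150 nt" of it
        # sits at its high-coordinate end
        t = make_tx("t", "g", "coding", "-", [(2000, 2500), (3000, 3080)])
        penult, final = partial_probe_targets(t)
        assert (penult.start, penult.end) == (3000, 3080)  # <100 nt: whole exon
        assert (final.start, final.end) == (2350, 2500)

    def test_strand_flip_mirrors_design(self):
        """A minus-strand design is the mirror image of the plus-strand one."""
        L = 10_000
        plus = make_tx("t", "g", "coding", "+", [(1000, 1300), (2000, 2600)])
        minus = make_tx(
            "t", "g", "coding", "-",
            [(L - 2600, L - 2000), (L - 1300, L - 1000)],
        )
        got_p = partial_probe_targets(plus)
        got_m = partial_probe_targets(minus)
        mirrored = sorted(
            (L - r.end, L - r.start) for r in got_m
        )
        assert sorted((r.start, r.end) for r in got_p) == mirrored

    def test_mono_exonic_uses_cds_tail(self):
        t = make_tx("t", "g", "coding", "+", [(1000, 2000)], [(1100, 1900)])
        (probe,) = partial_probe_targets(t)
        assert (probe.start, probe.end) == (1700, 1900)  # last 200 nt of CDS

    def test_mono_exonic_without_cds_is_design_error(self):
        t = make_tx("t", "g", "coding", "+", [(1000, 2000)])
        with pytest.raises(DesignError, match="t"):
            partial_probe_targets(t)


class TestIntronicControls:
    def make_ann(self, intron_len=2000):
        from captureseq.intervals import AnnotationSet

        t = make_tx(
            "t", "g", "coding", "+",
            [(0, 1000), (1000 + intron_len, 2000 + intron_len)],
        )
        return AnnotationSet([t])

    def test_centering_rule(self):
        # 2000 nt intron, 500 nt exon-margin trim each side -> 1000 nt piece;
        # the middle 200 nt sits at offset 400..600 within the piece
        got = design_intronic_controls(["g"], self.make_ann(2000), [], [])
        assert [(g.start, g.end) for g in got] == [(1900, 2100)]

    def test_pieces_not_over_min_are_dropped(self):
        # 1700 nt intron -> 700 nt piece > 200: kept; 1200 -> 200 nt piece,
        # not strictly over 200: gene omitted
        assert design_intronic_controls(["g"], self.make_ann(1700), [], [])
        assert design_intronic_controls(["g"], self.make_ann(1200), [], []) == []

    def test_longest_piece_selected(self):
        from captureseq.intervals import AnnotationSet

        t = make_tx(
            "t", "g", "coding", "+",
            [(0, 100), (1900, 2000), (4350, 4450)],  # introns 1800 and 2350 nt
        )
        ann = AnnotationSet([t])
        (got,) = design_intronic_controls(["g"], ann, [], [])
        # longest trimmed piece is 2500-3850 (1350 nt) from the second intron
        assert 2500 <= got.start and got.end <= 3850

    def test_control_len_larger_than_min_piece_rejected(self):
        with pytest.raises(DesignError):
            design_intronic_controls(
                ["g"], self.make_ann(), [], [], min_piece=100, control_len=200
            )


class TestSpikeinPadding:
    lengths = {"s1": 1000}

    def test_symmetric_pad(self):
        (got,) = prepare_spikein_targets([iv(100, 140, chrom="s1")], self.lengths)
        assert (got.start, got.end) == (95, 145)

    def test_under_30_dropped(self):
        assert prepare_spikein_targets([iv(100, 129, chrom="s1")], self.lengths) == []

    def test_boundary_shifted_pad(self):
        (got,) = prepare_spikein_targets([iv(0, 35, chrom="s1")], self.lengths)
        assert (got.start, got.end) == (0, 50)

    def test_long_regions_unchanged(self):
        r = iv(100, 200, chrom="s1")
        assert prepare_spikein_targets([r], self.lengths) == [r]

    def test_region_outside_bounds_rejected(self):
        from captureseq.intervals import IntervalError

        with pytest.raises(IntervalError):
            prepare_spikein_targets([iv(990, 1040, chrom="s1")], self.lengths)


class TestAssemblePanel:
    def test_total_bases_additivity(self):
        p = assemble_panel(
            "x",
            {"a": [iv(0, 1000)], "b": [iv(5000, 7000)]},
        )
        assert p.total_bases == 3000

    def test_overlapping_groups_counted_once(self):
        p = assemble_panel("x", {"a": [iv(0, 1000)], "b": [iv(500, 1500)]})
        assert p.total_bases == 1500

    def test_order_invariance(self):
        g1 = {"a": [iv(0, 1000)], "b": [iv(500, 1500)]}
        g2 = {"b": [iv(500, 1500)], "a": [iv(0, 1000)]}
        assert (
            assemble_panel("x", g1).total_bases
            == assemble_panel("x", g2).total_bases
        )

    def test_empty_panel_rejected(self):
        with pytest.raises(DesignError):
            assemble_panel("x", {"a": []})


# ---------------------------------------------------------------------------
# End-to-end design invariants on random toy genomes


@pytest.mark.parametrize("seed", range(8))
def test_ng_design_end_to_end_invariants(seed):
    """No final NG target base within 50 nt of a coding transcript, and no
    retained LD block overlapping one (per-base oracle)."""
    ann = generate_annotation(n_genes=30, chrom_len=1_000_000, seed=seed)
    L = 1_000_000
    tiers = [ann.tracks[f"ld_blocks_tier{i}"] for i in (1, 2, 3)]
    panel = design_ng_panel(ann.snps, tiers, ann, ann.tracks["repeats"])

    coding_mask = mask_of(
        [t.span for t in ann.transcripts_of_biotype("coding")], L
    )
    forbidden = dilate_mask(coding_mask, 50)
    target_mask = mask_of(panel.targets, L)
    assert not (target_mask & forbidden).any()

    rna_repeats = [
        r for r in ann.tracks["repeats"]
        if r.name in ("rRNA", "tRNA", "7SK", "srpRNA")
    ]
    repeat_forbidden = dilate_mask(mask_of(rna_repeats, L), 50)
    assert not (target_mask & repeat_forbidden).any()


@pytest.mark.parametrize("seed", range(6))
def test_intronic_controls_respect_all_margins(seed):
    """Controls never encroach on exon+500, repeat+100 or EST+50 zones."""
    ann = generate_annotation(n_genes=30, chrom_len=1_000_000, seed=100 + seed)
    L = 1_000_000
    genes = sorted(ann.by_gene())
    controls = design_intronic_controls(
        genes, ann, ann.tracks["repeats"], ann.tracks["ests"]
    )
    exon_zone = dilate_mask(
        mask_of([e for t in ann.transcripts for e in t.exons], L), 500
    )
    repeat_zone = dilate_mask(mask_of(ann.tracks["repeats"], L), 100)
    est_zone = dilate_mask(mask_of(ann.tracks["ests"], L), 50)
    cmask = mask_of(controls, L)
    assert not (cmask & (exon_zone | repeat_zone | est_zone)).any()
    for c in controls:
        assert c.length == 200
    # at most one control per gene
    assert len({c.name for c in controls}) == len(controls)
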