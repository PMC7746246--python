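# captureseq

Design and evaluation toolkit for **targeted RNA sequencing (RNA
CaptureSeq)** — experiments in which biotinylated oligonucleotide probes
hybridize to cDNA fragments from genes of interest, enriching them
before sequencing. The package is written for genomicists building
capture panels (GWAS/lncRNA loci, transcription-factor gene sets) and
for analysts quantifying how well a capture worked, especially on
ultra-low-input ("mini-bulk") samples where transcript dropout limits
conventional RNA-seq.

It provides four things:

1. **Panel design** (`captureseq.panel` on `captureseq.intervals`):
   rule-based target-region construction — genome-wide-significant SNP
   filtering (p < 5×10⁻⁸), tiered LD-block assignment, removal of blocks
   containing protein-coding transcripts, pull-in of lncRNA exons within
   50 kb of a block, 50 nt coding-proximity trimming, RNA-repeat
   masking, full vs partial probing of highly expressed genes (≥0.5%
   neuronal / >5% ENCODE read-share rules; 3′-end diagnostic fragments:
   last 200 nt of CDS, last 100 nt of the penultimate exon, first
   150 nt of the final exon), repeat-free intronic control regions
   (500/100/50 nt margins, middle 200 nt of the longest surviving
   piece), and spike-in region length filtering/padding.
2. **Enrichment evaluation** (`captureseq.enrichment`): on-target read
   fractions; the sample enrichment factor EF = post-capture on-target
   proportion / pre-capture on-target proportion; per-gene enrichment
   EF_g = mean post CPM / mean pre CPM displayed as log₂(EF_g + 1) with
   genes categorized as enriched / rescued / not-enriched / undetected;
   a continuous two-segment ("broken-stick") regression of enrichment
   on log₁₀ pre-capture expression with small-sample AICc model
   selection, whose breakpoint is the expression cut-off below which
   enrichment estimates inflate; replicate-CV comparison by Wilcoxon
   matched-pairs signed-rank test; pre/post read-balance validation;
   and sample-to-reference developmental-stage assignment by Pearson
   correlation of log-scale profiles.
3. **Spike-in QC** (`captureseq.spikein`): CPKM quantification of an
   ERCC-style known-concentration dilution ladder, detection thresholds
   and their fold-improvement, Spearman dose-response correlation,
   log–log regression slope, and depletion of non-targeted spike-ins.
4. **A generative simulator** (`captureseq.simulate`): log-normal gene
   abundances, abundance-dependent dropout `P(drop) = exp(−λ/κ)` in
   low-input pre-capture libraries, multinomial read sampling at fixed
   depth, per-gene capture efficiency with off-target carry-over, and
   2-fold spike-in dilution ladders — with the ground truth retained, so
   every estimator in the package can be tested by parameter recovery.

## Worked example

Simulate a transcription-factor-style capture (2000 genes, 5% targeted,
mean capture efficiency 60, three replicates of 10⁶ reads pre and post)
and evaluate it:

```python
from captureseq.simulate import make_scenario
from captureseq.cli import evaluate_counts, spikein_qc_report

bundle = make_scenario("tf-like", seed=1)
report = evaluate_counts(
    bundle.counts, bundle.truth.targeted_genes,
    on_target_ids=bundle.truth.on_target_ids(),
)
print(round(report["sample_enrichment_factor"], 2))   # 14.94
print(round(bundle.truth.expected_ef, 2))             # 14.96  (closed form)
print(report["gene_categories"])
# {'enriched': 97, 'rescued': 3, 'not_enriched': 0, 'undetected': 0}
qc = spikein_qc_report(bundle.counts, bundle.ladder)
print(qc["threshold_improvement_fold"])               # 4.0
```

The measured sample enrichment factor (14.94) recovers the generative
model's closed-form expectation EF = C/(C·p + 1 − p) (14.96, with C the
capture efficiency and p the pre-capture on-target share); the three
"rescued" genes are exactly the targeted genes that dropped out of the
low-input pre-capture libraries and were recovered by capture; and the
spike-in detection threshold improves 4-fold (two rungs of the 2-fold
dilution ladder) in this scenario.

The same workflow is available from a shell:

```sh
captureseq simulate --scenario tf-like --seed 1 --outdir work/
captureseq run --scenario ng-like --seed 1 --outdir work-ng/
captureseq design ng --snps snps.tsv --blocks t1.bed,t2.bed,t3.bed \
    --gtf ann.gtf --repeats repeats.bed --out panel.bed --log design.json
```

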