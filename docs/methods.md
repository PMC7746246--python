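# Methods

This note records the models, conventions and numerical choices behind
`captureseq`, in the spirit of a methods appendix: what is computed,
under which assumptions, and where the genuinely open choices were made.

## Coordinates and distance conventions

All internal coordinates are 0-based half-open (BED convention); GTF's
1-based inclusive coordinates are converted at the parsing boundary and
restored on writing, so interval lengths survive every round-trip
exactly. Distance between intervals is the gap — the number of bases
strictly between them on the same chromosome; overlapping or book-ended
intervals are at distance 0, and distance across chromosomes is
undefined (such pairs never interact).

Design rules phrased as "within N nt" do not, in general, say what
happens exactly at N. The package fixes the convention once:

* **trimming** rules (coding-proximity, repeat, EST margins) forbid
  gap < N and keep bases at gap ≥ N — equivalently, exclusions are
  dilated by N and subtracted;
* **inclusion** rules (lncRNA exons near LD blocks) keep gap ≤ N.

Strand is ignored by all distance and trimming operations because
hybridization capture is strand-agnostic; it is honored only where
transcript orientation matters (3′-end partial probing, intron
selection), where "first/last N nt" of a feature on the minus strand
maps to its lowest genomic coordinates.

Sorting ties are broken by interval name and then input order, so every
design output is deterministic.

## Panel design rules

* GWAS SNPs are kept at p < 5×10⁻⁸ (strict), de-duplicated as
  (SNP, phenotype) associations. LD blocks are consumed as precomputed
  interval sets in preference order (block estimation itself — plink
  D′ — is an upstream step, not re-implemented); a SNP is assigned to
  every overlapping block of the first set that contains one.
* "Contains a protein-coding transcript" uses the full transcript
  genomic extent (introns included) by default, since probes against
  intronic sequence still pull pre-mRNA; an exon-only mode is provided.
* The lncRNA pull-in trigger is gene-level: one exon of one transcript
  overlapping or within 50 kb of a block recruits all exons of all
  transcripts of that gene.
* Partial probing of highly expressed genes uses ≥ for the 0.5%
  neuronal read-share clause and strict > for the 5% ENCODE clause,
  matching the phrasing "0.5% or more … or over 5%".
* Intronic controls: per gene, introns (per-transcript exon gaps,
  unioned per gene) are trimmed 500 nt from any exon of any gene,
  100 nt from any repeat and 50 nt from any EST; pieces strictly longer
  than 200 nt survive; the longest piece (ties: leftmost) contributes
  its centered 200 nt window (offset ⌊(len−200)/2⌋). Anchoring the
  500 nt margin on *exons* rather than whole gene extents is a
  deliberate interpretation — anchoring on gene extents would erase
  every intron of its own host gene; the alternative (transcript
  extents of other genes) is available via `ann_anchor`. A 500 nt
  variant (`min_piece=500, control_len=500`) serves the GWAS-panel
  intronic controls.
* Spike-in regions shorter than 30 nt are dropped; regions of 30–49 nt
  are padded to exactly 50 nt, split as evenly as possible (odd deficit:
  extra base downstream), with any pad that would cross a sequence
  boundary shifted to the other side. A 51 nt target is accepted as
  input but never produced; the even-50 reading was chosen as the
  deterministic resolution of an ambiguous "50/51 nt" padding
  convention.

## Enrichment statistics

The sample enrichment factor is **post/pre**: on-target read proportion
after capture divided by before. (Enrichment factors of successful
captures are then ≫1, consistent with the tens-to-hundreds-fold values
such experiments report.)

Gene-wise enrichment uses CPM-normalized counts, averaged across all
replicates within each phase. EF_g = post mean / pre mean, displayed as
log₂(EF_g + 1): the +1 pseudocount maps not-enriched genes (EF < 1)
into (0, 1) while keeping the transform monotone. Genes are
categorized: *rescued* (zero counts in every pre-capture replicate,
detected post-capture), *undetected* (absent from both), *enriched*
(detected pre, EF > 1), *not-enriched* (detected pre, EF ≤ 1); the
categories partition the panel by construction. "Detected" means ≥1
read in ≥1 replicate (configurable). The enrichment success rate is the
percentage of pre-detected genes that are enriched.

The read-balance rule flags any pre/post pair where the pre-capture
library's usable reads are fewer than the post-capture library's
on-target reads; flagged pairs should be excluded rather than
downsampled (downsampling the pre library would bias read selection).

### Segmental regression and the expression cut-off

Gene enrichment log₂(EF+1) is regressed on log₁₀ pre-capture mean CPM
with a continuous two-segment model
y = a + b₁x (x ≤ x₀); y = a + b₁x₀ + b₂(x − x₀) (x > x₀).
The breakpoint is grid-searched over 101 x-quantiles between the 5th
and 95th percentiles (candidates must leave ≥3 distinct x on each
side), solving conditional OLS at each candidate and refining the best
cell by bounded scalar minimization to 10⁻⁶. The segmental model
competes against a single line by small-sample AICc,
n·ln(RSS/n) + 2K + 2K(K+1)/(n−K−1), with K = 5 (a, b₁, b₂, x₀, σ)
versus K = 3 (a, b, σ); the smaller AICc wins. When the segmental model
wins, 10^x₀ is reported as the CPM cut-off below which enrichment
estimates inflate.

A property worth knowing: with a *searched* breakpoint, the AICc
penalty difference between the two models is only ≈ 2·ΔK = 4.2, while
the best-of-~100-candidates RSS improvement on pure noise behaves like
the maximum of many correlated χ²₁ variables. On truly linear data the
single line is therefore preferred in a clear majority of datasets
(~74% at n = 200) but not near-universally; users should treat a
segmental selection with a small AICc margin as weak evidence.
Breakpoint *recovery* when a breakpoint exists is accurate: median
error ~0.01 log₁₀ units at n = 500, σ = 0.2.

Replicate variability is compared as per-gene CV (sd/mean, sd with
ddof = 1, genes with positive group mean) between pre and post, paired
by gene, with a two-sided Wilcoxon matched-pairs signed-rank test —
exact null for ≤25 non-zero differences, normal approximation with
continuity correction above; zero differences are dropped (Pratt
handling available).

Stage assignment correlates each sample against reference stage
profiles (replicates averaged per stage first) on log₂(x+1) expression
over the shared genes, assigning the argmax-Pearson stage; ties go to
the earliest stage in reference column order.

## Spike-in QC

Spike-ins are quantified as CPKM = count / (length/1000) /
(total/10⁶); the denominator is the library's total usable reads, not
the spike-in subtotal (both readings are defensible; the library total
is the implemented one and is configurable by passing a different
total). Detection uses the same ≥1-read-in-≥1-replicate rule as genes.
The detection threshold is the lowest known concentration among
detected targeted spike-ins — always a ladder rung — so the pre/post
threshold improvement is a power of the dilution factor by
construction. Dose-response linearity is summarized by Spearman ρ and
by the OLS slope of log₁₀ CPKM on log₁₀ concentration over detected
spike-ins (slope 1 = perfect quantitation). Depletion of non-targeted
spike-ins is the ratio of mean pre to mean post CPKM over the
non-targeted subset. Poor-quality libraries are flagged explicitly by a
complexity-percentile rule rather than silently excluded.

## The generative model

Gene abundances λ_g are log-normal (default: ln-scale mean 0, σ 1.5),
floored at 0.05 so that every truly expressed gene is detectable at the
default depth — the floor is what makes exact rescued-set recovery a
fair test rather than a coin flip. Libraries draw counts
Multinomial(depth, normalized weights), so library sizes are exact by
construction (Poisson sampling would only blur the depth). Spike-ins
enter with weight ∝ concentration × length, scaled to 2% of total
library mass.

Low-input dropout: gene g is lost with probability exp(−λ_g/κ), drawn
**once per gene** and applied to all pre-capture replicates — the loss
is modeled as happening in the shared low-input RNA extraction, not
per library. (A per-replicate variant would make "undetected
pre-capture" a stochastic event that no ground-truth set could predict
exactly.) The default κ = 0.16 was chosen from the closed-form
expectation E[exp(−λ/κ)] ≈ 0.10 under the default abundance
distribution, i.e. ~10% of genes drop out of a mini-bulk library —
the magnitude of rescue that capture experiments on ultra-low-input
samples report. The exponential-in-λ form itself is an assumption (no
quantitative dropout model is established for mini-bulk libraries); a
`dropout_post` switch additionally applies the same loss post-capture,
modeling library-construction loss that capture cannot rescue.

Capture multiplies targeted weights by per-gene efficiency C_g
(log-normal around the scenario's C; spread 0 by default) while
non-targeted material carries over with weight 1. With p the expected
pre-capture on-target share, the expected sample enrichment factor in
the homogeneous case is EF = C/(C·p + 1 − p); the truth object also
stores the exact expectation computed from the realized weight vectors,
which is what dropout and efficiency spread perturb. All randomness
flows from a single integer seed; scenario outputs are byte-identical
under a fixed seed.

Built-in scenarios (2000 genes, 3 replicates, 10⁶ reads per library):
*tf-like* targets 5% of genes at C = 60; *ng-like* targets 2% of genes
drawn from the lower-expression half (so the panel holds <1% of
transcriptome mass, as a noncoding-locus panel does) at C = 200;
*low-complexity-minibulk* doubles κ to 0.32. These sizes keep the full
test suite and the acceptance script to a few minutes on one CPU while
leaving every statistical check well-powered.

### What the simulator does and does not emulate

It emulates: log-scale expression with low-input dropout, fixed-depth
multinomial sampling, per-gene capture efficiency with off-target
carry-over, and a known-concentration 2-fold spike-in ladder. It does
not emulate: read-level artifacts (duplication, mappability, GC bias),
isoform structure, batch effects between captures, or partial/edge
overlap of reads with probe boundaries (counts are gene-level).
Passing recovery tests therefore demonstrates the correctness of the
estimators under the stated model, not robustness to every artifact of
real libraries.

## Degenerate inputs and tie-breaks

Empty intervals are rejected at construction; zero-length trim
leftovers are dropped. The segmental fit refuses fewer than 8 points or
fewer than 7 distinct x values. Spearman/slope computations refuse
fewer than 5/3 detected spike-ins. A constant expression profile is an
error in stage correlation (correlation undefined), as is a zero
library size in CPM normalization. Intronic-control ties (equal longest
pieces) go to the leftmost piece; stage-correlation ties to the
earliest stage; interval sorting ties to the lexicographically smaller
name.

## Known limitations

* Probe-level design (oligo tiling, melting temperature, mappability)
  is out of scope; the package designs target *regions*.
* The segmental/linear AICc comparison is anti-conservative with a
  searched breakpoint (see above); a parametric-bootstrap comparison
  would be better calibrated but is not implemented.
* BED-mode on-target counting treats any ≥1 nt overlap as on-target;
  fractional-overlap policies are not offered.
* The dropout model is per-gene Bernoulli; zero-inflation correlated
  across genes (e.g. cell-type composition effects) is not modeled.
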