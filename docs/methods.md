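# Methods

This note documents the models, parameter choices and numerical
conventions behind `dielshift`, and what the synthetic benchmark does
and does not establish about real data.

## Experimental design model

The design emulated throughout is a two-arm light-shift experiment on a
light:dark-synchronized picophytoplankton culture. Each arm
("experiment") has its own controls: control samples at T0, T1 and
T2.5 (hours after the shift, which occurs mid-light-period), and a
treatment — high light (HL) in one arm, high light plus UV (HL+UV) in
the other — sampled at T1 and T2.5, all in biological triplicate.
This yields the comparison lattice implemented in
`diffexpr.framework_contrasts`: treatment vs T0 control, treatment vs
time-matched control, control vs preceding control point, control vs
T0, and a cross-experiment comparison of the two T0 controls (a
negative control on the framework itself: with both arms generated
from the same condition parameters, it should return almost nothing).

## Read counting

Reads arrive as reference intervals (the aligner's work is out of
scope). Internally all intervals are 0-based half-open; GFF3 and the
tab-delimited alignment format are 1-based inclusive and converted only
at I/O boundaries.

A gene's *count window* is its full CDS span (chloroplast; gene span
for RNAs without a CDS) or the last 403 nt of the terminal exon
(nuclear). A terminal exon shorter than 403 nt clips the window to the
exon: the window definition names terminal exons, so extension across a
splice junction is not licensed. A read is credited to the window it
overlaps most; a read tied exactly between windows is dropped, which
keeps counts integral and deterministic at a negligible cost (ties
require exact overlap equality). Any overlap of ≥1 bp counts; no
minimum-overlap fraction is imposed. Recorded read strand is ignored
everywhere — the libraries are non-directional, and the generator
deliberately randomizes the recorded strand so that tests can verify
strand-flip invariance of the counts.

Two exclusion rules precede counting. Opposite-strand gene pairs whose
windows overlap (convergent 3' UTRs) are excluded entirely: with
3'-biased non-directional reads, no assignment there can be
gene-specific. Genes whose strand-oriented window sequences are
identical are merged into one joint record (`a+b`): their reads are
mutually unassignable but their sum is well defined, and their true
effects are constrained to be shared in the generator for the same
reason.

## Normalization and differential expression

Each compartment is normalized to its housekeeping denominator (23S
rRNA pooled over copies; GAPDH), giving per-sample abundance ratios.
This removes the compositional coupling created by a fixed sequencing
budget split between a high-copy organelle and the nucleus; a zero
housekeeping count is a hard error rather than a pseudocount, because
a silent pseudocount would corrupt every ratio in the sample.

Per contrast, the fold is the ratio of arithmetic group means of these
ratios (fold of mean-ratios, stated in the report header; the
alternative mean-of-ratios is not used), reported with the signed
convention +r / −1/r. A ratio of exactly zero (no signal over a
positive baseline) maps to −inf: a bounded-below decrease, binned into
the top category, rather than an undefined value; only a zero baseline
is flagged undefined. The test is a one-way fixed-effects ANOVA of the
two groups — equivalent to the pooled-variance F/t test — on
log2-transformed ratios. The log transform stabilizes the variance of
ratios; a linear-scale mode exists (`log_scale=False`). Zeros inside
the log use an offset of half the smallest nonzero ratio in the matrix,
applied *only* inside the transform; folds always come from un-offset
means. Two groups with zero variance and equal values give p = 1 by
convention. Raw p-values are used at α = 0.01 with a 1.5-fold
magnitude cutoff; no multiple-testing correction is applied, matching
the framework being emulated (a correction could be added downstream of
the emitted table, which carries raw p-values).

The inclusion filter requires ≥100 raw reads in at least one sample,
applied to un-normalized counts; excluded genes stay in the output with
their reason and can never be significant.

## Gene-model refinement

Coverage is exact per-base read membership. CDS extension applies only
to models that do not already end at a stop codon (models ending at a
stop are fixed points, so the operation is idempotent). Extension
walks codon-by-codon past the annotated end; each *sense* codon must
carry mean depth ≥ `min_depth` (default 5) to be traversed, while the
closing stop codon itself is exempt from the gate — reaching it is a
frame closure, not an expression claim, and read-placement edge effects
otherwise make the final codon's depth an artifact of read length.
If coverage fails before a stop is reached, or the contig ends, the
gene is left unmodified and flagged (`unsupported` / `no_stop`).
Extension never shortens a model, and every emitted CDS ends at a stop
and translates without internal stops.

Novel-ORF discovery scans maximal unannotated intervals whose mean
depth reaches `min_depth`, reporting ORFs of ≥ `min_codons` codons
(default 100) in all six frames. ORF length is counted *including* the
stop codon; starts are ATG-only by default (organelle alternative
starts are out of scope but the start codon is a parameter). The
5'-most start per stop is reported, longest ORF per interval first.
Detected ORFs are reported, never auto-added to the annotation used by
quantification: refinement and quantification are separate passes.

The inventory bookkeeping (`refined_inventory`) adds newly recognized
protein genes and duplicated rRNA copies to a prior per-type census —
for the canonical organelle case, a prior of 58 protein / 26 tRNA /
3 rRNA plus two novel protein genes and three recognized rRNA
duplicates totals 92.

## Cytometry and growth

Bead-relative values are ratios of arithmetic means on linear channel
values (means, not medians or geometric means, because the summary
being emulated is a mean per cell). Gain invariance is exact in real
arithmetic; in floating point it is bit-exact for power-of-two gain and
ULP-level otherwise. Percent change is 100·(xₜ−x₀)/x₀ against the T0
reference, which must be positive.

Growth rate per transfer is the least-squares slope of ln(signal)
against time, using one fixed-clock-time point per day so that bulk
fluorescence tracks cell abundance in a synchronized culture; the mean
± SE is taken over 3–5 consecutive transfers. A two-point mode is a
special case (two observations determine the slope exactly).
Divisions per day are k = μ/ln 2 (so μ = 1 d⁻¹ ⇒ k ≈ 1.44). Group
comparisons use one-way ANOVA across light levels per time point and
two-sample t-tests between growth-rate sets; single-replicate groups
skip the test with a warning rather than fabricating a p-value.

## qPCR

ΔCt subtracts the endogenous control (Actin) per sample; ΔΔCt
subtracts the *mean* ΔCt over calibrator replicates (replicate pooling
by the mean is a choice; it makes fold(calibrator mean) = 1 exactly).
Fold = 2^−ΔΔCt assumes amplification efficiency ≈ 1, which the
dilution-series check is designed to verify: efficiency
= 10^(−1/slope) − 1, with a perfect 2-fold chemistry giving slope
−3.3219 and 100%. Efficiency is reported but not folded into the fold
computation by default; an efficiency-corrected (Pfaffl-style) ratio
mode exists, off by default. Significance is a one-way ANOVA across
conditions at each time point on the ΔCt values (equivalent to log2
folds up to sign and a constant).

## The synthetic generator

The generator's defaults are the study conditions of the emulated
design, at desk scale:

| parameter | default | rationale |
|---|---|---|
| chloroplast contig | 20 kb, ~30 features | stand-in for a 73 kb organelle genome with ~90 genes; same structure, test-sized |
| nuclear contig | 96 kb, 30 genes | room for multi-exon genes and the planted special cases |
| chloroplast read share | 0.5 | high-copy organelle takes ~half the library |
| 3' bias | 0.9 within 8 read lengths (400 bp at 50 bp reads) | the tag chemistry concentrates nuclear reads at the 3' terminus |
| reads per sample | 100 000 | desk-scale stand-in for millions of mapped reads per sample |
| count noise | NB, var = μ + φμ², φ = 0.05 | standard overdispersion for biological replicate RNA-seq |
| housekeeping φ | 0.002 | housekeeping genes are stable by definition of their role |
| replicates | 3 | biological triplicates |
| treatment effects | HL modest (≤2–4×), HL+UV drastic (10–50×, both signs) | the qualitative contrast the design probes |
| diel drift | up to +30% by T2.5 on a third of genes | controls drift with the cell cycle even without treatment |
| FCM | lognormal events, σ=0.15; beads fixed at 4000 a.u.; HL+UV red endpoint −93% of T0 | bead normalization target and the emulated UV effect size |
| qPCR | Ct noise σ = 0.1 cycles, n = 4; truths 33/42× for the UV-induced target | 2-fold-per-cycle chemistry with realistic plate noise |
| growth | μ(irradiance) peaking at 1.78 d⁻¹ at 240 µmol photons m⁻² s⁻¹, 0.28 at 6, 0.96 at 750; 2% multiplicative noise | the emulated irradiance–growth relationship |

Per-sample expected counts renormalize gene weights within each
compartment so the compartment's read share is fixed: sequencing depth
is a budget, which reproduces exactly the compositional artifact that
housekeeping normalization removes (and makes the housekeeping ratio
recover the true fold factors identically). Randomness flows from a
single seed through named substreams (genome, alignments, fcm, growth,
qpcr), so outputs are byte-identical for identical configurations.

Planted features with exact ground truth: one chloroplast CDS
annotated 90 nt short of its true in-frame stop (full ORF written into
the sequence, extension region free of in-frame stops); one expressed
603-codon ORF absent from the annotation, pinned by an upstream
in-frame stop so its coordinates are unambiguous; one convergent
overlapping 3'-UTR pair; one pair of genes identical over the counting
window; one terminal exon of 300 nt.

**What the generator does not emulate:** sequencing error and mapping
ambiguity (reads are placed, not aligned), intron-aware read placement
(reads are genomic intervals; counting is overlap-based so this is
immaterial to the windows), alternative start codons, per-gene
library-preparation biases, FCS instrument artifacts and gating
(populations arrive labelled), and transfer-to-transfer acclimation
drift in growth series. Passing tests therefore demonstrate the
correctness of the analysis logic under the stated statistical
structure, not robustness to alignment or instrument pathology.

## Problem sizes and runtime

The default run is 30 samples × 100 000 reads (two experiments ×
5 groups × triplicates); the full pipeline completes in well under a
minute on one CPU and the whole test suite in about one minute. The
statistical calibration checks use 1000 all-null genes (n = 3 per
group) and 200 replicate simulations per planted fold — sizes at which
the binomial/Monte-Carlo tolerances quoted in the tests are meaningful.

## Known limitations

- The ANOVA is operationalized as two-group pairwise contrasts; an
  omnibus multi-group test per time point is available only on the
  qPCR side. Whether a multi-factor model would be preferable is a
  design question the pairwise comparison list answers conservatively.
- Greatest-overlap read assignment with tie-dropping discards a small,
  deterministic set of reads; with 403-nt windows and 50-bp reads the
  effect is negligible, but for windows close to read length it would
  not be.
- The −inf fold convention for zero numerators keeps sign and category
  information but removes the record from any magnitude arithmetic;
  downstream consumers should treat the top category as open-ended.
- Efficiency-corrected qPCR folds assume calibrator means are
  representative; with very few calibrator replicates the classic
  2^−ΔΔCt mode is the safer default, which is why it is the default.
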