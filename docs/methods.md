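# Methods

This note documents the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices a reader
would otherwise have to reverse-engineer from the code.

## Coordinates, sites and formats

Internal coordinates are 1-based inclusive on both ends, the convention
of the per-cytosine count report and GFF3; BED input/output converts at
the boundary (0-based half-open). Plus- and minus-strand cytosines are
distinct sites throughout — there is no CpG strand merging — matching
the strand-resolved cytosine report. A cytosine's context (CG / CHG /
CHH, H = A, C or T) is read 5′→3′ on its own strand; minus-strand
contexts walk leftward over complemented bases. Cytosines whose
trinucleotide is truncated by a chromosome end or interrupted by an N
are unclassifiable and excluded from site tables.

## Methylation levels and non-conversion correction

The raw level of a site or pooled region is ML = mC/(mC + umC); a region
level always pools counts (ΣmC / Σ(mC + umC)), which equals the
coverage-weighted mean of member-site levels. Bisulfite conversion is
imperfect: a fraction *r* of truly unmethylated cytosines survives
conversion and reads as methylated. *r* is estimated from the
unmethylated lambda spike-in as the unconverted fraction at lambda
cytosine positions (per-sample controls are pooled; typical values
~0.5%). Observed and true levels are then related by
ML_obs = ML_true + (1 − ML_true)·r, and the correction inverts this:
ML' = max(0, (ML_obs − r)/(1 − r)). The floor at zero means a site
reading exactly at the error rate is reported unmethylated. All
"corrected" quantities in the package pass through this single function.

**Methylated positions.** A site is *called methylated* when its
coverage is ≥ 5 (the exposed `min_coverage`, matching the 5× benchmark
coverage the sequencing design targets) and a one-sided binomial test of
n_meth out of coverage against success probability *r* rejects at
BH-adjusted q < 0.05. This calling rule is a documented choice of this
package, not a reconstruction of any published rule; the published
fraction of methylated genomic positions it corresponds to was reported
without one.

**Windows.** The descriptive sliding-window track uses 3,000-bp windows
at a 600-bp step, anchored at position 1 of every chromosome with the
final partial windows kept — full coverage and determinism over edge
conventions. Window statistics pool counts per context.

## Differential methylation

Replicate handling: the design's two samples per group are pooled
(counts summed) per position before testing, the only way to form one
2×2 table per position per comparison. For each of the four chained
comparisons (G2vG1, G3vG2, G4vG3, G5vG4), every position covered in
both groups is tested with a two-sided Fisher exact test; positions with
zero coverage in either group are skipped and counted. BH runs over all
tested positions of a comparison, jointly across contexts (composition
is reported afterward). DMCs require q < 0.05 and |ΔML'| > 0.2; the
difference is computed on corrected levels.

DMRs are built from DMC clusters, not from windows: same-direction DMCs
with adjacent distances < 300 bp form single-linkage clusters (a
direction change breaks a cluster, so every DMR has one hyper/hypo
label); clusters need ≥ 3 DMCs; the candidate region spans first to last
member DMC. The region difference is the pooled corrected-level
difference over **all** covered cytosines in the span — not the mean of
DMC differences — and must exceed 0.1 with the same sign as the member
DMCs (a cluster whose region-wide difference contradicts its DMC
direction is discarded as incoherent). All five thresholds
(0.05 / 0.2 / 0.1 / 3 / 300) are parameters with these defaults.

Numerics: the Fisher p-value is computed vectorised as the sum of
hypergeometric point probabilities not exceeding the observed table's,
via log-gamma, in chunks of 50,000 tables. Point probabilities within a
relative 1e-9 of the observed one count as ties; this absorbs float
rounding on mathematically equal probabilities and is far below the
smallest genuine ratio between distinct probabilities at the table sizes
WGBS coverage produces. The implementation agrees with exact rational
enumeration to < 1e-10 on all tables with total ≤ 40 and with an
independent library implementation on larger random tables.

## Annotation and profiles

The genome is decomposed into promoter (2 kb upstream of the TSS,
strand-aware, clipped at chromosome bounds), 5′/3′-UTR, exon, intron
(gaps between exons), 2-kb up/downstream flanks, TE copies labelled by
family, and intergenic (the complement; every base carries ≥ 1 label). A
gene's *body* is [TSS, TES] including introns and UTRs. Items are
assigned to every feature they overlap (TE overlap is any-overlap);
exclusive composition tables resolve multiple labels by the fixed
precedence promoter > UTR > exon > intron > flank > TE > intergenic. The
precedence is a design choice — exclusive percentages require one — with
promoters first because promoter methylation is the biologically loaded
category in this analysis. A *differentially methylated gene* is a gene
whose body or promoter overlaps ≥ 1 DMR; links are kept per comparison.

Metagene profiles align genes at TSS/TES: each 2-kb flank is cut into 20
fixed 100-bp bins and the body into 20 proportional bins; minus-strand
genes are orientation-flipped so bin 0 is always most 5′ (the flip is an
involution). Interval items (DMRs) enter by midpoint. Density is items
per bp per gene (bin widths differ between flank and body); level
profiles are unweighted per-bin means. Genes shorter than the number of
body bins are handled by proportional assignment.

## Expression, rhythm and integration

Time stamps: LD0, LD4, LD8, LD16 at 0/4/8/16 h and CL0, CL4, CL8, CL16,
CL24 at 24/28/32/40/48 h after the light/dark-cycle dawn. Expression is
analysed as log2(FPKM + 1); the pseudocount stabilises the FPKM scale
and is documented wherever used.

**Rhythm detection** fits, per gene, the fixed-period cosinor
y(t) = M + a·cos(ωt) + b·sin(ωt), ω = 2π/24 h, by least squares;
amplitude = √(a² + b²), phase = atan2(b, a)/ω mod 24 (hours of peak
after the time origin). Significance is an F-test of the two harmonic
terms against the intercept-only model, BH-corrected across genes;
rhythmic ⇔ q < 0.05. The period is fixed at 24 h (configurable): with a
single circadian day of free-running data, scanning periods is not
identifiable, and the sampling design duplicates phases across the two
days, which the fixed-period fit uses as internal replication. With nine
samples the per-gene residual has only six degrees of freedom, so the
default F-statistic moderates the residual variance across genes with
the standard empirical-Bayes scaled-chi-square model (prior df and prior
variance estimated from the spread of log residual variances by
digamma/trigamma moment matching; posterior variance
(d₀s₀² + 6s²)/(d₀ + 6); null distribution F(2, 6 + d₀)). The
moderation collapses to the common-variance limit unless the observed
log-variance spread exceeds its one-sided 95% chi-square sampling bound
— heterogeneity the data cannot distinguish from noise is not modelled.
A per-gene-variance F-test remains available (`moderate_variance=False`)
but at six residual df it cannot reach useful power at
BH-corrected thresholds for moderate amplitudes. Constant genes get
p = 1 by convention.

**Coupling.** Regional methylation is pooled per gene per group over six
strand-aware windows (0.5/1.0/1.5/2.0 kb upstream of the TSS, the body,
0.5 kb downstream of the TES); genes with no covered cytosine in a
window are absent, not zero. The methylation–expression relationship is
summarised by Spearman rank correlation (invariant to monotone
transforms of expression; Pearson available) over gene × group points,
with group expression the mean of member samples.

**Quadrants.** For each comparison, rhythmic genes linked to a DMR of
that comparison are classified by DMR direction × the sign of
log2((mean_b + 1)/(mean_a + 1)); there is deliberately no significance
gate on the expression change. Genes with zero expression in both
groups, or exactly zero change, are tallied separately so quadrant
counts always sum to the classified genes. A union rollup counts
distinct (gene, direction, change) classifications across comparisons.

**qPCR utility.** Relative quantification by 2^−ΔΔCt, with
ΔΔCt = (Ct_target − Ct_ref)_test − (Ct_target − Ct_ref)_control.

## The synthetic-data generator

The generator emulates the study's data shapes, not its biology, and is
the source of every test input.

*Genome and annotations.* Uniform-composition random sequence;
non-overlapping genes (1–6 exons, terminal UTRs, both strands) placed by
rejection sampling with bounded retries; TEs (200–2,000 bp) dropped into
the remaining space with family labels. Defaults: 2 chromosomes ×
200 kb, 100 genes, 40 TEs — small enough to iterate on, large enough for
~200,000 strand-specific cytosines.

*Methylome.* Per cytosine and sample, coverage is negative-binomial
(mean 30, matching the study's sequencing depth; dispersion 10 gives the
overdispersed spread typical of WGBS). The true level is the context
baseline — CG 0.4399, CHG 0.2984, CHH 0.1157, the study's leaf means —
times a feature multiplier (intergenic 1.0 as reference; flanks 1.2;
exon 0.8; intron 0.85; UTR 0.4; TE 1.8, with hAT and CMC-EnSpm at 2.2 to
plant the heavily methylated families), plus planted effects and a
per-sample jitter (SD 0.02 absolute — the study reports no within-group
variance, so a small nuisance value is exposed rather than asserted).
The observed methylated count is Binomial(coverage, level +
(1 − level)·r) with r = 0.005 (conversion efficiency "over 99%"):
non-conversion acts only on unmethylated molecules, exactly what the
lambda control (true level 0) measures.

*Planted differential regions* are step changes: an effect of Δ switches
on in the onset group of a comparison and persists through later groups.
In the chained design each planting therefore induces **two** truth
effects — +Δ in its own comparison and −Δ in the next — and both are
recorded in the ledger. Because sample CL0 serves in both G1 and G5
(closing the free-running day), a step is stopped before any group that
shares samples with pre-onset groups, so onsets are drawn from G2–G4 and
no effect leaks into its own baseline. Default planting applies Δ to all
three contexts of the region; restricting to a context subset (e.g.
CHH-only, the dominant context of daily methylation change) is a
parameter.

*Expression.* The cosinor model lives on the analysis scale:
log2(FPKM + 1) = mesor + A·cos(2π(t − φ)/24) + ε, with ε Gaussian
(SD 0.25 log2 units), mesor ~ N(4, 1.5²), uniform phase, amplitude drawn
from (0.75, 1.5) log2 units for the rhythmic fraction (default 12%, the
study's rhythmic-gene proportion) and 0 otherwise. Defining amplitude
and noise on this scale keeps their ratio exact for the detector.
Methylation coupling ties mesors to per-gene methylation ranks through a
bivariate-Gaussian copula whose Pearson parameter 2·sin(π·ρ_s/6) yields
the requested Spearman ρ_s (default +0.5 on the gene body, the sign of
the study's gene-body finding).

*What the generator does not emulate*, and what passing tests therefore
do not show about real data: no bimodal per-site methylation states —
every cytosine carries its context-baseline level, so the
"fraction of positions called methylated" saturates near 100% in
simulations, unlike real leaf methylomes where most cytosines are truly
unmethylated (reported fractions ~16–20%); no spatial autocorrelation
beyond planted regions; no strand asymmetry or hemimethylation; no
sequencing-error or mapping model (counts are taken as given); no read-
level artefacts (M-bias, duplicates). Recovery results certify the
statistics and their implementation, not performance on real libraries.

## Problem sizes and determinism

Benchmarks were sized for reproducibility on one CPU: DMR recovery and
null controls run on the 2 × 200-kb genome at 30× (≈200,000 sites ×
9 samples; ~20 s per full differential pass), context-level recovery on
a 1.2-Mb bare genome (≥10⁵ sites per context, the point where ±0.01
absolute recovery is statistically comfortable), and rhythm/coupling
benchmarks on 2,000-gene cohorts; empirical-FDR estimates pool twelve
cohorts because a single cohort's estimate has Monte-Carlo SD ~0.012,
too coarse to compare against a 0.05 bound. All generators take a
single integer seed; identical seed and configuration reproduce every
output byte-for-byte (floats are serialised at full precision).

## Known limitations

* Pooling replicates before Fisher's test ignores biological
  within-group variance; with two samples per group there is no room for
  a dispersion model, and planted-truth recovery is calibrated to the
  pooled test. Beta-binomial modelling is out of scope.
* The DMR region difference uses all covered cytosines in the span;
  sparse coverage inside a cluster can let a few high-coverage sites
  dominate.
* The cosinor fixes a 24-h period; genes rhythmic at other periods are
  found only insofar as they project onto the 24-h harmonic.
* Feature precedence and any-overlap TE assignment are conventions;
  composition percentages shift under different rules.
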