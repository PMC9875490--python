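# Methods

This note documents the models, estimators, numerical choices and known
limitations of `cabc`. It is written for users who need to know exactly
what each number means before trusting it on their own data.

## Coordinates and containers

All intervals are 0-based half-open (BED convention); conversions happen
only at I/O boundaries. The TSS of a minus-strand gene is `end − 1`.
Contact matrices are per-chromosome, cis-only, stored sparsely and kept
symmetric by construction; reading a triplet file mirrors single entries
and sums duplicates. All record orderings are `(chrom, start, end, id)`
lexicographic so outputs are deterministic.

## Compartment calling

The observed/expected (O/E) normalization divides each matrix entry by the
mean contact at its bin distance; distances whose mean is zero map to
zero. PC1 is the leading eigenvector of the Pearson correlation matrix of
O/E columns, computed with a dense symmetric eigendecomposition (matches a
reference eigensolver to 1e−8 on the matrix sizes this package targets).
Bins with fewer than 10 total contacts are masked (correlation on empty
columns is undefined) and return NaN.

The eigenvector's sign is arbitrary, so an explicit per-bin orientation
track is required; PC1 is flipped so its correlation with the track is
non-negative, with a deterministic fallback (first nonzero loading made
positive) when the correlation is exactly zero. The helper
`orientation_from_peaks` sums log-scale peak counts per bin: the log
compresses focal peaks so the track reflects broad accessibility, which is
the property that separates A from B.

**Switch classification.** Between conditions, each bin gets a two-sample
t statistic on replicate PC1 values, BH correction across bins, and the
rule: A2B/B2A requires a sign flip of the mean PC1 *and* FDR < 0.05; a
flip without support stays stable under the condition-1 label; bins with
|mean PC1| < 1e−4 in either condition are reported `ambiguous` and
excluded from summaries. With two replicates a per-bin variance has two
degrees of freedom and a plain t test has a hard p-value floor (~2.5e−3),
which no BH threshold over hundreds of bins can clear; since replicate
PC1 noise is close to homoscedastic along a chromosome, the per-bin
variance is therefore shrunk toward the chromosome-wide mean residual
variance with 8 prior degrees of freedom (empirical-Bayes moderation in
the limma style). This is the one place the package departs from a
textbook per-bin test, and it is what makes 2-replicate designs usable.

**Insulation.** A domain's insulation score is
`log2((mean intra-domain O/E + ε) / (mean domain-vs-flank O/E + ε))` with
equal-length flanks truncated at chromosome ends and ε = 1e−6. Scores are
invariant to global scaling of the matrix. Differential domains require
|Δscore| > 0.25 and BH-adjusted p < 0.05 from a per-domain t test.

## Differential testing

`nb_differential` is a deliberately small NB Wald test: median-of-ratios
size factors (geometric-mean reference over features with all-positive
counts); log2 fold-change of normalized condition means with pseudocount
0.5; a method-of-moments dispersion `α = (s² − m)/m²` per feature,
averaged over conditions, shrunk toward the across-feature mean with 10
prior degrees of freedom and floored at 0.01; a delta-method standard
error `SE² = (1/μ₁ + α)/n₁ + (1/μ₂ + α)/n₂` on the natural-log scale; and
a two-sided normal p-value with BH adjustment. Features with zero counts
everywhere are excluded. There is no shrinkage of fold-changes, no Cook's
filtering and no independent filtering — downstream logic consumes only
the (log2fc, padj) pair, and on matched simulations the test is
calibrated (null fraction p < 0.05 ≈ 0.05) with near-complete power at
|log2FC| = 3. The size-factor step assumes most features are not
differential, as such normalizations always do.

Classification uses strict inequalities for genes (|log2FC| > 2,
padj ≤ 0.05) and inclusive ones for peaks (≥ threshold), with 2.0 for
H3K27ac and 0.5 for ATAC differential peaks. Gene accessibility averages
(unweighted, signed) the log2FC of all peaks overlapping the gene body or
the strand-aware 750 bp window upstream of the TSS; the ±0.05 call
threshold is exposed as a parameter (0 reproduces the more liberal
convention). A peak spanning two genes contributes to both.

`enrichment_residuals` computes Pearson residuals `(O − E)/√E` from the
independence model and a Yates-corrected chi-squared p-value. The Yates
statistic is implemented directly as `max(|O − E| − 0.5, 0)² · Σ 1/E`
(in a 2×2 table |O − E| is the same in all four cells), so an exactly
independent table gives p = 1.

## ABC enhancer prediction

Candidate regions: the N strongest peaks by score contribute summit ± 250
bp; overlapping regions merge; merged regions are resized to 500 bp about
their midpoint. TSS ± 250 bp promoter elements are appended, and
peak-derived elements overlapping a promoter window are dropped so each
promoter enters the denominator exactly once. The same ± 250 bp promoter
window is reused for peak annotation — one promoter concept everywhere.

Activity is `√(ATAC × H3K27ac)` on depth-normalized counts
(reads-per-million per replicate within each assay, averaged per
condition, summed over peaks overlapping the element). An optional
quantile normalization maps positive activities onto a supplied sorted
reference by fractional rank with linear interpolation (ties share the
mean of their mapped values); exact zeros stay zero, because "zero
Activity" is a biologically meaningful state the decomposition reports
on. `synthetic_qnorm_reference` provides a labeled synthetic stand-in for
an empirical reference distribution.

Contact between an element and a promoter is the observed count between
their 5 kb bins scaled to contacts per million, plus a power-law
pseudocount `exp(b)·d^(−γ)` (same scaling) from a least-squares log-log
fit of mean contact vs distance over 10 kb–1 Mb. Pairs closer than one
bin carry no usable observed signal (the diagonal is dominated by
self-ligation), so they use the fit at `d = resolution` alone.

Scores are normalized per gene over all elements within 5 Mb of the TSS,
promoter included; an element is predicted at score ≥ 0.02 and never when
it is a promoter. Scores are invariant to global activity scaling,
monotone in an element's own activity, and threshold-monotone (the
predicted set at a higher threshold is a subset).

## Counterfactual decomposition

Link status compares predicted (element, gene) pairs: gained = predicted
only in condition 2, lost = only in condition 1, shared = both; the three
statuses partition the union. The DE filter keeps links whose gene is
differential at FDR ≤ 0.05 with no fold-change cutoff.

A counterfactual prediction takes Activity wholly from one condition and
Contact wholly from the other; "Contact" means the matrix *and* its
power-law fit as one unit, since the pseudocount scaling belongs to the
matrix it was fitted on. `constant_activity` (condition-1 Activity,
condition-2 Contact) isolates what contact changes alone would rewire;
`constant_contact` (condition-2 Activity, condition-1 Contact) isolates
activity-driven rewiring. Retained fraction = (gained + lost under the
counterfactual) / (gained + lost at baseline); it is NaN-flagged when the
baseline has no differential links. When the two sources come from the
same condition the counterfactual reproduces that condition's baseline
bit-for-bit, and on simulations where only one layer differs the retained
fractions are exactly {0, 1}.

Zero-Activity fractions count rewired links whose element has exactly
zero depth-normalized activity on the relevant side (pre-condition for
gained, post-condition for lost), per compartment switch class. Scatter
tables report one row per unique element for Activity changes and one row
per element–gene pair for Contact changes, with zeros floored at the
smallest positive observed value unless a pseudocount is supplied.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale, with planted truth for every layer. Defaults describe one
20 Mb chromosome: 400 bins at 50 kb; contiguous A/B blocks with geometric
run lengths (mean 10 bins — megabase-scale domains, not i.i.d. bins); 10%
of bins flipped in condition 2; expected contact
`scale · max(d,1)^(−γ) · (1 + 0.6 · 1[same state])` normalized to 2×10⁶
total cis contacts per replicate (5×10⁵ is enough for compartment
recovery; the deeper default keeps 5 kb-bin contact estimates outside the
shot-noise regime), drawn Poisson per replicate at both 50 kb and 5 kb.

Forty genes sit on a jittered grid with ≥ 400 kb TSS spacing. Each gene
gets Poisson(2) intergenic enhancers at exponentially distributed
distances (scale 30 kb, capped at 100 kb) — matching the empirically
front-loaded enhancer–promoter distance distribution — with a quarter
gained and a quarter lost between conditions; 60% of rewired elements are
exactly silent in their inactive condition, the rest retain 1/8 of their
signal. Promoters are constitutively active; one background
open-chromatin site per 50 kb bin tracks compartment state with a 4-fold
A/B contrast and keeps 20 kb clear of TSSs (promoter-proximal open sites
would be regulatory, which the truth tables do not model). ATAC and
H3K27ac counts are independent NB draws (dispersion 0.05) per replicate;
expression is NB around a lognormal baseline with
`log2FC = 1.0 × (net enhancer change) + N(0, 0.3)` — the jitter makes the
enhancer–expression relationship a correlation, not an identity. The
truth tables store the exact noiseless `effect × net change` alongside
the realized value.

The gene spacing and the TSS-exclusion zone are deliberate idealizations:
they make the planted single-target link assignment identifiable ground
truth. Real loci have overlapping regulatory neighborhoods, and there ABC
genuinely links elements to several genes — recovery scores on this
generator therefore measure the pipeline's correctness, not ABC's
biological accuracy. Other simplifications: no trans contacts, no
matrix balancing artifacts, no batch effects, no copy-number or
mappability structure, replicates are exchangeable draws from a shared
expectation, and expression is coupled only to enhancer rewiring (not
directly to compartment state), so compartment–expression enrichment is
null by design under the defaults.

Two switches support single-driver experiments: `shared_contacts=True`
gives condition 2 the *same* matrices as condition 1 (activity-only
change), `shared_activity=True` shares the peak counts (contact-only
change). Sharing the objects, not re-draws, is what makes the
decomposition's exactness checks exact.

## Problem sizes and determinism

Default analyses run on one 400-bin chromosome with two replicates per
condition, 5 kb matrices of 4,000 bins sampled per diagonal, ~600
candidate elements and 40 genes; a full two-condition analysis completes
in a few seconds on one core, and the acceptance script's
calibration checks use 10,000-feature null and 2,000-feature power
simulations. Every stochastic component takes an explicit seed or
`numpy.random.Generator`; identical configs produce byte-identical
bundles and identical result tables.

## Known limitations

* The compartment caller is the standard O/E-correlation eigenvector
  method; it does not reproduce any specific external tool's windowing,
  masking or per-chromosome sign conventions, so labels on real data can
  differ near boundaries.
* The NB test is not DESeq2: no fold-change shrinkage and no outlier
  handling, so single-replicate outliers propagate into log2FC.
* Contact uses raw (unbalanced) matrices plus a power-law floor; no
  KR/ICE balancing is applied, matching desk-scale synthetic inputs but
  not production Hi-C pipelines.
* Peak annotation fractions (promoter/genic/intergenic) depend on the
  ± 250 bp promoter window; tools with asymmetric windows will give
  different category splits on real data.
* Insulation scoring uses a single window scale and a ratio score; it is
  a summary of domain strength, not a TAD caller.
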