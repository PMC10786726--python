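# Methods

This note documents the models and procedures implemented in `apobectools`,
the assumptions behind them, the numerical choices, and what the synthetic
data do and do not establish about real data.

## Coordinate and channel conventions

Variants are 1-based inclusive (VCF convention); copy-number segment tables
are 0-based half-open. The 96 single-base-substitution channels follow the
COSMIC layout: six pyrimidine-oriented substitution classes (C>A, C>G, C>T,
T>A, T>C, T>G) × 16 flanking-base pairs in alphabetical order, i.e.
`index = 16·substitution + 4·five_prime + three_prime`. Mutations at purine
reference bases are reverse-complemented so the mutated base is always a
pyrimidine; the classifier records when this strand flip happened.

## Context classification

For each SNV the engine fetches the centered 3-mer (required) and 5-mer
(optional) from the reference, orients them to the pyrimidine strand, and
sets the APOBEC flags with fixed IUPAC sets (W = {A,T}, R = {A,G},
Y = {C,T}; TCN accepts any 3′ base). Flags are all false for substitutions
other than C>T and C>G. The RTCW/YTCW refinement needs the base 5′ of the
TCW triplet, so calls lacking a full 5-mer flank carry a null
pentanucleotide and false R/Y flags; on interior positions RTCW and YTCW
partition TCW exactly.

Design choices:

* Per-sample APOBEC fractions use **all** classified SNVs as the
  denominator, not only C>T/G changes.
* Mutations whose context window leaves the contig or contains a non-ACGT
  base are excluded from numerator and denominator alike and surfaced in a
  QC counter; silently keeping them would bias fractions on gappy
  references.
* Multi-nucleotide substitutions are treated as non-SNVs and skipped by the
  context statistics (counted in QC). No background-availability
  "enrichment score" is computed: the statistics reported are raw fractions
  and counts.

The classifier is validated against an independent brute-force scanner that
enumerates both strands explicitly, and against a strand-mirroring property
(classifying on the reverse-complement genome with mirrored coordinates
gives identical flags).

## Signature refitting

A sample's catalog is normalized to channel fractions `m` and approximated
as `P w` with nonnegative per-signature weights. The fit follows the
forward-selection scheme of deconstructSigs: seed with the single signature
minimizing squared reconstruction error (its weight optimized by a bounded
golden-section search), then sweep the signatures in turn, re-optimizing one
weight at a time by golden-section search on [0, 1] (tolerance 1e-4) and
keeping any improvement. Because the objective is a convex quadratic, these
coordinate sweeps converge to the nonnegative least-squares optimum.

Stopping rule: sweeps stop when a full sweep improves the squared error by
less than a factor of 1e-3 of its current value, or the error is numerically
zero (1e-14). A *relative* criterion is used deliberately: an absolute
threshold of 1e-3 on the squared error would leave weights only loosely
determined (error is quadratic in the weights near the optimum), whereas the
relative rule lets exactly representable catalogs converge to the NNLS
solution within 1e-3 per weight while terminating promptly on noisy
catalogs, whose error plateaus at the sampling-noise floor.

After convergence, weights are normalized to fractions, contributions below
the cutoff (default 6%) are zeroed **once**, and the survivors renormalized;
iterative re-application of the cutoff is not performed. Samples with fewer
than `min_mutations` (default 10) mutations are excluded rather than fitted,
because a handful of mutations cannot discriminate signatures. Reported fit
diagnostics are the squared channel-fraction residual and the cosine
similarity between `m` and the reconstruction. No genome/exome
trinucleotide-frequency correction is applied by default: the synthetic
pipeline draws catalogs and refits them on the same genome, so no
renormalization between trinucleotide baselines is needed; a correction
matrix can be folded into the signature TSV when fitting external data.

Derived quantities:

* **APOBEC burden** = (w_SBS2 + w_SBS13) × total mutations, rounded half-up.
* **Dominant signature** = argmax weight, ties broken by numeric-aware name
  order (SBS2 before SBS13) with an explicit tie flag.
* **Per-mutation attribution**: P(s | channel c) ∝ w_s · P_s[c]; a channel
  with zero probability under every active signature is unattributable and
  signalled as such. The attribution rule is this package's choice of the
  natural posterior under the mixture model.
* **Clonal/subclonal difference**: signatures are refit separately on each
  patient's clonal and subclonal catalogs (subset-refit, the default mode;
  per-mutation attribution is available as an alternative view) and the
  difference of APOBEC weights is tested across patients with the one-sided
  exact Wilcoxon signed-rank test. Patients whose clonal or subclonal
  catalog falls below `min_mutations` are flagged and omitted from the test.

The bundled signature file is **synthetic**: five profiles with the
qualitative shapes of SBS1 (C>T at NCG), SBS2 (C>T at TCN), SBS5 (flat,
C>T/T>C-dominated), SBS13 (C>G at TCN) and SBS40 (flat, C>A-tilted), written
as exact decimals summing to one. They are distinguishable by design and
are not the COSMIC profiles; any COSMIC-format TSV can be substituted.

## Variant filtering

Filter cascades are pure functions from variant records to decisions, with
a fixed word-to-operator mapping: "minimum X"/"at least X" → ≥ X;
"over X"/"greater than X"/"more than X" → strictly > X; P-value thresholds
strict. The implemented rule sets:

* **SNV (tumor/normal exome)**: depth ≥ 30, alt reads ≥ 5, somatic P < 0.01,
  VAF ≥ 5%; calls with 2% ≤ VAF < 5% pass only if the second caller also
  detected them; VAF < 2% always fails. The 5% bound is taken as inclusive
  (its inclusivity is not fully determined by the prose; the boundary is
  unit-tested explicitly).
* **Indel**: both indel callers required, primary somatic P < 0.001,
  depth ≥ 50, alt reads ≥ 10, VAF ≥ 2%.
* **Germline exclusion**: fail when the matched normal shows > 5 alternate
  reads or VAF > 1% (both strict).
* **Cell-line WGS**: caller PASS flag, depth > 30 (strict), alt reads ≥ 4,
  VAF > 0.05 (strict).

Missing required evidence produces an explicit per-variant *error* decision,
never a silent pass, so pass + fail + error counts always reconcile with the
input count. Caller labels are free text matched case-insensitively against
a preset role mapping. Upstream caller parameterization (coverage floors
inside VarScan2 etc.) is out of scope: the cascades consume caller output.

## CIN metrics

**SCNA ITH** overlays all regions of a tumor into elementary intervals of
constant per-region copy number. A base is *altered* when any region departs
from the baseline copy number (default 2, configurable), and *heterogeneous*
when the regions additionally disagree on the copy-number state there. The
metric is heterogeneous bases / altered bases. Judging heterogeneity
per-base on state equality (rather than on event-boundary matching) makes
the metric well-defined and invariant to re-splitting segments, which is
tested. Regions must tile a common genome extent so the overlay is total.
The value is undefined (signalled) when nothing is altered.

**Missegregation**: per subject, percent = 100 · errors / anaphases, where
errors are lagging chromosomes plus anaphase bridges. When a recombination
efficiency is supplied (e.g. 0.82 for an 82%-efficient conditional allele),
the per-subject percentage is divided by it and capped at 100, expressing
the error rate per recombined cell. The group value is the harmonic mean of
per-subject percentages. The harmonic mean is undefined when a subject has
zero errors; the default policy raises, and an explicit `pooled` policy
falls back to pooled errors/anaphases with a warning. How zero-error
subjects were handled upstream is not specified in the source analyses, so
both behaviors are explicit rather than silent.

## Exact statistics

* **Mann–Whitney U**: the null distribution of U is built by exact integer
  dynamic programming (the Gaussian-binomial generating function), giving
  rational p-values with denominator C(n1+n2, n1). Two-sided p doubles the
  smaller tail, the convention that reproduces conventionally reported
  small-sample values (e.g. 2/924 ≈ 0.0022 for complete separation at
  6 vs 6). Ties switch to the mid-rank normal approximation with tie
  correction and continuity correction, flagged non-exact.
* **Wilcoxon signed-rank**: exact subset-sum DP over the 2^n sign patterns
  for n ≤ 25 with untied ranks; zero differences are dropped before ranking
  (Wilcoxon's original policy; Pratt ranking available behind a flag).
* **Fisher 2×2**: hypergeometric enumeration in rational arithmetic; the
  two-sided p sums tables with point probability ≤ the observed one, an
  exact comparison because probabilities are kept as fractions.
* **Spearman**: mid-rank correlation with the t-approximation p-value;
  optional pair bootstrap (default B = 1,000, percentile 95% CI, explicit
  seed) reporting the replicate mean and CI. Bootstrap parameters are this
  package's defaults — the upstream analyses do not state theirs — and the
  p-value in bootstrap mode is labelled approximate.
* **Cohen's d** with (n−1)-weighted pooled standard deviation.

## Synthetic data: what it emulates and what it does not

`simulate_reference` draws i.i.d. bases at a target GC content.
`simulate_catalog` samples mutation channels from the signature mixture
reweighted by the genome's trinucleotide availability (renormalized), then
places each mutation uniformly among matching sites on either strand,
without replacement, emitting purine-site mutations as the complementary
substitution. On the default GC-0.5 i.i.d. genome, trinucleotide
availability is nearly uniform, so the rebuilt catalog is
multinomial-distributed around the intended mixture and an uncorrected
refit recovers the weights in expectation; this is verified by a recovery
test (median absolute weight error ≤ 0.03 at n = 5,000 over 20 seeds). The
simulator also returns its channel draw, and the context engine rebuilds it
*exactly* — the core cross-module consistency check.

`simulate_paired_cohort` adds, per patient, a post-treatment burst of
mutations at unused TCW sites (C>T : C>G odds 2 : 1 by default, blending
the C>T-dominated SBS2 and C>G-dominated SBS13 footprints).
`simulate_multiregion_segments` plants clonal (all-region) and subclonal
(proper-subset) copy-number events of configurable total mass on disjoint
intervals and reports the planted heterogeneous/altered base counts, so the
ITH metric can be checked for exact equality. `simulate_caller_calls` draws
depth (Poisson, mean 80× tumor / 40× normal), alt reads (binomial given a
Beta-distributed true VAF: mean 0.40 clonal, 0.15 subclonal), a small
Beta-distributed somatic P, trace normal contamination, and per-caller
detection as a logistic function of VAF; variants no caller detects are
dropped, as they would never appear in real call sets.

Not emulated: read-level errors and alignment artifacts, mutational hotspots
and chromatin covariates, kataegis clustering, indel spectra beyond simple
placement, subclonal copy-number mixtures within a region, and human-genome
trinucleotide composition. Passing tests therefore establish the *internal
correctness* of the statistics and algorithms under the stated generative
assumptions — not that real tumor data meet those assumptions.

## Problem sizes and determinism

Default test/verification sizes: 50–200 kb genomes, 400–5,000 mutations per
catalog, 20 seeds for recovery, 500-call filter fixtures, 2–8 patients or
regions for cohort statistics — sizes at which every check runs in seconds
while the binomial/multinomial error bounds used by the calibration tests
are already tight. All generators take explicit seeds and are reproducible
bit-for-bit; the pipeline summary is a pure function of (config, seed) and
two runs at the same seed produce byte-identical JSON.

## Known limitations

* The forward-selection refit matches NNLS on exactly representable
  catalogs but, like deconstructSigs, offers no uncertainty quantification
  on weights.
* The 6% cutoff is applied once after convergence; signatures whose weight
  drops below the cutoff only after renormalization are kept.
* SCNA ITH uses a fixed integer baseline copy number rather than a
  ploidy-adjusted baseline; for heavily aneuploid genomes the baseline
  should be set per tumor.
* Exact tests enumerate; beyond n ≈ 25 pairs (signed-rank) or pooled
  n ≈ 60 (Mann–Whitney) the implementations switch to normal
  approximations and say so in the result's `method`/`exact` fields.
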