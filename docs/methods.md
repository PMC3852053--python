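# Methods

## The experimental design being modeled

The pipeline targets a three-arm culture experiment: enriched adult DRG
sensory neurons exposed for 24 h to vehicle, GMCSF or GCSF (triplicate
wells per arm), profiled on bead arrays carrying roughly 46 000 probes
against roughly 30 000 transcripts, with one to three probes per
transcript. Downstream validation uses TaqMan qPCR, NanoString nCounter
counts referenced to five housekeeping genes, and nociceptive behavioral
assays (von Frey filaments, Hargreaves radiant heat) in groups of six
mice.

## Statistical model, stage by stage

**Normalization.** Quantile normalization is applied within experimental
groups: for each group the columns are sorted, the per-rank means form a
reference distribution, and every sample's values are replaced by the
reference values at their ranks. Ties receive the mean of the reference
values across the tied ranks — the standard convention; the method
definition does not dictate one. A `global` mode normalizes all nine
arrays together; the per-group mode is the default because the stated
design normalizes "within each experimental group", and both are kept
because the original processing software's exact grouping is not
recoverable.

**Differential expression.** Each probe is tested with the equal-variance
two-sample two-tailed *t* test. Tests run on log2 intensities (variance
stabilization; standard microarray practice) while fold changes are ratios
of linear-scale group means — the raw-vs-log choice is not documented for
the original analysis, so it is explicit and configurable (`log_scale`).
Signed folds are +r for induction, −1/r for repression (ties +1), so the
magnitude is never below 1. BH adjustment runs across all probes of one
stimulus-vs-vehicle contrast; that family matches how per-stimulus
significant counts are reported. Degenerate zero-pooled-variance probes
get p = 1 when the means agree and p = 0 (flagged) when they differ; the
flag exists because a zero-variance "certain" call deserves scrutiny in
real data.

**Probe collapse.** Significance is decided per probe first (BH-adjusted
p ≤ α); only significant probes enter the concordance rules, and a
transcript with none is `not_significant`. No transcript-level p value is
invented, because the transcript-level quantity reported by this kind of
screen is a count of significantly regulated transcripts, not a combined
p. "Take the regulation value from the majority" is implemented as the
arithmetic mean of the majority probes' signed folds, consistent with the
unanimous-case averaging. Two probes disagreeing 1-vs-1 are discarded:
the majority rule is read as requiring one dissenter among *several*
(≥ 3) probes. An exhaustive enumeration test over every sign ×
significance pattern for 1–4 probes pins this behavior against an
independent rule interpreter.

**Cross-stimulus classification.** The partition (common-up, common-down,
reciprocal, one-stimulus-only) is computed on the collapsed retained sets;
an optional `min_fold` reproduces the two-fold-cutoff variant, since
published per-stimulus totals are ambiguous between "significant" and
"significant and > 2-fold". The ±4-fold stringency filter is inclusive
(|fold| ≥ 4), the literal reading of "at least 4-fold".

**Networks.** The direct-interaction network is the induced subgraph of a
supplied edge-list database on the seed genes; seeds absent from the
database are recorded as unmapped rather than dropped silently (curated
databases typically annotate only part of a regulated pool). "Nodal
points" are ranked purely by degree, ties broken lexicographically:
proprietary network-scoring schemes are unpublished, and hub connectivity
is the observable such analyses display. Edge mechanism/direction
attributes are carried but ignored by ranking.

**Enrichment.** Upper-tail hypergeometric P(X ≥ k) per category, BH over
the categories actually tested; zero-overlap categories are excluded from
the family, matching common enrichment-tool behavior. No GO-graph
propagation is attempted — annotations are a plain input.

**Validation quantification.** ΔΔCt: ΔCt = mean Ct(target) − mean
Ct(reference) per group, fold = 2^−(ΔCt_treated − ΔCt_control); invariant
to per-plate Ct shifts. nCounter: "arithmetic average value over all 5
housekeeping genes" is read as the mean of the five per-housekeeping-gene
fold changes, each formed from per-sample target/housekeeping ratios
averaged within group (the alternative — normalizing by the mean
housekeeping count — sits behind `method="hk_mean"`). Both readings are
invariant to rescaling all counts of any one sample (lane effects).
Concordance is the fraction of shared genes whose regulation directions
agree.

**Behavioral statistics.** One-way repeated-measures ANOVA is computed
from the closed-form decomposition (total − subject − factor sums of
squares) rather than through a packaged fitter, because Fisher's LSD
needs the error mean square and its degrees of freedom, which packaged
RM-ANOVA summaries do not expose; the packaged fitter serves as an
independent cross-check in the tests. LSD contrasts are unadjusted
two-sided t tests on MS_error — in a two-level design the LSD p equals
the omnibus p and F = t². Between-group contrasts at a single timepoint
(inhibitor vs vehicle) use the pooled within-group MS of a one-way ANOVA
across groups at that timepoint. Latencies at the 15 s cutoff are treated
as observed values; no censoring model is fitted, mirroring how such data
are conventionally analyzed.

## Synthetic data: what it emulates and what it does not

Each transcript draws a log2 baseline N(7, 1.5²) shared by its probes;
each probe adds a N(0, 0.3²) offset; treatment adds a signed log2 effect
to treated arrays only; i.i.d. N(0, 0.25²) log2 noise sits on top. The
defaults are the study-sized conditions: 30 723 transcripts, 1/2/3 probes
with weights 0.55/0.40/0.05 (≈ 46 000 probes), 3 replicates per arm,
effect magnitudes uniform on [2, 8]-fold, and class proportions derived
from the published cross-stimulus breakdown (12.7% common-up, 30.1%
common-down, 1.4% reciprocal, 7.4% GMCSF-only, 10.8% GCSF-only, the rest
null). The intensity scales themselves (baseline mean/sd, probe offset,
noise sd) are not published anywhere; they were chosen once as typical
BeadArray log2 magnitudes and are config fields, not claims about the
original data. Discordant probes are planted by flipping the effect sign
on exactly one probe of a multi-probe transcript (rate 0.05 by default),
which directly exercises the discard/majority collapse rules.

The generator deliberately omits scanner artifacts, background
fluorescence, intensity-dependent variance, probe GC effects and
bead-level replication. Passing recovery tests therefore demonstrates the
*logic* of the chain — normalization, testing, FDR, collapse,
classification — under a clean noise model, not robustness to real
BeadArray pathologies.

The qPCR generator shifts treated Ct by −log2(fold) with Gaussian cycle
noise; the nCounter generator scales treated counts by the fold with
log-normal noise and treatment-independent housekeeping genes; the
behavior generator draws von Frey responses as Binomial(5, p)·20% and
latencies as censored Gaussians; the interaction-database generator is
Erdős–Rényi with optional wired-in hubs.

**Stand-in reference lists.** The real supplementary table of
significantly regulated transcripts is not deposited as machine-readable
data; only its summary counts are printed. `table_s1_standin` therefore
fabricates GMCSF/GCSF lists whose joint structure matches those printed
counts (15 833 / 16 882 regulated; 3898 common-up, 9254 common-down, 421
reciprocal; 661 / 611 at the four-fold filter) with random magnitudes and
shuffled order. It exists so the classification stage can be exercised at
published scale, and it is labelled synthetic everywhere; recomputing its
counts checks the set algebra, not the original measurements.

## Problem sizes and numerical choices

The end-to-end recovery benchmark uses 4000 transcripts with a sparser
planted mix (10/10/5/5/5% + 65% null), fold-8 effects and log2 noise 0.2;
at the default dense mix the adaptive BH threshold admits enough
false positives in the opposite contrast to leak a few percent of the
stimulus-specific classes into the "common" pools, which is a property of
BH at α = 0.05, not of the implementation. Calibration screens use 10 000
probes for the type-I error check and 200 replicate 2000-probe screens
for realized FDR. Quantile-normalization equality is asserted to 1e−9;
fold-change and ANOVA cross-checks to relative 1e−9; Monte-Carlo
estimator recovery to 5% on 200 replicates. Sorting uses stable mergesort
throughout so tie order is deterministic, and every generator is driven
by a single `numpy` `default_rng` seed: identical seeds give bit-identical
outputs.

## Known limitations

- No moderated (empirical-Bayes) test statistics; with n = 3 per arm the
  plain t test is noticeably underpowered for small folds, which is
  faithful to the modeled analysis but not the modern recommendation.
- Probe collapse assumes probe→transcript annotation is correct and
  one-to-one per probe; re-annotation against current genome builds is
  out of scope.
- Degree ranking is a transparent but crude hub score; it ignores edge
  direction, mechanism and any curated pathway weighting.
- Enrichment treats categories as flat sets (no ontology ancestor
  closure).
- The behavioral module implements the one-factor repeated-measures
  framework; fully crossed mixed designs (group × time interactions)
  are reduced to within-factor LSD plus per-timepoint between-group LSD.
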