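# Methods

This note documents the statistical machinery implemented in `pvalscan`,
the design choices made where the design was genuinely open, and what the
synthetic-data studies do and do not demonstrate.

## Histogram classification

A validated p-value set is binned into B equal-width bins over [0, 1]
(default B = 40); bin b covers [(b−1)/B, b/B) with the last bin closed, so
p = 1.0 — common in discrete tests — lands in bin B. Sets with fewer finite
values than bins are reported `unclassifiable` rather than classified from
a histogram whose expected count per bin is below one.

Peak detection uses the exact binomial null: under uniformity each bin
count is Binomial(m, 1/B), and the QC threshold is the smallest integer c
with CDF(c; m, 1/B) ≥ 1 − α/B (α = 0.05 by default, configurable). A bin is
flagged iff its count is **strictly** greater than c. The Bonferroni
division by B bounds the probability that any bin of a truly uniform set is
flagged by ≈ α; the measured rate over 500 pure-null sets of 20,000 values
is ~3.5%. For m = 20,000, B = 40, α = 0.05 the threshold is 568 (mean bin
count 500).

Classes are a total function of the flagged-bin layout, decided in this
order: no flags → `uniform`; any maximal run of flagged bins touching
neither boundary → `other`; runs at both boundaries → `bimodal` (a single
run spanning the whole range also counts as touching both boundaries); a
single left- (right-) anchored run of length ≤ floor(B/3) →
`anti_conservative` (`conservative`), longer → `other`. The B/3 cap
operationalizes "a peak confined to a third of the unit interval"; bimodal
runs are deliberately uncapped. All thresholds and the bin count are
exposed as arguments.

## pi0 estimators

Both estimators are pure functions of the p-values, invariant to input
order, clamped to [0, 1], and meaningful only for uniform or
anti-conservative sets; the pipeline enforces that gate, the functions do
not.

**Rank-lfdr.** Sort p decreasingly, pair p(j) with rank i_j = n+1−j, set
q_j = min(n·p(j)/i_j, 1), and estimate pi0 = 2 Σ i_j q_j / (n(n+1)). The
formula averages q-value-like quantities over ranks; on an all-ones input
it returns exactly 1. The implementation is cross-checked in the test
suite against (a) an exact rational-arithmetic re-implementation with a
different loop order (agreement to 1e-12) and (b) `limma::propTrueNull
(method="lfdr")` via Rscript (agreement to 1e-9).

**Storey smoother.** pi0(λ) = #{p > λ}/(n(1−λ)) is computed on the grid
λ = 0.05, 0.10, …, 0.95 (ties p = λ count as *not* above λ), then a natural
cubic smoothing spline with 3 effective degrees of freedom is fitted and
read off at max(λ). The spline is the classical Reinsch construction: the
roughness penalty K = Q R⁻¹ Qᵀ is diagonalized once and the penalty weight
is solved so that the trace of the smoother matrix equals the requested df
(brentq on a strictly monotone scalar function). Fitted values agree with
R's `smooth.spline(df=3, all.knots=TRUE)` to ~1e-5. The estimator requires
n ≥ 100 (the lambda tail is estimated from n(1−λ_max) = n/20 observations
and is unstable below that); if every p-value lies below the smallest λ the
estimate is 0 with a warning flag. Grid and df are configurable.

On mixture sets with z-test alternatives at δ = 3 and n = 20,000, both
estimators recover true pi0 ∈ {0.2, 0.5, 0.8, 0.95} with median absolute
error ≤ 0.05 (50 seeds each, computed by the test suite).

## Table mining

Column roles are assigned deterministically from lower-cased names:
unadjusted p-value columns match `p[^a-zA-Z]{0,4}val`; columns matching
`adj|fdr|corr|thresh` — or a q-value-style name (`q[^a-zA-Z]{0,4}val`),
our extension, since cuffdiff's `q_value` carries no "adj" marker — are
`adjusted` and never returned as p-value sets; expression metrics match
`basemean`, `value`, `fpkm`, `logcpm`, `rpkm`, `aveexpr` with the longest
match winning. Precedence is adjusted > pvalue > expression > other, so
`p_value` is a p-value column even though it also contains "value".

Candidate sets are screened before analysis: `all_nan` (no finite values),
`out_of_range` (any finite value outside [0, 1]), `truncated`
(max p < 0.9 — significant-only exports), `right_skewed` (the last decile
significantly outweighs the first by a one-sided binomial test at 1e-3 AND
the last decile bin is the global maximum — 1−p transforms and score
columns). Both screen thresholds are configurable. Note that the
right-skew screen also catches *strongly* conservative sets (a large atom
at 1 makes the last bin the global maximum), so in full-corpus scans such
sets are excluded at validation rather than classified; the classifier and
the rescue path, which operate on already-accepted sets, handle
conservative shapes directly.

The DE tool is inferred with free-text evidence (a tool-name regex over
lower-cased text) taking precedence over column heuristics: fpkm-scale
expression (including cuffdiff's `value_*` FPKM columns) plus `p_value` →
cuffdiff; basemean plus `pval` / `pvalue` → DESeq / DESeq2; logcpm → edgeR;
aveexpr plus `p.value` and publication after 2014-01-01 → limma; otherwise
unknown. Per-group sample size uses the balanced-design rule
n_samples / (n_pvalue_sets + 1), defined only when the division is exact.

Readers handle tab/comma/semicolon text (delimiter sniffed from the header
line), transparent gzip, and .xlsx; undecodable or delimiter-free files
yield an import-failure record rather than a crash. Legacy .xls, .rtf and
.tar are recorded as import failures.

## Synthetic data: what it emulates

**Mixture sets** model the canonical two-group setting: a fraction pi0 of
Uniform(0, 1) nulls plus round((1−pi0)·n) alternatives, either p = 1 − Φ(z)
with z ~ Normal(δ, 1) (so per-test power at level a is Φ(δ − z₁₋ₐ), the
closed form used throughout the studies) or p ~ Beta(a, b) with a < 1 ≤ b.
Ground-truth labels are kept on the object.

**Malformed sets** are explicit mixtures of a uniform background with mass
placed where each pathology lives: `conservative` = 18% uniform mass on
[0.925, 1] plus a 10% atom at exactly 1.0 (discrete tests report p = 1);
`bimodal` = extra mass in the outermost bins on both sides, weighted so the
left end stays at least as heavy as the right (a heavier right end would
trip the right-skew screen); `hump` = a truncated Normal(0.5, 0.08) bump;
`spiky` = three interior atoms. Weights are fixed so that at 20,000
features the intended bins clear the threshold by several standard
deviations; each kind hits its nominal class in ≥ 90% of seeds.

**Count experiments** draw per-feature negative-binomial counts
(var = μ + φμ², default dispersion φ = 0.05, a typical bulk-RNA-seq
biological-replicate value) with log2 mean expression Uniform(3, 12) for
ordinary features and Uniform(−2, 2.3) for the designated low-count
fraction (group mean < 5 at unit depth); library depths vary by 2^±0.5;
DE features have the second group scaled by 2^(±lfc) with random sign
(default |lfc| = 1, i.e. fold changes 0.5 and 2). Size factors are
median-of-ratios over all-positive features, falling back to total-count
scaling below 100 such features; baseMean is the mean of size-factor
normalized counts and is exactly recomputable from the stored counts.

The per-feature test is Welch's t on log2(count/sf + 0.5) for ≥ 2
replicates per group. Degenerate cells are resolved explicitly: both groups
constant and equal → p = 1; constant but unequal → p = 0 (the infinite-t
artifact a naive test on constant low counts genuinely produces). For
single-replicate designs the test is the exact conditional (binomial) test
of the count pair given its total, two-sided by the doubling rule — heavily
discrete, with atoms at 1 and at interior values such as 0.5.

Two calibration facts about this emulation, measured and frozen by the
test suite rather than assumed: (i) a fully null, well-expressed experiment
with 5 replicates per group is classified `uniform` in ~88–91% of seeds —
slightly below the nominal Bonferroni expectation because the t statistic
on log-NB data carries an intrinsic ~1% mid-bin excess from the left skew
of the log-gamma mixing distribution (verified not to be caused by depth
variation); the test asserts the measured bound (≥ 0.85). (ii) The
simulator's single-replicate sets come out `bimodal`/`other`, not
`conservative` — interior atoms from the doubling rule force `other` —
so the conservative-rescue study constructs conservative tables directly
(see below).

**Fixtures** render a simulated table in six column-naming dialects
(cuffdiff, DESeq, DESeq2, edgeR, limma, and an anonymous one), any of
tab/comma/semicolon delimiters, optionally gzipped, with a JSON manifest
recording every column's true role; mining precision and recall are
exactly 1.0 across all of them.

## Filtering and rescue

The governing expression metric is the highest-priority one present
(basemean > logcpm > aveexpr > fpkm > rpkm > value); the per-feature value
is the row mean across columns sharing that metric; a feature is kept iff
the value is ≥ the metric's threshold (boundary kept), NaN dropped.
`value` columns are cuffdiff FPKM values and use the fpkm threshold.
Filtering is deterministic and monotone in the thresholds.

The rescue study (200 experiments, 3 replicates per group, 10% DE, 60%
low-count features) raises the anti-conservative fraction from ~0 before
filtering to ~0.9 after. The conservative arm pairs conservative p-value
sets with expression drawn independently of p — modelling conservativeness
that originates in the test rather than in low counts — and measures a
rescue rate of 0, consistent with filtering being unable to cure it.

## Pipeline determinism

Scans walk files in sorted order; the one-set-per-file choice derives from
the run seed and a CRC of the file name, so reruns are byte-identical and
adding files does not reshuffle existing choices. All parameters are echoed
into the report (`schema_version` 1). The `--all-sets` flag analyzes every
p-value column instead.

## Study sizes

The bundled studies use 20,000 features per set (the field-typical panel
size) with 200 replicates for classification fractions, 500 for the
false-peak rate, 50 per pi0 level for recovery, and 100 per arm for the
small-N comparison; at these sizes every Monte Carlo quantity asserted in
the tests is stable to well within its asserted margin across seed blocks.

## Known limitations

* The count-level emulation replaces read-level simulation and third-party
  DE engines by self-contained tests; it reproduces the *mechanisms*
  (discreteness, low power, low-count artifacts) but no particular tool's
  output, and real processed tables carry pathologies (mixed decimal
  separators, multi-sheet workbooks, partial exports) beyond the fixture
  dialects.
* Passing the recovery and rescue studies shows the estimators and the
  filter behave correctly under the generative model above; it does not
  certify pi0 estimates on real data whose tests are miscalibrated — that
  is precisely what the classification step is for.
* The right-skew validity screen and the conservative class overlap by
  construction; corpus-level conservative counts from a full scan are
  therefore lower bounds.
* Corpus-scale summaries (class proportions over public repositories,
  tool associations) require the external corpus and are out of scope; the
  pipeline computes the same descriptive summaries on any local directory.
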