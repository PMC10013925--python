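# pvalscan

Quality assessment of differential-expression p-value sets from
high-throughput sequencing experiments.

A bulk or single-cell RNA-seq differential-expression (DE) analysis tests
~20,000 features at once and therefore produces a large set of p-values
whose *distribution* is itself diagnostic: if the test is calibrated and
most features are null, the histogram is flat with (at most) a spike near
zero. Departures from that shape — spikes at one, peaks at both ends, humps
in the middle — flag broken assumptions, most often discrete tests applied
to features with too few counts. `pvalscan` is for methodologists and
analysts who want to audit such p-value sets at scale: it mines p-value and
expression columns out of heterogeneous processed tables, classifies each
histogram, estimates the proportion of true nulls, and quantifies how much
of a malformed distribution can be "rescued" by removing low-count features
before testing.

## What it computes

**Histogram classification.** A set of m p-values is binned into B = 40
equal-width bins. Under uniformity each bin count is Binomial(m, 1/B); a
bin is a *peak* when its count strictly exceeds the smallest integer c with

    P(Binomial(m, 1/B) <= c) >= 1 - alpha/B        (alpha = 0.05),

a Bonferroni correction that controls the family-wise false-peak rate.
The peak layout then assigns one of five classes: `uniform` (no peaks),
`anti_conservative` (a left-boundary run spanning <= B/3 bins — the
theoretically expected shape), `conservative` (the mirrored right-boundary
run), `bimodal` (runs at both boundaries), `other` (any interior peak or an
over-wide boundary run).

**pi0 estimation.** For well-behaved (uniform / anti-conservative) sets the
proportion of true nulls pi0 is estimated two ways:

* *rank-lfdr*: with p-values sorted decreasingly, p(j) paired with rank
  i_j = n+1-j and q_j = min(n p(j)/i_j, 1), the estimate is
  2 Σ_j i_j q_j / (n(n+1)), clamped to [0, 1];
* *Storey smoother*: pi0(λ) = #{p > λ} / (n(1−λ)) on λ = 0.05, …, 0.95,
  extrapolated to λ → 1 by a natural cubic smoothing spline with 3 effective
  degrees of freedom.

**Low-count rescue.** Features are dropped when their expression metric
(baseMean, logCPM, AveExpr, FPKM/RPKM, cuffdiff `value_*`) falls below
metric-specific thresholds (basemean 10, logcpm 1, rpkm/fpkm 1, aveexpr
3.32); the set is re-classified and re-estimated, and class transitions are
tallied into a 5×5 matrix.

**Synthetic ground truth.** A first-class simulation module generates
uniform/alternative mixtures, deliberately malformed sets, and two-group
negative-binomial count experiments (Welch t on log2 normalized counts, or
an exact conditional count test for single-replicate designs) whose
low-count features produce honest discrete-p artifacts.

## Worked example

```python
from pvalscan import *

ps = generate_pvalue_set(MixtureConfig(n_features=20_000, pi0=0.8, delta=3.0, seed=7))
report = classify_set(ps.values)
print("class:", report.klass)
print("qc threshold:", report.qc_threshold, "| flagged bins:", report.flagged_bins)
print("pi0 (rank-lfdr):   %.3f" % pi0_lfdr(ps.values).value)
print("pi0 (Storey spline): %.3f" % pi0_storey_smoother(ps.values).value)

table = simulate_count_experiment(CountSimConfig(
    n_features=20_000, n_per_group=3, frac_de=0.1, frac_low_count=0.6, seed=1))
result = rescue_set(table)
print("before:", result.before_class, "| after:", result.after_class,
      "| kept %d of %d features" % (result.n_after, result.n_before))
print("pi0 after rescue: %.3f" % result.after_pi0)
```

prints

```
class: anti_conservative
qc threshold: 568 | flagged bins: (1, 2)
pi0 (rank-lfdr):   0.811
pi0 (Storey spline): 0.808
before: other | after: anti_conservative | kept 7699 of 20000 features
pi0 after rescue: 0.946
```

The mixture truly contains 20% alternatives and both estimators recover
pi0 ≈ 0.8. The count experiment is unclassifiable-as-expected before
filtering (60% of its features are low-count and produce discrete p-value
atoms); dropping features with baseMean < 10 restores the anti-conservative
shape, and the recovered pi0 ≈ 0.95 reflects that most *well-expressed*
features are null.

A command-line interface wraps the same pipeline:

```sh
pvalscan simulate counts -p n_features=20000 -p frac_low_count=0.6 --seed 1 --out corpus/
pvalscan scan corpus/ --seed 0 --out scan.json
pvalscan rescue corpus/ --out rescue.json
pvalscan report scan.json
```

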