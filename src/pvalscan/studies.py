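"""Monte Carlo study drivers built on the simulators and the classifier.

These functions run the package's headline simulation studies: how many
true effects a 20,000-feature panel can hide inside a "uniform" histogram,
the false-peak rate of the classifier on pure nulls, parameter recovery of
the pi0 estimators, the small-sample overestimation of pi0, and the
low-count filtering rescue. They are used both by the test suite and by
the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import filtering, histogram, pi0 as pi0mod
from .synthetic import CountSimConfig, MixtureConfig, generate_pvalue_set, \
    simulate_count_experiment

DEFAULT_EFFECT_COUNTS = (25, 50, 100, 200, 400, 800)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def uniform_fraction(
    n_effects: int,
    n_features: int = 20_000,
    delta: float = 2.0,
    n_reps: int = 200,
    bins: int = histogram.DEFAULT_BINS,
    alpha: float = histogram.DEFAULT_ALPHA,
    seed: int = 0,
) -> float:
    """Fraction of replicate mixture sets classified "uniform".

    Each replicate holds ``n_effects`` z-test alternatives (z ~ Normal(delta, 1),
    p one-sided) among ``n_features`` total.
    """
    pi0 = 1.0 - n_effects / n_features
    hits = 0
    for s in _child_seeds(seed, n_reps):
        ps = generate_pvalue_set(MixtureConfig(
            n_features=n_features, pi0=pi0, alt_model="ztest",
            delta=delta, seed=int(s)))
        report = histogram.classify_set(ps.values, bins=bins, alpha=alpha)
        hits += report.klass == "uniform"
    return hits / n_reps


def swamping_search(
    effect_counts=DEFAULT_EFFECT_COUNTS,
    n_features: int = 20_000,
    delta: float = 2.0,
    n_reps: int = 200,
    bins: int = histogram.DEFAULT_BINS,
    alpha: float = histogram.DEFAULT_ALPHA,
    seed: int = 0,
) -> tuple[int | None, dict[int, float]]:
    """Largest effect count whose sets are majority-classified "uniform".

    True effects are swamped by the ~m/B null counts in the lowest bin
    until their number pushes that bin over the peak threshold. Returns
    (largest such count or None, per-count uniform fractions).
    """
    fractions = {
        int(k): uniform_fraction(
            int(k), n_features=n_features, delta=delta, n_reps=n_reps,
            bins=bins, alpha=alpha, seed=int(seed) + int(k))
        for k in effect_counts
    }
    majority = [k for k, frac in fractions.items() if frac > 0.5]
    return (max(majority) if majority else None), fractions


def null_nonuniform_fraction(
    n_sets: int = 500,
    n_features: int = 20_000,
    bins: int = histogram.DEFAULT_BINS,
    alpha: float = histogram.DEFAULT_ALPHA,
    seed: int = 0,
) -> float:
    """Fraction of pure-null sets classified anything but "uniform".

    The Bonferroni construction bounds the expected fraction by ~alpha.
    """
    non_uniform = 0
    for s in _child_seeds(seed, n_sets):
        p = np.random.default_rng(int(s)).random(n_features)
        report = histogram.classify_set(p, bins=bins, alpha=alpha)
        non_uniform += report.klass != "uniform"
    return non_uniform / n_sets


def pi0_recovery(
    true_pi0s=(0.2, 0.5, 0.8, 0.95),
    n_features: int = 20_000,
    delta: float = 3.0,
    n_reps: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Median absolute error of both pi0 estimators across true values.

    Returns a tidy frame with columns true_pi0, method, median_estimate,
    median_abs_error.
    """
    rows = []
    for true_pi0 in true_pi0s:
        ests = {"lfdr_rank": [], "storey_smoother": []}
        for s in _child_seeds(seed + int(true_pi0 * 1000), n_reps):
            ps = generate_pvalue_set(MixtureConfig(
                n_features=n_features, pi0=float(true_pi0), alt_model="ztest",
                delta=delta, seed=int(s)))
            ests["lfdr_rank"].append(pi0mod.pi0_lfdr(ps.values).value)
            ests["storey_smoother"].append(pi0mod.pi0_storey_smoother(ps.values).value)
        for method, vals in ests.items():
            vals = np.asarray(vals)
            rows.append({
                "true_pi0": float(true_pi0), "method": method,
                "median_estimate": float(np.median(vals)),
                "median_abs_error": float(np.median(np.abs(vals - true_pi0))),
            })
    return pd.DataFrame(rows)


def small_n_pi0_medians(
    n_per_group=(2, 10),
    true_pi0: float = 0.5,
    n_features: int = 20_000,
    n_reps: int = 100,
    seed: int = 0,
) -> dict[int, float]:
    """Median estimated pi0 (rank-lfdr) from count experiments at each N.

    With few replicates per group the per-feature test is underpowered,
    alternative p-values spread over (0, 1), and pi0 is overestimated.
    """
    medians: dict[int, float] = {}
    for k in n_per_group:
        ests = []
        for s in _child_seeds(seed + 7919 * int(k), n_reps):
            table = simulate_count_experiment(CountSimConfig(
                n_features=n_features, n_per_group=int(k),
                frac_de=1.0 - true_pi0, frac_low_count=0.0, seed=int(s)))
            ests.append(pi0mod.pi0_lfdr(table.numeric("pvalue")).value)
        medians[int(k)] = float(np.median(ests))
    return medians


@dataclass(frozen=True)
class RescueStudy:
    """Corpus-level outcome of the low-count filtering rescue simulation."""

    before_anticons_fraction: float
    after_anticons_fraction: float
    transition: filtering.TransitionMatrix
    results: list


def rescue_study(
    n_sets: int = 200,
    n_features: int = 20_000,
    n_per_group: int = 3,
    frac_de: float = 0.1,
    frac_low_count: float = 0.6,
    seed: int = 0,
) -> RescueStudy:
    """Simulate count experiments rich in low-count features and rescue them.

    Low-count features produce discrete p-value artifacts that deform the
    unfiltered histogram; removing them should raise the anti-conservative
    fraction.
    """
    results = []
    for s in _child_seeds(seed, n_sets):
        table = simulate_count_experiment(CountSimConfig(
            n_features=n_features, n_per_group=n_per_group, frac_de=frac_de,
            frac_low_count=frac_low_count, seed=int(s)))
        results.append(filtering.rescue_set(table))
    before = np.mean([r.before_class == "anti_conservative" for r in results])
    after = np.mean([r.after_class == "anti_conservative" for r in results])
    return RescueStudy(
        before_anticons_fraction=float(before),
        after_anticons_fraction=float(after),
        transition=filtering.transition_summary(results),
        results=results,
    )


def conservative_rescue_rate(
    n_sets: int = 100,
    n_features: int = 20_000,
    seed: int = 0,
) -> tuple[float, int]:
    """Rescue rate among synthetic sets whose unfiltered class is conservative.

    Conservative histograms arise when the test itself is conservative
    across the whole expression range (discrete tests, underpowered
    designs), not specifically from low-count features; the sets here pair
    conservative p-values with expression values drawn independently of p,
    so filtering removes an unbiased subsample and should rarely change the
    class. Returns (rescued fraction among conservative sets, number of
    conservative sets seen).
    """
    import pandas as pd

    from .mining import ProcessedTable
    from .synthetic import generate_malformed_set

    conservative = 0
    rescued = 0
    for s in _child_seeds(seed, n_sets):
        rng = np.random.default_rng(int(s))
        ps = generate_malformed_set("conservative", n_features, seed=int(s))
        base_mean = 2.0 ** rng.uniform(-2.0, 12.0, size=n_features)
        table = ProcessedTable(df=pd.DataFrame(
            {"baseMean": base_mean, "pvalue": ps.values}))
        result = filtering.rescue_set(table)
        if result.before_class == "conservative":
            conservative += 1
            rescued += result.rescued
    rate = rescued / conservative if conservative else 0.0
    return float(rate), conservative
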