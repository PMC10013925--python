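"""Ground-truth properties of the mixture, malformed and count simulators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pvalscan import (
    CountSimConfig, MixtureConfig, classify_set, generate_malformed_set,
    generate_pvalue_set, simulate_count_experiment,
)
from pvalscan.synthetic import MALFORMED_KINDS


class TestMixtureGenerator:
    def test_label_bookkeeping_is_exact(self):
        for pi0, n in [(0.8, 20_000), (0.995, 20_000), (0.333, 999), (1.0, 7), (0.0, 7)]:
            ps = generate_pvalue_set(MixtureConfig(n_features=n, pi0=pi0, seed=1))
            assert ps.values.size == n
            assert int(ps.is_alternative.sum()) == round((1 - pi0) * n)

    def test_pure_null_is_uniform(self):
        """For pi0=1 the KS test at alpha=0.01 rejects in <~2% of seeds."""
        rejections = sum(
            stats.kstest(
                generate_pvalue_set(
                    MixtureConfig(n_features=5000, pi0=1.0, seed=s)).values,
                "uniform").pvalue < 0.01
            for s in range(300)
        )
        assert rejections <= 9  # 3% allows for MC noise around the 1% rate

    def test_null_effect_alternative_matches_uniform(self):
        """delta=0 makes the alternative law coincide with the null."""
        ps = generate_pvalue_set(
            MixtureConfig(n_features=20_000, pi0=0.0, delta=0.0, seed=3))
        assert stats.kstest(ps.values, "uniform").pvalue > 0.001

    def test_expected_small_pvalue_count_closed_form(self):
        """pi0=0.995, delta=2: E[#{p < 0.025}] = 19900*0.025 + 100*Phi(0.04)."""
        expected = 19_900 * 0.025 + 100 * stats.norm.cdf(2 - stats.norm.isf(0.025))
        assert expected == pytest.approx(549.1, abs=0.5)
        counts = [
            (generate_pvalue_set(MixtureConfig(
                n_features=20_000, pi0=0.995, delta=2.0, seed=s)).values < 0.025).sum()
            for s in range(40)
        ]
        sem = np.sqrt(expected) / np.sqrt(40)  # ~binomial sd over 40 reps
        assert abs(np.mean(counts) - expected) < 5 * sem

    def test_beta_alternative_and_config_validation(self):
        ps = generate_pvalue_set(MixtureConfig(
            n_features=1000, pi0=0.5, alt_model="beta", beta_a=0.2, seed=2))
        alt = ps.values[ps.is_alternative]
        null = ps.values[~ps.is_alternative]
        assert alt.mean() < null.mean()
        with pytest.raises(ValueError):
            MixtureConfig(pi0=1.5)
        with pytest.raises(ValueError):
            MixtureConfig(delta=np.inf)
        with pytest.raises(ValueError):
            MixtureConfig(alt_model="beta", beta_a=1.5)
        with pytest.raises(ValueError):
            MixtureConfig(alt_model="gamma")

    def test_reproducibility_bit_identical(self):
        a = generate_pvalue_set(MixtureConfig(seed=42))
        b = generate_pvalue_set(MixtureConfig(seed=42))
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.is_alternative, b.is_alternative)


class TestMalformedGenerator:
    def test_conservative_construction(self):
        ps = generate_malformed_set("conservative", 20_000, seed=0)
        assert (ps.values == 1.0).mean() >= 0.08  # atom at exactly 1
        rep = classify_set(ps.values)
        assert rep.klass == "conservative"
        assert 40 in rep.flagged_bins and 1 not in rep.flagged_bins

    def test_bimodal_construction(self):
        rep = classify_set(generate_malformed_set("bimodal", 20_000, seed=0).values)
        assert rep.klass == "bimodal"
        assert 1 in rep.flagged_bins and 40 in rep.flagged_bins

    def test_hump_is_interior_and_other(self):
        ps = generate_malformed_set("hump", 20_000, seed=0)
        rep = classify_set(ps.values)
        assert rep.klass == "other"
        assert all(1 < b < 40 for b in rep.flagged_bins)
        # peak strictly inside (0.2, 0.8)
        assert 0.2 < np.argmax(rep.counts) / 40 < 0.8

    def test_spiky_atoms(self):
        ps = generate_malformed_set("spiky", 20_000, seed=0)
        values, counts = np.unique(ps.values, return_counts=True)
        assert (counts > 500).sum() == 3  # three interior atoms
        assert classify_set(ps.values).klass == "other"

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            generate_malformed_set("wavy", 100, 0)

    def test_reproducibility(self):
        for kind in MALFORMED_KINDS:
            a = generate_malformed_set(kind, 5000, seed=9).values
            b = generate_malformed_set(kind, 5000, seed=9).values
            assert np.array_equal(a, b)


class TestCountSimulator:
    def test_counts_are_nonnegative_integers_and_basemean_consistent(self):
        table = simulate_count_experiment(
            CountSimConfig(n_features=3000, n_per_group=4, frac_low_count=0.3, seed=2))
        counts = table.meta["counts"]
        assert counts.dtype.kind == "i" and counts.min() >= 0
        sf = table.meta["size_factors"]
        recomputed = (counts / sf[None, :]).mean(axis=1)
        np.testing.assert_allclose(recomputed, table.numeric("baseMean"),
                                   rtol=0, atol=1e-9)

    def test_reproducibility(self):
        cfg = CountSimConfig(n_features=1000, seed=5)
        a = simulate_count_experiment(cfg)
        b = simulate_count_experiment(cfg)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_null_experiment_classified_uniform(self):
        """Well-expressed null experiments are majority 'uniform'.

        The Welch test on log counts carries a small intrinsic mid-bin
        excess, so the uniform rate sits near 0.9; the bound asserted here
        is the Monte Carlo estimate minus sampling slack.
        """
        hits = sum(
            classify_set(simulate_count_experiment(CountSimConfig(
                n_features=20_000, n_per_group=5, frac_de=0.0,
                frac_low_count=0.0, seed=s)).numeric("pvalue")).klass == "uniform"
            for s in range(100)
        )
        assert hits >= 85

    def test_de_experiment_is_anti_conservative(self):
        hits = sum(
            classify_set(simulate_count_experiment(CountSimConfig(
                n_features=20_000, n_per_group=10, frac_de=0.1,
                log2_fold_change=1.0, seed=s)).numeric("pvalue")).klass
            == "anti_conservative"
            for s in range(15)
        )
        assert hits >= 12

    def test_single_replicate_design_degenerates(self):
        """n=1 uses the exact pair test: discrete p with atoms (incl. 1),
        and the sets are rarely anti-conservative."""
        anti = 0
        for s in range(15):
            table = simulate_count_experiment(CountSimConfig(
                n_features=20_000, n_per_group=1, frac_de=0.05,
                frac_low_count=0.3, seed=s))
            p = table.numeric("pvalue")
            assert (p == 1.0).sum() > 100
            assert np.unique(p[table.meta["low_count"]]).size < 2000
            anti += classify_set(p).klass == "anti_conservative"
        assert anti <= 3

    def test_low_count_features_have_discrete_pvalues(self):
        table = simulate_count_experiment(CountSimConfig(
            n_features=20_000, n_per_group=3, frac_de=0.1,
            frac_low_count=0.6, seed=4))
        p = table.numeric("pvalue")
        low = table.meta["low_count"]
        # ties at exactly 1 arise from all-equal low-count rows
        assert (p[low] == 1.0).sum() > 50
        assert classify_set(p).klass in ("bimodal", "other", "conservative")

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CountSimConfig(n_per_group=0)
        with pytest.raises(ValueError):
            CountSimConfig(dispersion=0.0)
        with pytest.raises(ValueError):
            CountSimConfig(frac_de=1.2)
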