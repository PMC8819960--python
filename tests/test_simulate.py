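"""Synthetic community generator and scenario engines."""

import numpy as np
import pandas as pd
import pytest

import rftest as rt
from rftest.forest import ForestConfig
from rftest.simulate import scale, signal_sum


class TestSynthCommunity:
    def test_row_sums_equal_depth(self, small_community):
        assert (small_community.table.sum(axis=1) == small_community.depth).all()

    def test_counts_non_negative_integers(self, small_community):
        values = small_community.table.to_numpy()
        assert (values >= 0).all()
        assert np.issubdtype(values.dtype, np.integer)

    def test_same_seed_reproduces_everything(self):
        a = rt.synth_community(n=20, p=30, depth=300, seed=5)
        b = rt.synth_community(n=20, p=30, depth=300, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.tree == b.tree
        assert a.lineages.keys() == b.lineages.keys()

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            rt.synth_community(n=10, p=5, depth=100, seed=0)

    def test_lineages_are_monophyletic(self, community):
        for lin in community.lineages.values():
            assert set(lin.taxa) == set(
                community.tree.descendant_leaves(lin.node)
            )

    def test_registry_calibration_over_seeds(self):
        """The focal lineage hits ~15% of taxa and ~21% of abundance and
        its nested sub-lineage ~5%/~11%, averaged over seeds."""
        a_otu, a_ab, b_otu, b_ab = [], [], [], []
        for s in range(20):
            c = rt.synth_community(n=50, p=200, depth=20000, seed=s)
            a_otu.append(c.lineages["A"].otu_fraction)
            a_ab.append(c.lineages["A"].abundance_fraction)
            b_otu.append(c.lineages["B"].otu_fraction)
            b_ab.append(c.lineages["B"].abundance_fraction)
        assert 0.12 <= np.mean(a_otu) <= 0.18
        assert 0.17 <= np.mean(a_ab) <= 0.25
        assert 0.03 <= np.mean(b_otu) <= 0.07
        assert 0.088 <= np.mean(b_ab) <= 0.132  # 0.11 +/- 20% relative

    def test_nested_lineage_structure(self, community):
        assert set(community.lineages["B"].taxa) < set(community.lineages["A"].taxa)
        assert not set(community.lineages["C"].taxa) & set(
            community.lineages["A"].taxa
        )


class TestSelectSignalSet:
    def test_random_full_density_selects_all(self, small_community):
        s = rt.select_signal_set(small_community, "random", 1.0, seed=0)
        assert set(s) == set(small_community.taxa)

    def test_clustered_sets_nested_across_densities(self, community):
        s5 = rt.select_signal_set(community, "clustered", 0.05, seed=1)
        s15 = rt.select_signal_set(community, "clustered", 0.15, seed=1)
        assert set(s5) < set(s15)

    def test_random_sets_nested_across_densities(self, community):
        s5 = rt.select_signal_set(community, "random", 0.05, seed=3)
        s15 = rt.select_signal_set(community, "random", 0.15, seed=3)
        assert set(s5) < set(s15)

    def test_random_inclusion_frequency_matches_density(self, small_community):
        density = 0.2
        p = len(small_community.taxa)
        counts = pd.Series(0, index=list(small_community.taxa))
        n_seeds = 500
        for s in range(n_seeds):
            for t in rt.select_signal_set(small_community, "random", density, s):
                counts[t] += 1
        freq = counts / n_seeds
        assert (freq - density).abs().max() < 0.05

    def test_unreachable_clustered_density_errors(self, community):
        with pytest.raises(ValueError, match="lineage"):
            rt.select_signal_set(community, "clustered", 0.9, seed=0)


class TestOutcomes:
    def test_scale_zero_mean_unit_sd(self, small_community):
        v = scale(small_community.table.sum(axis=1).to_numpy() * 0 +
                  np.random.default_rng(0).normal(size=30))
        assert abs(v.mean()) < 1e-10
        assert abs(v.std(ddof=1) - 1) < 1e-10

    def test_scale_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            scale(np.ones(10))

    def test_null_binary_case_fraction_half(self):
        """beta0=0, beta=0, no covariate: P(y=1) = 1/2 for every sample."""
        c = rt.synth_community(n=1000, p=20, depth=100, seed=9)
        spec = rt.ScenarioSpec(scenario="S0", outcome_type="binary", beta=0.0)
        y, z = rt.outcome_linear(c, (), spec, np.random.default_rng(0))
        assert z is None
        assert abs(y.mean() - 0.5) < 0.04

    def test_continuous_null_centered_at_beta0(self):
        c = rt.synth_community(n=400, p=20, depth=100, seed=10)
        spec = rt.ScenarioSpec(scenario="S0", outcome_type="continuous", beta=0.0)
        y, _ = rt.outcome_linear(c, (), spec, np.random.default_rng(1))
        assert abs(y.mean() - 10.0) < 0.2  # beta0 = 10, sigma = 1

    def test_covariate_modes(self, small_community):
        spec_i = rt.ScenarioSpec(scenario="S0", outcome_type="continuous",
                                 beta=0.0, covariate_mode="independent")
        y, z = rt.outcome_linear(small_community, (), spec_i,
                                 np.random.default_rng(2))
        assert z is not None and len(z) == 30
        assert spec_i.resolved_sigma == 3.0
        spec_c = rt.ScenarioSpec(scenario="S0", outcome_type="binary",
                                 beta=0.0, covariate_mode="correlated")
        _, zc = rt.outcome_linear(small_community, (), spec_c,
                                  np.random.default_rng(3))
        lin = small_community.lineages["A"]
        sig = scale(signal_sum(small_community.table, lin.taxa))
        assert np.corrcoef(zc, sig)[0, 1] > 0.3

    def test_mean_normalization_changes_weighting(self, small_community):
        taxa = list(small_community.taxa[:10])
        plain = signal_sum(small_community.table, taxa)
        normed = signal_sum(small_community.table, taxa, mean_normalize=True,
                            on_absent="drop")
        assert not np.allclose(scale(plain), scale(normed))

    def test_absent_taxon_errors_by_default(self):
        table = pd.DataFrame(
            {"T1": [1.0, 2.0], "T2": [0.0, 0.0]}, index=["a", "b"]
        )
        with pytest.raises(ValueError, match="absent"):
            signal_sum(table, ["T1", "T2"], mean_normalize=True)
        # drop mode keeps the present taxon's contribution
        np.testing.assert_array_equal(
            signal_sum(table, ["T1", "T2"], mean_normalize=True,
                       on_absent="drop"),
            table["T1"].to_numpy() / 1.5,
        )
        with pytest.raises(ValueError, match="every signal taxon"):
            signal_sum(table, ["T2"], mean_normalize=True, on_absent="drop")


class TestNonlinearLink:
    def test_dyadic_points_exact(self):
        table = pd.DataFrame({"T1": [0.0, 1.0, 3.0, 7.0]}, index=list("abcd"))
        np.testing.assert_array_equal(
            signal_sum(table, ["T1"], link="log2p1"), [0, 1, 2, 3]
        )

    def test_link_changes_outcome(self, small_community):
        spec = rt.ScenarioSpec(scenario="S3", outcome_type="continuous",
                               signal_type="clustered", density=0.15, beta=1.0)
        sig = rt.select_signal_set(small_community, "clustered", 0.15, seed=0)
        y_lin, _ = rt.outcome_linear(small_community, sig, spec,
                                     np.random.default_rng(7))
        y_log, _ = rt.outcome_nonlinear(small_community, sig, spec,
                                        np.random.default_rng(7))
        assert not np.allclose(y_lin, y_log)


class TestInteraction:
    def test_disjointness_enforced(self, small_community):
        spec = rt.ScenarioSpec(scenario="S4", outcome_type="continuous",
                               beta=1.33, interaction=True)
        taxa = list(small_community.taxa)
        with pytest.raises(ValueError, match="disjoint"):
            rt.outcome_interaction(small_community, taxa[:5], taxa[4:9], spec,
                                   np.random.default_rng(0))

    def test_beta_zero_is_pure_null(self, small_community):
        spec = rt.ScenarioSpec(scenario="S4", outcome_type="continuous",
                               beta=0.0, interaction=True)
        y, _ = rt.outcome_interaction(small_community, (), (), spec,
                                      np.random.default_rng(1))
        assert len(y) == 30

    def test_marginal_association_suppressed(self):
        """The product construction hides the signal from either factor
        alone. For symmetric factors the marginal correlation would be
        exactly 0; skewed compositional sums leave the residual
        corr(y, f1) = beta E[f1^2 f2] / sd(y), which the empirical
        correlation must match, and which is far below the correlation
        carried by the product term itself."""
        c = rt.synth_community(n=5000, p=60, depth=1000, seed=13)
        sA = c.lineages["A"].taxa
        sC = c.lineages["C"].taxa
        spec = rt.ScenarioSpec(scenario="S4", outcome_type="continuous",
                               signal_type="clustered", beta=1.33,
                               interaction=True, n=5000)
        y, _ = rt.outcome_interaction(c, sA, sC, spec, np.random.default_rng(2))
        f1 = scale(signal_sum(c.table, sA))
        f2 = scale(signal_sum(c.table, sC))
        predicted = spec.beta * np.mean(f1 * f1 * f2) / y.std()
        observed = np.corrcoef(y, f1)[0, 1]
        assert observed == pytest.approx(predicted, abs=0.03)
        r_product = np.corrcoef(y, f1 * f2)[0, 1]
        assert abs(observed) < 0.5 * abs(r_product)


class TestOutliers:
    def test_zero_outliers_identity(self, small_community):
        out = rt.inject_outliers(small_community, 0, np.random.default_rng(0))
        assert out is small_community

    def test_rows_keep_multiset_and_sum(self, small_community):
        out = rt.inject_outliers(small_community, 5, np.random.default_rng(1))
        for i in range(small_community.n_samples):
            a = np.sort(small_community.table.iloc[i].to_numpy())
            b = np.sort(out.table.iloc[i].to_numpy())
            np.testing.assert_array_equal(a, b)
        assert (out.table.sum(axis=1) == small_community.depth).all()

    def test_exactly_k_rows_differ(self):
        c = rt.synth_community(n=50, p=100, depth=2000, seed=3)
        out = rt.inject_outliers(c, 3, np.random.default_rng(2))
        differs = (out.table.to_numpy() != c.table.to_numpy()).any(axis=1)
        assert differs.sum() == 3


class TestDriver:
    def test_alpha_one_rejects_everything(self):
        spec = rt.ScenarioSpec(scenario="S0", outcome_type="binary", beta=0.0,
                               n=25, p=25, depth=200)
        with pytest.warns(UserWarning):
            res = rt.estimate_error_rate(
                spec, n_runs=20, B=5, alpha=1.0,
                config=ForestConfig(n_trees=25, n_repeats=1), seed=0,
            )
        assert res.rejection_rate == 1.0

    def test_ci_shrinks_with_more_runs(self):
        spec = rt.ScenarioSpec(scenario="S0", outcome_type="binary", beta=0.0,
                               n=25, p=25, depth=200)
        cfg = ForestConfig(n_trees=25, n_repeats=1)
        small = rt.estimate_error_rate(spec, n_runs=20, B=19, alpha=0.5,
                                       config=cfg, seed=1)
        big = rt.estimate_error_rate(spec, n_runs=40, B=19, alpha=0.5,
                                     config=cfg, seed=1)
        w_small = small.ci_high - small.ci_low
        w_big = big.ci_high - big.ci_low
        assert 0.5 < w_big / w_small < 0.9  # ~ 1/sqrt(2)

    def test_too_few_runs_rejected(self):
        spec = rt.ScenarioSpec(scenario="S0", beta=0.0)
        with pytest.raises(ValueError, match="n_runs"):
            rt.estimate_error_rate(spec, n_runs=5)

    def test_simulate_dataset_deterministic(self):
        spec = rt.ScenarioSpec(scenario="S1", outcome_type="binary",
                               signal_type="clustered", density=0.15, beta=2.0,
                               n=20, p=30, depth=200)
        a = rt.simulate_dataset(spec, seed=77)
        b = rt.simulate_dataset(spec, seed=77)
        pd.testing.assert_frame_equal(a.table, b.table)
        np.testing.assert_array_equal(a.y, b.y)
        assert a.signal == b.signal

    def test_outliers_injected_after_outcome(self):
        """Outcomes are generated from the clean table; corruption then
        touches exactly the configured number of rows."""
        spec = rt.ScenarioSpec(scenario="S5", outcome_type="binary",
                               signal_type="clustered", density=0.15, beta=2.0,
                               n_outliers=3, n=30, p=60, depth=1000)
        clean_spec = rt.ScenarioSpec(**{**spec.to_dict(), "n_outliers": 0})
        ds = rt.simulate_dataset(spec, seed=31)
        ds_clean = rt.simulate_dataset(clean_spec, seed=31)
        np.testing.assert_array_equal(ds.y, ds_clean.y)
        differs = (ds.table.to_numpy() != ds_clean.table.to_numpy()).any(axis=1)
        assert differs.sum() == 3
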