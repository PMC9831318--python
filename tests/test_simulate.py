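"""Synthetic-data generator: determinism, the paternity mechanism, moments."""

import numpy as np
import pytest

from batemeta.phylo import is_ultrametric, phylo_correlation, tree_depth
from batemeta.meta import MetaModelSpec, fit_reml
from batemeta.simulate import (
    SimulationConfig,
    recovery_experiment,
    simulate_individual_study,
    simulate_meta_dataset,
    simulate_tree,
)


class TestSimulateTree:
    def test_two_tips_share_nothing(self):
        corr = phylo_correlation(simulate_tree(2, seed=1))
        np.testing.assert_allclose(corr.values, np.eye(2))

    def test_seeded_newick_identical(self):
        a = simulate_tree(12, seed=5).as_string(schema="newick")
        b = simulate_tree(12, seed=5).as_string(schema="newick")
        assert a == b

    def test_unit_depth_ultrametric_psd(self):
        tree = simulate_tree(50, seed=9)
        assert is_ultrametric(tree)
        assert tree_depth(tree) == pytest.approx(1.0)
        corr = phylo_correlation(tree)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)
        assert np.linalg.eigvalsh(corr.values).min() >= -1e-8

    def test_too_few_species(self):
        with pytest.raises(ValueError):
            simulate_tree(1, seed=0)


class TestIndividualStudy:
    def test_genetic_never_exceeds_copulatory(self):
        config = SimulationConfig(fecundity_mean=6.0, offspring_sampled=3)
        for seed in range(20):
            df = simulate_individual_study(config, seed=seed, n_females=100)
            assert (df["genetic_mating_success"] <= df["mating_success"]).all()
            assert (df.loc[df["mating_success"] == 0, "reproductive_success"] == 0).all()

    def test_null_slope_copulatory_uncorrelated_genetic_inflated(self):
        """Under a flat fitness-by-matings relationship the behavioural count
        is uncorrelated with offspring number, while the parentage-based
        count is positively correlated when few offspring are genotyped."""
        config = SimulationConfig(beta_true=0.0, zero_truncated=True,
                                  fecundity_mean=5.0, fecundity_dispersion=2.0,
                                  offspring_sampled=4)
        rc, rg = [], []
        for rep in range(60):
            df = simulate_individual_study(config, seed=3000 + rep, n_females=200)
            rc.append(np.corrcoef(df.mating_success, df.reproductive_success)[0, 1])
            rg.append(np.corrcoef(df.genetic_mating_success, df.reproductive_success)[0, 1])
        assert abs(np.mean(rc)) < 0.05
        assert np.mean(rg) > 0.2

    def test_exhaustive_genotyping_recovers_copulatory_count(self):
        """With high fecundity and all offspring genotyped the genetic count
        converges to the behavioural count."""
        config = SimulationConfig(zero_truncated=True, fecundity_mean=100.0,
                                  offspring_sampled=1000)
        df = simulate_individual_study(config, seed=5, n_females=300)
        agree = (df["mating_success"] == df["genetic_mating_success"]).mean()
        assert agree > 0.95

    def test_positive_slope_shows_up_in_correlation(self):
        config = SimulationConfig(beta_true=5.0, zero_truncated=True,
                                  fecundity_mean=5.0)
        rs = [
            np.corrcoef(
                (d := simulate_individual_study(config, seed=s, n_females=200)).mating_success,
                d.reproductive_success,
            )[0, 1]
            for s in range(20)
        ]
        assert np.mean(rs) > 0.3


class TestMetaDataset:
    def test_seeded_output_identical(self, small_tree):
        config = SimulationConfig(n_species=15, n_studies=18, n_effects=25, seed=4)
        r1, t1 = simulate_meta_dataset(config, small_tree, seed=4)
        r2, t2 = simulate_meta_dataset(config, small_tree, seed=4)
        assert r1.equals(r2)
        assert t1.equals(t2)

    def test_shape_and_schema(self, literature_like_dataset):
        records, truth, _ = literature_like_dataset
        assert len(records) == 120
        assert records["study_id"].nunique() == 84
        assert records["species"].nunique() == 77
        assert (records["var_r"] > 0).all()
        assert records["r"].abs().max() < 1
        assert set(records["mating_system"].unique()) <= {"low", "high"}

    def test_truth_decomposition_consistent(self, literature_like_dataset):
        records, truth, _ = literature_like_dataset
        config = truth.attrs["config"]
        recon = config.mu + truth[["species_effect", "study_effect", "obs_effect"]].sum(axis=1)
        np.testing.assert_allclose(recon, truth["theta"], atol=1e-12)

    def test_between_species_variance_matches_sigma2_phylo(self):
        """Moment check: with only phylogenetic variance the spread of
        species effects approximates sigma2_phylo."""
        config = SimulationConfig(n_species=200, n_studies=200, n_effects=200,
                                  sigma2_study=0.0, sigma2_obs=0.0,
                                  sigma2_phylo=0.04, seed=6)
        tree = simulate_tree(200, seed=6)
        _, truth = simulate_meta_dataset(config, tree, seed=6)
        realized = truth.drop_duplicates("effect_id")["species_effect"].var(ddof=1)
        assert realized == pytest.approx(0.04, rel=0.35)

    def test_degenerate_limit_recovers_mu(self):
        config = SimulationConfig(n_species=10, n_studies=10, n_effects=40,
                                  sigma2_phylo=0.0, sigma2_study=0.0, sigma2_obs=0.0,
                                  n_females_median=500, n_females_sigma=0.0,
                                  n_females_max=500, mu=0.4, seed=7)
        records, _ = simulate_meta_dataset(config, simulate_tree(10, 7), seed=7)
        assert records["r"].mean() == pytest.approx(0.4, abs=0.02)

    def test_individual_mode_agrees_with_fast_mode(self, small_tree):
        """The fully simulated individual-study route gives meta-model
        estimates consistent with the fast route at matched parameters."""
        base = dict(n_species=15, n_studies=30, n_effects=60,
                    mating_rate=3.0, fecundity_mean=8.0)
        corr = phylo_correlation(small_tree)
        fast = SimulationConfig(fast_mode=True, seed=8, **base)
        full = SimulationConfig(fast_mode=False, seed=8, **base)
        r_fast, _ = simulate_meta_dataset(fast, small_tree, seed=8)
        r_full, _ = simulate_meta_dataset(full, small_tree, seed=8)
        f1 = fit_reml(MetaModelSpec(), r_fast, corr)
        f2 = fit_reml(MetaModelSpec(), r_full, corr)
        assert f2.pooled_estimate == pytest.approx(f1.pooled_estimate, abs=0.1)


class TestRecoveryExperiment:
    def test_zero_replicates_error(self):
        with pytest.raises(ValueError):
            recovery_experiment(SimulationConfig(), 0, seed=1)

    def test_small_run_reports_bias_rmse_coverage(self):
        config = SimulationConfig(n_species=12, n_studies=15, n_effects=30, seed=2)
        table, summary = recovery_experiment(config, 3, seed=2)
        assert len(table) == 3
        assert summary["failures"] == 0
        assert np.isfinite(summary["bias_mu"])
        assert np.isfinite(summary["rmse_mu"])
        assert 0.0 <= summary["coverage_mu"] <= 1.0

    def test_null_mean_effect_recovered(self):
        config = SimulationConfig(mu=0.0, sigma2_phylo=0.005, sigma2_study=0.005,
                                  sigma2_obs=0.005, n_species=20, n_studies=25,
                                  n_effects=50, seed=3)
        _, summary = recovery_experiment(config, 5, seed=3)
        assert abs(summary["bias_mu"]) < 0.03
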