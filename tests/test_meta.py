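"""Multilevel meta-model: closed forms, oracles, posterior summaries."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from batemeta.meta import (
    MetaModelSpec,
    build_design,
    fit_mcmc,
    fit_reml,
    heterogeneity_decomposition,
    marginal_r2,
    mcmc_p_value,
    posterior_mode_hpd,
    typical_sampling_variance,
)

QUICK_CHAIN = dict(iterations=6000, burn_in=1000, thinning=5)


class TestRemlClosedForms:
    def test_reduces_to_inverse_variance_weighted_mean(self, toy_records):
        """With no random components the REML fit is the fixed-effect
        inverse-variance weighted mean with its closed-form SE."""
        fit = fit_reml(MetaModelSpec(random_terms=()), toy_records)
        w = 1 / toy_records["var_r"].to_numpy()
        expected = np.average(toy_records["r"], weights=w)
        assert fit.pooled_estimate == pytest.approx(expected, abs=1e-10)
        assert fit.pooled_estimate == pytest.approx(0.28, abs=1e-10)

    def test_identical_records_give_zero_heterogeneity(self):
        records = pd.DataFrame(
            {
                "effect_id": [f"e{i}" for i in range(10)],
                "study_id": [f"s{i}" for i in range(10)],
                "species": [f"sp{i}" for i in range(10)],
                "r": [0.3] * 10,
                "n": [50] * 10,
                "var_r": np.linspace(0.01, 0.05, 10),
            }
        )
        fit = fit_reml(MetaModelSpec(random_terms=("study", "observation")), records)
        assert fit.pooled_estimate == pytest.approx(0.3, abs=1e-8)
        assert all(v == pytest.approx(0.0, abs=1e-7) for v in fit.variance_components.values())

    def test_record_order_invariance(self, small_dataset):
        records, _, corr = small_dataset
        fit1 = fit_reml(MetaModelSpec(), records, corr)
        shuffled = records.sample(frac=1.0, random_state=4).reset_index(drop=True)
        fit2 = fit_reml(MetaModelSpec(), shuffled, corr)
        assert fit2.pooled_estimate == pytest.approx(fit1.pooled_estimate, abs=1e-7)
        for key in fit1.variance_components:
            assert fit2.variance_components[key] == pytest.approx(
                fit1.variance_components[key], abs=1e-6
            )

    def test_estimate_near_truth_on_synthetic_data(self, literature_like_dataset):
        records, truth, corr = literature_like_dataset
        fit = fit_reml(MetaModelSpec(), records, corr)
        config = truth.attrs["config"]
        assert fit.pooled_estimate == pytest.approx(config.mu, abs=0.15)
        assert fit.fixed_estimates.iloc[0]["lower"] < config.mu < fit.fixed_estimates.iloc[0]["upper"]


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
class TestMetaforOracle:
    def test_matches_rma_mv_on_small_dataset(self, small_dataset, tmp_path):
        """Independent oracle: metafor's rma.mv with the same phylogenetic
        correlation matrix reproduces our REML estimates."""
        records, _, corr = small_dataset
        records.to_csv(tmp_path / "records.csv", index=False)
        sub = corr.submatrix(sorted(records["species"].unique()))
        pd.DataFrame(sub.values, index=sub.labels, columns=sub.labels).to_csv(
            tmp_path / "corr.csv"
        )
        script = """
        suppressMessages(library(metafor))
        d <- read.csv("records.csv")
        C <- as.matrix(read.csv("corr.csv", row.names=1))
        colnames(C) <- rownames(C)
        d$species_phylo <- d$species
        res <- rma.mv(yi = r, V = var_r,
                      random = list(~1|species_phylo, ~1|study_id, ~1|effect_id),
                      R = list(species_phylo = C), data = d, method = "REML")
        cat(jsonlite::toJSON(list(b = as.numeric(res$b), sigma2 = res$sigma2),
                             digits = 10))
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, cwd=tmp_path,
            timeout=300,
        )
        assert out.returncode == 0, out.stderr
        oracle = json.loads(out.stdout)
        ours = fit_reml(MetaModelSpec(), records, corr)
        assert ours.pooled_estimate == pytest.approx(oracle["b"][0], abs=1e-4)
        for s_ours, s_theirs in zip(
            [ours.variance_components[t] for t in ("phylogeny", "study", "observation")],
            oracle["sigma2"],
        ):
            assert s_ours == pytest.approx(s_theirs, abs=1e-4)


class TestGibbsSampler:
    def test_seeded_runs_are_identical(self, small_dataset):
        records, _, corr = small_dataset
        spec = MetaModelSpec(seed=42, **QUICK_CHAIN)
        s1, _ = fit_mcmc(spec, records, corr)
        s2, _ = fit_mcmc(spec, records, corr)
        pd.testing.assert_frame_equal(s1, s2)

    def test_sample_count_matches_spec(self, small_dataset):
        records, _, corr = small_dataset
        spec = MetaModelSpec(seed=1, **QUICK_CHAIN)
        samples, fit = fit_mcmc(spec, records, corr)
        assert len(samples) == spec.n_samples == 1000
        assert fit.diagnostics["n_samples"] == 1000

    def test_posterior_tracks_reml_on_small_data(self, small_dataset):
        records, _, corr = small_dataset
        reml = fit_reml(MetaModelSpec(), records, corr)
        spec = MetaModelSpec(seed=7, iterations=30_000, burn_in=5_000, thinning=5)
        _, mcmc = fit_mcmc(spec, records, corr)
        assert mcmc.pooled_estimate == pytest.approx(reml.pooled_estimate, abs=0.06)

    def test_prior_sensitivity_is_mild_on_well_identified_data(self, literature_like_dataset):
        """An alternative uninformative variance prior shifts the posterior
        mean of the pooled effect negligibly (the posterior mean is used for
        the comparison because the KDE mode has its own Monte-Carlo wobble)."""
        records, _, corr = literature_like_dataset
        base = MetaModelSpec(seed=9, iterations=30_000, burn_in=5_000, thinning=5)
        alt = MetaModelSpec(seed=9, prior_V=0.5, prior_nu=0.02,
                            iterations=30_000, burn_in=5_000, thinning=5)
        s_base, _ = fit_mcmc(base, records, corr)
        s_alt, _ = fit_mcmc(alt, records, corr)
        shift = abs(s_base["intercept"].mean() - s_alt["intercept"].mean())
        assert shift < 0.01

    def test_divergence_guard_and_chain_validation(self, toy_records):
        with pytest.raises(ValueError, match="iterations"):
            MetaModelSpec(iterations=100, burn_in=200)
        with pytest.raises(ValueError, match="thinning"):
            MetaModelSpec(thinning=0)


class TestPosteriorSummaries:
    def test_constant_samples(self):
        assert posterior_mode_hpd(np.full(200, 3.14)) == (3.14, 3.14, 3.14)

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError, match="100"):
            posterior_mode_hpd(np.arange(50))

    def test_standard_normal_mode_and_hpd(self):
        rng = np.random.default_rng(12345)
        draws = rng.standard_normal(1_000_000)
        mode, lo, hi = posterior_mode_hpd(draws)
        assert mode == pytest.approx(0.0, abs=0.02)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_exponential_hpd_starts_at_zero_and_beats_equal_tails(self):
        rng = np.random.default_rng(999)
        draws = rng.exponential(1.0, 200_000)
        mode, lo, hi = posterior_mode_hpd(draws)
        assert lo == pytest.approx(0.0, abs=0.01)
        assert hi == pytest.approx(2.996, abs=0.05)  # -log(0.05)
        eq_lo, eq_hi = np.quantile(draws, [0.025, 0.975])
        assert hi - lo < eq_hi - eq_lo

    def test_mcmc_p_value_tail_doubling(self):
        s = np.concatenate([np.full(90, 1.0), np.full(10, -1.0)])
        assert mcmc_p_value(s) == pytest.approx(0.2)
        assert mcmc_p_value(np.full(100, 2.0)) == pytest.approx(0.01)


class TestHeterogeneity:
    def test_equal_components_equal_quarters(self):
        shares = heterogeneity_decomposition(
            {"phylogeny": 1.0, "study": 1.0, "observation": 1.0}, [1.0] * 10
        )
        assert all(v == pytest.approx(0.25) for v in shares.values())

    def test_zero_components(self):
        shares = heterogeneity_decomposition(
            {"phylogeny": 0.0, "study": 0.0, "observation": 0.0}, [0.5] * 5
        )
        assert all(v == 0.0 for v in shares.values())

    def test_typical_variance_equals_v_for_equal_weights(self):
        assert typical_sampling_variance([0.37] * 12) == pytest.approx(0.37)

    def test_mean_method_option(self):
        assert typical_sampling_variance([0.1, 0.3], method="mean") == pytest.approx(0.2)

    def test_scale_invariance_of_shares(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0.01, 0.1, 20)
        comps = {"phylogeny": 0.05, "study": 0.02, "observation": 0.01}
        base = heterogeneity_decomposition(comps, v)
        scaled = heterogeneity_decomposition(
            {k: 10 * s for k, s in comps.items()}, 10 * v
        )
        for key in base:
            assert scaled[key] == pytest.approx(base[key])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            heterogeneity_decomposition({}, [0.1])


class TestMarginalR2:
    def test_hand_ratio(self, small_dataset):
        records, _, corr = small_dataset
        fit = fit_reml(
            MetaModelSpec(fixed_terms=("ms_method",)), records, corr
        )
        X, _ = build_design(records, ("ms_method",))
        beta = fit.fixed_estimates["estimate"].to_numpy()
        expected = np.var(X @ beta, ddof=1) / (
            np.var(X @ beta, ddof=1) + sum(fit.variance_components.values())
        )
        assert marginal_r2(fit, X) == pytest.approx(expected)
        assert fit.marginal_R2[0] == pytest.approx(expected)

    def test_intercept_only_errors(self, small_dataset):
        records, _, corr = small_dataset
        fit = fit_reml(MetaModelSpec(), records, corr)
        X, _ = build_design(records, ())
        with pytest.raises(ValueError, match="moderator"):
            marginal_r2(fit, X)

    def test_fully_explanatory_moderator(self):
        """A binary moderator that alone generates the spread drives R2 -> 1."""
        rng = np.random.default_rng(8)
        group = np.repeat(["copulatory", "genetic"], 30)
        r = np.where(group == "genetic", 0.6, 0.1) + rng.normal(0, 0.01, 60)
        records = pd.DataFrame(
            {
                "effect_id": [f"e{i}" for i in range(60)],
                "study_id": [f"s{i}" for i in range(60)],
                "species": [f"sp{i}" for i in range(60)],
                "r": r,
                "n": [400] * 60,
                "var_r": [0.0025] * 60,
                "ms_method": group,
            }
        )
        fit = fit_reml(
            MetaModelSpec(fixed_terms=("ms_method",), random_terms=("study", "observation")),
            records,
        )
        assert fit.marginal_R2[0] > 0.9


class TestDesign:
    def test_moderator_coding_against_baselines(self, small_dataset):
        records, _, _ = small_dataset
        X, names = build_design(records, ("ms_method", "year", "polyandry"))
        assert names[0] == "intercept"
        assert "ms_method[genetic]" in names
        year_col = X[:, names.index("year_centered")]
        assert year_col.mean() == pytest.approx(0.0)

    def test_singular_design_rejected(self, small_dataset):
        records, _, _ = small_dataset
        records = records.copy()
        records["dup"] = records["polyandry"]
        with pytest.raises(ValueError, match="singular"):
            build_design(records, ("polyandry", "dup"))
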