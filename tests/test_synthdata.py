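"""Generators: range contracts, determinism, and agreement with closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

import adipoloc as al
from adipoloc import synthdata


def region_config(**kw):
    base = dict(n_variants=10, n_individuals=500, ld_rho=0.5, seed=1)
    base.update(kw)
    return al.RegionSimConfig(**base)


class TestSimulateGenotypes:
    def test_dosages_in_range_and_positions_increasing(self):
        panel = al.simulate_genotypes(region_config(seed=99))
        assert np.isin(panel.dosages, (0, 1, 2)).all()
        assert (np.diff(panel.positions) > 0).all()

    def test_deterministic_given_seed(self):
        a = al.simulate_genotypes(region_config(seed=7))
        b = al.simulate_genotypes(region_config(seed=7))
        c = al.simulate_genotypes(region_config(seed=8))
        assert (a.dosages == b.dosages).all()
        assert not (a.dosages == c.dosages).all()

    def test_independence_when_rho_zero(self):
        panel = al.simulate_genotypes(
            region_config(n_variants=8, n_individuals=20_000, ld_rho=0.0, seed=3)
        )
        r = panel.ld_matrix()
        off = r[~np.eye(8, dtype=bool)]
        assert np.nanmean(np.abs(off)) < 0.02

    def test_adjacent_correlation_matches_thresholded_gaussian(self):
        """Dosage correlation of neighbours equals the latent AR(1) correlation
        pushed through the allele-frequency thresholds (tetrachoric identity),
        checked against the closed-form bivariate-normal orthant probability."""
        rho = 0.95
        panel = al.simulate_genotypes(
            region_config(n_variants=4, n_individuals=100_000, ld_rho=rho, seed=11)
        )
        r_emp = panel.ld_matrix()
        for j in range(3):
            f1, f2 = panel.allele_freqs[j], panel.allele_freqs[j + 1]
            t1, t2 = norm.ppf(f1), norm.ppf(f2)
            p11 = multivariate_normal.cdf([t1, t2], mean=[0, 0], cov=[[1, rho], [rho, 1]])
            expected = (p11 - f1 * f2) / np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))
            assert r_emp[j, j + 1] == pytest.approx(expected, abs=0.02)

    def test_empirical_frequency_within_configured_range(self):
        panel = al.simulate_genotypes(
            region_config(n_variants=12, n_individuals=50_000, maf_range=(0.1, 0.4), seed=5)
        )
        emp = panel.dosages.mean(axis=0) / 2
        assert np.all(emp > 0.08) and np.all(emp < 0.43)

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            region_config(n_variants=0)
        with pytest.raises(ValueError):
            region_config(ld_rho=1.0)
        with pytest.raises(ValueError):
            region_config(maf_range=(0.4, 0.1))
        with pytest.raises(ValueError):
            region_config(causal_indices=(10,), effect_sizes=(0.1,))


class TestSimulateTrait:
    def test_null_effects_give_centred_slopes(self):
        config = region_config(n_variants=10, n_individuals=5000, seed=21)
        panel = al.simulate_genotypes(config)
        trait = al.simulate_trait(panel, config)
        stats = al.marginal_summary_stats(panel, trait)
        assert np.abs(stats["beta"]).max() < 0.1
        assert abs(stats["beta"].mean()) < 0.03

    def test_ols_sampling_theory_at_causal_variant(self):
        """Replicated estimates at the causal variant are centred on the true
        effect with standard error ~ sigma/(sd(dosage)*sqrt(n))."""
        b, sigma, n = 0.3, 1.0, 2000
        betas, ses = [], []
        for rep in range(40):
            config = region_config(
                n_variants=5,
                n_individuals=n,
                ld_rho=0.3,
                causal_indices=(2,),
                effect_sizes=(b,),
                noise_sd=sigma,
                seed=300 + rep,
            )
            panel = al.simulate_genotypes(config)
            trait = al.simulate_trait(panel, config)
            stats = al.marginal_summary_stats(panel, trait)
            row = stats.iloc[2]
            betas.append(row["beta"])
            ses.append(row["se"])
            expected_se = sigma / (panel.dosages[:, 2].std() * np.sqrt(n))
            assert row["se"] == pytest.approx(expected_se, rel=0.10)
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert np.mean(betas) == pytest.approx(b, abs=3 * mc_se + 0.02)

    def test_doubling_n_shrinks_se_by_sqrt2(self):
        medians = []
        for n in (1000, 2000):
            ses = []
            for rep in range(30):
                config = region_config(n_variants=4, n_individuals=n, seed=700 + rep)
                panel = al.simulate_genotypes(config)
                trait = al.simulate_trait(panel, config)
                ses.append(al.marginal_summary_stats(panel, trait)["se"].median())
            medians.append(np.median(ses))
        assert medians[0] / medians[1] == pytest.approx(np.sqrt(2), rel=0.1)


def toy_panel(dosages, positions=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    m = dosages.shape[1]
    return al.GenotypePanel(
        dosages=dosages,
        positions=np.asarray(positions if positions is not None else 100 * np.arange(1, m + 1)),
        variant_ids=[f"v{j}" for j in range(m)],
        effect_alleles=["A"] * m,
        other_alleles=["G"] * m,
        allele_freqs=dosages.mean(axis=0) / 2,
    )


class TestMarginalSummaryStats:
    def test_perfect_fit_gives_unit_beta_zero_se(self):
        panel = toy_panel([[0], [1], [2], [1], [0], [2]])
        stats = al.marginal_summary_stats(panel, panel.dosages[:, 0].astype(float))
        assert stats["beta"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert stats["se"].iloc[0] == pytest.approx(0.0, abs=1e-7)

    def test_matches_hand_computed_ols_on_four_rows(self):
        # g1=[0,1,2,1], g2=[1,0,1,2], y=[1,2,3,4]:
        # beta1 = Sxy/Sxx = 2/2 = 1; RSS = 3 -> se = sqrt(3/2/2)
        # beta2 = 2/2 = 1; same RSS by symmetry of this table
        panel = toy_panel([[0, 1], [1, 0], [2, 1], [1, 2]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        stats = al.marginal_summary_stats(panel, y)
        assert stats["beta"].tolist() == pytest.approx([1.0, 1.0], abs=1e-12)
        assert stats["se"].iloc[0] == pytest.approx(np.sqrt(3.0 / 2.0 / 2.0), abs=1e-12)

    def test_agrees_with_lstsq_oracle_to_ten_digits(self):
        rng = np.random.default_rng(17)
        dosages = rng.integers(0, 3, size=(50, 10))
        panel = toy_panel(dosages)
        y = rng.normal(size=50)
        stats = al.marginal_summary_stats(panel, y)
        for j in range(10):
            x = np.column_stack([np.ones(50), dosages[:, j].astype(float)])
            coef, rss, *_ = np.linalg.lstsq(x, y, rcond=None)
            se = np.sqrt(rss[0] / 48 * np.linalg.inv(x.T @ x)[1, 1])  # sigma2 = RSS/(n-2)
            assert stats["beta"].iloc[j] == pytest.approx(coef[1], rel=1e-10)
            assert stats["se"].iloc[j] == pytest.approx(se, rel=1e-10)

    def test_permutation_of_individuals_leaves_betas_unchanged(self):
        rng = np.random.default_rng(23)
        dosages = rng.integers(0, 3, size=(40, 6))
        y = rng.normal(size=40)
        perm = rng.permutation(40)
        a = al.marginal_summary_stats(toy_panel(dosages), y)
        b = al.marginal_summary_stats(toy_panel(dosages[perm]), y[perm])
        np.testing.assert_allclose(a["beta"], b["beta"], rtol=1e-12)

    def test_monomorphic_excluded_with_warning(self):
        panel = toy_panel([[0, 1], [0, 0], [0, 2], [0, 1]])
        with pytest.warns(UserWarning, match="monomorphic"):
            stats = al.marginal_summary_stats(panel, np.array([1.0, 2.0, 3.0, 4.0]))
        assert stats["variant_id"].tolist() == ["v1"]

    def test_all_monomorphic_is_an_error(self):
        panel = toy_panel([[1, 2], [1, 2], [1, 2]])
        with pytest.raises(ValueError, match="monomorphic"):
            al.marginal_summary_stats(panel, np.array([1.0, 2.0, 3.0]))


class TestSimulateColocPair:
    def test_identical_seed_bitwise_identical(self):
        config = region_config(causal_indices=(2, 7), effect_sizes=(0.4, 0.4), seed=5)
        a = al.simulate_coloc_pair("H4", config)
        b = al.simulate_coloc_pair("H4", config)
        pd.testing.assert_frame_equal(a.stats_a, b.stats_a)
        pd.testing.assert_frame_equal(a.stats_b, b.stats_b)

    def test_h3_requires_two_distinct_causal_variants(self):
        with pytest.raises(ValueError, match="H3"):
            al.simulate_coloc_pair(
                "H3", region_config(causal_indices=(2,), effect_sizes=(0.4,))
            )

    def test_scenario_truth_labels(self):
        config = region_config(causal_indices=(2, 7), effect_sizes=(0.4, 0.4), seed=5)
        pair = al.simulate_coloc_pair("H1", config)
        assert pair.causal_a == (2,) and pair.causal_b == ()
        pair = al.simulate_coloc_pair("H3", config)
        assert pair.causal_a == (2,) and pair.causal_b == (7,)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            al.simulate_coloc_pair("H9", region_config())


class TestSimulateAEI:
    def test_identity_calibration_noise_free(self):
        config = al.AEISimConfig(
            true_ea_percent={("s1", "tissue", "gDNA"): 50.0}, seed=1
        )
        sim = al.simulate_aei(config)
        assert (sim.standard_curve["observed_pct"] == sim.standard_curve["true_pct"]).all()
        assert sim.samples["observed_pct"].iloc[0] == 50.0

    def test_affine_bias_applied_exactly(self):
        config = al.AEISimConfig(
            calibration_slope=0.8, calibration_intercept=10.0, mix_levels=(30.0,), seed=1
        )
        sim = al.simulate_aei(config)
        assert (sim.standard_curve["observed_pct"] == 34.0).all()

    def test_replicate_spread_matches_noise_sd(self):
        config = al.AEISimConfig(noise_sd=2.0, n_replicate_pairs=2000, mix_levels=(50.0,), seed=9)
        sim = al.simulate_aei(config)
        assert sim.standard_curve["observed_pct"].std(ddof=1) == pytest.approx(2.0, rel=0.05)

    def test_truncation_counted_and_warned(self):
        config = al.AEISimConfig(
            calibration_slope=1.0,
            calibration_intercept=40.0,
            mix_levels=(70.0,),
            seed=1,
        )
        with pytest.warns(UserWarning, match="truncated"):
            sim = al.simulate_aei(config)
        assert sim.n_truncated == config.n_replicate_pairs
        assert (sim.standard_curve["observed_pct"] == 100.0).all()


class TestSimulateAdipocyteAreas:
    def test_degenerate_spread_collapses_to_median(self):
        config = al.AdipocyteSimConfig(groups={"abdo": (8.0, 1e-9)}, n_cells=100, seed=2)
        areas = al.simulate_adipocyte_areas(config)
        np.testing.assert_allclose(areas["area_um2"], np.exp(8.0), rtol=1e-6)

    def test_sample_median_matches_lognormal_identity(self):
        config = al.AdipocyteSimConfig(groups={"g": (8.5, 0.6)}, n_cells=100_000, seed=3)
        areas = al.simulate_adipocyte_areas(config)
        assert np.median(areas["area_um2"]) == pytest.approx(np.exp(8.5), rel=0.02)

    def test_cell_count_honoured_exactly(self):
        config = al.AdipocyteSimConfig(groups={"a": (8.0, 0.5), "b": (8.2, 0.5)}, n_cells=317, seed=4)
        areas = al.simulate_adipocyte_areas(config)
        assert areas.groupby("biopsy_id").size().tolist() == [317, 317]


class TestSimulateGrowth:
    def test_noise_free_count_doubles_over_one_doubling_time(self):
        config = al.GrowthSimConfig(true_doubling_time=1.5, timepoints=(0.0, 1.5), seed=1)
        series = al.simulate_growth(config)
        assert series.counts[1] / series.counts[0] == pytest.approx(2.0, rel=1e-12)

    def test_doubling_time_inverts_noise_free_series(self):
        config = al.GrowthSimConfig(
            true_doubling_time=2.7, timepoints=(0.0, 1.0, 3.0, 4.0, 8.0), seed=1
        )
        series = al.simulate_growth(config)
        for i in range(len(series.timepoints) - 1):
            for j in range(i + 1, len(series.timepoints)):
                td = al.doubling_time(
                    series.timepoints[i], series.counts[i],
                    series.timepoints[j], series.counts[j],
                )
                assert td == pytest.approx(2.7, rel=1e-12)

    def test_noisy_recovery_within_ten_percent_in_95_percent_of_replicates(self):
        hits = 0
        for rep in range(1000):
            config = al.GrowthSimConfig(
                true_doubling_time=2.0,
                timepoints=(0.0, 2.0, 4.0, 6.0),
                count_noise_cv=0.05,
                seed=rep,
            )
            series = al.simulate_growth(config)
            td = al.fit_doubling_time(series)
            hits += abs(td - 2.0) / 2.0 < 0.10
        assert hits >= 950


class TestSimulateCohort:
    def test_menopause_coding_follows_age_cutoff(self):
        cohort = al.simulate_cohort(al.CohortSimConfig(n=500, seed=6)).table
        women_post = cohort[(cohort.sex == 1) & (cohort.age >= 51)]
        women_pre = cohort[(cohort.sex == 1) & (cohort.age < 51)]
        men = cohort[cohort.sex == 0]
        assert (women_post.menopause == 1).all()
        assert (women_pre.menopause == 0).all()
        assert (men.menopause == 0).all()

    def test_dosages_and_trait_valid(self):
        cohort = al.simulate_cohort(al.CohortSimConfig(n=500, seed=6)).table
        assert cohort.dosage.isin([0, 1, 2]).all()
        assert (cohort.trait > 0).all()
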