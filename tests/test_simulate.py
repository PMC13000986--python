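"""The synthetic-data generator: determinism, namespacing, the generating
model's variance structure, and feasibility checks."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from seqherb.dataset_io import CATEGORY_OUTCOMES
from seqherb.effect_sizes import compute_effect_sizes
from seqherb.simulate import (
    ConfigError,
    SimulationConfig,
    simulate_dataset,
    simulate_tree,
)


class TestDeterminism:
    def test_same_config_and_seed_reproduce_bitwise(self):
        cfg = dataclasses.replace(SimulationConfig(seed=42), n_studies=15)
        ds1, t1 = simulate_dataset(cfg)
        ds2, t2 = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(ds1.frame, ds2.frame)
        assert t1.theta == t2.theta

    def test_different_seeds_differ(self):
        cfg = dataclasses.replace(SimulationConfig(seed=1), n_studies=10)
        ds1, _ = simulate_dataset(cfg)
        ds2, _ = simulate_dataset(dataclasses.replace(cfg, seed=2))
        assert not ds1.frame["mean_treatment"].equals(ds2.frame["mean_treatment"])

    def test_adding_studies_does_not_perturb_existing_ones(self):
        small = dataclasses.replace(SimulationConfig(seed=9), n_studies=10)
        big = dataclasses.replace(small, n_studies=20)
        ds_small, _ = simulate_dataset(small)
        ds_big, _ = simulate_dataset(big)
        first = ds_big.frame[ds_big.frame["study_id"].isin(ds_small.frame["study_id"])]
        pd.testing.assert_frame_equal(
            ds_small.frame.reset_index(drop=True), first.reset_index(drop=True)
        )


class TestStructure:
    def test_records_respect_category_outcome_pairing(self, small_sim):
        ds, _ = small_sim
        for cat, outcomes in CATEGORY_OUTCOMES.items():
            sub = ds.frame[ds.frame["response_category"] == cat]
            assert set(sub["outcome"]) <= set(outcomes)

    def test_same_species_flag_consistent(self, small_sim):
        ds, _ = small_sim
        expected = ds.frame["inducer_species"] == ds.frame["subsequent_species"]
        assert (ds.frame["same_species"] == expected).all()

    def test_binary_records_have_counts_not_means(self, small_sim):
        ds, _ = small_sim
        binary = ds.frame["events_treatment"].notna()
        assert ds.frame.loc[binary, "mean_treatment"].isna().all()
        assert (
            ds.frame.loc[binary, "events_treatment"]
            <= ds.frame.loc[binary, "n_treatment"]
        ).all()

    def test_no_heterogeneity_huge_groups_concentrates_g_at_theta(self):
        cfg = dataclasses.replace(
            SimulationConfig.recovery(seed=5),
            n_studies=60,
            sigma2_study=0.0,
            sigma2_treatment=0.0,
            group_size_range=(4000, 4000),
        )
        ds, truth = simulate_dataset(cfg)
        es = compute_effect_sizes(ds.frame)
        theta = np.array([truth.theta[r] for r in es["record_id"]])
        assert np.allclose(theta, -0.33, atol=1e-12)
        assert np.std(es["yi"] - theta) < 0.05
        assert abs(np.mean(es["yi"] - theta)) < 0.01

    def test_variance_decomposition_matches_configured_components(self):
        cfg = dataclasses.replace(
            SimulationConfig.recovery(seed=17),
            n_studies=500,
            treatments_per_study=(2, 4),
            records_per_treatment=(1, 2),
        )
        ds, truth = simulate_dataset(cfg)
        u_study = np.array(
            [u for (_, cat), u in truth.u_study.items() if cat == "herbivore_performance"]
        )
        u_trt = np.array(
            [u for (_, cat), u in truth.u_treatment.items() if cat == "herbivore_performance"]
        )
        # Monte-Carlo error at 500 studies ~ sqrt(2/500)*sigma2 ~ 0.013
        assert np.var(u_study) == pytest.approx(0.2, abs=0.04)
        assert np.var(u_trt) == pytest.approx(0.1, abs=0.02)
        assert abs(np.mean(u_study)) < 0.06

    def test_small_study_bias_injection_correlates_theta_with_se(self):
        cfg = dataclasses.replace(
            SimulationConfig.recovery(seed=23), n_studies=300, small_study_bias=1.5
        )
        ds, truth = simulate_dataset(cfg)
        es = compute_effect_sizes(ds.frame)
        theta = np.array([truth.theta[r] for r in es["record_id"]])
        se = np.sqrt(es["vi"].to_numpy())
        assert np.corrcoef(theta, se)[0, 1] > 0.2


class TestFeasibility:
    def test_invalid_configs_rejected_before_sampling(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_studies=0).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(binary_fraction=1.5).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(sd_scale=0.0).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(control_rate_range=(0.0, 0.9)).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(sigma2_taxon=0.1).validate()  # needs a tree
        with pytest.raises(ConfigError):
            dataclasses.replace(
                SimulationConfig(), treatments_per_study=(3, 1)
            ).validate()


class TestTree:
    def test_two_taxa_tree_is_a_cherry_with_bounded_correlation(self):
        from seqherb.phylo import correlation_from_tree

        tree = simulate_tree(["Aus aus", "Bus bus"], seed=1)
        corr = correlation_from_tree(tree)
        assert corr.matrix.shape == (2, 2)
        assert 0 <= corr.matrix[0, 1] < 1

    def test_simulated_trees_are_ultrametric(self):
        tree = simulate_tree([f"Sp {i}" for i in range(10)], seed=4)
        depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
        assert np.ptp(depths) < 1e-9

    def test_correlated_taxon_effects_follow_the_tree(self):
        """Taxon deviates drawn through the tree correlation reproduce that
        correlation empirically across replicate datasets."""
        from seqherb.phylo import correlation_from_tree

        taxa = ["Brassica oleracea", "Brassica nigra", "Solanum lycopersicum"]
        tree = simulate_tree(taxa, seed=2)
        corr = correlation_from_tree(tree)
        draws = []
        for seed in range(200):
            cfg = dataclasses.replace(
                SimulationConfig.recovery(seed=seed),
                n_studies=2,
                sigma2_taxon=1.0,
                taxon_corr=corr,
            )
            _, truth = simulate_dataset(cfg)
            draws.append([truth.u_taxon[t] for t in corr.taxa])
        emp = np.corrcoef(np.array(draws).T)
        assert np.allclose(emp, corr.matrix, atol=0.2)
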