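"""REML fitter correctness: closed forms, grid-search oracle agreement,
invariances, Wald inference, heterogeneity and prediction intervals, and an
external cross-check against R metafor's rma.mv on a small fixture."""

import dataclasses
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from seqherb.effect_sizes import compute_effect_sizes
from seqherb.reml import (
    ModelError,
    ModelSpec,
    RandomSpec,
    fit_multilevel,
    heterogeneity_i2,
    heterogeneity_i2_value,
    omnibus_moderator_test,
    predict_mean_and_pi,
)
from seqherb.simulate import SimulationConfig, simulate_dataset

from oracles import grid_search_reml, reml_neg2ll_dense


def _frame(study, treatment=None, record=None, **extra):
    k = len(study)
    data = {
        "record_id": record if record is not None else [f"r{i}" for i in range(k)],
        "study_id": [str(s) for s in study],
        "treatment_id": treatment if treatment is not None else ["t0"] * k,
    }
    data.update(extra)
    return pd.DataFrame(data)


def _random_instance(rng, max_k=12):
    """A small nested dataset with 2 variance components.

    Every study carries two treatments and some treatments carry replicate
    records, so the study and treatment groupings never coincide and both
    components are identified (no likelihood ridge).
    """
    n_stud = int(rng.integers(2, 4))
    rows, y, v = [], [], []
    for s in range(n_stud):
        for t in range(2):
            n_rec = int(rng.integers(1, 3))
            for r in range(n_rec):
                rows.append((f"s{s}", f"s{s}_t{t}"))
                y.append(rng.normal(0, 0.8))
                v.append(rng.uniform(0.05, 0.3))
    rows, y, v = rows[:max_k], y[:max_k], v[:max_k]
    frame = _frame([a for a, _ in rows], [b for _, b in rows])
    return np.array(y), np.array(v), frame


class TestClosedForms:
    def test_single_record_degenerates_to_the_observation(self):
        frame = _frame(["s1"])
        fit = fit_multilevel([0.4], [0.09], ModelSpec.three_level(), frame)
        assert fit.estimate == pytest.approx(0.4, abs=1e-12)
        assert fit.se[0] == pytest.approx(0.3, abs=1e-12)

    def test_balanced_equal_variance_closed_form(self):
        # one random level per observation, v constant: tau2 = s_y^2 - v
        frame = _frame(["a", "b", "c"])
        spec = ModelSpec(random=(RandomSpec("study_id"),))
        fit = fit_multilevel([0.5, 0.0, -0.5], [0.1, 0.1, 0.1], spec, frame)
        assert fit.estimate == pytest.approx(0.0, abs=1e-8)
        assert fit.vc["study_id"] == pytest.approx(0.15, abs=1e-6)
        assert fit.se[0] == pytest.approx(np.sqrt(0.25 / 3), abs=1e-6)

    def test_pinned_zero_components_give_exact_gls(self, rng):
        y, v, frame = _random_instance(rng)
        fit = fit_multilevel(y, v, ModelSpec(random=()), frame)
        w = 1 / v
        gls = np.sum(w * y) / np.sum(w)
        assert fit.estimate == pytest.approx(gls, abs=1e-12)
        assert fit.se[0] == pytest.approx(np.sqrt(1 / np.sum(w)), abs=1e-12)

    def test_rank_deficient_design_names_aliased_level(self):
        frame = _frame(["s1", "s1", "s2", "s2"], mod=["x", "x", "x", "x"])
        with pytest.raises(ModelError, match="single level"):
            fit_multilevel([0.1] * 4, [0.1] * 4, ModelSpec(fixed="mod"), frame)


class TestGridOracle:
    def test_fitter_matches_grid_search_on_random_small_instances(self, rng):
        spec = ModelSpec.three_level()
        for _ in range(25):
            y, v, frame = _random_instance(rng)
            fit = fit_multilevel(y, v, spec, frame)
            groupings = [
                frame["study_id"].to_numpy(),
                (frame["study_id"] + "/" + frame["treatment_id"]).to_numpy(),
            ]
            X = np.ones((len(y), 1))
            oracle = grid_search_reml(y, v, X, groupings)
            ours = np.array([fit.vc["study_id"], fit.vc["treatment_key"]])
            assert np.allclose(ours, oracle, atol=1e-4), (ours, oracle)
            # and the criterion value itself cannot beat the oracle's
            assert reml_neg2ll_dense(ours, y, v, X, groupings) <= (
                reml_neg2ll_dense(oracle, y, v, X, groupings) + 1e-6
            )


class TestInvariances:
    def test_record_order_and_label_invariance(self, rng):
        y, v, frame = _random_instance(rng)
        spec = ModelSpec.three_level()
        fit = fit_multilevel(y, v, spec, frame)
        perm = rng.permutation(len(y))
        shuffled = frame.iloc[perm].reset_index(drop=True)
        relabeled = shuffled.assign(
            study_id="study " + shuffled["study_id"],
            treatment_id=shuffled["treatment_id"] + " xx",
        )
        fit2 = fit_multilevel(y[perm], v[perm], spec, relabeled)
        assert fit2.estimate == pytest.approx(fit.estimate, abs=2e-5)
        assert fit2.vc["study_id"] == pytest.approx(fit.vc["study_id"], abs=2e-5)
        assert fit2.vc["treatment_key"] == pytest.approx(
            fit.vc["treatment_key"], abs=2e-5
        )

    def test_location_shift_moves_intercept_only(self, rng):
        y, v, frame = _random_instance(rng)
        spec = ModelSpec.three_level()
        fit = fit_multilevel(y, v, spec, frame)
        fit2 = fit_multilevel(y + 1.7, v, spec, frame)
        assert fit2.estimate == pytest.approx(fit.estimate + 1.7, abs=2e-5)
        assert fit2.vc["study_id"] == pytest.approx(fit.vc["study_id"], abs=2e-5)
        assert fit2.vc["treatment_key"] == pytest.approx(
            fit.vc["treatment_key"], abs=2e-5
        )


class TestInference:
    def test_duplicated_groups_give_null_omnibus(self):
        # moderator with two identical groups: QM ~ 0, p ~ 1
        y = [0.3, -0.2, 0.5, 0.3, -0.2, 0.5]
        v = [0.1] * 6
        frame = _frame(
            ["s1", "s2", "s3", "s4", "s5", "s6"],
            mod=["a", "a", "a", "b", "b", "b"],
        )
        fit = fit_multilevel(y, v, ModelSpec(fixed="mod", random=(RandomSpec("study_id"),)), frame)
        assert fit.qm == pytest.approx(0.0, abs=1e-8)
        assert fit.qm_p == pytest.approx(1.0, abs=1e-6)

    def test_single_coefficient_qm_is_z_squared(self, small_es):
        sub = small_es[
            (small_es["metric"] == "hedges_g")
            & (small_es["response_category"] == "herbivore_performance")
        ]
        fit = fit_multilevel(
            sub["yi"].to_numpy(), sub["vi"].to_numpy(),
            ModelSpec.three_level(fixed="setting"), sub,
        )
        z2 = (fit.beta[1] / fit.se[1]) ** 2
        qm, df, p = omnibus_moderator_test(fit)
        assert df == 1
        assert qm == pytest.approx(z2, rel=1e-10)

    def test_categorical_moderator_df_is_levels_minus_one(self, small_es):
        sub = small_es[
            (small_es["metric"] == "hedges_g")
            & (small_es["response_category"] == "herbivore_performance")
        ]
        fit = fit_multilevel(
            sub["yi"].to_numpy(), sub["vi"].to_numpy(),
            ModelSpec.three_level(fixed="outcome"), sub,
        )
        assert fit.qm_df == sub["outcome"].nunique() - 1

    def test_ci_is_inside_pi_and_contains_beta(self, small_es):
        sub = small_es[
            (small_es["metric"] == "hedges_g")
            & (small_es["response_category"] == "herbivore_performance")
        ]
        fit = fit_multilevel(
            sub["yi"].to_numpy(), sub["vi"].to_numpy(), ModelSpec.three_level(), sub
        )
        ci, pi = predict_mean_and_pi(fit)
        assert pi[0] <= ci[0] <= fit.estimate <= ci[1] <= pi[1]

    def test_pi_equals_ci_without_heterogeneity(self):
        frame = _frame(["s1", "s2", "s3"])
        fit = fit_multilevel([0.1, 0.1, 0.1], [0.2] * 3, ModelSpec(random=(RandomSpec("study_id"),)), frame)
        ci, pi = predict_mean_and_pi(fit)
        assert fit.vc["study_id"] == pytest.approx(0.0, abs=1e-8)
        assert pi == pytest.approx(ci, abs=1e-7)

    def test_pi_hand_computed_width(self):
        # se = 0.1, total sigma2 = 0.03: half-width = z * sqrt(0.04) ~ 0.392
        from seqherb.reml import Z975

        half = Z975 * np.sqrt(0.1**2 + 0.03)
        assert half == pytest.approx(0.392, abs=2e-3)


class TestHeterogeneity:
    def test_zero_components_give_zero_i2(self):
        assert heterogeneity_i2_value(0.0, np.array([0.1, 0.2])) == 0.0

    def test_hand_computed_i2(self):
        # sum sigma2 = 0.2, v typical = 0.05 -> 80%
        v = np.array([0.05, 0.05, 0.05])
        assert heterogeneity_i2_value(0.2, v) == pytest.approx(80.0, abs=1e-10)

    def test_i2_within_bounds_on_simulated_fit(self, small_es):
        sub = small_es[small_es["metric"] == "hedges_g"]
        fit = fit_multilevel(
            sub["yi"].to_numpy(), sub["vi"].to_numpy(), ModelSpec.three_level(), sub
        )
        i2 = heterogeneity_i2(fit, sub["vi"].to_numpy())
        assert 0 <= i2 <= 100
        assert fit.i2 == pytest.approx(i2)


class TestPhyloTerm:
    def test_identity_correlation_matches_iid_taxon_term(self, rng):
        y, v, frame = _random_instance(rng)
        taxa = ["Aus bus", "Cus dus", "Eus fus"]
        frame = frame.assign(
            plant_species=[taxa[i % 3] for i in range(len(frame))]
        )
        from seqherb.phylo import PhyloCorrelation

        ident = PhyloCorrelation(taxa, np.eye(3))
        spec_corr = ModelSpec.three_level().with_phylo("plant_species", ident)
        spec_iid = ModelSpec(
            random=ModelSpec.three_level().random + (RandomSpec("plant_species"),)
        )
        f1 = fit_multilevel(y, v, spec_corr, frame)
        f2 = fit_multilevel(y, v, spec_iid, frame)
        assert f1.estimate == pytest.approx(f2.estimate, abs=1e-6)
        assert f1.vc["plant_species"] == pytest.approx(
            f2.vc["plant_species"], abs=1e-5
        )

    def test_missing_taxon_in_correlation_raises(self, rng):
        y, v, frame = _random_instance(rng)
        frame = frame.assign(plant_species="Unknown species")
        from seqherb.phylo import PhyloCorrelation

        corr = PhyloCorrelation(["Aus bus"], np.eye(1))
        with pytest.raises(ModelError, match="lacks taxa"):
            fit_multilevel(y, v, ModelSpec.three_level().with_phylo("plant_species", corr), frame)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_agrees_with_metafor_rma_mv(tmp_path):
    """External oracle: metafor's rma.mv on a 12-study nested fixture."""
    cfg = dataclasses.replace(SimulationConfig.recovery(seed=7), n_studies=12)
    ds, _ = simulate_dataset(cfg)
    es = compute_effect_sizes(ds.frame)
    fix = tmp_path / "fix.csv"
    es[["record_id", "study_id", "treatment_id", "yi", "vi"]].to_csv(fix, index=False)
    fit = fit_multilevel(
        es["yi"].to_numpy(), es["vi"].to_numpy(), ModelSpec.three_level(), es
    )
    script = tmp_path / "check.R"
    script.write_text(
        'suppressMessages(library(metafor))\n'
        f'd <- read.csv("{fix}")\n'
        'res <- rma.mv(yi, vi, random = ~1 | study_id/treatment_id, data = d,\n'
        '              method = "REML", control = list(rel.tol = 1e-10))\n'
        'cat(coef(res), res$se, res$sigma2, logLik(res), sep = "\\n")\n'
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    beta, se, s2_study, s2_trt, ll = map(float, out.stdout.split())
    assert fit.estimate == pytest.approx(beta, abs=1e-6)
    assert fit.se[0] == pytest.approx(se, abs=1e-6)
    assert fit.vc["study_id"] == pytest.approx(s2_study, abs=1e-5)
    assert fit.vc["treatment_key"] == pytest.approx(s2_trt, abs=1e-5)
    assert fit.reml_loglik == pytest.approx(ll, abs=1e-4)
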