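"""GLMM tests: candidate set, AICc, likelihood oracles, and ranking."""

import numpy as np
import pandas as pd
import pytest

from preyflow import models, synthetic
from preyflow.models import (
    ModelSpec,
    aicc,
    build_candidate_set,
    build_design,
    compress_unit_interval,
    fit_glmm,
    rank_models,
    simulate_family_response,
)


@pytest.fixture(scope="module")
def metadata():
    return synthetic.metadata_frame(synthetic.design_crossover(master_seed=7))


@pytest.fixture(scope="module")
def design(metadata):
    return build_design(metadata)[0]


def linear_predictor(design, metadata, coef_turb=0.0, tank_sd=0.0, intercept=0.0, rng=None):
    eta = intercept + coef_turb * design["turb"].to_numpy()
    if tank_sd > 0:
        eff = rng.normal(0, tank_sd, 4)
        eta = eta + eff[metadata["tank"].to_numpy() - 1]
    return eta


class TestAicc:
    def test_closed_form(self):
        assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)

    def test_large_n_limit_is_aic(self):
        assert aicc(0.0, 2, 10**9) == pytest.approx(4.0, abs=1e-6)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            aicc(0.0, 9, 10)


class TestCandidateSet:
    @pytest.mark.parametrize("kind", models.RESPONSE_KINDS)
    def test_eight_specs_per_response(self, kind):
        specs = build_candidate_set(kind)
        assert len(specs) == 8
        assert specs[0].name == "Null" and specs[0].fixed_terms == ()
        assert all(s.family == models.RESPONSE_FAMILY[kind] for s in specs)

    def test_interaction_spec_has_four_fixed_coefficients(self):
        (spec,) = [s for s in build_candidate_set("proportion") if s.name == "Temp×Turb"]
        assert spec.n_fixed == 4

    def test_unknown_response_rejected(self):
        with pytest.raises(ValueError):
            build_candidate_set("velocity")

    @pytest.mark.parametrize(
        "name, df", [("Null", 3), ("Turbidity", 4), ("Temp+Turb", 5), ("Temp×Turb", 6)]
    )
    @pytest.mark.parametrize("kind", models.RESPONSE_KINDS)
    def test_df_ladder_every_family(self, metadata, design, rng, kind, name, df):
        # parameter count: fixed effects + dispersion + random-intercept variance
        family = models.RESPONSE_FAMILY[kind]
        eta = linear_predictor(design, metadata, intercept={"negbinom": 2.0}.get(family, 0.0))
        y = simulate_family_response(family, eta, {"beta": 20.0, "gamma": 4.0}.get(family, 2.0), rng)
        spec = ModelSpec(name, models.MODEL_TERMS[name], family)
        fit = fit_glmm(y, metadata, spec, compute_se=False)
        assert fit.k == df


class TestFitOracles:
    def test_gaussian_no_random_effect_matches_ols(self, metadata, design, rng):
        # a single tank level pins the random intercept at (effectively) zero
        meta1 = metadata.copy()
        meta1["tank"] = 1
        eta = linear_predictor(design, metadata, coef_turb=0.8, intercept=1.0)
        y = eta + rng.normal(0, 0.4, len(eta))
        fit = fit_glmm(y, meta1, ModelSpec("Turbidity", ("turb",), "gaussian"))
        X = np.column_stack([np.ones(len(y)), design["turb"]])
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coefficients["const"] == pytest.approx(beta_ols[0], abs=1e-6)
        assert fit.coefficients["turb"] == pytest.approx(beta_ols[1], abs=1e-6)

    def test_gamma_intercept_only_equals_log_mean(self, metadata, rng):
        meta1 = metadata.copy()
        meta1["tank"] = 1
        y = rng.gamma(3.0, 2.0, len(meta1))
        fit = fit_glmm(y, meta1, ModelSpec("Null", (), "gamma"))
        assert fit.coefficients["const"] == pytest.approx(np.log(y.mean()), abs=1e-6)

    def test_gaussian_matches_mixedlm_ml(self, metadata, design, rng):
        import statsmodels.api as sm

        eta = linear_predictor(design, metadata, coef_turb=0.8, tank_sd=0.4, intercept=1.0, rng=rng)
        y = eta + rng.normal(0, 0.5, len(eta))
        fit = fit_glmm(y, metadata, ModelSpec("Turbidity", ("turb",), "gaussian"))
        df = pd.DataFrame({"y": y, "turb": design["turb"], "tank": metadata["tank"]})
        oracle = sm.MixedLM.from_formula("y ~ turb", groups="tank", data=df).fit(reml=False)
        assert fit.log_likelihood == pytest.approx(oracle.llf, abs=1e-4)
        assert fit.coefficients["const"] == pytest.approx(oracle.params["Intercept"], abs=1e-4)
        assert fit.coefficients["turb"] == pytest.approx(oracle.params["turb"], abs=1e-4)

    def test_quadrature_stable_between_15_and_25_nodes(self, metadata, design, rng):
        eta = linear_predictor(design, metadata, coef_turb=0.6, tank_sd=0.4, intercept=-1.0, rng=rng)
        y = simulate_family_response("beta", eta, 30.0, rng)
        spec = ModelSpec("Turbidity", ("turb",), "beta")
        ll15 = fit_glmm(y, metadata, spec, n_quad=15, compute_se=False).log_likelihood
        ll25 = fit_glmm(y, metadata, spec, n_quad=25, compute_se=False).log_likelihood
        assert abs(ll15 - ll25) < 1e-3

    def test_adding_terms_never_lowers_loglik(self, metadata, design, rng):
        eta = linear_predictor(design, metadata, coef_turb=-0.5, tank_sd=0.3, intercept=3.0, rng=rng)
        y = simulate_family_response("negbinom", eta, 5.0, rng)
        lls = {}
        for name in ("Null", "Turbidity", "Temp+Turb", "Temp×Turb"):
            spec = ModelSpec(name, models.MODEL_TERMS[name], "negbinom")
            lls[name] = fit_glmm(y, metadata, spec, compute_se=False).log_likelihood
        assert lls["Turbidity"] >= lls["Null"] - 1e-4
        assert lls["Temp+Turb"] >= lls["Turbidity"] - 1e-4
        assert lls["Temp×Turb"] >= lls["Temp+Turb"] - 1e-4

    def test_beta_parameter_recovery(self, metadata, design):
        # quick 3-SE sanity check; the 200-replicate 2-SE recovery study
        # runs in the acceptance suite
        truth = 0.6
        reps = 60
        rng = np.random.default_rng(99)
        estimates = []
        for _ in range(reps):
            eta = linear_predictor(design, metadata, coef_turb=truth, tank_sd=0.3, intercept=-1.5, rng=rng)
            y = simulate_family_response("beta", eta, 40.0, rng)
            fit = fit_glmm(y, metadata, ModelSpec("Turbidity", ("turb",), "beta"), compute_se=False)
            estimates.append(fit.coefficients["turb"])
        mean = np.mean(estimates)
        mc_se = np.std(estimates, ddof=1) / np.sqrt(reps)
        assert abs(mean - truth) < 3 * mc_se

    def test_response_support_validated(self, metadata):
        with pytest.raises(ValueError):
            fit_glmm(np.full(91, -1.0), metadata, ModelSpec("Null", (), "gamma"))
        with pytest.raises(ValueError):
            fit_glmm(np.full(91, 1.5), metadata, ModelSpec("Null", (), "negbinom"))

    def test_missing_responses_dropped_casewise(self, metadata, rng):
        y = rng.gamma(2.0, 1.0, 91)
        y[:10] = np.nan
        fit = fit_glmm(y, metadata, ModelSpec("Null", (), "gamma"), compute_se=False)
        assert fit.n == 81


class TestCompression:
    def test_interior_untouched(self):
        y = np.array([0.2, 0.5, 0.9])
        np.testing.assert_array_equal(compress_unit_interval(y), y)

    def test_boundary_compressed_inside(self):
        y = np.array([0.0, 0.5, 1.0])
        out = compress_unit_interval(y)
        assert np.all((out > 0) & (out < 1))
        assert out[1] == pytest.approx((0.5 * 2 + 0.5) / 3)


class TestRanking:
    def _fits(self, metadata, design, rng, coef_turb):
        eta = linear_predictor(design, metadata, coef_turb=coef_turb, tank_sd=0.2, intercept=3.0, rng=rng)
        y = simulate_family_response("negbinom", eta, 6.0, rng)
        return [
            fit_glmm(y, metadata, spec, compute_se=False)
            for spec in build_candidate_set("n_events")
        ]

    def test_best_model_has_delta_zero_and_rows_sorted(self, metadata, design, rng):
        table = rank_models(self._fits(metadata, design, rng, -0.8))
        assert table["delta_aicc"].iloc[0] == 0.0
        assert table["aicc"].is_monotonic_increasing
        assert len(table) == 8

    def test_strong_turbidity_effect_outranks_null(self, metadata, design, rng):
        table = rank_models(self._fits(metadata, design, rng, -0.8)).set_index("model")
        assert table.loc["Turbidity", "delta_aicc"] < table.loc["Null", "delta_aicc"]

    def test_fewer_than_two_converged_rejected(self, metadata, design, rng):
        fits = self._fits(metadata, design, rng, 0.0)[:1]
        with pytest.raises(ValueError):
            rank_models(fits)

    def test_extra_parameter_caveat_flagged(self):
        # a larger model within 2 units of a better smaller one gets the flag
        base = dict(coefficients={}, coefficients_original_scale={}, se={},
                    dispersion=1.0, re_sd=0.1, n=91, converged=True, n_quad=15)
        small = models.FitResult(
            spec=ModelSpec("Turbidity", ("turb",), "negbinom"),
            log_likelihood=-100.0, k=4, aicc=aicc(-100.0, 4, 91), **base)
        big_ll = -99.2  # barely better fit, one more parameter
        big = models.FitResult(
            spec=ModelSpec("Temp+Turb", ("temp", "turb"), "negbinom"),
            log_likelihood=big_ll, k=5, aicc=aicc(big_ll, 5, 91), **base)
        table = rank_models([small, big]).set_index("model")
        assert table.loc["Temp+Turb", "delta_aicc"] <= 2
        assert bool(table.loc["Temp+Turb", "extra_param_caveat"])
        assert not bool(table.loc["Turbidity", "extra_param_caveat"])
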