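"""MCMC fitting, derived quantities and convergence diagnostics."""

import numpy as np
import pytest
from scipy.special import expit

from germfire import (
    GerminationObservation,
    ModelSpec,
    SamplerConfig,
    SpeciesScenario,
    ValidationError,
    effect_draws,
    ess,
    fit_model,
    fit_overdispersed,
    posterior_predictive_check,
    rhat,
    simulate_species,
    treatment_probabilities,
)
from germfire.model import (
    build_design,
    derive_treatment_probabilities,
    detect_separation,
)


def _fit(obs, spec=None, cfg=None, **kw):
    X, G, V, exp, trts = build_design(obs)
    spec = spec or ModelSpec(experiment=exp)
    cfg = cfg or SamplerConfig(
        chains=3, iterations=3000, burn_in=1500, thinning=1, seed=11
    )
    return fit_model(X, (G, V), spec, cfg, row_treatments=trts, **kw)


class TestDesign:
    def test_indicator_coding_experiment1(self):
        obs = [
            GerminationObservation("sp", 1, t, 1, 50, 50, 10)
            for t in ("C", "H", "S", "HS")
        ]
        X, G, V, exp, trts = build_design(obs)
        assert exp == 1
        assert X.tolist() == [
            [1, 0, 0, 0],
            [1, 1, 0, 0],
            [1, 0, 1, 0],
            [1, 1, 1, 1],
        ]

    def test_indicator_coding_experiment2(self):
        obs = [
            GerminationObservation("sp", 2, t, 1, 50, 50, 10) for t in ("C", "HS")
        ]
        X, *_ = build_design(obs)
        assert X.tolist() == [[1, 0], [1, 1]]

    def test_mixed_experiments_rejected(self):
        obs = [
            GerminationObservation("sp", 1, "C", 1, 50, 50, 10),
            GerminationObservation("sp", 2, "HS", 1, 50, 50, 10),
        ]
        with pytest.raises(ValidationError, match="mixed experiment"):
            build_design(obs)

    def test_separation_detection(self):
        obs = [
            GerminationObservation("sp", 1, t, r, 50, 50, 50 if t == "HS" else 25)
            for t in ("C", "H", "S", "HS")
            for r in range(1, 6)
        ]
        X, G, V, _, trts = build_design(obs)
        assert detect_separation(G, V, trts) == ["HS"]


class TestDerivedProbabilities:
    def test_zero_coefficients_give_half(self):
        pi, trts = derive_treatment_probabilities(np.zeros((10, 4)), 1)
        assert trts == ("C", "H", "S", "HS")
        assert np.allclose(pi, 0.5)

    def test_inverse_logit_closed_form(self):
        beta = np.array([[0.0, 2.1972, 0.0, 0.0]])
        pi, _ = derive_treatment_probabilities(beta, 1)
        assert pi[0, 1] == pytest.approx(0.9, abs=1e-3)  # pi_H
        assert pi[0, 0] == 0.5  # pi_C

    def test_extreme_intercept_limit(self):
        pi, _ = derive_treatment_probabilities(np.array([[-30.0, 0, 0, 0]]), 1)
        assert pi[0, 0] < 1e-10

    def test_additive_structure_experiment1(self):
        rng = np.random.default_rng(0)
        beta = rng.normal(size=(50, 4))
        pi, _ = derive_treatment_probabilities(beta, 1)
        assert np.allclose(pi[:, 3], expit(beta.sum(axis=1)))  # pi_HS
        assert np.allclose(pi[:, 2], expit(beta[:, 0] + beta[:, 2]))  # pi_S


class TestFitting:
    def test_parameter_recovery(self):
        sc = SpeciesScenario("sp", (0.2, 0.2, 0.9, 0.9))
        fit = _fit(simulate_species(sc, seed=21))
        pi = fit.pi_flat.mean(axis=0)
        for est, true in zip(pi, sc.pi):
            assert abs(est - true) < 0.07

    def test_deterministic_under_fixed_seed(self, fd_observations):
        a = _fit(fd_observations)
        b = _fit(fd_observations)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.pi, b.pi)

    def test_conjugate_oracle_flat_prior(self):
        # intercept-only data: posterior mean of pi matches the
        # Beta(G+1, V-G+1) conjugate oracle within Monte Carlo error
        obs = [
            GerminationObservation("sp", 2, "C", r, 50, 50, 30) for r in range(1, 6)
        ]
        cfg = SamplerConfig(chains=4, iterations=8000, burn_in=3000, thinning=1, seed=2)
        fit = _fit(obs, cfg=cfg)
        oracle = (150 + 1) / (250 + 2)
        assert fit.pi_for("C").mean() == pytest.approx(oracle, abs=0.01)

    def test_logistic_monotonicity(self, fd_observations):
        fit = _fit(fd_observations)
        eta = fit.beta_flat[:, 0]  # logit of control probability
        pi = fit.pi_flat[:, 0]
        assert np.array_equal(np.argsort(eta), np.argsort(pi))

    def test_separated_data_under_student_t(self, fi_separated_observations):
        fit = _fit(
            fi_separated_observations,
            spec=ModelSpec(experiment=1, prior_family="student_t"),
        )
        assert (fit.pi_flat > 0.95).all()
        assert not any("separation" in w for w in fit.warnings)

    def test_flat_prior_on_separated_data_flagged(self, fi_separated_observations):
        fit = _fit(fi_separated_observations)
        assert any("Student-t" in w for w in fit.warnings)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError, match="0 <= G <= V"):
            fit_model(
                np.ones((1, 2)),
                (np.array([10.0]), np.array([5.0])),
                ModelSpec(experiment=2),
                SamplerConfig(chains=2, iterations=100, burn_in=50, thinning=1),
            )


class TestEffects:
    def test_identical_probabilities_give_zero_contrasts(self):
        fit = _fit(
            simulate_species(SpeciesScenario("sp", (0.6, 0.6, 0.6, 0.6)), seed=5)
        )
        eff = effect_draws(fit)
        for name in ("H-C", "S-C", "HS-C", "HS-S", "interaction"):
            assert abs(np.mean(eff[name])) < 8  # percent points

    def test_smoke_effect_recovered(self, fd_observations):
        eff = effect_draws(_fit(fd_observations))["S-C"]
        lo, hi = np.percentile(eff, [2.5, 97.5])
        assert lo > 50  # true smoke effect +85 points

    def test_experiment2_has_no_single_cue_contrast(self):
        obs = simulate_species(
            SpeciesScenario("sp", (0.1, 0.9), experiment=2), seed=3
        )
        fit = _fit(obs)
        with pytest.raises(KeyError, match="H-C"):
            effect_draws(fit, ["H-C"])
        assert set(effect_draws(fit)) == {"HS-C"}

    def test_percent_scale_option(self, fd_observations):
        fit = _fit(fd_observations)
        p = treatment_probabilities(fit, percent=True)
        assert 0 <= p["C"].min() and p["HS"].max() <= 100
        assert p["HS"].mean() > 50


class TestRhat:
    def test_identical_stationary_chains(self, rng):
        x = rng.standard_normal(4000)
        chains = np.stack([x, x, x])
        assert rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains(self, rng):
        chains = np.stack(
            [rng.normal(0, 1, 2000), rng.normal(50, 1, 2000)]
        )
        assert rhat(chains) > 5

    def test_single_chain_error(self, rng):
        with pytest.raises(ValueError, match="2 chains"):
            rhat(rng.standard_normal((1, 100)))

    def test_well_mixed_fit_converges(self, fd_observations):
        fit = _fit(fd_observations)
        assert max(fit.rhat.values()) < 1.1
        assert fit.converged


class TestESS:
    def test_iid_draws(self, rng):
        x = rng.standard_normal((3, 5000))
        assert ess(x) == pytest.approx(15_000, rel=0.15)

    def test_ar1_closed_form(self, rng):
        rho, n = 0.9, 200_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        innov = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + innov[i]
        expected = n * (1 - rho) / (1 + rho)
        assert ess(x[None, :]) == pytest.approx(expected, rel=0.2)

    def test_agrees_with_arviz_on_fit(self, fd_observations):
        az = pytest.importorskip("arviz")
        fit = _fit(fd_observations)
        mine = ess(fit.beta[:, :, 0])
        theirs = float(az.ess(fit.beta[:, :, 0][None].squeeze(0), method="mean"))
        assert mine == pytest.approx(theirs, rel=0.25)


class TestPosteriorPredictive:
    def test_calibrated_for_well_specified_data(self, fd_observations):
        fit = _fit(fd_observations)
        p, *_ = posterior_predictive_check(fit, seed=99)
        assert 0.05 < p < 0.95

    def test_overdispersion_detected_and_fixed(self):
        sc = SpeciesScenario("od", (0.3, 0.3, 0.7, 0.7), dish_sd=1.0)
        obs = simulate_species(sc, seed=3)
        X, G, V, exp, trts = build_design(obs)
        spec = ModelSpec(experiment=1)
        cfg = SamplerConfig(chains=4, iterations=6000, burn_in=3000, thinning=2, seed=5)
        glm = fit_model(X, (G, V), spec, cfg, row_treatments=trts)
        assert glm.bayesian_p < 0.05
        glmm = fit_overdispersed(X, (G, V), spec, cfg, row_treatments=trts)
        assert 0.05 < glmm.bayesian_p < 0.95


class TestOverdispersedFit:
    def test_sigma_shrinks_when_generator_has_none(self, fd_observations):
        cfg = SamplerConfig(chains=3, iterations=4000, burn_in=2000, thinning=1, seed=8)
        X, G, V, exp, trts = build_design(fd_observations)
        fit = fit_overdispersed(
            X, (G, V), ModelSpec(experiment=1), cfg, row_treatments=trts
        )
        assert np.median(fit.sigma_flat) < 0.5

    def test_sigma_recovery(self):
        sc = SpeciesScenario("od", (0.3, 0.3, 0.7, 0.7), dish_sd=1.0)
        obs = simulate_species(sc, seed=3)
        X, G, V, exp, trts = build_design(obs)
        cfg = SamplerConfig(chains=4, iterations=8000, burn_in=4000, thinning=2, seed=5)
        fit = fit_overdispersed(
            X, (G, V), ModelSpec(experiment=1), cfg, row_treatments=trts
        )
        from germfire import mode_estimate

        assert mode_estimate(fit.sigma_flat) == pytest.approx(1.0, abs=0.35)

    def test_effect_directions_unchanged_on_fd_archetype(self):
        sc = SpeciesScenario("fd", (0.05, 0.05, 0.9, 0.95), dish_sd=0.5)
        obs = simulate_species(sc, seed=13)
        X, G, V, exp, trts = build_design(obs)
        cfg = SamplerConfig(chains=3, iterations=4000, burn_in=2000, thinning=1, seed=7)
        glm = fit_model(X, (G, V), ModelSpec(experiment=1), cfg, row_treatments=trts)
        glmm = fit_overdispersed(
            X, (G, V), ModelSpec(experiment=1), cfg, row_treatments=trts
        )
        for fit in (glm, glmm):
            eff = effect_draws(fit)["S-C"]
            assert np.percentile(eff, 2.5) > 10


class TestConfigInvariants:
    def test_retained_draw_count(self):
        cfg = SamplerConfig(chains=5, iterations=80_000, burn_in=50_000, thinning=10)
        assert cfg.retained == 15_000

    def test_burnin_bound(self):
        with pytest.raises(ValueError):
            SamplerConfig(chains=2, iterations=100, burn_in=100, thinning=1)

    def test_fit_draw_count_matches_config(self, fd_observations):
        fit = _fit(fd_observations)
        assert fit.beta_flat.shape[0] == fit.config.retained
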