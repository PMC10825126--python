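"""Occupancy model: likelihood, latent-state conditional, MCMC, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from camcat import (
    DetectionHistory,
    MCMCSettings,
    OccupancyModelSpec,
    PosteriorDraws,
    compare_species,
    derive_site_probabilities,
    joint_log_density,
    run_mcmc,
    standardize,
    summarize,
    update_latent_z,
)
from camcat.occupancy import (
    conditional_z_probability,
    effective_sample_size,
    logsumexp_over_latents,
    marginal_log_likelihood_brute,
    split_rhat,
)

INTERCEPT_ONLY = OccupancyModelSpec(psi_covariates=(), p_covariates=())


def _history(y_totals, n_occ=3):
    y_totals = np.asarray(y_totals)
    y = np.zeros((len(y_totals), n_occ), dtype=np.int8)
    for i, t in enumerate(y_totals):
        y[i, :t] = 1
    return DetectionHistory(sites=[f"s{i}" for i in range(len(y_totals))],
                            y=y, n=np.full(len(y_totals), n_occ))


def _empty_design(n_sites):
    return standardize(
        pd.DataFrame({"dummy": np.linspace(0, 1, n_sites)}), ["dummy"]
    )


class TestJointLogDensity:
    def test_intercept_only_closed_form(self):
        # one site, beta = alpha = 0 so psi = p = 0.5; z=1, y=0 of n=3:
        # likelihood = log 0.5 + 3 log 0.5
        h = _history([0])
        lp = joint_log_density([0.0], [0.0], [1], h, _empty_design(1),
                               INTERCEPT_ONLY)
        prior = stats.norm.logpdf([0.0, 0.0], 0.0, INTERCEPT_ONLY.prior_sd).sum()
        assert lp - prior == pytest.approx(4 * np.log(0.5), abs=1e-12)

    def test_detection_implies_occupancy(self):
        h = _history([2])
        lp = joint_log_density([0.0], [0.0], [0], h, _empty_design(1),
                               INTERCEPT_ONLY)
        assert lp == -np.inf

    def test_dimension_mismatch_rejected(self):
        h = _history([0, 1])
        with pytest.raises(ValueError):
            joint_log_density([0.0, 1.0], [0.0], [1, 1], h, _empty_design(2),
                              INTERCEPT_ONLY)

    def test_brute_force_latent_enumeration_oracle(self):
        # marginal likelihood by per-site closed form == logsumexp of the
        # joint over all 2^S latent vectors (priors cancel)
        rng = np.random.default_rng(4)
        S = 6
        cov = pd.DataFrame({"u": rng.normal(size=S), "v": rng.normal(size=S)})
        design = standardize(cov, ["u", "v"])
        spec = OccupancyModelSpec(psi_covariates=("u",), p_covariates=("v",))
        h = _history(rng.integers(0, 4, size=S))
        beta = rng.normal(size=2)
        alpha = rng.normal(size=2)
        lse = logsumexp_over_latents(beta, alpha, h, design, spec)
        prior = stats.norm.logpdf(np.concatenate([beta, alpha]), 0.0,
                                  spec.prior_sd).sum()
        brute = marginal_log_likelihood_brute(beta, alpha, h, design, spec)
        assert lse - prior == pytest.approx(brute, abs=1e-10)


class TestLatentUpdate:
    def test_closed_form_conditional(self):
        # Pr(z=1 | y=0, psi=0.5, p=0.5, n=3) = 0.5*0.125/(0.5*0.125+0.5) = 1/9
        pr = conditional_z_probability(0.5, 0.0, 3)
        assert pr == pytest.approx(1 / 9, abs=1e-12)

    def test_detection_forces_occupancy(self):
        h = _history([1, 0])
        rng = np.random.default_rng(0)
        z = np.array([update_latent_z([0.0], [0.0], h, _empty_design(2),
                                      INTERCEPT_ONLY, rng)
                      for _ in range(50)])
        assert (z[:, 0] == 1).all()

    def test_perfect_detection_limit(self):
        # p -> 1 with no detections leaves no room for occupancy
        assert conditional_z_probability(0.5, 30.0, 3) == pytest.approx(0.0, abs=1e-12)

    def test_empirical_frequency_matches_conditional(self):
        h = _history([0])
        rng = np.random.default_rng(1)
        draws = [update_latent_z([0.0], [0.0], h, _empty_design(1),
                                 INTERCEPT_ONLY, rng)[0]
                 for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(1 / 9, abs=0.02)


class TestMCMC:
    def test_same_seed_bit_identical(self, small_study):
        settings = MCMCSettings(chains=2, adapt=100, burn=100, iterations=200,
                                seed=5)
        d1 = run_mcmc(small_study["history"], small_study["design"],
                      small_study["spec"], settings)
        d2 = run_mcmc(small_study["history"], small_study["design"],
                      small_study["spec"], settings)
        np.testing.assert_array_equal(d1.beta, d2.beta)
        np.testing.assert_array_equal(d1.alpha, d2.alpha)
        np.testing.assert_array_equal(d1.z, d2.z)

    def test_distinct_seeds_differ(self, small_study):
        settings = MCMCSettings(chains=1, adapt=100, burn=100, iterations=200,
                                seed=5)
        d1 = run_mcmc(small_study["history"], small_study["design"],
                      small_study["spec"], settings)
        d2 = run_mcmc(small_study["history"], small_study["design"],
                      small_study["spec"],
                      MCMCSettings(chains=1, adapt=100, burn=100,
                                   iterations=200, seed=6))
        assert not np.array_equal(d1.beta, d2.beta)

    def test_full_model_recovery_single_replicate(self, small_study):
        settings = MCMCSettings(chains=3, adapt=500, burn=500, iterations=2000,
                                seed=2)
        draws = run_mcmc(small_study["history"], small_study["design"],
                         small_study["spec"], settings)
        summary = summarize(draws)
        assert (summary["rhat"] < 1.1).all()
        truth = small_study["truth"]
        inside = 0
        named = {**{f"psi_{k}": v for k, v in truth.beta_true.items() if k != "intercept"},
                 "psi_intercept": truth.beta_true["intercept"],
                 **{f"p_{k}": v for k, v in truth.alpha_true.items() if k != "intercept"},
                 "p_intercept": truth.alpha_true["intercept"]}
        for name, true_val in named.items():
            row = summary.loc[name]
            inside += row["lci"] <= true_val <= row["uci"]
        assert inside >= 8  # 10 params at nominal 95%


def _fabricated_draws(values):
    values = np.asarray(values, float)[..., None]
    dummy = np.zeros_like(values)
    return PosteriorDraws(beta=values, alpha=dummy, z=np.zeros(
        (values.shape[0], values.shape[1], 1), dtype=np.uint8),
        psi_names=["psi_intercept"], p_names=["p_intercept"],
        X_psi=np.ones((1, 1)), X_p=np.ones((1, 1)))


class TestSummaries:
    def test_constant_chains_degenerate(self):
        draws = _fabricated_draws(np.full((3, 100), 2.5))
        row = summarize(draws).loc["psi_intercept"]
        assert row["sd"] == 0.0
        assert row["rhat"] == 1.0
        assert row["overlap0"] == 0 and row["f"] == 1.0

    def test_standard_normal_draws(self):
        rng = np.random.default_rng(8)
        draws = _fabricated_draws(rng.standard_normal((3, 15000)))
        row = summarize(draws).loc["psi_intercept"]
        assert abs(row["mean"]) < 0.02
        assert row["lci"] == pytest.approx(-1.96, abs=0.05)
        assert row["uci"] == pytest.approx(1.96, abs=0.05)
        assert row["rhat"] < 1.01
        assert row["overlap0"] == 1
        assert row["f"] == pytest.approx(0.5, abs=0.02)
        assert row["ess"] > 0.5 * 45000

    def test_strictly_positive_draws_sign_coherent(self):
        rng = np.random.default_rng(9)
        draws = _fabricated_draws(rng.random((2, 500)) + 1.0)
        row = summarize(draws).loc["psi_intercept"]
        assert row["overlap0"] == 0 and row["f"] == 1.0

    def test_single_chain_rhat_missing(self, caplog):
        rng = np.random.default_rng(10)
        draws = _fabricated_draws(rng.standard_normal((1, 400)))
        with caplog.at_level("WARNING", logger="camcat"):
            row = summarize(draws).loc["psi_intercept"]
        assert np.isnan(row["rhat"])
        assert "single chain" in caplog.text

    def test_rhat_and_ess_match_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        # AR(1) chains with known autocorrelation
        chains = np.empty((4, 2000))
        for c in range(4):
            e = rng.standard_normal(2000)
            x = np.empty(2000)
            x[0] = e[0]
            for t in range(1, 2000):
                x[t] = 0.6 * x[t - 1] + e[t]
            chains[c] = x
        ours_rhat = split_rhat(chains)
        ours_ess = effective_sample_size(chains)
        ref_rhat = float(az.rhat(chains, method="split"))
        ref_ess = float(az.ess(chains, method="mean"))
        assert ours_rhat == pytest.approx(ref_rhat, abs=5e-3)
        assert ours_ess == pytest.approx(ref_ess, rel=0.15)


class TestDerivedProbabilities:
    def test_zero_coefficients_give_half(self):
        draws = PosteriorDraws(
            beta=np.zeros((2, 50, 1)), alpha=np.zeros((2, 50, 1)),
            z=np.zeros((2, 50, 4), dtype=np.uint8),
            psi_names=["psi_intercept"], p_names=["p_intercept"],
            X_psi=np.ones((4, 1)), X_p=np.ones((4, 1)),
            sites=list("abcd"))
        probs = derive_site_probabilities(draws)
        np.testing.assert_allclose(probs["psi_mean"], 0.5)
        np.testing.assert_allclose(probs["p_mean"], 0.5)

    def test_link_consistency_with_reported_intercept(self):
        # logit^-1(-1.117) must round to the reported 0.247 occupancy
        assert expit(-1.117) == pytest.approx(0.247, abs=5e-4)

    def test_logistic_monotonicity(self):
        X = np.array([[1.0, -1.0], [1.0, 0.0], [1.0, 1.0]])
        draws = PosteriorDraws(
            beta=np.full((1, 20, 2), [0.3, 0.9]), alpha=np.zeros((1, 20, 1)),
            z=np.zeros((1, 20, 3), dtype=np.uint8),
            psi_names=["psi_intercept", "psi_v"], p_names=["p_intercept"],
            X_psi=X, X_p=np.ones((3, 1)))
        psi = derive_site_probabilities(draws)["psi_mean"].to_numpy()
        assert psi[0] < psi[1] < psi[2]


class TestSpeciesComparison:
    def test_identical_vectors(self):
        v = np.full(20, 0.3)
        c = compare_species(v, v)
        assert c.t_statistic == 0.0 and c.p_value == 1.0

    def test_shift_direction_and_antisymmetry(self):
        rng = np.random.default_rng(5)
        b = rng.normal(0.2, 0.05, 154)
        a = b + 0.07
        c = compare_species(a, b)
        assert c.t_statistic > 0
        assert compare_species(b, a).t_statistic == pytest.approx(-c.t_statistic)

    def test_magnitude_matches_welch_formula(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.247, 0.02, 154)
        b = rng.normal(0.178, 0.02, 154)
        c = compare_species(a, b)
        assert abs(c.t_statistic) > 20
        assert c.p_value < 1e-6
        se = np.sqrt(a.var(ddof=1) / 154 + b.var(ddof=1) / 154)
        assert c.t_statistic == pytest.approx((a.mean() - b.mean()) / se)
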