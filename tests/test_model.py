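"""The joint-model mathematical core: probabilities, history likelihood,
latent marginalization and priors."""

import math

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import norm

from ivf_jointfx.cohort import AgeClass, Center
from ivf_jointfx.model import (
    ModelParams,
    PriorConfig,
    couple_history_loglik,
    discontinuation_probability,
    enumerate_terminal_histories,
    log_prior,
    marginal_couple_loglik,
    success_probability,
)

from conftest import make_history


def random_params(rng, sigma_f=None, sigma_eps=None):
    keys = ["<25", "25-29", "35-39", ">=40"]
    return ModelParams(
        alpha_succ=rng.normal(),
        alpha_disc=rng.normal(),
        beta_age_succ={k: rng.normal() for k in keys},
        beta_age_disc={k: rng.normal() for k in keys},
        beta_center_succ=rng.normal(),
        beta_center_disc=rng.normal(),
        lambda_paris=rng.normal(scale=0.5),
        lambda_midcity=rng.normal(scale=0.5),
        sigma_f=rng.uniform(0.3, 1.5) if sigma_f is None else sigma_f,
        sigma_eps=rng.uniform(0.0, 0.8) if sigma_eps is None else sigma_eps,
    )


class TestProbabilities:
    def test_null_params_give_half(self):
        p = ModelParams()
        assert success_probability(Center.PARIS, AgeClass.A30_34, p) == 0.5
        assert discontinuation_probability(Center.PARIS, AgeClass.A30_34, p) == 0.5

    def test_intercept_inverts_logit(self):
        p = ModelParams(alpha_succ=logit(0.22))
        assert success_probability(Center.PARIS, AgeClass.A30_34, p) == pytest.approx(0.22)

    def test_latent_shifts_success(self):
        p = ModelParams()
        assert success_probability(Center.PARIS, AgeClass.A30_34, p, f=1.0) == pytest.approx(
            expit(1.0)
        )

    def test_midcity_loading_applies_to_latent(self):
        p = ModelParams(lambda_midcity=-0.21)
        got = discontinuation_probability(Center.MIDCITY, AgeClass.A30_34, p, f=1.0)
        assert got == pytest.approx(expit(-0.21))
        # the Parisian loading is separate
        assert discontinuation_probability(Center.PARIS, AgeClass.A30_34, p, f=1.0) == 0.5

    def test_oldest_class_odds(self):
        p = ModelParams(beta_age_disc={">=40": math.log(2.9)})
        got = discontinuation_probability(Center.PARIS, AgeClass.GE40, p)
        assert got == pytest.approx(2.9 / 3.9)

    def test_monotone_in_f_and_intercept(self):
        p = ModelParams()
        fs = np.linspace(-3, 3, 11)
        vals = [success_probability(Center.PARIS, AgeClass.A30_34, p, f) for f in fs]
        assert np.all(np.diff(vals) > 0)
        alphas = np.linspace(-3, 3, 11)
        vals = [
            success_probability(Center.PARIS, AgeClass.A30_34, ModelParams(alpha_succ=a))
            for a in alphas
        ]
        assert np.all(np.diff(vals) > 0)


class TestHistoryLoglik:
    def test_single_success_at_even_odds(self):
        h = make_history("c", Center.PARIS, AgeClass.A30_34, (0, "success"))
        assert couple_history_loglik(h, ModelParams()) == pytest.approx(math.log(0.5))

    def test_fail_then_discontinue_at_even_odds(self):
        h = make_history("c", Center.PARIS, AgeClass.A30_34, (0, "disc"))
        assert couple_history_loglik(h, ModelParams()) == pytest.approx(2 * math.log(0.5))

    def test_censored_run_has_no_final_disc_term(self):
        h = make_history("c", Center.PARIS, AgeClass.A30_34, (3, "censored"))
        # three (fail, continue) pairs plus one bare failure: 7 even-odds terms
        assert couple_history_loglik(h, ModelParams()) == pytest.approx(7 * math.log(0.5))

    def test_invalid_history_rejected(self):
        from ivf_jointfx.cohort import AttemptRecord, CoupleHistory

        bad = CoupleHistory(
            "c", Center.PARIS, AgeClass.A30_34, (AttemptRecord(2, 1, None),)
        )
        with pytest.raises(ValueError, match="invalid history"):
            couple_history_loglik(bad, ModelParams())

    def test_tree_normalizes_for_random_params(self):
        """The conditional probabilities of all complete observable
        histories sum to one for arbitrary parameters and latents."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            params = random_params(rng)
            f, eps = rng.normal(size=2)
            for center in Center:
                total = sum(
                    math.exp(couple_history_loglik(h, params, f, eps))
                    for h in enumerate_terminal_histories(center, AgeClass.A35_39)
                )
                assert total == pytest.approx(1.0, abs=1e-12)


class TestMarginalLoglik:
    def test_degenerate_scales_reduce_to_conditional(self):
        h = make_history("c", Center.MIDCITY, AgeClass.GE40, (1, "disc"))
        p = ModelParams(alpha_succ=-0.6, alpha_disc=0.4, sigma_f=0.0, sigma_eps=0.0)
        assert marginal_couple_loglik(h, p) == pytest.approx(
            couple_history_loglik(h, p, 0.0, 0.0)
        )

    def test_factorizes_when_unlinked(self):
        """With lambda = 0 and sigma_eps = 0, the discontinuation factor has
        a closed form and the marginal splits into a product; the joint
        quadrature must agree with the factorized computation."""
        rng = np.random.default_rng(9)
        params = random_params(rng, sigma_eps=0.0)
        params.lambda_paris = 0.0
        params.lambda_midcity = 0.0
        h = make_history("c", Center.MIDCITY, AgeClass.A25_29, (2, "disc"))
        joint = marginal_couple_loglik(h, params, quadrature_order=40)

        # factorization oracle: success factor by 1-D quadrature, the
        # discontinuation factor in closed form
        from ivf_jointfx.model import _gh_nodes

        x, w = _gh_nodes(params.sigma_f, 40)
        eta = (
            params.alpha_succ
            + params.age_effect_succ(AgeClass.A25_29)
            + params.beta_center_succ
            + x
        )
        succ_factor = float(np.sum(w * expit(-eta) ** 3))  # three failures
        pi = discontinuation_probability(Center.MIDCITY, AgeClass.A25_29, params)
        disc_factor = (1 - pi) ** 2 * pi
        assert joint == pytest.approx(math.log(succ_factor) + math.log(disc_factor), abs=1e-8)

    def test_quadrature_matches_monte_carlo(self):
        """Order-30 Gauss-Hermite agrees with a large plain-MC integration
        of the latent pair on a random history."""
        rng = np.random.default_rng(3)
        params = random_params(rng, sigma_f=1.0, sigma_eps=0.5)
        h = make_history("c", Center.MIDCITY, AgeClass.A35_39, (2, "disc"))
        got = marginal_couple_loglik(h, params, quadrature_order=30)
        n = 400_000
        f = params.sigma_f * rng.standard_normal(n)
        eps = params.sigma_eps * rng.standard_normal(n)
        ll = couple_history_loglik(h, params, f, eps)
        mc = math.log(np.exp(ll).mean())
        assert got == pytest.approx(mc, abs=2e-3)

    def test_sign_anchoring_of_latent(self):
        """Flipping the loading sign together with the latent's (fixed)
        unit coefficient in the success equation leaves the marginal
        unchanged - which is why that coefficient is pinned at +1."""
        rng = np.random.default_rng(17)
        params = random_params(rng, sigma_eps=0.4)
        h = make_history("c", Center.MIDCITY, AgeClass.A30_34, (1, "disc"))
        base = marginal_couple_loglik(h, params, quadrature_order=40)

        from ivf_jointfx.model import _gh_nodes

        xf, wf = _gh_nodes(params.sigma_f, 40)
        xe, we = _gh_nodes(params.sigma_eps, 40)
        F, E = np.meshgrid(xf, xe, indexing="ij")
        W = np.outer(wf, we)
        # flipped model: success coefficient -1, loading -lambda
        eta_s = params.alpha_succ + params.beta_center_succ - F
        eta_d = params.alpha_disc + params.beta_center_disc + (-params.lambda_midcity) * F + E
        p, pi = expit(eta_s), expit(eta_d)
        lik = (1 - p) * (1 - pi) * (1 - p) * pi
        flipped = math.log(float((lik * W).sum()))
        assert base == pytest.approx(flipped, abs=1e-10)


class TestLogPrior:
    def test_normal_density_at_mode(self):
        prior = PriorConfig(fixed_effect_sd=10.0, loading_sd=2.0)
        params = ModelParams(sigma_f=1.0, sigma_eps=0.5)
        lp = log_prior(params, prior)
        n_fixed = 12  # 2 intercepts + 8 age + 2 center
        expected = n_fixed * norm.logpdf(0.0, scale=10.0) + 2 * norm.logpdf(0.0, scale=2.0)
        from scipy.stats import halfnorm

        expected += halfnorm.logpdf(1.0) + halfnorm.logpdf(0.5)
        assert lp == pytest.approx(expected)

    def test_doubling_sd_costs_log2_per_effect(self):
        params = ModelParams(sigma_f=1.0, sigma_eps=0.5)
        lp1 = log_prior(params, PriorConfig(fixed_effect_sd=10.0))
        lp2 = log_prior(params, PriorConfig(fixed_effect_sd=20.0))
        assert lp1 - lp2 == pytest.approx(12 * math.log(2))

    def test_out_of_support_scale(self):
        assert log_prior(ModelParams(sigma_f=0.0), PriorConfig()) == -math.inf

    def test_matches_independent_summation(self):
        rng = np.random.default_rng(23)
        params = random_params(rng)
        prior = PriorConfig(fixed_effect_sd=3.0, loading_sd=1.5)
        fixed = (
            [params.alpha_succ, params.alpha_disc, params.beta_center_succ,
             params.beta_center_disc]
            + list(params.beta_age_succ.values())
            + list(params.beta_age_disc.values())
        )
        oracle = sum(norm.logpdf(v, scale=3.0) for v in fixed)
        oracle += sum(
            norm.logpdf(v, scale=1.5) for v in (params.lambda_paris, params.lambda_midcity)
        )
        from scipy.stats import halfnorm

        oracle += halfnorm.logpdf(params.sigma_f) + halfnorm.logpdf(params.sigma_eps)
        assert log_prior(params, prior) == pytest.approx(oracle)

    def test_prior_scaling_variants(self):
        base = PriorConfig()
        tight = base.scaled(0.1)
        assert tight.fixed_effect_sd == pytest.approx(1.0)
        assert tight.loading_sd == pytest.approx(0.2)
        assert tight.sigma_f_prior[1] == pytest.approx(0.1)
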