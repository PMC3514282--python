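"""The shared random-effects joint model for IVF success and discontinuation.

Two mixed logistic regressions are linked by a couple-level latent factor
``f_i ~ N(0, sigma_f^2)``:

    logit(p_i)  = alpha_succ + beta_age_succ[age_i] + beta_center_succ[center_i] + f_i
    logit(pi_i) = alpha_disc + beta_age_disc[age_i] + beta_center_disc[center_i]
                  + lambda_{center_i} * f_i + eps_i

``p_i`` is the per-attempt live-birth probability and ``pi_i`` the
probability of discontinuing after a failed attempt.  The loading ``lambda``
is center-specific; a negative value means the latent factor raises the
chance of success while lowering the risk of discontinuation (opposite
impacts).  ``eps_i ~ N(0, sigma_eps^2)`` is a couple-level disturbance
specific to the discontinuation process.

The observation scheme: for attempts j = 1..4 a Bernoulli success outcome;
for each failed attempt j <= 3 a Bernoulli discontinuation outcome; failures
at attempt 4 are censored (no discontinuation outcome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.special import expit, log_expit, logsumexp
from scipy.special import roots_hermitenorm
from scipy.stats import norm, halfnorm, cauchy

from .cohort import (
    AgeClass,
    AttemptRecord,
    Center,
    CoupleHistory,
    MAX_ATTEMPTS,
    NONREF_AGE_CLASSES,
    REFERENCE_AGE,
    validate_history,
)

__all__ = [
    "ModelParams",
    "PriorConfig",
    "success_probability",
    "discontinuation_probability",
    "couple_history_loglik",
    "marginal_couple_loglik",
    "log_prior",
    "enumerate_terminal_histories",
    "history_pattern",
]

_AGE_KEYS = tuple(a.value for a in NONREF_AGE_CLASSES)


def _age_dict(d: Optional[dict]) -> dict[str, float]:
    out = {k: 0.0 for k in _AGE_KEYS}
    if d:
        for k, v in d.items():
            key = AgeClass.parse(k).value
            if key == REFERENCE_AGE.value:
                if v != 0.0:
                    raise ValueError("reference age class 30-34 must have effect 0")
                continue
            out[key] = float(v)
    return out


@dataclass
class ModelParams:
    """All coefficients of the joint model (logit scale).

    Reference levels (effect 0 by construction): center PARIS, age 30-34.
    ``beta_age_*`` map non-reference age-class labels to coefficients.
    """

    alpha_succ: float = 0.0
    alpha_disc: float = 0.0
    beta_age_succ: dict[str, float] = field(default_factory=dict)
    beta_age_disc: dict[str, float] = field(default_factory=dict)
    beta_center_succ: float = 0.0
    beta_center_disc: float = 0.0
    lambda_paris: float = 0.0
    lambda_midcity: float = 0.0
    sigma_f: float = 1.0
    sigma_eps: float = 0.0

    def __post_init__(self) -> None:
        self.beta_age_succ = _age_dict(self.beta_age_succ)
        self.beta_age_disc = _age_dict(self.beta_age_disc)
        if self.sigma_f < 0 or self.sigma_eps < 0:
            raise ValueError("sigma_f and sigma_eps must be nonnegative")

    # -- coefficient lookups ------------------------------------------------
    def age_effect_succ(self, age: AgeClass) -> float:
        return 0.0 if age == REFERENCE_AGE else self.beta_age_succ[age.value]

    def age_effect_disc(self, age: AgeClass) -> float:
        return 0.0 if age == REFERENCE_AGE else self.beta_age_disc[age.value]

    def center_effect_succ(self, center: Center) -> float:
        return self.beta_center_succ if center == Center.MIDCITY else 0.0

    def center_effect_disc(self, center: Center) -> float:
        return self.beta_center_disc if center == Center.MIDCITY else 0.0

    def loading(self, center: Center) -> float:
        return self.lambda_paris if center == Center.PARIS else self.lambda_midcity

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass
class PriorConfig:
    """Independent priors: Normal(0, fixed_effect_sd^2) on every intercept
    and covariate effect, Normal(0, loading_sd^2) on the two loadings, and a
    named scale prior (half-normal by default) on sigma_f and sigma_eps.

    The loadings get their own, tighter default (sd 2): a loading multiplies
    a unit-scale latent factor, so values beyond +/-2 are already extreme,
    and a very diffuse loading prior lets the chain wander unboundedly in
    the weakly identified region where sigma_f is small (the funnel).

    ``informativeness_level`` tags sensitivity variants; ``scaled`` returns a
    variant with every sd multiplied by the given factor (0.1x = more
    informative, 10x = less informative).
    """

    fixed_effect_sd: float = 10.0
    loading_sd: float = 2.0
    sigma_f_prior: tuple[str, float] = ("halfnormal", 1.0)
    sigma_eps_prior: tuple[str, float] = ("halfnormal", 1.0)
    informativeness_level: str = "default"

    def __post_init__(self) -> None:
        self.sigma_f_prior = (str(self.sigma_f_prior[0]), float(self.sigma_f_prior[1]))
        self.sigma_eps_prior = (str(self.sigma_eps_prior[0]), float(self.sigma_eps_prior[1]))
        if self.fixed_effect_sd <= 0 or self.loading_sd <= 0:
            raise ValueError("prior sds must be positive")
        for fam, scale in (self.sigma_f_prior, self.sigma_eps_prior):
            if fam not in ("halfnormal", "halfcauchy"):
                raise ValueError(f"unknown scale-prior family {fam!r}")
            if scale <= 0:
                raise ValueError("scale-prior hyperparameter must be positive")

    def scaled(self, factor: float, level: Optional[str] = None) -> "PriorConfig":
        return PriorConfig(
            fixed_effect_sd=self.fixed_effect_sd * factor,
            loading_sd=self.loading_sd * factor,
            sigma_f_prior=(self.sigma_f_prior[0], self.sigma_f_prior[1] * factor),
            sigma_eps_prior=(self.sigma_eps_prior[0], self.sigma_eps_prior[1] * factor),
            informativeness_level=level or f"{self.informativeness_level}*{factor:g}",
        )


# ---------------------------------------------------------------------------
# Linear predictors and probabilities
# ---------------------------------------------------------------------------

def success_linear_predictor(center: Center, age: AgeClass, params: ModelParams, f=0.0):
    return params.alpha_succ + params.age_effect_succ(age) + params.center_effect_succ(center) + f


def discontinuation_linear_predictor(center: Center, age: AgeClass, params: ModelParams, f=0.0, eps=0.0):
    return (
        params.alpha_disc
        + params.age_effect_disc(age)
        + params.center_effect_disc(center)
        + params.loading(center) * f
        + eps
    )


def success_probability(center: Center, age: AgeClass, params: ModelParams, f: float = 0.0):
    """Per-attempt live-birth probability, inverse-logit of the success
    linear predictor; strictly increasing in ``f``."""
    return expit(success_linear_predictor(center, age, params, f))


def discontinuation_probability(
    center: Center, age: AgeClass, params: ModelParams, f: float = 0.0, eps: float = 0.0
):
    """Probability of discontinuing after a failed attempt."""
    return expit(discontinuation_linear_predictor(center, age, params, f, eps))


# ---------------------------------------------------------------------------
# History likelihood
# ---------------------------------------------------------------------------

def couple_history_loglik(history: CoupleHistory, params: ModelParams, f=0.0, eps=0.0):
    """Log-probability of one couple's observed history given the latents.

    Sum of per-attempt Bernoulli log-probabilities for success and, for each
    failed attempt 1-3, for the observed continuation decision.  Censored
    attempt-4 failures contribute only the success term.  ``f`` and ``eps``
    may be arrays (broadcasting), enabling vectorized quadrature.
    """
    violations = validate_history(history)
    if violations:
        raise ValueError(f"invalid history for couple {history.couple_id!r}: " + "; ".join(violations))
    eta_s = success_linear_predictor(history.center, history.age_class, params, f)
    eta_d = discontinuation_linear_predictor(history.center, history.age_class, params, f, eps)
    ll = 0.0
    for a in history.attempts:
        ll = ll + (log_expit(eta_s) if a.success == 1 else log_expit(-eta_s))
        if a.success == 0 and a.discontinued is not None:
            ll = ll + (log_expit(eta_d) if a.discontinued == 1 else log_expit(-eta_d))
    return ll


def _gh_nodes(sigma: float, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights integrating a N(0, sigma^2) density exactly in the
    Gauss-Hermite sense; degenerates to a point mass at sigma = 0."""
    if sigma == 0.0:
        return np.zeros(1), np.ones(1)
    x, w = roots_hermitenorm(order)
    return sigma * x, w / math.sqrt(2.0 * math.pi)


def marginal_couple_loglik(history: CoupleHistory, params: ModelParams, quadrature_order: int = 30):
    """Log-likelihood of a history with the latent pair (f, eps) integrated
    out by Gauss-Hermite product quadrature against N(0, sigma_f^2) x
    N(0, sigma_eps^2)."""
    if quadrature_order < 1:
        raise ValueError("quadrature_order must be >= 1")
    xf, wf = _gh_nodes(params.sigma_f, quadrature_order)
    xe, we = _gh_nodes(params.sigma_eps, quadrature_order)
    F, E = np.meshgrid(xf, xe, indexing="ij")
    W = np.log(np.outer(wf, we))
    ll = couple_history_loglik(history, params, F, E)
    return float(logsumexp(ll + W))


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

def _scale_logpdf(value: float, prior: tuple[str, float]) -> float:
    fam, scale = prior
    if value < 0:
        return -np.inf
    if fam == "halfnormal":
        return float(halfnorm.logpdf(value, scale=scale))
    # half-Cauchy: twice the Cauchy density on the nonnegative half-line
    return float(math.log(2.0) + cauchy.logpdf(value, scale=scale))


def log_prior(params: ModelParams, prior: PriorConfig) -> float:
    """Sum of independent log prior densities.  Returns -inf when a scale
    parameter is outside its support (sigma_f <= 0 with latent structure on)."""
    if params.sigma_f <= 0 or params.sigma_eps < 0:
        return -np.inf
    fixed = [
        params.alpha_succ,
        params.alpha_disc,
        params.beta_center_succ,
        params.beta_center_disc,
        *params.beta_age_succ.values(),
        *params.beta_age_disc.values(),
    ]
    lp = float(np.sum(norm.logpdf(fixed, scale=prior.fixed_effect_sd)))
    lp += float(
        np.sum(norm.logpdf([params.lambda_paris, params.lambda_midcity], scale=prior.loading_sd))
    )
    lp += _scale_logpdf(params.sigma_f, prior.sigma_f_prior)
    lp += _scale_logpdf(params.sigma_eps, prior.sigma_eps_prior)
    return lp


# ---------------------------------------------------------------------------
# History-tree enumeration
# ---------------------------------------------------------------------------

def enumerate_terminal_histories(
    center: Center = Center.PARIS,
    age: AgeClass = REFERENCE_AGE,
    couple_id: str = "enum",
) -> list[CoupleHistory]:
    """All complete observable histories under the observation scheme:
    success at attempt j (j = 1..4), failure-then-discontinuation at attempt
    j (j = 1..3), and the censored run of four failures.  Their conditional
    probabilities sum to one for any parameter values."""
    histories = []
    for j in range(1, MAX_ATTEMPTS + 1):
        prefix = tuple(AttemptRecord(k, 0, 0) for k in range(1, j))
        histories.append(CoupleHistory(couple_id, center, age, prefix + (AttemptRecord(j, 1, None),)))
        if j < MAX_ATTEMPTS:
            histories.append(CoupleHistory(couple_id, center, age, prefix + (AttemptRecord(j, 0, 1),)))
    full_fail = tuple(AttemptRecord(k, 0, 0) for k in range(1, MAX_ATTEMPTS)) + (
        AttemptRecord(MAX_ATTEMPTS, 0, None),
    )
    histories.append(CoupleHistory(couple_id, center, age, full_fail))
    return histories


def history_pattern(history: CoupleHistory) -> tuple[int, str]:
    """Summarize a valid history as (number of fail-and-continue attempts,
    terminal outcome in {'success', 'disc', 'censored'}).  With constant
    per-attempt probabilities this pattern determines the likelihood."""
    n_continue = len(history.attempts) - 1
    last = history.attempts[-1]
    if last.success == 1:
        outcome = "success"
    elif last.discontinued == 1:
        outcome = "disc"
    else:
        outcome = "censored"
    return n_continue, outcome
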