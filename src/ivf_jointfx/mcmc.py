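"""MCMC fitting of the joint model, convergence diagnostics and posterior
odds-ratio summaries.

The sampler is a blocked Gibbs scheme with Polya-Gamma data augmentation:
one PG(1, eta) variable per Bernoulli observation makes every logistic
coefficient block (success fixed effects, discontinuation fixed effects
jointly with the free loadings, and the couple latents f_i / eps_i)
conditionally Gaussian.  Mixing of the weakly identified directions is
handled by extra kernel components on the collapsed state (the PG
variables are discarded between sweeps): exact Gibbs translation moves
between the latent means and the intercept/center coefficients, and
interweaved (ASIS) slice updates of sigma_f and sigma_eps in the
non-centered parametrization, alongside a cheap conditional random-walk
step (its adaptation frozen after burn-in).

The fitting protocol mirrors the study: multiple independent chains with
dispersed initial values, a burn-in, and thinning; convergence is assessed
with the Brooks-Gelman corrected potential scale reduction factor and
within-chain autocorrelations of the retained draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import log_expit
from sklearn.base import BaseEstimator

from .cohort import (
    AgeClass,
    Center,
    Cohort,
    MAX_ATTEMPTS,
    NONREF_AGE_CLASSES,
)
from .model import ModelParams, PriorConfig, couple_history_loglik, _scale_logpdf
from .polya_gamma import sample_pg1

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "ORSummary",
    "fit_mcmc",
    "gelman_rubin",
    "or_summary",
    "SharedRandomEffectsModel",
]

_AGE_KEYS = tuple(a.value for a in NONREF_AGE_CLASSES)

#: The study's chain protocol: 2 chains x 300,000 iterations, burn-in
#: 50,000, keep every 100th (retained sample size 5,000).
STUDY_PROTOCOL = dict(n_chains=2, n_iterations=300_000, burn_in=50_000, thin=100)

#: Desk-scale protocol used throughout the test battery.
DESK_PROTOCOL = dict(n_chains=2, n_iterations=6_000, burn_in=1_000, thin=5)


@dataclass
class MCMCConfig:
    n_chains: int = 2
    n_iterations: int = 6_000
    burn_in: int = 1_000
    thin: int = 5
    seed: int = 0
    init_spread: float = 1.0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.init_spread <= 0:
            raise ValueError("init_spread must be positive")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @classmethod
    def study_protocol(cls, seed: int = 0) -> "MCMCConfig":
        return cls(seed=seed, **STUDY_PROTOCOL)

    @classmethod
    def desk(cls, seed: int = 0) -> "MCMCConfig":
        return cls(seed=seed, **DESK_PROTOCOL)


@dataclass
class ORSummary:
    """Posterior odds-ratio summary for one coefficient: quantiles at
    0.025/0.25/0.5/0.75/0.975 of exp(draws), plus the posterior mean."""

    coefficient: str
    quantiles: dict[float, float]
    mean: float
    reference: str

    @property
    def median(self) -> float:
        return self.quantiles[0.5]

    def credible_interval(self) -> tuple[float, float]:
        return self.quantiles[0.025], self.quantiles[0.975]


class PosteriorSamples:
    """Thinned multi-chain posterior draws keyed by parameter name.

    ``draws[name]`` has shape (n_chains, retained_per_chain).  Reference
    descriptions for odds-ratio reporting: center effects compare MIDCITY
    to PARIS; age effects compare each class to 30-34.
    """

    def __init__(self, draws: dict[str, np.ndarray], config: MCMCConfig,
                 latent_f: Optional[np.ndarray] = None):
        self.draws = draws
        self.config = config
        self.latent_f = latent_f

    @property
    def parameter_names(self) -> list[str]:
        return list(self.draws)

    def pooled(self, name: str) -> np.ndarray:
        if name not in self.draws:
            raise KeyError(f"unknown coefficient {name!r}; have {self.parameter_names}")
        return self.draws[name].reshape(-1)

    def rhat(self) -> dict[str, float]:
        return {k: gelman_rubin(v) for k, v in self.draws.items()}

    def autocorrelation(self, name: str, max_lag: int = 10) -> np.ndarray:
        """Mean over chains of the within-chain autocorrelation of the
        retained draws at lags 1..max_lag."""
        x = self.draws[name]
        out = np.zeros(max_lag)
        for lag in range(1, max_lag + 1):
            acs = []
            for chain in x:
                c = chain - chain.mean()
                denom = float(c @ c)
                acs.append(float(c[:-lag] @ c[lag:]) / denom if denom > 0 else 0.0)
            out[lag - 1] = float(np.mean(acs))
        return out

    def summary(self) -> pd.DataFrame:
        rows = {}
        rh = self.rhat() if self.draws[next(iter(self.draws))].shape[0] >= 2 else {}
        for name, x in self.draws.items():
            flat = x.reshape(-1)
            rows[name] = {
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "q2.5": np.quantile(flat, 0.025),
                "median": np.quantile(flat, 0.5),
                "q97.5": np.quantile(flat, 0.975),
                "rhat": rh.get(name, np.nan),
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, draw, parameter, value."""
        recs = []
        for name, x in self.draws.items():
            for chain in range(x.shape[0]):
                for draw in range(x.shape[1]):
                    recs.append((chain, draw, name, x[chain, draw]))
        return pd.DataFrame(recs, columns=["chain", "draw", "parameter", "value"])

    def params_at(self, chain: int, draw: int) -> ModelParams:
        """Materialize one draw as a ModelParams."""
        g = lambda name, default=0.0: float(self.draws[name][chain, draw]) if name in self.draws else default
        return ModelParams(
            alpha_succ=g("alpha_succ"),
            alpha_disc=g("alpha_disc"),
            beta_age_succ={k: g(f"beta_age_succ[{k}]") for k in _AGE_KEYS},
            beta_age_disc={k: g(f"beta_age_disc[{k}]") for k in _AGE_KEYS},
            beta_center_succ=g("beta_center_succ"),
            beta_center_disc=g("beta_center_disc"),
            lambda_paris=g("lambda_paris"),
            lambda_midcity=g("lambda_midcity"),
            sigma_f=g("sigma_f", 1.0),
            sigma_eps=g("sigma_eps", 0.0),
        )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(chains) -> float:
    """Brooks-Gelman corrected potential scale reduction factor.

    ``chains``: array-like of shape (m, n), m >= 2 chains of n >= 2 draws.
    Returns the corrected PSRF sqrt((d+3)/(d+1) * Vhat/W) where d is the
    estimated degrees of freedom of the t-approximation to the pooled
    posterior variance estimate Vhat.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two chains")
    m, n = x.shape
    if n < 2:
        raise ValueError("need at least two draws per chain")
    s2 = x.var(axis=1, ddof=1)
    xbar = x.mean(axis=1)
    W = s2.mean()
    B = n * xbar.var(ddof=1)
    if W == 0.0:
        return 1.0
    sig2hat = ((n - 1) * W + B) / n
    V = sig2hat + B / (m * n)
    muhat = xbar.mean()
    var_w = s2.var(ddof=1) / m
    var_b = (2.0 * B * B) / (m - 1)
    cov_wb = (n / m) * (
        np.cov(s2, xbar**2, ddof=1)[0, 1] - 2.0 * muhat * np.cov(s2, xbar, ddof=1)[0, 1]
    )
    var_V = ((n - 1) ** 2 * var_w + (1 + 1 / m) ** 2 * var_b + 2 * (n - 1) * (1 + 1 / m) * cov_wb) / n**2
    if var_V <= 0:
        return float(math.sqrt(V / W))
    d = 2.0 * V * V / var_V
    return float(math.sqrt((V / W) * (d + 3.0) / (d + 1.0)))


def or_summary(samples: PosteriorSamples, coefficient: str) -> ORSummary:
    """Odds-ratio summary (exp of pooled draws) at the five probabilities
    used for the boxplot displays."""
    ors = np.exp(samples.pooled(coefficient))
    probs = (0.025, 0.25, 0.5, 0.75, 0.975)
    qs = {p: float(np.quantile(ors, p)) for p in probs}
    if "center" in coefficient or "lambda" in coefficient:
        ref = "MIDCITY vs PARIS (reference)"
    elif "age" in coefficient:
        ref = "vs age 30-34 (reference)"
    else:
        ref = "per unit on the logit scale"
    return ORSummary(coefficient, qs, float(ors.mean()), ref)


# ---------------------------------------------------------------------------
# Data compilation
# ---------------------------------------------------------------------------

class _CompiledCohort:
    """Design arrays for the augmented sampler: one row per Bernoulli
    observation, indexed back to couples."""

    def __init__(self, cohort: Cohort, covariates: Sequence[str]):
        n = len(cohort)
        if n == 0:
            raise ValueError("empty cohort")
        use_age = "age" in covariates
        use_center = "center" in covariates
        if use_center and len({c.center for c in cohort}) < 2:
            raise ValueError("a center is absent from the cohort: center effect inestimable")
        if use_age and {c.age_class for c in cohort} != set(AgeClass):
            missing = set(AgeClass) - {c.age_class for c in cohort}
            raise ValueError(
                "age classes absent from the cohort: effect inestimable: "
                + ", ".join(sorted(a.value for a in missing))
            )
        self.col_names = ["alpha"]
        if use_age:
            self.col_names += [f"age[{k}]" for k in _AGE_KEYS]
        if use_center:
            self.col_names += ["center"]
        C = np.zeros((n, len(self.col_names)))
        C[:, 0] = 1.0
        self.is_midcity = np.zeros(n, dtype=bool)
        for i, c in enumerate(cohort):
            if use_age and c.age_class != AgeClass.A30_34:
                C[i, 1 + _AGE_KEYS.index(c.age_class.value)] = 1.0
            if c.center == Center.MIDCITY:
                self.is_midcity[i] = True
                if use_center:
                    C[i, self.col_names.index("center")] = 1.0
        self.C = C
        self.n_couples = n

        ci_s, y_s, ci_d, y_d = [], [], [], []
        for i, c in enumerate(cohort):
            for a in c.attempts:
                ci_s.append(i)
                y_s.append(a.success)
                if a.success == 0 and a.discontinued is not None:
                    ci_d.append(i)
                    y_d.append(a.discontinued)
        self.ci_s = np.asarray(ci_s, dtype=np.intp)
        self.y_s = np.asarray(y_s, dtype=float)
        self.ci_d = np.asarray(ci_d, dtype=np.intp)
        self.y_d = np.asarray(y_d, dtype=float)
        self.Xs = C[self.ci_s]
        self.Xd = C[self.ci_d]
        self.kappa_s = self.y_s - 0.5
        self.kappa_d = self.y_d - 0.5
        self.midcity_d = self.is_midcity[self.ci_d]


def _draw_gaussian_block(XtOX, rhs, prior_prec, rng):
    """Sample from N(Lambda^-1 rhs, Lambda^-1), Lambda = XtOX + diag(prior
    precisions); ``prior_prec`` may be a scalar or a per-column vector."""
    prec = XtOX + np.diag(np.broadcast_to(prior_prec, (XtOX.shape[0],)))
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    z = rng.standard_normal(len(rhs))
    return mean + np.linalg.solve(L.T, z)


def _data_loglik(data, xb_s, xb_d, lam_obs, f, eps):
    """Exact logistic log-likelihood of all observations given latents."""
    eta_s = xb_s + f[data.ci_s]
    eta_d = xb_d + lam_obs * f[data.ci_d] + eps[data.ci_d]
    return float(
        log_expit((2.0 * data.y_s - 1.0) * eta_s).sum()
        + log_expit((2.0 * data.y_d - 1.0) * eta_d).sum()
    )


def _slice_log_scale(logpost, theta0, rng, w=0.7, max_steps=8):
    """Neal's stepping-out slice sampler on a 1-D log-scale coordinate."""
    y = logpost(theta0) + math.log(rng.random())
    lo = theta0 - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logpost(lo) <= y:
            break
        lo -= w
    for _ in range(max_steps):
        if logpost(hi) <= y:
            break
        hi += w
    while True:
        prop = lo + (hi - lo) * rng.random()
        if logpost(prop) > y:
            return prop
        if prop < theta0:
            lo = prop
        else:
            hi = prop


def _mh_log_scale(sigma, values, prior, step, rng):
    """One adaptive-MH update of a latent scale on the log scale; returns
    (new_sigma, accepted)."""
    n = values.size

    def logpost(s):
        if s <= 0:
            return -np.inf
        return (
            -n * math.log(s)
            - float(values @ values) / (2.0 * s * s)
            + _scale_logpdf(s, prior)
            + math.log(s)  # Jacobian of the log transform
        )

    prop = sigma * math.exp(step * rng.standard_normal())
    if math.log(rng.random()) < logpost(prop) - logpost(sigma):
        return prop, True
    return sigma, False


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

def fit_mcmc(
    cohort: Cohort,
    prior: Optional[PriorConfig] = None,
    config: Optional[MCMCConfig] = None,
    *,
    covariates: Sequence[str] = ("age", "center"),
    fix_lambda: Optional[dict[Center, float]] = None,
    sigma_f: float | str = "free",
    sigma_eps: float | str = "free",
    save_latents: bool = False,
    _flat_likelihood: bool = False,
    _no_translations: bool = False,
) -> PosteriorSamples:
    """Fit the joint model by Polya-Gamma-augmented Gibbs sampling.

    Parameters
    ----------
    cohort, prior, config : the data, prior configuration and chain protocol.
    covariates : which fixed effects to include ("age", "center"); an empty
        tuple fits the intercept-only reduced model.
    fix_lambda : map center -> value pinning that center's loading (used by
        the null model of the Bayes-factor test); free loadings otherwise.
    sigma_f, sigma_eps : "free" to sample under the prior, or a nonnegative
        number to fix the scale (0 switches the latent off).
    save_latents : retain the per-couple f draws alongside the parameters.

    Returns a :class:`PosteriorSamples` with per-chain retained draws for
    every model parameter (fixed ones appear as constant series).
    """
    prior = prior or PriorConfig()
    config = config or MCMCConfig()
    fix_lambda = {Center.parse(k): float(v) for k, v in (fix_lambda or {}).items()}
    data = _CompiledCohort(cohort, covariates)
    n = data.n_couples
    p_cols = len(data.col_names)

    free_sigma_f = sigma_f == "free"
    free_sigma_eps = sigma_eps == "free"
    sigma_f0 = 1.0 if free_sigma_f else float(sigma_f)
    sigma_eps0 = 0.5 if free_sigma_eps else float(sigma_eps)
    if sigma_f0 < 0 or sigma_eps0 < 0:
        raise ValueError("fixed scales must be nonnegative")
    use_f = free_sigma_f or sigma_f0 > 0
    use_eps = free_sigma_eps or sigma_eps0 > 0
    prior_prec = 1.0 / prior.fixed_effect_sd**2
    loading_prec = 1.0 / prior.loading_sd**2

    # sanity: the likelihood must be finite at the initial state
    init_params = ModelParams(sigma_f=sigma_f0 if use_f else 0.0, sigma_eps=0.0)
    for c in cohort:
        ll = couple_history_loglik(c, init_params, 0.0, 0.0)
        if not np.isfinite(ll):
            raise ValueError(f"non-finite likelihood at initialization for couple {c.couple_id!r}")

    n_keep = config.retained_per_chain
    names = ["alpha_succ"]
    if "age" in covariates:
        names += [f"beta_age_succ[{k}]" for k in _AGE_KEYS]
    if "center" in covariates:
        names += ["beta_center_succ"]
    names += ["alpha_disc"]
    if "age" in covariates:
        names += [f"beta_age_disc[{k}]" for k in _AGE_KEYS]
    if "center" in covariates:
        names += ["beta_center_disc"]
    names += ["lambda_paris", "lambda_midcity", "sigma_f", "sigma_eps"]
    out = {k: np.empty((config.n_chains, n_keep)) for k in names}
    latent_store = np.empty((config.n_chains, n_keep, n)) if save_latents else None

    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.spawn(config.n_chains)

    def record(chain, idx, beta_s, beta_d, lam, sf, se):
        out["alpha_succ"][chain, idx] = beta_s[0]
        for k, name in enumerate(data.col_names[1:], start=1):
            tgt = "beta_center_succ" if name == "center" else f"beta_age_succ[{name[4:-1]}]"
            out[tgt][chain, idx] = beta_s[k]
        out["alpha_disc"][chain, idx] = beta_d[0]
        for k, name in enumerate(data.col_names[1:], start=1):
            tgt = "beta_center_disc" if name == "center" else f"beta_age_disc[{name[4:-1]}]"
            out[tgt][chain, idx] = beta_d[k]
        out["lambda_paris"][chain, idx] = lam[0]
        out["lambda_midcity"][chain, idx] = lam[1]
        out["sigma_f"][chain, idx] = sf
        out["sigma_eps"][chain, idx] = se

    for chain in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[chain])
        spread = config.init_spread * (0.1 + chain)
        beta_s = spread * rng.standard_normal(p_cols)
        beta_d = spread * rng.standard_normal(p_cols)
        lam = np.zeros(2)  # [paris, midcity]
        for ci, center in enumerate((Center.PARIS, Center.MIDCITY)):
            if center in fix_lambda:
                lam[ci] = fix_lambda[center]
            else:
                lam[ci] = 0.2 * spread * rng.standard_normal()
        sf = sigma_f0 * math.exp(0.2 * spread * rng.standard_normal()) if free_sigma_f else sigma_f0
        se = sigma_eps0 * math.exp(0.2 * spread * rng.standard_normal()) if free_sigma_eps else sigma_eps0
        f = np.zeros(n)
        eps = np.zeros(n)
        step_f, step_e = 0.3, 0.3
        acc_f = acc_e = try_f = try_e = 0

        lam_free = [c not in fix_lambda for c in (Center.PARIS, Center.MIDCITY)]
        mid_d = data.midcity_d
        sgn_s = 2.0 * data.y_s - 1.0
        sgn_d = 2.0 * data.y_d - 1.0
        keep_idx = 0
        for it in range(config.n_iterations):
            if _flat_likelihood:
                # test hook: posterior == prior
                beta_s = prior.fixed_effect_sd * rng.standard_normal(p_cols)
                beta_d = prior.fixed_effect_sd * rng.standard_normal(p_cols)
                for ci in range(2):
                    if lam_free[ci]:
                        lam[ci] = prior.loading_sd * rng.standard_normal()
                if free_sigma_f:
                    sf = abs(prior.sigma_f_prior[1] * rng.standard_normal())
                if free_sigma_eps:
                    se = abs(prior.sigma_eps_prior[1] * rng.standard_normal())
            else:
                lam_obs = np.where(mid_d, lam[1], lam[0])
                fd = f[data.ci_d]
                epsd = eps[data.ci_d]
                xb_s = data.Xs @ beta_s
                xb_d = data.Xd @ beta_d
                om_s = sample_pg1(xb_s + f[data.ci_s], rng)
                om_d = sample_pg1(xb_d + lam_obs * fd + epsd, rng)

                # success fixed effects
                XtOX = (data.Xs * om_s[:, None]).T @ data.Xs
                rhs = data.Xs.T @ (data.kappa_s - om_s * f[data.ci_s])
                beta_s = _draw_gaussian_block(XtOX, rhs, prior_prec, rng)
                xb_s = data.Xs @ beta_s

                # discontinuation fixed effects and free loadings, one
                # Gaussian block (removes the beta_d / lambda random walk)
                free_cols = []
                offset_d = epsd.copy()
                for ci in range(2):
                    g = fd * (mid_d if ci == 1 else ~mid_d)
                    if lam_free[ci] and use_f:
                        free_cols.append(g)
                    else:
                        offset_d += lam[ci] * g
                Xd_aug = np.column_stack([data.Xd] + free_cols) if free_cols else data.Xd
                XtOX = (Xd_aug * om_d[:, None]).T @ Xd_aug
                rhs = Xd_aug.T @ (data.kappa_d - om_d * offset_d)
                block_prec = np.r_[np.full(p_cols, prior_prec), np.full(len(free_cols), loading_prec)]
                block = _draw_gaussian_block(XtOX, rhs, block_prec, rng)
                beta_d = block[:p_cols]
                if free_cols:
                    k = p_cols
                    for ci in range(2):
                        if lam_free[ci] and use_f:
                            lam[ci] = block[k]
                            k += 1
                xb_d = data.Xd @ beta_d
                lam_obs = np.where(mid_d, lam[1], lam[0])

                # couple latents f
                if use_f and sf > 0:
                    prec_f = (
                        np.bincount(data.ci_s, weights=om_s, minlength=n)
                        + np.bincount(data.ci_d, weights=om_d * lam_obs**2, minlength=n)
                        + 1.0 / sf**2
                    )
                    num_f = np.bincount(
                        data.ci_s, weights=data.kappa_s - om_s * xb_s, minlength=n
                    ) + np.bincount(
                        data.ci_d,
                        weights=lam_obs * (data.kappa_d - om_d * (xb_d + epsd)),
                        minlength=n,
                    )
                    f = num_f / prec_f + rng.standard_normal(n) / np.sqrt(prec_f)
                    fd = f[data.ci_d]

                # couple disturbances eps
                if use_eps and se > 0:
                    prec_e = np.bincount(data.ci_d, weights=om_d, minlength=n) + 1.0 / se**2
                    num_e = np.bincount(
                        data.ci_d,
                        weights=data.kappa_d - om_d * (xb_d + lam_obs * fd),
                        minlength=n,
                    )
                    eps = num_e / prec_e + rng.standard_normal(n) / np.sqrt(prec_e)

                # Exact Gibbs translation moves on reparametrized axes: the
                # mean of the latent vectors trades off against intercept and
                # center coefficients only through the priors (the linear
                # predictors are invariant), so the shift has a closed-form
                # Gaussian conditional.  These break the slow random walk
                # between latent means and the intercepts.
                if use_f and sf > 0 and "center" in data.col_names and not _no_translations:
                    i_c = data.col_names.index("center")
                    n_p = int((~data.is_midcity).sum())
                    n_m = int(data.is_midcity.sum())
                    # Parisian couples' f-mean
                    prec = n_p / sf**2 + 2.0 * prior_prec * (1.0 + lam[0] ** 2)
                    mean = (
                        -float(f[~data.is_midcity].sum()) / sf**2
                        + prior_prec * (beta_s[0] - beta_s[i_c] + lam[0] * (beta_d[0] - beta_d[i_c]))
                    ) / prec
                    delta = mean + rng.standard_normal() / math.sqrt(prec)
                    f[~data.is_midcity] += delta
                    beta_s[0] -= delta
                    beta_s[i_c] += delta
                    beta_d[0] -= lam[0] * delta
                    beta_d[i_c] += lam[0] * delta
                    # medium-sized-city couples' f-mean
                    prec = n_m / sf**2 + prior_prec * (1.0 + lam[1] ** 2)
                    mean = (
                        -float(f[data.is_midcity].sum()) / sf**2
                        + prior_prec * (beta_s[i_c] + lam[1] * beta_d[i_c])
                    ) / prec
                    delta = mean + rng.standard_normal() / math.sqrt(prec)
                    f[data.is_midcity] += delta
                    beta_s[i_c] -= delta
                    beta_d[i_c] -= lam[1] * delta
                    fd = f[data.ci_d]
                    xb_s = data.Xs @ beta_s
                    xb_d = data.Xd @ beta_d
                if use_eps and se > 0 and not _no_translations:
                    prec = n / se**2 + prior_prec
                    mean = (-float(eps.sum()) / se**2 + prior_prec * beta_d[0]) / prec
                    delta = mean + rng.standard_normal() / math.sqrt(prec)
                    eps += delta
                    beta_d[0] -= delta
                    epsd = eps[data.ci_d]
                    xb_d = data.Xd @ beta_d

                # latent scales: conditional log-scale MH ...
                if free_sigma_f:
                    sf, acc = _mh_log_scale(sf, f, prior.sigma_f_prior, step_f, rng)
                    acc_f += acc
                    try_f += 1
                if free_sigma_eps:
                    se, acc = _mh_log_scale(se, eps, prior.sigma_eps_prior, step_e, rng)
                    acc_e += acc
                    try_e += 1

                # Interweaved (ASIS) scale updates: in the non-centered
                # parametrization f = sigma_f * u the scale is informed
                # directly by the data, so a 1-D slice move here mixes the
                # scales across their whole posterior even when the latent
                # vectors move slowly.
                if free_sigma_f and sf > 0:
                    u = f / sf
                    a_s = sgn_s * (xb_s + 0.0)
                    b_s = sgn_s * u[data.ci_s]
                    a_d = sgn_d * (xb_d + epsd)
                    b_d = sgn_d * (lam_obs * u[data.ci_d])

                    def logpost_sf(theta):
                        s = math.exp(theta)
                        return (
                            float(log_expit(a_s + s * b_s).sum())
                            + float(log_expit(a_d + s * b_d).sum())
                            + _scale_logpdf(s, prior.sigma_f_prior)
                            + theta
                        )

                    sf = math.exp(_slice_log_scale(logpost_sf, math.log(sf), rng))
                    f = sf * u
                    fd = f[data.ci_d]
                if free_sigma_eps and se > 0:
                    v = eps / se
                    a_d = sgn_d * (xb_d + lam_obs * fd)
                    b_d = sgn_d * v[data.ci_d]

                    def logpost_se(theta):
                        s = math.exp(theta)
                        return (
                            float(log_expit(a_d + s * b_d).sum())
                            + _scale_logpdf(s, prior.sigma_eps_prior)
                            + theta
                        )

                    se = math.exp(_slice_log_scale(logpost_se, math.log(se), rng))
                    eps = se * v
                    epsd = eps[data.ci_d]

                # Robbins-Monro adaptation toward 44% acceptance, burn-in only
                if it < config.burn_in and it % 50 == 49:
                    if try_f:
                        step_f = float(np.clip(step_f * math.exp((acc_f / try_f - 0.44) / 2), 1e-3, 5.0))
                        acc_f = try_f = 0
                    if try_e:
                        step_e = float(np.clip(step_e * math.exp((acc_e / try_e - 0.44) / 2), 1e-3, 5.0))
                        acc_e = try_e = 0

            if it >= config.burn_in and (it - config.burn_in) % config.thin == config.thin - 1:
                record(chain, keep_idx, beta_s, beta_d, lam, sf, se)
                if save_latents:
                    latent_store[chain, keep_idx] = f
                keep_idx += 1

    return PosteriorSamples(out, config, latent_f=latent_store)


# ---------------------------------------------------------------------------
# sklearn-style estimator surface
# ---------------------------------------------------------------------------

class SharedRandomEffectsModel(BaseEstimator):
    """Joint success/discontinuation model as a scikit-learn estimator.

    ``fit`` accepts either a :class:`Cohort` or a long-format DataFrame with
    the cohort CSV columns.  Fitted attributes: ``posterior_`` (the draws),
    ``rhat_`` (Brooks-Gelman PSRF per parameter), ``summary_`` (posterior
    summary frame).  ``or_summary`` exposes odds-ratio quantile summaries
    for any coefficient.
    """

    def __init__(
        self,
        prior: Optional[PriorConfig] = None,
        n_chains: int = 2,
        n_iterations: int = 6_000,
        burn_in: int = 1_000,
        thin: int = 5,
        seed: int = 0,
        init_spread: float = 1.0,
        covariates: Sequence[str] = ("age", "center"),
        fix_lambda: Optional[dict] = None,
        sigma_f: float | str = "free",
        sigma_eps: float | str = "free",
        save_latents: bool = False,
    ):
        self.prior = prior
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.init_spread = init_spread
        self.covariates = covariates
        self.fix_lambda = fix_lambda
        self.sigma_f = sigma_f
        self.sigma_eps = sigma_eps
        self.save_latents = save_latents

    def _config(self) -> MCMCConfig:
        return MCMCConfig(
            n_chains=self.n_chains,
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
            init_spread=self.init_spread,
        )

    def fit(self, X, y=None) -> "SharedRandomEffectsModel":
        cohort = X if isinstance(X, Cohort) else Cohort.from_dataframe(pd.DataFrame(X))
        self.posterior_ = fit_mcmc(
            cohort,
            prior=self.prior,
            config=self._config(),
            covariates=tuple(self.covariates),
            fix_lambda=self.fix_lambda,
            sigma_f=self.sigma_f,
            sigma_eps=self.sigma_eps,
            save_latents=self.save_latents,
        )
        self.n_couples_ = len(cohort)
        self.rhat_ = self.posterior_.rhat() if self.n_chains >= 2 else {}
        self.summary_ = self.posterior_.summary()
        return self

    def or_summary(self, coefficient: str) -> ORSummary:
        if not hasattr(self, "posterior_"):
            raise AttributeError("call fit before or_summary")
        return or_summary(self.posterior_, coefficient)
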