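"""Partial Bayes factor tests of the center loadings, with the 2*logBF
evidence scale and the split-sample prior-sensitivity analysis.

The hypothesis lambda_center = 0 (no couple-level link between success and
discontinuation in that center) is tested by a partial Bayes factor: the
cohort is split into a learning sample and a test sample; both the full
model M1 and the null model M0 (tested loading pinned at 0) are fitted on
the learning sample, and the Bayes factor is the ratio of posterior-
predictive marginal likelihoods of the held-out test sample, with the
learning-sample posterior playing the role of the prior.  This sidesteps
the indeterminacy of Bayes factors under vague priors.

Evidence convention (null over alternative, so negative values favor a
nonzero loading): L = 2 log BF > -2 - no evidence that lambda != 0;
-6 < L <= -2 - significantly different from 0; L <= -6 - strongly so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.special import log_expit, logsumexp

from .cohort import AgeClass, Center, Cohort
from .model import PriorConfig, history_pattern
from .mcmc import MCMCConfig, PosteriorSamples, fit_mcmc

__all__ = [
    "SplitSpec",
    "EvidenceCategory",
    "BFResult",
    "STUDY_SPLITS",
    "split_cohort",
    "predictive_log_marginal",
    "partial_bayes_factor",
    "classify_evidence",
    "bf_sensitivity",
    "SensitivityReport",
]

#: The three learning/test splits of the 3,002-couple design: learning
#: samples of 2,702, 1,502 and 502 women (test samples 300, 1,500, 2,500).
STUDY_SPLITS = ((2702, 300), (1502, 1500), (502, 2500))


@dataclass(frozen=True)
class SplitSpec:
    n_learning: int
    n_test: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_learning < 1 or self.n_test < 1:
            raise ValueError("both parts of the split must be non-empty")


class EvidenceCategory(str, Enum):
    NO_EVIDENCE = "NO_EVIDENCE"
    SIGNIFICANT = "SIGNIFICANT"
    STRONG = "STRONG"


@dataclass
class BFResult:
    """Partial-Bayes-factor outcome on the L = 2 log BF scale (null over
    alternative; negative L is evidence for a nonzero loading)."""

    L: float
    bf: float
    category: EvidenceCategory
    tested_loading: Center
    split: SplitSpec
    mc_error: float
    prior_level: str = "default"


def classify_evidence(L: float) -> EvidenceCategory:
    """Map L = 2 log BF to its evidence category (thresholds -2 and -6)."""
    if not math.isfinite(L):
        raise ValueError("L must be finite")
    if L <= -6.0:
        return EvidenceCategory.STRONG
    if L <= -2.0:
        return EvidenceCategory.SIGNIFICANT
    return EvidenceCategory.NO_EVIDENCE


def split_cohort(cohort: Cohort, spec: SplitSpec) -> tuple[Cohort, Cohort]:
    """Disjoint, exhaustive, uniformly random learning/test split."""
    n = len(cohort)
    if spec.n_learning + spec.n_test != n:
        raise ValueError(
            f"split sizes {spec.n_learning}+{spec.n_test} != cohort size {n}"
        )
    perm = np.random.default_rng(spec.seed).permutation(n)
    return cohort.subset(perm[: spec.n_learning]), cohort.subset(perm[spec.n_learning :])


def _group_test_cohort(test: Cohort):
    """Collapse a test cohort to unique (center, age, pattern) cells with
    multiplicities; with per-attempt probabilities constant within a couple
    the likelihood depends on the history only through its pattern."""
    cells: dict[tuple, int] = {}
    for c in test:
        key = (c.center, c.age_class, history_pattern(c))
        cells[key] = cells.get(key, 0) + 1
    return cells


def predictive_log_marginal(
    test: Cohort,
    posterior: PosteriorSamples,
    quadrature_order: int = 20,
    max_draws: Optional[int] = None,
) -> tuple[float, float]:
    """Posterior-predictive log marginal likelihood of a test cohort.

    Averages, over retained posterior draws theta_t, the test cohort's
    latent-marginalized likelihood; the inner (f, eps) integral uses
    Gauss-Hermite product quadrature on standardized nodes (scaled per draw
    by the drawn sigma_f, sigma_eps), so the only Monte-Carlo error is the
    average over posterior draws.  Returns (log marginal, MC standard error
    of the log).
    """
    if len(test) == 0:
        raise ValueError("empty test cohort")
    draws = {k: v.reshape(-1) for k, v in posterior.draws.items()}
    T_all = next(iter(draws.values())).size
    if max_draws is not None and max_draws < T_all:
        sel = np.linspace(0, T_all - 1, max_draws).astype(int)
        draws = {k: v[sel] for k, v in draws.items()}
    T = next(iter(draws.values())).size

    from .model import _gh_nodes  # standardized nodes, sigma = 1

    xf, wf = _gh_nodes(1.0, quadrature_order)
    xe, we = _gh_nodes(1.0, quadrature_order)
    logW = np.log(np.outer(wf, we)).reshape(-1)  # (K,)
    Ff = np.repeat(xf, xe.size)  # (K,)
    Ee = np.tile(xe, xf.size)

    sf = draws.get("sigma_f", np.zeros(T))
    se = draws.get("sigma_eps", np.zeros(T))
    F = sf[:, None] * Ff[None, :]  # (T, K) latent f per draw/node
    E = se[:, None] * Ee[None, :]

    def d(name):
        return draws.get(name, np.zeros(T))

    total = np.zeros(T)
    for (center, age, (n_cont, outcome)), count in _group_test_cohort(test).items():
        age_key = age.value
        lin_s = d("alpha_succ").copy()
        lin_d = d("alpha_disc").copy()
        if age != AgeClass.A30_34:
            lin_s = lin_s + d(f"beta_age_succ[{age_key}]")
            lin_d = lin_d + d(f"beta_age_disc[{age_key}]")
        if center == Center.MIDCITY:
            lin_s = lin_s + d("beta_center_succ")
            lin_d = lin_d + d("beta_center_disc")
            lam = d("lambda_midcity")
        else:
            lam = d("lambda_paris")
        eta_s = lin_s[:, None] + F
        eta_d = lin_d[:, None] + lam[:, None] * F + E
        log_p = log_expit(eta_s)
        log_1mp = log_expit(-eta_s)
        log_pi = log_expit(eta_d)
        log_1mpi = log_expit(-eta_d)
        ll = n_cont * (log_1mp + log_1mpi)
        if outcome == "success":
            ll = ll + log_p
        elif outcome == "disc":
            ll = ll + log_1mp + log_pi
        else:  # censored: three continuations then a bare failure
            ll = ll + log_1mp
        total += count * logsumexp(ll + logW[None, :], axis=1)

    m = total.max()
    w = np.exp(total - m)
    log_ml = m + math.log(w.mean())
    se_log = float(w.std(ddof=1) / (math.sqrt(T) * w.mean())) if T > 1 else float("nan")
    return float(log_ml), se_log


def partial_bayes_factor(
    cohort: Cohort,
    tested: Center,
    spec: SplitSpec,
    prior: Optional[PriorConfig] = None,
    mcmc: Optional[MCMCConfig] = None,
    quadrature_order: int = 20,
    max_draws: Optional[int] = None,
    null_in_both: bool = False,
    sigma_eps: float | str = "free",
) -> BFResult:
    """Partial Bayes factor for lambda_tested = 0.

    Fits M1 (all loadings free) and M0 (the tested center's loading fixed
    at 0) on the learning sample with a common seed (common random numbers
    lower the variance of L), then compares posterior-predictive marginal
    likelihoods on the test sample: L = 2 (log m0 - log m1).
    ``null_in_both`` pins the loading in both models (a null-calibration
    hook: L should then vanish).  ``sigma_eps`` is forwarded to both fits;
    passing 0 runs the comparison in the no-disturbance model variant,
    where the null model cannot absorb loading-induced heterogeneity.
    """
    prior = prior or PriorConfig()
    mcmc = mcmc or MCMCConfig()
    learning, test = split_cohort(cohort, spec)
    fix0 = {tested: 0.0}
    fix1 = {tested: 0.0} if null_in_both else None
    post1 = fit_mcmc(learning, prior, mcmc, fix_lambda=fix1, sigma_eps=sigma_eps)
    post0 = fit_mcmc(learning, prior, mcmc, fix_lambda=fix0, sigma_eps=sigma_eps)
    log_m1, se1 = predictive_log_marginal(test, post1, quadrature_order, max_draws)
    log_m0, se0 = predictive_log_marginal(test, post0, quadrature_order, max_draws)
    L = 2.0 * (log_m0 - log_m1)
    mc_error = 2.0 * math.hypot(se0, se1)
    return BFResult(
        L=L,
        bf=math.exp(L / 2.0),
        category=classify_evidence(L),
        tested_loading=tested,
        split=spec,
        mc_error=mc_error,
        prior_level=prior.informativeness_level,
    )


class SensitivityReport(list):
    """List of BFResult with a stability flag: is the evidence category the
    same for every (prior, split) combination?"""

    @property
    def stable(self) -> bool:
        return len({r.category for r in self}) <= 1


def default_splits(n: int, seed: int = 0) -> list[SplitSpec]:
    """The three-way split design at cohort size n: the study's exact sizes
    when n = 3,002, otherwise the same learning fractions (90%, 50%, 17%)."""
    if n == 3002:
        return [SplitSpec(a, b, seed=seed + i) for i, (a, b) in enumerate(STUDY_SPLITS)]
    fracs = (0.9, 0.5, 1 / 6)
    out = []
    for i, fr in enumerate(fracs):
        nl = max(1, min(n - 1, round(n * fr)))
        out.append(SplitSpec(nl, n - nl, seed=seed + i))
    return out


def bf_sensitivity(
    cohort: Cohort,
    tested: Center,
    prior_variants: Optional[Sequence[PriorConfig]] = None,
    splits: Optional[Sequence[SplitSpec]] = None,
    mcmc: Optional[MCMCConfig] = None,
    quadrature_order: int = 20,
    max_draws: Optional[int] = None,
) -> SensitivityReport:
    """Partial Bayes factors across prior-informativeness variants and
    learning/test splits (defaults: base prior with sds scaled by 0.1x and
    10x; the three-way split design)."""
    if prior_variants is None:
        base = PriorConfig()
        prior_variants = [
            base.scaled(0.1, "more informative"),
            base,
            base.scaled(10.0, "less informative"),
        ]
    if splits is None:
        splits = default_splits(len(cohort))
    if not prior_variants or not splits:
        raise ValueError("need at least one prior variant and one split")
    report = SensitivityReport()
    for prior in prior_variants:
        for spec in splits:
            report.append(
                partial_bayes_factor(
                    cohort, tested, spec, prior, mcmc, quadrature_order, max_draws
                )
            )
    return report
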