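"""End-to-end orchestration: simulate (or load) a cohort, describe it, fit
the joint model, test the loadings, and render a report.

One master seed drives every random stage: stage seeds are drawn from a
``numpy.random.SeedSequence`` spawned per stage name, so reruns with the
same configuration are bit-for-bit identical and a stage can be re-executed
in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import Center, Cohort, read_cohort_csv, write_cohort_csv
from .descriptives import attempt_rates, baseline_table, cumulative_rates
from .model import PriorConfig
from .mcmc import MCMCConfig, fit_mcmc, or_summary
from .bayes_factor import BFResult, SplitSpec, default_splits, partial_bayes_factor

__all__ = ["AnalysisConfig", "run_analysis", "load_config"]

log = logging.getLogger("ivf_jointfx")

_OR_COEFFS = (
    "beta_center_succ",
    "beta_center_disc",
    "beta_age_succ[<25]",
    "beta_age_succ[25-29]",
    "beta_age_succ[35-39]",
    "beta_age_succ[>=40]",
    "beta_age_disc[<25]",
    "beta_age_disc[25-29]",
    "beta_age_disc[35-39]",
    "beta_age_disc[>=40]",
)


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run.  Exactly one of ``generator``
    (simulate a cohort) or ``cohort_path`` (load one) must be set."""

    generator: Optional[dict] = None
    cohort_path: Optional[str] = None
    prior: PriorConfig = field(default_factory=PriorConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    splits: Optional[Sequence[SplitSpec]] = None
    run_bf_tests: bool = True
    output_dir: str = "results"
    report_format: str = "markdown"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.cohort_path is None):
            raise ValueError("set exactly one of generator and cohort_path")
        if self.report_format not in ("text", "markdown"):
            raise ValueError("report_format must be 'text' or 'markdown'")
        if isinstance(self.prior, dict):
            self.prior = PriorConfig(**self.prior)
        if isinstance(self.mcmc, dict):
            self.mcmc = MCMCConfig(**self.mcmc)
        if self.splits is not None:
            self.splits = [
                s if isinstance(s, SplitSpec) else SplitSpec(**s) for s in self.splits
            ]

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return AnalysisConfig.from_dict(yaml.safe_load(fh))


def _stage_seeds(master: int, names: Sequence[str]) -> dict[str, int]:
    """Independent 31-bit stage seeds derived from the master seed."""
    root = np.random.SeedSequence(master)
    children = root.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        for name, child in zip(names, children)
    }


def _lambda_report(summary: pd.DataFrame, bf_results: Sequence[BFResult]) -> pd.DataFrame:
    rows = {}
    by_center = {r.tested_loading: r for r in bf_results}
    for center, name in ((Center.PARIS, "lambda_paris"), (Center.MIDCITY, "lambda_midcity")):
        s = summary.loc[name]
        r = by_center.get(center)
        rows[name] = {
            "posterior_mean": round(s["mean"], 2),
            "posterior_sd": round(s["sd"], 2),
            "ci_low": round(s["q2.5"], 1),
            "ci_high": round(s["q97.5"], 1),
            "L": round(r.L, 2) if r else np.nan,
            "category": r.category.value if r else "",
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full workflow, writing all artifacts under ``output_dir``.

    Returns a bundle with the cohort, rate tables, posterior summary,
    odds-ratio summaries, loading report and Bayes-factor results.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["simulate", "fit", "split"])
    bundle: dict = {}

    def stage(name):
        def deco(fn):
            try:
                log.info("stage %s: starting", name)
                return fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return deco

    @stage("cohort")
    def cohort() -> Cohort:
        if config.cohort_path is not None:
            path = Path(config.cohort_path)
            if not path.exists():
                raise FileNotFoundError(f"cohort file not found: {path}")
            return read_cohort_csv(path)
        from .simulate import GeneratorConfig, simulate_cohort

        gen = dict(config.generator)
        gen.setdefault("seed", seeds["simulate"])
        c = simulate_cohort(GeneratorConfig.from_dict(gen))
        write_cohort_csv(c, out / "cohort.csv")
        return c

    bundle["cohort"] = cohort

    @stage("descriptives")
    def descr():
        rates = attempt_rates(cohort)
        cum = cumulative_rates(cohort)
        base = baseline_table(cohort)
        rates.table.to_csv(out / "attempt_rates.csv", index=False)
        cum.to_csv(out / "cumulative_rates.csv")
        base.percent.to_csv(out / "baseline_age_table.csv")
        return rates, cum, base

    bundle["attempt_rates"], bundle["cumulative_rates"], bundle["baseline"] = descr

    @stage("fit")
    def fit():
        mcmc = MCMCConfig(
            n_chains=config.mcmc.n_chains,
            n_iterations=config.mcmc.n_iterations,
            burn_in=config.mcmc.burn_in,
            thin=config.mcmc.thin,
            seed=seeds["fit"],
            init_spread=config.mcmc.init_spread,
        )
        post = fit_mcmc(cohort, config.prior, mcmc)
        summary = post.summary()
        summary.to_csv(out / "posterior_summary.csv")
        post.to_dataframe().to_csv(out / "posterior_draws.csv", index=False)
        for name, r in post.rhat().items():
            log.info("R-hat %-22s %.3f", name, r)
        return post, summary

    bundle["posterior"], bundle["posterior_summary"] = fit

    @stage("or_summaries")
    def ors():
        rows = {}
        for coef in _OR_COEFFS:
            s = or_summary(bundle["posterior"], coef)
            rows[coef] = {f"q{p}": v for p, v in s.quantiles.items()} | {"mean": s.mean}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.to_csv(out / "odds_ratios.csv")
        return df

    bundle["odds_ratios"] = ors

    @stage("bf_tests")
    def bf():
        if not config.run_bf_tests:
            return []
        splits = config.splits or default_splits(len(cohort), seed=seeds["split"])
        results = []
        for center in (Center.PARIS, Center.MIDCITY):
            spec = splits[0]
            results.append(
                partial_bayes_factor(cohort, center, spec, config.prior, config.mcmc)
            )
        pd.DataFrame(
            [
                {
                    "center": r.tested_loading.value,
                    "L": r.L,
                    "bf": r.bf,
                    "category": r.category.value,
                    "mc_error": r.mc_error,
                    "n_learning": r.split.n_learning,
                    "n_test": r.split.n_test,
                }
                for r in results
            ]
        ).to_csv(out / "bf_results.csv", index=False)
        return results

    bundle["bf_results"] = bf

    @stage("report")
    def report():
        lam = _lambda_report(bundle["posterior_summary"], bundle["bf_results"])
        lam.to_csv(out / "lambda_report.csv")
        md = config.report_format == "markdown"
        lines = []
        h = (lambda s: f"## {s}") if md else (lambda s: s.upper())
        lines.append(h("Shared random-effects joint analysis"))
        lines.append(f"Couples: {len(cohort)}; seed: {config.seed}")
        lines.append(h("Center loadings (link between processes)"))
        lines.append(lam.to_string())
        lines.append(h("Cumulative rates"))
        lines.append(bundle["cumulative_rates"].round(1).to_string())
        lines.append(h("Odds ratios (posterior quantiles)"))
        lines.append(bundle["odds_ratios"].round(3).to_string())
        text = "\n\n".join(lines) + "\n"
        ext = "md" if md else "txt"
        (out / f"report.{ext}").write_text(text, encoding="utf-8")
        return text

    bundle["report"] = report
    bundle["lambda_report"] = _lambda_report(bundle["posterior_summary"], bundle["bf_results"])
    return bundle
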