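"""Descriptive layer: per-attempt and cumulative rates by center, the
baseline age table, and chi-square center comparisons.

Rate definitions follow the study conventions: the live-birth rate at
attempt j is live births among couples undergoing attempt j; the
discontinuation rate at attempt j is discontinuations among couples who
failed attempt j (attempts 1-3 only; attempt-4 failures are censored).
Percentages are reported in full precision internally and rounded half-up
to integers for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cohort import AgeClass, Center, Cohort, MAX_ATTEMPTS

__all__ = [
    "RateTable",
    "BaselineTable",
    "attempt_rates",
    "cumulative_rates",
    "center_comparison",
    "baseline_table",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal rounding with ties away from zero (the convention of the
    printed tables), unlike numpy's banker's rounding."""
    if np.isnan(x):
        return x
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class RateTable:
    """Per (center, attempt) live-birth and discontinuation rates with
    numerators and denominators.  ``table`` columns: center, attempt,
    live_birth_pct, live_birth_events, live_birth_at_risk, disc_pct,
    disc_events, disc_at_risk.  Rates are percentages; a zero denominator
    yields NaN (undefined)."""

    table: pd.DataFrame

    def rate(self, center: Center | str, attempt: int, kind: str = "live_birth") -> float:
        center = Center.parse(center) if isinstance(center, str) else center
        row = self.table[(self.table["center"] == center.value) & (self.table["attempt"] == attempt)]
        if row.empty:
            raise KeyError(f"no row for {center.value} attempt {attempt}")
        return float(row.iloc[0][f"{kind}_pct"])

    def rounded(self, decimals: int = 0) -> pd.DataFrame:
        out = self.table.copy()
        for col in ("live_birth_pct", "disc_pct"):
            out[col] = out[col].map(lambda v: round_half_up(v, decimals))
        return out


@dataclass
class BaselineTable:
    """Age-class distribution by center: percentages (columns sum to 100 up
    to rounding), raw counts, and the Pearson chi-square comparison."""

    percent: pd.DataFrame
    counts: pd.DataFrame
    chi2: float
    pvalue: float


def attempt_rates(cohort: Cohort) -> RateTable:
    """Observed per-attempt rates by center (full-precision percentages)."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    for center in Center:
        at_risk = np.zeros(MAX_ATTEMPTS, dtype=int)
        births = np.zeros(MAX_ATTEMPTS, dtype=int)
        failures = np.zeros(MAX_ATTEMPTS, dtype=int)
        discs = np.zeros(MAX_ATTEMPTS, dtype=int)
        for c in cohort:
            if c.center != center:
                continue
            for a in c.attempts:
                j = a.attempt_index - 1
                at_risk[j] += 1
                if a.success == 1:
                    births[j] += 1
                else:
                    failures[j] += 1
                    if a.discontinued == 1:
                        discs[j] += 1
        for j in range(MAX_ATTEMPTS):
            lb_pct = 100.0 * births[j] / at_risk[j] if at_risk[j] else np.nan
            last = j == MAX_ATTEMPTS - 1  # attempt-4 failures are censored
            disc_pct = np.nan if last or failures[j] == 0 else 100.0 * discs[j] / failures[j]
            rows.append(
                {
                    "center": center.value,
                    "attempt": j + 1,
                    "live_birth_pct": lb_pct,
                    "live_birth_events": births[j],
                    "live_birth_at_risk": at_risk[j],
                    "disc_pct": disc_pct,
                    "disc_events": np.nan if last else discs[j],
                    "disc_at_risk": np.nan if last else failures[j],
                }
            )
    return RateTable(pd.DataFrame(rows))


def cumulative_rates(cohort: Cohort) -> pd.DataFrame:
    """Cumulative (over up to four attempts) live-birth and discontinuation
    percentages, by center and overall.  A couple counts as a cumulative
    discontinuation when its final record has discontinued = 1."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = {}
    groups: dict[str, list] = {c.value: [] for c in Center}
    for c in cohort:
        groups[c.center.value].append(c)
    groups["overall"] = list(cohort)
    for label, couples in groups.items():
        n = len(couples)
        s = sum(1 for c in couples if c.succeeded)
        d = sum(1 for c in couples if c.discontinued)
        rows[label] = {
            "n": n,
            "live_births": s,
            "live_birth_pct": 100.0 * s / n if n else np.nan,
            "discontinuations": d,
            "disc_pct": 100.0 * d / n if n else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def center_comparison(counts) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2 x K table of
    counts; p-value from the chi-square distribution with K-1 df."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("need a 2-D table with at least 2 columns")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row or column total")
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    stat = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, float(chi2.sf(stat, df))


def baseline_table(cohort: Cohort) -> BaselineTable:
    """Age-class distribution at the first attempt by center, with the
    Pearson comparison of the two centers."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    counts = pd.DataFrame(
        0, index=[a.value for a in AgeClass], columns=[c.value for c in Center], dtype=int
    )
    for c in cohort:
        counts.loc[c.age_class.value, c.center.value] += 1
    percent = 100.0 * counts / counts.sum(axis=0)
    nonzero_rows = counts.loc[counts.sum(axis=1) > 0]
    # the comparison needs both centers and >= 2 occupied age classes
    if nonzero_rows.shape[0] >= 2 and (counts.sum(axis=0) > 0).all():
        stat, p = center_comparison(nonzero_rows.to_numpy().T)
    else:
        stat, p = np.nan, np.nan
    return BaselineTable(percent=percent, counts=counts, chi2=stat, pvalue=p)
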