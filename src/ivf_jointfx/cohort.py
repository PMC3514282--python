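"""Cohort domain types, attempt-history validation and CSV I/O.

The unit of observation is a couple followed over up to four IVF attempts
(oocyte aspirations).  Each attempt yields a live-birth indicator; among
failed attempts 1-3 a discontinuation indicator records whether the couple
returned for another attempt.  Failures at attempt 4 are administratively
censored: no discontinuation outcome is observable because follow-up stops
after the fourth aspiration.

The on-disk format is a long CSV, one row per couple-attempt, with columns
``couple_id, center, age_class, attempt, success, discontinued``.
Discontinuation is recorded on the row of the failed attempt after which the
couple did not return; the censored attempt-4 failure leaves the field empty.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "AgeClass",
    "Center",
    "AttemptRecord",
    "CoupleHistory",
    "Cohort",
    "MAX_ATTEMPTS",
    "validate_history",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: Administrative limit: data collection stops after the fourth aspiration.
MAX_ATTEMPTS = 4


class Center(str, Enum):
    """IVF center; PARIS is the reference level for effect coding."""

    PARIS = "PARIS"
    MIDCITY = "MIDCITY"

    @classmethod
    def parse(cls, label: str) -> "Center":
        try:
            return cls(label.strip().upper())
        except ValueError:
            raise ValueError(f"unknown center label {label!r}") from None


class AgeClass(str, Enum):
    """Woman's age class at the first attempt; "30-34" is the reference."""

    LT25 = "<25"
    A25_29 = "25-29"
    A30_34 = "30-34"
    A35_39 = "35-39"
    GE40 = ">=40"

    @classmethod
    def parse(cls, label: str) -> "AgeClass":
        s = label.strip()
        # "17-24" is how the youngest class is printed in baseline tables.
        s = {"17-24": "<25", "≥40": ">=40", "≥ 40": ">=40"}.get(s, s)
        try:
            return cls(s)
        except ValueError:
            raise ValueError(f"unknown age class label {label!r}") from None


#: Reference levels used for effect coding throughout the package.
REFERENCE_CENTER = Center.PARIS
REFERENCE_AGE = AgeClass.A30_34

#: Non-reference age classes, in display order.
NONREF_AGE_CLASSES = (AgeClass.LT25, AgeClass.A25_29, AgeClass.A35_39, AgeClass.GE40)


@dataclass(frozen=True)
class AttemptRecord:
    """One IVF attempt: its index (1-4), success, and - among failures at
    attempts 1-3 - whether the couple discontinued afterwards (None when
    unobservable: after a success, or for a censored attempt-4 failure)."""

    attempt_index: int
    success: int
    discontinued: Optional[int] = None


@dataclass(frozen=True)
class CoupleHistory:
    """A couple's covariates and ordered attempt outcomes."""

    couple_id: str
    center: Center
    age_class: AgeClass
    attempts: tuple[AttemptRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "attempts", tuple(self.attempts))

    @property
    def succeeded(self) -> bool:
        return any(a.success == 1 for a in self.attempts)

    @property
    def discontinued(self) -> bool:
        return bool(self.attempts) and self.attempts[-1].discontinued == 1


@dataclass
class Cohort:
    """A list of couple histories with unique ids."""

    couples: list[CoupleHistory] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.couples)

    def __iter__(self) -> Iterator[CoupleHistory]:
        return iter(self.couples)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Cohort) and self.couples == other.couples

    def subset(self, indices: Iterable[int]) -> "Cohort":
        return Cohort([self.couples[i] for i in indices])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Cohort":
        """Build (and validate) a cohort from a long-format frame with the
        CSV columns; missing discontinued may be NA, None or empty string."""
        couples = []
        for cid, grp in df.groupby("couple_id", sort=False):
            rows = []
            for _, r in grp.iterrows():
                disc = r["discontinued"]
                if disc is None or (isinstance(disc, str) and disc.strip() == "") or pd.isna(disc):
                    disc = None
                else:
                    disc = int(disc)
                rows.append(
                    {
                        "center": Center.parse(str(r["center"])),
                        "age_class": AgeClass.parse(str(r["age_class"])),
                        "attempt": int(r["attempt"]),
                        "success": int(r["success"]),
                        "discontinued": disc,
                    }
                )
            history = _history_from_rows(str(cid), rows)
            violations = validate_history(history)
            if violations:
                raise CohortValidationError(f"couple {cid!r}: " + "; ".join(violations))
            couples.append(history)
        return cls(couples)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format, one row per couple-attempt; missing discontinued is NA."""
        rows = []
        for c in self.couples:
            for a in c.attempts:
                rows.append(
                    {
                        "couple_id": c.couple_id,
                        "center": c.center.value,
                        "age_class": c.age_class.value,
                        "attempt": a.attempt_index,
                        "success": a.success,
                        "discontinued": a.discontinued,
                    }
                )
        df = pd.DataFrame(rows, columns=["couple_id", "center", "age_class", "attempt", "success", "discontinued"])
        df["discontinued"] = df["discontinued"].astype("Int64")
        return df


def validate_history(history: CoupleHistory) -> list[str]:
    """Check a couple history against the observation-scheme invariants.

    Returns one human-readable entry per violated invariant (empty list when
    the history is valid).  Violations are returned rather than raised so
    that callers can report all problems for a couple at once.
    """
    v: list[str] = []
    attempts = history.attempts
    if not attempts:
        return ["history has no attempt records"]
    if len(attempts) > MAX_ATTEMPTS:
        v.append(f"more than {MAX_ATTEMPTS} attempts")
    if [a.attempt_index for a in attempts] != list(range(1, len(attempts) + 1)):
        v.append("non-consecutive attempt indices (must run 1..k)")
    for a in attempts[:-1]:
        if a.success == 1:
            v.append("record after success (a live birth must be the final record)")
            break
    for a in attempts[:-1]:
        if a.discontinued == 1:
            v.append("record after discontinuation (discontinuation must be final)")
            break
    last = attempts[-1]
    for a in attempts:
        if a.success not in (0, 1):
            v.append(f"attempt {a.attempt_index}: success must be 0 or 1")
        if a.discontinued not in (0, 1, None):
            v.append(f"attempt {a.attempt_index}: discontinued must be 0, 1 or missing")
        if a.success == 1 and a.discontinued is not None:
            v.append(f"attempt {a.attempt_index}: discontinued must be missing after a live birth")
        if a.success == 0 and a.attempt_index == MAX_ATTEMPTS and a.discontinued is not None:
            v.append("attempt 4 failure is censored: discontinued must be missing")
        if (
            a.success == 0
            and a.attempt_index < MAX_ATTEMPTS
            and a.discontinued is None
        ):
            v.append(f"attempt {a.attempt_index}: failed non-censored attempt needs a discontinuation outcome")
    if last.success == 0 and last.discontinued == 0 and last.attempt_index < MAX_ATTEMPTS:
        v.append("continuing failure must be followed by another attempt")
    return v


class CohortValidationError(ValueError):
    """A couple history violates the observation-scheme invariants."""


class CohortParseError(ValueError):
    """A CSV row could not be parsed."""


def _history_from_rows(couple_id: str, rows: list[dict]) -> CoupleHistory:
    rows = sorted(rows, key=lambda r: r["attempt"])
    center = rows[0]["center"]
    age = rows[0]["age_class"]
    for r in rows:
        if r["center"] != center or r["age_class"] != age:
            raise CohortValidationError(
                f"couple {couple_id!r}: center/age_class differ across rows"
            )
    attempts = tuple(
        AttemptRecord(r["attempt"], r["success"], r["discontinued"]) for r in rows
    )
    return CoupleHistory(couple_id, center, age, attempts)


def read_cohort_csv(path: str | Path) -> Cohort:
    """Read a long-format cohort CSV, validating every couple history.

    Raises :class:`CohortParseError` with the offending line number on
    malformed rows and :class:`CohortValidationError` naming the couple on
    invariant breaches.
    """
    path = Path(path)
    required = ["couple_id", "center", "age_class", "attempt", "success", "discontinued"]
    by_couple: dict[str, list[dict]] = {}
    order: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(required) <= set(reader.fieldnames):
            raise CohortParseError(f"{path}: header must contain columns {required}")
        for lineno, row in enumerate(reader, start=2):
            try:
                center = Center.parse(row["center"])
                age = AgeClass.parse(row["age_class"])
                attempt = int(row["attempt"])
                success = int(row["success"])
                disc_raw = (row["discontinued"] or "").strip()
                disc = None if disc_raw == "" else int(disc_raw)
            except (ValueError, TypeError, KeyError) as exc:
                raise CohortParseError(f"{path}:{lineno}: {exc}") from None
            if success not in (0, 1) or disc not in (0, 1, None):
                raise CohortParseError(
                    f"{path}:{lineno}: success/discontinued must be 0/1 (or empty)"
                )
            cid = row["couple_id"]
            if cid not in by_couple:
                by_couple[cid] = []
                order.append(cid)
            by_couple[cid].append(
                {"center": center, "age_class": age, "attempt": attempt, "success": success, "discontinued": disc}
            )
    couples = []
    for cid in order:
        history = _history_from_rows(cid, by_couple[cid])
        violations = validate_history(history)
        if violations:
            raise CohortValidationError(f"couple {cid!r}: " + "; ".join(violations))
        couples.append(history)
    return Cohort(couples)


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to long CSV (UTF-8, comma, 0/1 binaries, empty = missing)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["couple_id", "center", "age_class", "attempt", "success", "discontinued"])
        for c in cohort:
            for a in c.attempts:
                writer.writerow(
                    [
                        c.couple_id,
                        c.center.value,
                        c.age_class.value,
                        a.attempt_index,
                        a.success,
                        "" if a.discontinued is None else a.discontinued,
                    ]
                )
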