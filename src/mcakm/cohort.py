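"""Claims-based cohort construction for the young-lung-cancer study design.

Selects newly diagnosed lung-cancer patients aged 20-39 at first
diagnosis within the 2001-2007 index window, drops patients with any
baseline psychiatric code (depression, anxiety, bipolar or
alcohol-induced disorder sets) during 2001, and codes the depression
and anxiety outcomes as "Yes" only when at least three matching
diagnoses on distinct dates follow the index visit — the confirmation
rule guarding against single false-positive psychiatric codes.

ICD-9-CM code sets are shipped as a JSON registry.  Pattern syntax:
a trailing ``X`` is a wildcard character, a bare prefix matches every
extension (``162`` matches ``162``, ``162.3``, ``162.31``) and a range
such as ``296.2X-296.3X`` expands to its explicit list of prefixes.
Matching ignores the dot separator.
"""

from __future__ import annotations

import datetime
import json
import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "CodeSet",
    "CohortCriteria",
    "match_code",
    "expand_pattern",
    "load_codesets",
    "build_cohort",
    "read_claims_csv",
]

_PATTERN_RE = re.compile(r"^[VE]?\d+(\.\d*)?$")
_BASELINE_EXCLUSION_SETS = ("depression", "anxiety", "bipolar", "alcohol_induced")
_OUTCOME_SETS = ("depression", "anxiety")


def _normalize(code: str) -> str:
    return code.replace(".", "").strip().upper()


def expand_pattern(pattern: str) -> list[str]:
    """Expand one registry pattern to a list of normalized code prefixes.

    >>> expand_pattern("296.2X-296.3X")
    ['2962', '2963']
    >>> expand_pattern("571.0-571.3")
    ['5710', '5711', '5712', '5713']
    """
    pattern = pattern.strip().replace("–", "-")
    if "-" in pattern:
        lo, hi = (p.strip() for p in pattern.split("-", 1))
        lo, hi = lo.rstrip("X"), hi.rstrip("X")
        if not (_PATTERN_RE.match(lo) and _PATTERN_RE.match(hi)):
            raise ValueError(f"malformed ICD-9 range pattern {pattern!r}")
        lo_n, hi_n = _normalize(lo), _normalize(hi)
        if len(lo_n) != len(hi_n) or lo_n[:-1] != hi_n[:-1]:
            raise ValueError(
                f"range pattern {pattern!r} endpoints must differ in their last digit only"
            )
        first, last = int(lo_n[-1]), int(hi_n[-1])
        if first > last:
            raise ValueError(f"range pattern {pattern!r} is descending")
        return [lo_n[:-1] + str(d) for d in range(first, last + 1)]
    bare = pattern.rstrip("X").rstrip(".")
    if not bare or not _PATTERN_RE.match(bare):
        raise ValueError(f"malformed ICD-9 pattern {pattern!r}")
    return [_normalize(bare)]


@dataclass(frozen=True)
class CodeSet:
    """A named set of ICD-9-CM patterns, expanded and validated at load time."""

    name: str
    patterns: tuple[str, ...]
    prefixes: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"code set {self.name!r} has no patterns")
        expanded: list[str] = []
        for p in self.patterns:
            expanded.extend(expand_pattern(p))
        object.__setattr__(self, "prefixes", tuple(expanded))


def match_code(code: str, codeset: CodeSet) -> bool:
    """True iff the (dot-insensitive) code falls under any pattern prefix."""
    if not code or not str(code).strip():
        raise ValueError("empty ICD-9 code")
    norm = _normalize(str(code))
    return any(norm.startswith(prefix) for prefix in codeset.prefixes)


def load_codesets() -> dict[str, CodeSet]:
    """The packaged ICD-9-CM registry for the study's case/exclusion sets."""
    text = resources.files("mcakm.data").joinpath("icd9_codesets.json").read_text()
    raw = json.loads(text)
    return {name: CodeSet(name, tuple(patterns)) for name, patterns in raw.items()}


@dataclass(frozen=True)
class CohortCriteria:
    """Eligibility windows and thresholds for cohort construction.

    ``min_confirmations`` is the number of distinct-date diagnoses after
    the index visit needed to code an outcome as present (default 3).
    ``max_gap_days`` optionally requires those dates to form a run with
    no gap exceeding the limit; by default any 3+ distinct dates qualify,
    since the confirmation sequence has no stated maximum spacing.
    """

    age_range: tuple[int, int] = (20, 39)
    index_window: tuple[datetime.date, datetime.date] = (
        datetime.date(2001, 1, 1),
        datetime.date(2007, 12, 31),
    )
    exclusion_window: tuple[datetime.date, datetime.date] = (
        datetime.date(2001, 1, 1),
        datetime.date(2001, 12, 31),
    )
    min_confirmations: int = 3
    max_gap_days: int | None = None

    def __post_init__(self) -> None:
        if self.min_confirmations < 1:
            raise ValueError("min_confirmations must be >= 1")
        for lo, hi in (self.index_window, self.exclusion_window):
            if lo > hi:
                raise ValueError("invalid date window")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("invalid age range")


def _age_at(birth: datetime.date, when: datetime.date) -> int:
    return when.year - birth.year - ((when.month, when.day) < (birth.month, birth.day))


def _confirmed(dates: list[datetime.date], criteria: CohortCriteria) -> bool:
    if len(dates) < criteria.min_confirmations:
        return False
    if criteria.max_gap_days is None:
        return True
    run = 1
    for prev, cur in zip(dates, dates[1:]):
        run = run + 1 if (cur - prev).days <= criteria.max_gap_days else 1
        if run >= criteria.min_confirmations:
            return True
    return run >= criteria.min_confirmations


def build_cohort(
    claims: pd.DataFrame,
    birthdates: dict[str, datetime.date],
    criteria: CohortCriteria | None = None,
    codesets: dict[str, CodeSet] | None = None,
    censoring: dict[str, datetime.date] | None = None,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the eligibility and confirmation rules to a claims table.

    Parameters
    ----------
    claims
        Long-format table with columns patient_id, visit_date, icd9
        (order of rows irrelevant; any extra columns ignored).
    birthdates
        patient_id -> date of birth.  Patients without one are logged
        as unresolvable rather than silently dropped.
    censoring
        Optional patient_id -> death/withdrawal date; patients censored
        on or before the end of the index window are excluded.
    covariates
        Optional precomputed categorical columns (indexed by
        patient_id) joined onto the retained cohort.

    Returns
    -------
    (cohort, exclusion_log)
        ``cohort`` has one row per retained patient with outcome columns
        ``depression``/``anxiety`` coded Yes/No; ``exclusion_log`` has
        columns patient_id, reason with exactly one row per dropped
        patient.  Every input patient appears in exactly one of the two.
    """
    criteria = criteria or CohortCriteria()
    codesets = codesets or load_codesets()
    censoring = censoring or {}
    for required in ("lung_cancer",) + _OUTCOME_SETS:
        if required not in codesets:
            raise ValueError(f"missing required code set {required!r}")

    claims = claims.copy()
    if len(claims):
        claims["visit_date"] = pd.to_datetime(claims["visit_date"]).dt.date
    claims = claims.sort_values(["patient_id", "visit_date", "icd9"], kind="stable")

    retained_rows: list[dict] = []
    log_rows: list[dict] = []
    lo_age, hi_age = criteria.age_range

    for pid, visits in claims.groupby("patient_id", sort=True):
        if pid not in birthdates:
            log_rows.append({"patient_id": pid, "reason": "missing_birthdate"})
            continue
        dates = list(visits["visit_date"])
        codes = list(visits["icd9"].astype(str))

        lung_dates = [
            d for d, c in zip(dates, codes) if match_code(c, codesets["lung_cancer"])
        ]
        if not lung_dates:
            log_rows.append({"patient_id": pid, "reason": "no_lung_cancer_diagnosis"})
            continue
        index_date = min(lung_dates)
        if not criteria.index_window[0] <= index_date <= criteria.index_window[1]:
            log_rows.append({"patient_id": pid, "reason": "index_outside_window"})
            continue
        age = _age_at(birthdates[pid], index_date)
        if not lo_age <= age <= hi_age:
            log_rows.append({"patient_id": pid, "reason": "age_out_of_range"})
            continue

        baseline_reason = None
        for set_name in _BASELINE_EXCLUSION_SETS:
            cs = codesets.get(set_name)
            if cs is None:
                continue
            if any(
                criteria.exclusion_window[0] <= d <= criteria.exclusion_window[1]
                and match_code(c, cs)
                for d, c in zip(dates, codes)
            ):
                baseline_reason = f"baseline_{set_name}"
                break
        if baseline_reason:
            log_rows.append({"patient_id": pid, "reason": baseline_reason})
            continue

        if pid in censoring and censoring[pid] <= criteria.index_window[1]:
            log_rows.append({"patient_id": pid, "reason": "died_or_withdrew"})
            continue

        row = {"patient_id": pid, "age_at_index": age, "index_date": index_date}
        for outcome in _OUTCOME_SETS:
            cs = codesets[outcome]
            confirm_dates = sorted(
                {d for d, c in zip(dates, codes) if d > index_date and match_code(c, cs)}
            )
            row[outcome] = "Yes" if _confirmed(confirm_dates, criteria) else "No"
        retained_rows.append(row)

    cohort = pd.DataFrame(
        retained_rows,
        columns=["patient_id", "age_at_index", "index_date", *_OUTCOME_SETS],
    ).set_index("patient_id")
    log = pd.DataFrame(log_rows, columns=["patient_id", "reason"])
    if covariates is not None and len(cohort):
        cohort = cohort.join(covariates, how="left")
    return cohort, log


def read_claims_csv(path) -> pd.DataFrame:
    claims = pd.read_csv(path, dtype={"patient_id": str, "icd9": str})
    claims["visit_date"] = pd.to_datetime(claims["visit_date"]).dt.date
    return claims
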