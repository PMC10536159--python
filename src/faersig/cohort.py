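"""Target-drug exposure flagging, date-window filtering and descriptive summaries.

Exposure follows the spontaneous-report convention: a case is "exposed" when
any of its drug rows carries an accepted role code (by default PS, primary
suspect) and its free-text drug name contains one of the configured target
synonyms as a whole word — FAERS drug names are uncurated, so salts and
brand names ("EPIRUBICIN HYDROCHLORIDE", "ELLENCE") must match via
substrings, not exact equality.
"""

from __future__ import annotations

import dataclasses
import logging
import re

import numpy as np
import pandas as pd

from ._util import normalize_term, quarter_bounds
from .faers_io import CaseSet

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_BIN_LABELS",
    "ExposureCohort",
    "DemographicsSummary",
    "convert_age",
    "flag_exposure",
    "apply_window",
    "summarize",
]

#: FAERS age unit codes → factor converting to years.
_AGE_FACTORS = {"DEC": 10.0, "YR": 1.0, "MON": 1 / 12, "WK": 1 / 52.18, "DY": 1 / 365.25, "HR": 1 / 8766}

_AGE_EDGES = [0, 20, 30, 40, 50, 60, 70, 80, np.inf]
AGE_BIN_LABELS = ["<20", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79", ">=80"]

#: Serious-outcome codes reported in the descriptive block.
_SERIOUS = [("DE", "Death"), ("DS", "Disability"), ("HO", "Hospitalization"), ("LT", "Life-threatening")]


def convert_age(value, unit_code) -> float | None:
    """Convert a FAERS (age, age_cod) pair to years.

    DEC is decades, YR years, MON months, WK weeks, DY days, HR hours.
    Unknown code, null or negative value → None (negatives warn).
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    factor = _AGE_FACTORS.get(str(unit_code).strip().upper())
    if factor is None:
        return None
    value = float(value)
    if value < 0:
        logger.warning("convert_age: negative age %r ignored", value)
        return None
    return value * factor


def _ages_in_years(demo: pd.DataFrame) -> pd.Series:
    factors = demo["age_cod"].map(_AGE_FACTORS)
    years = demo["age"] * factors
    return years.where(demo["age"] >= 0)


@dataclasses.dataclass
class ExposureCohort:
    """A deduplicated case set together with the target-exposed subset."""

    case_set: CaseSet
    exposed_ids: frozenset
    target_synonyms: tuple
    role_filter: frozenset

    def __post_init__(self):
        if not self.role_filter:
            raise ValueError("role_filter must be non-empty")

    @property
    def n_cases(self) -> int:
        return len(self.case_set)

    @property
    def n_exposed(self) -> int:
        return len(self.exposed_ids)

    def exposed_mask(self, caseids: pd.Series) -> np.ndarray:
        return caseids.isin(self.exposed_ids).to_numpy()


def flag_exposure(case_set: CaseSet, synonyms, role_filter=("PS",)) -> ExposureCohort:
    """Mark cases listing the target drug with an accepted role.

    Matching is case-insensitive word-boundary substring on the normalized
    drug name, against any synonym.
    """
    synonyms = tuple(synonyms)
    if not synonyms:
        raise ValueError("synonyms must be non-empty")
    roles = frozenset(r.strip().upper() for r in role_filter)
    pattern = re.compile("|".join(rf"\b{re.escape(normalize_term(s))}\b" for s in synonyms))

    drug = case_set.drug
    in_role = drug["role_cod"].isin(roles)
    candidates = drug.loc[in_role, ["primaryid", "drugname_norm"]]
    # match unique names once, then broadcast
    uniq = candidates["drugname_norm"].unique()
    hit_names = {n for n in uniq if pattern.search(n)}
    hits = candidates[candidates["drugname_norm"].isin(hit_names)]
    exposed = frozenset(case_set.case_of(hits).astype(int))
    logger.info("flag_exposure: %d/%d cases exposed (roles=%s)", len(exposed), len(case_set), sorted(roles))
    return ExposureCohort(case_set, exposed, synonyms, roles)


def apply_window(cohort: ExposureCohort, start_quarter: str, end_quarter: str) -> ExposureCohort:
    """Restrict to cases received within [start_quarter, end_quarter] (inclusive).

    Quarters are ``YYYYQn`` strings.  Cases with a null receipt date are
    dropped, with a logged count.
    """
    start, _ = quarter_bounds(start_quarter)
    _, end = quarter_bounds(end_quarter)
    if start > end:
        raise ValueError(f"window start {start_quarter} after end {end_quarter}")
    demo = cohort.case_set.demo
    dt = demo["fda_dt"]
    n_null = int(dt.isna().sum())
    if n_null:
        logger.info("apply_window: dropping %d cases with null receipt date", n_null)
    keep = demo.loc[(dt >= pd.Timestamp(start)) & (dt <= pd.Timestamp(end)), "caseid"]
    subset = cohort.case_set.subset(keep)
    return ExposureCohort(
        subset,
        frozenset(cohort.exposed_ids & set(keep)),
        cohort.target_synonyms,
        cohort.role_filter,
    )


@dataclasses.dataclass
class DemographicsSummary:
    """Descriptive summary of the exposed cases (counts and percentages).

    Percentages use the total exposed-case count as denominator and are
    reported to two decimals; with zero cases they are None.  A case lands in
    exactly one sex bin, one age bin and one country, but may contribute to
    several serious-outcome categories (they are not mutually exclusive).
    """

    n_events: int
    sex_counts: dict
    age_counts: dict
    country_counts: dict  # ranked descending
    outcome_counts: dict  # Death / Disability / Hospitalization / Life-threatening
    other_outcome_counts: dict  # CA / RI / OT, kept for completeness

    def pct(self, count: int) -> float | None:
        if self.n_events == 0:
            return None
        return round(100.0 * count / self.n_events, 2)

    def to_frame(self) -> pd.DataFrame:
        rows = [("Number of events", "Total", self.n_events, None)]
        for section, counts in (
            ("Gender", self.sex_counts),
            ("Age", self.age_counts),
            ("Reported countries", self.country_counts),
            ("Serious outcomes", self.outcome_counts),
        ):
            for label, count in counts.items():
                rows.append((section, label, count, self.pct(count)))
        return pd.DataFrame(rows, columns=["section", "label", "count", "percent"])


def summarize(cohort: ExposureCohort) -> DemographicsSummary:
    """Tabulate sex, age bins, countries and serious outcomes of exposed cases."""
    cs = cohort.case_set
    demo = cs.demo[cs.demo["caseid"].isin(cohort.exposed_ids)]
    n = len(demo)

    sex = demo["sex"].map({"M": "Male", "F": "Female"}).fillna("Unknown")
    sex = sex.where(demo["sex"].isin(["M", "F"]), "Unknown")
    sex_counts = {k: int((sex == k).sum()) for k in ["Male", "Female", "Unknown"]}

    years = _ages_in_years(demo)
    binned = pd.cut(years, bins=_AGE_EDGES, labels=AGE_BIN_LABELS, right=False)
    age_counts = {lab: int((binned == lab).sum()) for lab in AGE_BIN_LABELS}
    age_counts["Unknown"] = int(binned.isna().sum())

    country = demo["occr_country"].replace("", "Unknown")
    vc = country.value_counts()
    country_counts = {str(k): int(v) for k, v in vc.items()}

    outc = cs.outc[cs.outc["primaryid"].isin(demo["primaryid"])]
    pairs = outc.drop_duplicates(["primaryid", "outc_cod"])
    code_counts = pairs["outc_cod"].value_counts()
    outcome_counts = {label: int(code_counts.get(code, 0)) for code, label in _SERIOUS}
    other = {c: int(code_counts.get(c, 0)) for c in ["CA", "RI", "OT"]}

    return DemographicsSummary(n, sex_counts, age_counts, country_counts, outcome_counts, other)
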