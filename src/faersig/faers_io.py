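"""Reading, writing and deduplicating FAERS-style quarterly ASCII tables.

The FDA Adverse Event Reporting System publishes each quarter as a set of
``$``-delimited ASCII tables.  This module handles the four tables the
disproportionality analysis needs:

* ``DEMO`` — one row per report version: demographics and receipt date,
* ``DRUG`` — the drugs on each report with their role codes (PS/SS/C/I),
* ``REAC`` — the MedDRA preferred terms (PTs) reported,
* ``OUTC`` — the outcome codes (DE, LT, HO, DS, CA, RI, OT).

A safety report ("case") may be submitted several times; every submission
shares the ``caseid`` but gets a fresh ``primaryid`` and an incremented
``caseversion``.  :func:`deduplicate_cases` collapses these to one current
record per case using the FDA-recommended rule: keep the highest
``caseversion``, break ties by latest ``fda_dt`` (missing dates sort first),
then by highest ``primaryid``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import normalize_term

logger = logging.getLogger(__name__)

__all__ = [
    "Dialect",
    "RawRecordSet",
    "ReportCase",
    "CaseSet",
    "SchemaError",
    "read_quarter",
    "write_quarter",
    "deduplicate_cases",
    "concat_raw",
]

DEMO_COLUMNS = ["primaryid", "caseid", "caseversion", "fda_dt", "age", "age_cod", "sex", "occr_country"]
DRUG_COLUMNS = ["primaryid", "drug_seq", "drugname", "role_cod"]
REAC_COLUMNS = ["primaryid", "pt"]
OUTC_COLUMNS = ["primaryid", "outc_cod"]

_DEMO_REQUIRED = ["primaryid", "caseid", "caseversion"]


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


@dataclasses.dataclass(frozen=True)
class Dialect:
    """Field layout of the quarterly tables.

    FAERS convention is ``$`` with no quoting; tab or comma are accepted for
    hand-written fixtures.
    """

    delimiter: str = "$"
    encoding: str = "utf-8"


@dataclasses.dataclass
class RawRecordSet:
    """The four raw tables of one (or several concatenated) quarters.

    Each attribute is a :class:`pandas.DataFrame` with the fixed column sets
    in :data:`DEMO_COLUMNS` etc.  ``fda_dt`` is datetime64 (NaT when
    unparseable), ``age`` float (NaN when unparseable); text fields keep
    ``""`` for blanks.  ``warnings`` counts skipped/coerced input lines.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    warnings: dict = dataclasses.field(default_factory=dict)

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    @property
    def n_cases(self) -> int:
        return self.demo["caseid"].nunique()


@dataclasses.dataclass(frozen=True)
class ReportCase:
    """One deduplicated safety report."""

    caseid: int
    primaryid: int
    receipt_date: dt.date | None
    age_years: float | None
    sex: str
    country: str
    drugs: tuple  # of (normalized drug name, role_cod)
    reactions: frozenset  # of PT strings as reported
    outcomes: frozenset  # of outcome codes


class CaseSet:
    """Deduplicated reports, one per caseid, held as columnar tables.

    Keeps the same four-frame layout as :class:`RawRecordSet` (restricted to
    the surviving ``primaryid`` per case) so downstream aggregation stays
    vectorised; :meth:`to_report_cases` materialises per-case objects when
    convenient.
    """

    def __init__(self, demo: pd.DataFrame, drug: pd.DataFrame, reac: pd.DataFrame, outc: pd.DataFrame):
        self.demo = demo.reset_index(drop=True)
        self.drug = drug.reset_index(drop=True)
        self.reac = reac.reset_index(drop=True)
        self.outc = outc.reset_index(drop=True)
        if "drugname_norm" not in self.drug.columns:
            self.drug = self.drug.assign(drugname_norm=self.drug["drugname"].map(normalize_term))
        # primaryid -> caseid lookup for joining the satellite tables
        self._case_of = self.demo.set_index("primaryid")["caseid"]

    def __len__(self) -> int:
        return len(self.demo)

    @property
    def caseids(self) -> pd.Series:
        return self.demo["caseid"]

    def case_of(self, frame: pd.DataFrame) -> pd.Series:
        """caseid for each row of a satellite frame (by primaryid)."""
        return frame["primaryid"].map(self._case_of)

    def subset(self, keep_caseids) -> "CaseSet":
        keep = set(keep_caseids)
        demo = self.demo[self.demo["caseid"].isin(keep)]
        pids = set(demo["primaryid"])
        return CaseSet(
            demo,
            self.drug[self.drug["primaryid"].isin(pids)],
            self.reac[self.reac["primaryid"].isin(pids)],
            self.outc[self.outc["primaryid"].isin(pids)],
        )

    def to_report_cases(self) -> list[ReportCase]:
        from .cohort import convert_age  # deferred: cohort imports this module

        drugs_by_pid: dict = {}
        for pid, name, role in self.drug[["primaryid", "drugname_norm", "role_cod"]].itertuples(index=False):
            drugs_by_pid.setdefault(pid, []).append((name, role))
        reac_by_pid: dict = {}
        for pid, pt in self.reac[["primaryid", "pt"]].itertuples(index=False):
            reac_by_pid.setdefault(pid, set()).add(pt)
        outc_by_pid: dict = {}
        for pid, oc in self.outc[["primaryid", "outc_cod"]].itertuples(index=False):
            outc_by_pid.setdefault(pid, set()).add(oc)
        cases = []
        for row in self.demo.itertuples(index=False):
            date = None if pd.isna(row.fda_dt) else row.fda_dt.date()
            age = None if pd.isna(row.age) else float(row.age)
            cases.append(
                ReportCase(
                    caseid=int(row.caseid),
                    primaryid=int(row.primaryid),
                    receipt_date=date,
                    age_years=convert_age(age, row.age_cod),
                    sex=row.sex,
                    country=row.occr_country,
                    drugs=tuple(drugs_by_pid.get(row.primaryid, [])),
                    reactions=frozenset(reac_by_pid.get(row.primaryid, set())),
                    outcomes=frozenset(outc_by_pid.get(row.primaryid, set())),
                )
            )
        return cases


def _read_table(path, dialect: Dialect, required: list[str], int_cols: list[str], warnings: dict):
    """Parse one $-delimited table into a list-of-lists keyed by column.

    The format is unquoted single-character-delimited text; lines with the
    wrong field count, or with an unparseable mandatory integer key, are
    skipped and counted (never abort).
    """
    path = Path(path)
    name = path.name
    with open(path, encoding=dialect.encoding, errors="replace") as fh:
        header = fh.readline()
        if header == "":
            raise SchemaError(f"{path}: empty file, no header line")
        cols = [c.strip().lower() for c in header.rstrip("\r\n").split(dialect.delimiter)]
        for col in required:
            if col not in cols:
                raise SchemaError(f"{path}: missing mandatory column {col!r}")
        ncol = len(cols)
        rows = []
        for line in fh:
            line = line.rstrip("\r\n")
            if line == "":
                continue
            fields = line.split(dialect.delimiter)
            if len(fields) != ncol:
                warnings[f"{name}:malformed_lines"] = warnings.get(f"{name}:malformed_lines", 0) + 1
                continue
            rows.append(fields)
    df = pd.DataFrame(rows, columns=cols, dtype=object) if rows else pd.DataFrame({c: [] for c in cols}, dtype=object)
    for col in int_cols:
        if col in df.columns and len(df):
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad = parsed.isna()
            if bad.any():
                warnings[f"{name}:bad_{col}"] = warnings.get(f"{name}:bad_{col}", 0) + int(bad.sum())
                df = df[~bad]
                parsed = parsed[~bad]
            df[col] = parsed.astype(np.int64)
    return df.reset_index(drop=True)


def _finalize_demo(df: pd.DataFrame, warnings: dict) -> pd.DataFrame:
    for col in DEMO_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col not in ("age",) else np.nan
    if len(df):
        fda = pd.to_datetime(df["fda_dt"].astype(str).str.strip(), format="%Y%m%d", errors="coerce")
        n_bad_dt = int((fda.isna() & (df["fda_dt"].astype(str).str.strip() != "")).sum())
        if n_bad_dt:
            warnings["DEMO:unparseable_fda_dt"] = warnings.get("DEMO:unparseable_fda_dt", 0) + n_bad_dt
        df["fda_dt"] = fda
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
        df["age_cod"] = df["age_cod"].astype(str).str.strip().str.upper()
        df["sex"] = df["sex"].astype(str).str.strip().str.upper()
        df["occr_country"] = df["occr_country"].astype(str).str.strip().str.upper()
    else:
        df["fda_dt"] = pd.to_datetime(df["fda_dt"])
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return df[DEMO_COLUMNS]


def read_quarter(demo_path, drug_path, reac_path, outc_path, dialect: Dialect = Dialect()) -> RawRecordSet:
    """Read one quarter's DEMO/DRUG/REAC/OUTC tables.

    Column names are matched case-insensitively against the standard FAERS
    names.  Unparseable ``age``/``fda_dt`` values become null; malformed
    lines are skipped with a warning counter; rows in the satellite tables
    whose ``primaryid`` is absent from DEMO are dropped (and counted).
    A missing mandatory DEMO column raises :class:`SchemaError`.
    """
    warnings: dict = {}
    demo = _read_table(demo_path, dialect, _DEMO_REQUIRED, ["primaryid", "caseid", "caseversion"], warnings)
    demo = _finalize_demo(demo, warnings)
    drug = _read_table(drug_path, dialect, ["primaryid", "drugname"], ["primaryid"], warnings)
    reac = _read_table(reac_path, dialect, ["primaryid", "pt"], ["primaryid"], warnings)
    outc = _read_table(outc_path, dialect, ["primaryid", "outc_cod"], ["primaryid"], warnings)

    if "drug_seq" not in drug.columns:
        drug["drug_seq"] = 1
    drug["drug_seq"] = pd.to_numeric(drug["drug_seq"], errors="coerce").fillna(0).astype(np.int64)
    if "role_cod" not in drug.columns:
        drug["role_cod"] = ""
    drug["role_cod"] = drug["role_cod"].astype(str).str.strip().str.upper()
    drug = drug[DRUG_COLUMNS]
    reac = reac[REAC_COLUMNS]
    outc = outc[OUTC_COLUMNS]
    outc["outc_cod"] = outc["outc_cod"].astype(str).str.strip().str.upper()

    known = set(demo["primaryid"])
    for name, frame in (("DRUG", drug), ("REAC", reac), ("OUTC", outc)):
        orphan = ~frame["primaryid"].isin(known)
        if orphan.any():
            warnings[f"{name}:orphan_rows"] = int(orphan.sum())
    drug = drug[drug["primaryid"].isin(known)].reset_index(drop=True)
    reac = reac[reac["primaryid"].isin(known)].reset_index(drop=True)
    outc = outc[outc["primaryid"].isin(known)].reset_index(drop=True)

    raw = RawRecordSet(demo, drug, reac, outc, warnings)
    logger.info(
        "read_quarter: %d demo, %d drug, %d reac, %d outc rows (warnings: %s)",
        len(demo), len(drug), len(reac), len(outc), warnings or "none",
    )
    return raw


def _fmt_number(x) -> str:
    if pd.isna(x):
        return ""
    f = float(x)
    return str(int(f)) if f == int(f) else repr(f)


def _fmt_date(x) -> str:
    return "" if pd.isna(x) else pd.Timestamp(x).strftime("%Y%m%d")


def _frame_lines(df: pd.DataFrame, columns: list[str], fmt: dict, delim: str) -> list[str]:
    lines = [delim.join(columns)]
    for row in df[columns].itertuples(index=False):
        fields = []
        for col, val in zip(columns, row):
            fields.append(fmt[col](val) if col in fmt else ("" if pd.isna(val) else str(val)))
        lines.append(delim.join(fields))
    return lines


def write_quarter(data, out_dir, dialect: Dialect = Dialect()) -> dict[str, Path]:
    """Write DEMO/DRUG/REAC/OUTC tables in the layout :func:`read_quarter` accepts.

    ``data`` may be a :class:`RawRecordSet` or a :class:`CaseSet`.  Field
    values round-trip through :func:`read_quarter` unchanged (dates rendered
    YYYYMMDD, integral numerics without a decimal point, nulls as blanks).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(data, CaseSet):
        data = RawRecordSet(data.demo, data.drug[DRUG_COLUMNS], data.reac, data.outc)
    d = dialect.delimiter
    num = {"age": _fmt_number, "fda_dt": _fmt_date}
    paths = {}
    for name, frame, columns, fmt in (
        ("DEMO", data.demo, DEMO_COLUMNS, num),
        ("DRUG", data.drug, DRUG_COLUMNS, {}),
        ("REAC", data.reac, REAC_COLUMNS, {}),
        ("OUTC", data.outc, OUTC_COLUMNS, {}),
    ):
        path = out_dir / f"{name}.txt"
        text = "\n".join(_frame_lines(frame, columns, fmt, d)) + "\n"
        path.write_text(text, encoding=dialect.encoding)
        paths[name] = path
    return paths


def deduplicate_cases(raw: RawRecordSet) -> CaseSet:
    """Collapse multiple case versions to one current report per ``caseid``.

    Keeps, per caseid, the row with the highest ``caseversion``; ties broken
    by latest ``fda_dt`` (null dates sort before any dated record), then by
    highest ``primaryid``.  Satellite rows are joined by the surviving
    ``primaryid``.  Idempotent; empty input gives an empty case set.
    """
    demo = raw.demo
    order = demo.sort_values(
        ["caseid", "caseversion", "fda_dt", "primaryid"],
        kind="mergesort",
        na_position="first",
    )
    kept = order.groupby("caseid", sort=True).tail(1)
    pids = set(kept["primaryid"])
    case_set = CaseSet(
        kept.sort_values("caseid", kind="mergesort"),
        raw.drug[raw.drug["primaryid"].isin(pids)],
        raw.reac[raw.reac["primaryid"].isin(pids)],
        raw.outc[raw.outc["primaryid"].isin(pids)],
    )
    logger.info("deduplicate_cases: %d report versions -> %d cases", len(demo), len(case_set))
    return case_set


def concat_raw(parts: list[RawRecordSet]) -> RawRecordSet:
    """Concatenate several quarters into one record set."""
    if not parts:
        raise ValueError("concat_raw: no record sets given")
    warnings: dict = {}
    for p in parts:
        for k, v in p.warnings.items():
            warnings[k] = warnings.get(k, 0) + v
    return RawRecordSet(
        pd.concat([p.demo for p in parts], ignore_index=True),
        pd.concat([p.drug for p in parts], ignore_index=True),
        pd.concat([p.reac for p in parts], ignore_index=True),
        pd.concat([p.outc for p in parts], ignore_index=True),
        warnings,
    )
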