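"""Preferred-term → system-organ-class mapping.

MedDRA itself is licensed and never shipped; this module consumes any
user-supplied two-level hierarchy table (columns ``pt``, ``soc_name``,
``soc_code``) as a stand-in.  Multi-axial PTs must already be reduced to
their primary SOC in the input table.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from ._util import normalize_term

logger = logging.getLogger(__name__)

__all__ = ["SocAssignment", "UNMAPPED", "HierarchyTable", "HierarchyError", "load_hierarchy"]

_REQUIRED = ["pt", "soc_name", "soc_code"]


class HierarchyError(ValueError):
    """Malformed or internally inconsistent hierarchy table."""


class SocAssignment(NamedTuple):
    soc_name: str
    soc_code: int


#: Explicit marker returned for PTs absent from the hierarchy.  Unmapped PTs
#: are counted by callers, never silently dropped.
UNMAPPED = SocAssignment("<unmapped>", 0)


@dataclasses.dataclass(frozen=True)
class HierarchyTable:
    """Mapping from normalized PT string to its (single, primary) SOC."""

    entries: dict  # normalized pt -> SocAssignment
    display: dict = dataclasses.field(default_factory=dict)  # normalized pt -> original casing

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pt: str) -> bool:
        return normalize_term(pt) in self.entries

    @property
    def soc_names(self) -> list[str]:
        return sorted({v.soc_name for v in self.entries.values()})

    def soc_code_of(self, soc_name: str) -> int:
        for v in self.entries.values():
            if v.soc_name == soc_name:
                return v.soc_code
        raise KeyError(soc_name)

    def map_series(self, pts: pd.Series) -> pd.Series:
        """Vectorised :func:`map_pt` returning the SOC name (NaN if unmapped)."""
        lut = {k: v.soc_name for k, v in self.entries.items()}
        return pts.map(normalize_term).map(lut)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.display.get(k, k), v.soc_name, v.soc_code)
            for k, v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=_REQUIRED)

    def write(self, path, sep: str = "\t") -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep=sep, index=False)
        return path


def map_pt(pt: str, h: HierarchyTable) -> SocAssignment:
    """Look up a PT's SOC after normalization; :data:`UNMAPPED` if absent."""
    return h.entries.get(normalize_term(pt), UNMAPPED)


def load_hierarchy(path) -> HierarchyTable:
    """Load a PT→SOC table from delimited text (tab or comma, autodetected).

    Duplicate PT rows agreeing on the SOC are deduplicated; duplicates that
    conflict raise :class:`HierarchyError` naming every conflicting PT.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _REQUIRED:
        if col not in df.columns:
            raise HierarchyError(f"{path}: missing column {col!r}")
    df = df.dropna(subset=["pt"])
    df["pt_norm"] = df["pt"].map(normalize_term)
    df["soc_code"] = pd.to_numeric(df["soc_code"], errors="raise").astype(int)
    df["soc_name"] = df["soc_name"].astype(str).str.strip()

    conflicts = (
        df.groupby("pt_norm")[["soc_name", "soc_code"]]
        .nunique()
        .pipe(lambda g: g[(g["soc_name"] > 1) | (g["soc_code"] > 1)])
    )
    if len(conflicts):
        raise HierarchyError(
            f"{path}: PTs mapped to conflicting SOCs: {', '.join(sorted(conflicts.index))}"
        )

    entries: dict = {}
    display: dict = {}
    for row in df.drop_duplicates("pt_norm").itertuples(index=False):
        entries[row.pt_norm] = SocAssignment(row.soc_name, int(row.soc_code))
        display[row.pt_norm] = str(row.pt).strip()
    logger.info("load_hierarchy: %d PTs across %d SOCs", len(entries), len({v.soc_name for v in entries.values()}))
    return HierarchyTable(entries, display)
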