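"""Small shared helpers (text normalization, quarter parsing)."""

from __future__ import annotations

import datetime as _dt
import re

_WS = re.compile(r"\s+")

_QUARTER = re.compile(r"^(\d{4})Q([1-4])$", re.IGNORECASE)


def normalize_term(s: str) -> str:
    """Normalize a free-text term: strip, case-fold, collapse internal whitespace.

    Applied to both drug names and reaction preferred terms before any
    matching, so lookups are insensitive to case and spacing.
    """
    return _WS.sub(" ", str(s).strip()).casefold()


def quarter_bounds(q: str) -> tuple[_dt.date, _dt.date]:
    """Return (first day, last day) of a quarter written as ``YYYYQn``."""
    m = _QUARTER.match(q.strip())
    if not m:
        raise ValueError(f"malformed quarter string: {q!r} (expected e.g. 2014Q1)")
    year, n = int(m.group(1)), int(m.group(2))
    start = _dt.date(year, 3 * (n - 1) + 1, 1)
    if n == 4:
        end = _dt.date(year, 12, 31)
    else:
        end = _dt.date(year, 3 * n + 1, 1) - _dt.timedelta(days=1)
    return start, end
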