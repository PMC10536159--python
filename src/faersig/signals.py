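"""Disproportionality statistics and signal screens for spontaneous reports.

For each term (a MedDRA PT, or its SOC after mapping) a 2×2 contingency
table is built over (case, distinct-term) counting units:

====================  ==============  ===============
                      target drug     all other drugs
term of interest      a               b
all other terms       c               d
====================  ==============  ===============

and four estimators of disproportionate reporting are computed:

* **ROR**  = ad/(bc), 95% CI = exp(ln ROR ± z·√(1/a+1/b+1/c+1/d))
* **PRR**  = (a/(a+b)) / (c/(c+d)), 95% CI = exp(ln PRR ± z·√(1/a−1/(a+b)+1/c−1/(c+d)))
* **IC**   = log2(a·N/((a+b)(a+c))) with IC−2SD = IC − 2·√V(IC)
* **EBGM** = a·N/((a+b)(a+c)) (the observed/expected reporting ratio) with a
  Wald-style lower bound EBGM05 = EBGM·exp(−z·√(1/a+1/b+1/c+1/d))

so that IC = log2(EBGM) identically.  Signal rules: ROR/PRR flag when a≥3
and the CI lower bound exceeds 1; BCPNN flags when IC−2SD>0 with strength
bands (0,1.5] "+", (1.5,3] "++", >3 "+++"; EBGM flags when EBGM05>2.  A
consensus "ADR" requires all four.

V(IC) defaults to the delta-method variance of the log2 observed/expected
ratio, ``(1/ln2)²·(1/a − 1/(a+b) − 1/(a+c) + 1/N)``; ``ic_variance="bayes"``
selects the Bate-style Bayesian credibility variance instead (the IC point
estimate is unchanged).

Zero cells leave the ratio statistics undefined.  The default policy adds
0.5 to every cell of affected tables only (flagged ``continuity_corrected``);
``zero_cell="strict"`` propagates NaN instead.  The chi-square is always
computed on the raw counts (Yates-corrected by default).
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

from ._util import normalize_term
from .cohort import ExposureCohort
from .faers_io import CaseSet
from .meddra_map import HierarchyTable

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "SignalStats",
    "SignalDecision",
    "Thresholds",
    "ScreenResult",
    "build_contingency",
    "ror_stat",
    "prr_stat",
    "chi_square",
    "information_component",
    "ebgm_stat",
    "classify",
    "screen",
    "reverse_screen",
    "implied_point_from_ci",
]

_LN2 = math.log(2.0)


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """2×2 drug-by-event counts; ``a`` is target drug with target term."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.N < 1:
            raise ValueError("contingency table is empty")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclasses.dataclass(frozen=True)
class SignalStats:
    """All four estimators with interval bounds for one term."""

    term: str
    level: str  # "PT" or "SOC"
    code: int | None
    a: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    prr_lo: float
    prr_hi: float
    chi2: float
    ic: float
    ic_minus_2sd: float
    ebgm: float
    ebgm05: float
    continuity_corrected: bool = False


@dataclasses.dataclass(frozen=True)
class SignalDecision:
    ror_signal: bool
    prr_signal: bool
    bcpnn_signal: bool
    ebgm_signal: bool
    consensus: bool
    bcpnn_band: str  # one of "-", "+", "++", "+++"


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """Signal rules: gates, interval level and BCPNN band edges."""

    min_a: int = 3
    z: float = 1.96
    ror_lo_cutoff: float = 1.0
    prr_lo_cutoff: float = 1.0
    ic_low_cutoff: float = 0.0
    ebgm05_cutoff: float = 2.0
    band_edges: tuple = (0.0, 1.5, 3.0)


# ---------------------------------------------------------------------------
# vectorised core


def _apply_zero_cell(a, b, c, d, policy: str):
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    if policy == "correct":
        shift = np.where(zero, 0.5, 0.0)
        return a + shift, b + shift, c + shift, d + shift, zero
    if policy == "strict":
        nan = np.where(zero, np.nan, 0.0)
        return a + nan, b + nan, c + nan, d + nan, zero
    raise ValueError(f"unknown zero-cell policy {policy!r}")


def _ic_variance_delta(a, b, c, d):
    n = a + b + c + d
    v = (1.0 / a - 1.0 / (a + b) - 1.0 / (a + c) + 1.0 / n) / _LN2**2
    return np.maximum(v, 0.0)


def _ic_variance_bayes(a, b, c, d):
    # Closed-form posterior variance of the information component under the
    # standard Bayesian confidence-propagation prior (Beta/Dirichlet with
    # alpha1=beta1=1, alpha=beta=2, gamma11=1).
    n = a + b + c + d
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    gamma = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
    t1 = (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
    t2 = (n - a - b + al - a1) / ((a + b + a1) * (1 + n + al))
    t3 = (n - a - c + be - b1) / ((a + c + b1) * (1 + n + be))
    return (t1 + t2 + t3) / _LN2**2


def _chi_square_raw(a, b, c, d, yates: bool):
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    diff = np.abs(a * d - b * c)
    if yates:
        diff = np.maximum(diff - n / 2.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * diff**2 / denom, np.nan)
    return chi2


def compute_stats_arrays(a, b, c, d, *, zero_cell="correct", yates=True, ic_variance="delta", z=1.96) -> dict:
    """All statistics for arrays of 2×2 tables (scalars broadcast)."""
    a0 = np.asarray(a, dtype=float)
    chi2 = _chi_square_raw(a, b, c, d, yates)
    ac, bc_, cc, dc, corrected = _apply_zero_cell(a, b, c, d, zero_cell)
    n = ac + bc_ + cc + dc
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = ac * dc / (bc_ * cc)
        se_ror = np.sqrt(1 / ac + 1 / bc_ + 1 / cc + 1 / dc)
        prr = (ac / (ac + bc_)) / (cc / (cc + dc))
        se_prr = np.sqrt(1 / ac - 1 / (ac + bc_) + 1 / cc - 1 / (cc + dc))
        ebgm = ac * n / ((ac + bc_) * (ac + cc))
        ic = np.log2(ebgm)
        if ic_variance == "delta":
            v_ic = _ic_variance_delta(ac, bc_, cc, dc)
        elif ic_variance == "bayes":
            v_ic = _ic_variance_bayes(ac, bc_, cc, dc)
        else:
            raise ValueError(f"unknown ic_variance {ic_variance!r}")
        zq = float(z)
        out = {
            "a": a0,
            "ror": ror,
            "ror_lo": ror * np.exp(-zq * se_ror),
            "ror_hi": ror * np.exp(zq * se_ror),
            "prr": prr,
            "prr_lo": prr * np.exp(-zq * se_prr),
            "prr_hi": prr * np.exp(zq * se_prr),
            "chi2": chi2,
            "ic": ic,
            "ic_minus_2sd": ic - 2.0 * np.sqrt(v_ic),
            "ebgm": ebgm,
            "ebgm05": ebgm * np.exp(-zq * se_ror),
            "ebgm_hi": ebgm * np.exp(zq * se_ror),
            "continuity_corrected": corrected,
        }
    return out


def _scalar(t: ContingencyTable, keys, **kw):
    s = compute_stats_arrays(t.a, t.b, t.c, t.d, **kw)
    return tuple(float(s[k]) for k in keys)


def ror_stat(t: ContingencyTable, *, zero_cell="correct", z=1.96):
    """Reporting odds ratio with 95% CI: (ror, lo, hi)."""
    return _scalar(t, ("ror", "ror_lo", "ror_hi"), zero_cell=zero_cell, z=z)


def prr_stat(t: ContingencyTable, *, zero_cell="correct", z=1.96):
    """Proportional reporting ratio with 95% CI: (prr, lo, hi)."""
    return _scalar(t, ("prr", "prr_lo", "prr_hi"), zero_cell=zero_cell, z=z)


def chi_square(t: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-square on the 2×2 (Yates continuity correction by default)."""
    return float(_chi_square_raw(t.a, t.b, t.c, t.d, yates))


def information_component(t: ContingencyTable, *, zero_cell="correct", ic_variance="delta"):
    """BCPNN information component: (ic, ic_minus_2sd)."""
    return _scalar(t, ("ic", "ic_minus_2sd"), zero_cell=zero_cell, ic_variance=ic_variance)


def ebgm_stat(t: ContingencyTable, *, zero_cell="correct", z=1.96):
    """Observed/expected reporting ratio with its lower bound: (ebgm, ebgm05)."""
    return _scalar(t, ("ebgm", "ebgm05"), zero_cell=zero_cell, z=z)


def implied_point_from_ci(lo: float, hi: float) -> float:
    """Point estimate implied by a log-symmetric interval: √(lo·hi).

    Any interval of the form exp(ln θ ± z·s) satisfies θ = √(lo·hi), so this
    recovers the point estimate from published bounds.
    """
    if not (0 < lo <= hi):
        raise ValueError(f"need 0 < lo <= hi, got ({lo}, {hi})")
    return math.sqrt(lo * hi)


def _band(ic_low: float, edges) -> str:
    if not np.isfinite(ic_low) or ic_low <= edges[0]:
        return "-"
    if ic_low <= edges[1]:
        return "+"
    if ic_low <= edges[2]:
        return "++"
    return "+++"


def classify(s: SignalStats, thresholds: Thresholds = Thresholds()) -> SignalDecision:
    """Apply the per-algorithm signal rules; NaN statistics never flag."""
    th = thresholds
    gate = s.a >= th.min_a
    ror_sig = bool(gate and s.ror_lo > th.ror_lo_cutoff)
    prr_sig = bool(gate and s.prr_lo > th.prr_lo_cutoff)
    bcpnn_sig = bool(s.ic_minus_2sd > th.ic_low_cutoff)
    ebgm_sig = bool(s.ebgm05 > th.ebgm05_cutoff)
    band = _band(s.ic_minus_2sd, th.band_edges)
    return SignalDecision(ror_sig, prr_sig, bcpnn_sig, ebgm_sig,
                          ror_sig and prr_sig and bcpnn_sig and ebgm_sig, band)


# ---------------------------------------------------------------------------
# counting units and screens


class TermNotFoundError(KeyError):
    pass


def _units(case_set: CaseSet, hierarchy: HierarchyTable | None, level: str):
    """Distinct (caseid, term) units at the requested level.

    Returns (units frame with columns caseid/term_norm/term, n_unmapped).
    At SOC level PTs are mapped first and unmapped PTs dropped (counted);
    a case contributes at most one unit per distinct term at the level.
    """
    reac = case_set.reac
    df = pd.DataFrame({"caseid": case_set.case_of(reac).to_numpy(), "pt": reac["pt"].to_numpy()})
    df["term_norm"] = df["pt"].map(normalize_term)
    n_unmapped = 0
    if level.upper() == "SOC":
        if hierarchy is None:
            raise ValueError("SOC-level screening requires a hierarchy table")
        lut = {k: v.soc_name for k, v in hierarchy.entries.items()}
        df["term"] = df["term_norm"].map(lut)
        n_unmapped = int(df["term"].isna().sum())
        if n_unmapped:
            logger.info("screen: %d reaction rows with unmapped PT dropped at SOC level", n_unmapped)
        df = df.dropna(subset=["term"])
        df["term_norm"] = df["term"]
    elif level.upper() == "PT":
        # display name: first-seen original casing per normalized term
        df["term"] = df["pt"]
    else:
        raise ValueError(f"unknown level {level!r}")
    units = df.drop_duplicates(["caseid", "term_norm"])[["caseid", "term_norm", "term"]]
    return units.reset_index(drop=True), n_unmapped


def build_contingency(cohort: ExposureCohort, hierarchy: HierarchyTable | None, term: str, level: str = "PT") -> ContingencyTable:
    """2×2 table for one term at PT or SOC level.

    Counting unit is the (deduplicated case, distinct term at level) pair, so
    ``a`` equals the number of exposed cases reporting the term.
    """
    units, _ = _units(cohort.case_set, hierarchy, level)
    key = normalize_term(term) if level.upper() == "PT" else term
    mask = cohort.exposed_mask(units["caseid"])
    sel = (units["term_norm"] == key).to_numpy()
    if not sel.any():
        raise TermNotFoundError(f"term {term!r} not present at level {level}")
    a = int((sel & mask).sum())
    b = int((sel & ~mask).sum())
    c = int((~sel & mask).sum())
    d = int((~sel & ~mask).sum())
    return ContingencyTable(a, b, c, d)


@dataclasses.dataclass
class ScreenResult:
    """Ranked disproportionality screen with the AE→ADR cascade counts."""

    level: str
    entries: list  # of (SignalStats, SignalDecision), ebgm-descending
    cascade: dict  # n_terms / ror_prr / ror_prr_bcpnn / consensus
    n_unmapped_pts: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, dcs in self.entries:
            rows.append({
                "term": s.term, "level": s.level, "code": s.code, "a": s.a,
                "ror": s.ror, "ror_lo": s.ror_lo, "ror_hi": s.ror_hi,
                "prr": s.prr, "prr_lo": s.prr_lo, "prr_hi": s.prr_hi,
                "chi2": s.chi2, "ic": s.ic, "ic_minus_2sd": s.ic_minus_2sd,
                "ebgm": s.ebgm, "ebgm05": s.ebgm05,
                "band": dcs.bcpnn_band,
                "ror_signal": dcs.ror_signal, "prr_signal": dcs.prr_signal,
                "bcpnn_signal": dcs.bcpnn_signal, "ebgm_signal": dcs.ebgm_signal,
                "consensus": dcs.consensus,
                "continuity_corrected": s.continuity_corrected,
            })
        return pd.DataFrame(rows)


def _assemble(display_terms, codes, level, stats, thresholds) -> list:
    entries = []
    for i, term in enumerate(display_terms):
        s = SignalStats(
            term=term, level=level, code=codes[i],
            a=int(stats["a"][i]),
            ror=float(stats["ror"][i]), ror_lo=float(stats["ror_lo"][i]), ror_hi=float(stats["ror_hi"][i]),
            prr=float(stats["prr"][i]), prr_lo=float(stats["prr_lo"][i]), prr_hi=float(stats["prr_hi"][i]),
            chi2=float(stats["chi2"][i]),
            ic=float(stats["ic"][i]), ic_minus_2sd=float(stats["ic_minus_2sd"][i]),
            ebgm=float(stats["ebgm"][i]), ebgm05=float(stats["ebgm05"][i]),
            continuity_corrected=bool(stats["continuity_corrected"][i]),
        )
        entries.append((s, classify(s, thresholds)))
    # EBGM descending, ties by a descending then term name; NaN EBGM last
    entries.sort(key=lambda e: (-(e[0].ebgm if np.isfinite(e[0].ebgm) else -np.inf), -e[0].a, e[0].term))
    return entries


def screen(
    cohort: ExposureCohort,
    hierarchy: HierarchyTable | None = None,
    level: str = "PT",
    *,
    thresholds: Thresholds = Thresholds(),
    zero_cell: str = "correct",
    yates: bool = True,
    ic_variance: str = "delta",
) -> ScreenResult:
    """Rank every term with a ≥ 1 by EBGM and flag signals under all four rules.

    Also reports the screening cascade: total terms (AEs), terms passing
    ROR∧PRR, ROR∧PRR∧BCPNN, and the four-algorithm consensus (ADRs).
    """
    level = level.upper()
    units, n_unmapped = _units(cohort.case_set, hierarchy, level)
    if len(units) == 0:
        return ScreenResult(level, [], {"n_terms": 0, "ror_prr": 0, "ror_prr_bcpnn": 0, "consensus": 0}, n_unmapped)
    mask = cohort.exposed_mask(units["caseid"])
    grouped = units.assign(exposed=mask).groupby("term_norm", sort=True)
    agg = grouped.agg(a=("exposed", "sum"), total=("exposed", "size"), term=("term", "first"))
    agg = agg[agg["a"] >= 1]
    if len(agg) == 0:
        return ScreenResult(level, [], {"n_terms": 0, "ror_prr": 0, "ror_prr_bcpnn": 0, "consensus": 0}, n_unmapped)
    n_units = len(units)
    n_exposed_units = int(mask.sum())
    a = agg["a"].to_numpy(dtype=np.int64)
    b = agg["total"].to_numpy(dtype=np.int64) - a
    c = n_exposed_units - a
    d = n_units - a - b - c
    stats = compute_stats_arrays(a, b, c, d, zero_cell=zero_cell, yates=yates, ic_variance=ic_variance, z=thresholds.z)
    if level == "SOC" and hierarchy is not None:
        code_lut = {v.soc_name: v.soc_code for v in hierarchy.entries.values()}
        codes = [code_lut.get(t) for t in agg["term"]]
    else:
        codes = [None] * len(agg)
    entries = _assemble(list(agg["term"]), codes, level, stats, thresholds)
    cascade = {
        "n_terms": len(entries),
        "ror_prr": sum(1 for _, d_ in entries if d_.ror_signal and d_.prr_signal),
        "ror_prr_bcpnn": sum(1 for _, d_ in entries if d_.ror_signal and d_.prr_signal and d_.bcpnn_signal),
        "consensus": sum(1 for _, d_ in entries if d_.consensus),
    }
    return ScreenResult(level, entries, cascade, n_unmapped)


def reverse_screen(
    case_set: CaseSet,
    hierarchy: HierarchyTable | None,
    event_term: str,
    exclude_combination: bool = True,
    *,
    role_filter=("PS",),
    thresholds: Thresholds = Thresholds(),
    zero_cell: str = "correct",
    yates: bool = True,
    ic_variance: str = "delta",
) -> list:
    """Screen every primary-suspect drug against one event PT.

    Enumerates the normalized drug names appearing with an accepted role on
    cases reporting ``event_term``; names containing the ``\\`` ingredient
    separator are dropped when ``exclude_combination`` (fixed-dose
    combinations confound single-ingredient attribution).  For each drug a
    2×2 table (that drug vs all others) is built over (case, distinct-PT)
    units and all four statistics computed.  Returns
    [(drugname, SignalStats, SignalDecision), ...] ranked by EBGM descending.
    """
    units, _ = _units(case_set, None, "PT")
    key = normalize_term(event_term)
    event_cases = set(units.loc[units["term_norm"] == key, "caseid"])
    if not event_cases:
        logger.warning("reverse_screen: event %r not reported by any case", event_term)
        return []
    roles = frozenset(r.strip().upper() for r in role_filter)
    drug = case_set.drug[case_set.drug["role_cod"].isin(roles)]
    drug = drug.assign(caseid=case_set.case_of(drug).to_numpy())
    names = sorted(set(drug.loc[drug["caseid"].isin(event_cases), "drugname_norm"]))
    if exclude_combination:
        kept = [n for n in names if "\\" not in n]
        for n in names:
            if "\\" in n:
                logger.info("reverse_screen: excluding combination product %r", n)
        names = kept

    is_event = (units["term_norm"] == key).to_numpy()
    n_units = len(units)
    results = []
    exposed_by_drug = drug.groupby("drugname_norm")["caseid"].agg(set)
    for name in names:
        exposed_ids = exposed_by_drug.get(name, set())
        mask = units["caseid"].isin(exposed_ids).to_numpy()
        a = int((is_event & mask).sum())
        b = int((is_event & ~mask).sum())
        c = int((~is_event & mask).sum())
        d = n_units - a - b - c
        stats = compute_stats_arrays(a, b, c, d, zero_cell=zero_cell, yates=yates, ic_variance=ic_variance, z=thresholds.z)
        entry = _assemble([name], [None], "PT", {k: np.atleast_1d(v) for k, v in stats.items()}, thresholds)[0]
        s, dcs = entry
        s = dataclasses.replace(s, term=name)
        results.append((name, s, dcs))
    results.sort(key=lambda r: (-(r[1].ebgm if np.isfinite(r[1].ebgm) else -np.inf), -r[1].a, r[0]))
    return results
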