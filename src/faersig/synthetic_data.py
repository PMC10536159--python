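"""FAERS-like report simulator with known ground truth.

Generates raw quarterly record sets that mimic the structure of real
spontaneous-report data — caseid/caseversion duplicates, drug role codes,
reaction PTs, outcome codes, demographics — with configurable injected
drug–event associations, so every pipeline stage (parsing, deduplication,
exposure flagging, screening) can be tested against exact bookkeeping.

Model
-----
Each case draws one primary-suspect (PS) drug: the target drug with
probability ``p_target_ps``, otherwise a weighted choice from the catalogue.
Optional concomitant drugs get roles SS and C.  Reaction PTs are independent
Bernoulli draws per case; an injected association ``(drug, pt, θ)``
multiplies the *conditional odds* of that PT, given that the drug is the
case's PS drug, by θ:

    q = θ·p / (1 − p + θ·p)

so the case-level exposure–event odds ratio is exactly θ.  Cases drawing an
empty PT set are redrawn (every FAERS report lists at least one reaction);
with the default rare injected baselines this conditioning is negligible.
Demographics, outcomes and receipt dates are drawn from fixed marginals
modelled on a published epirubicin reporting cohort.

All randomness flows from one root seed through named child streams (drugs,
events, demographics, dates, duplicates), so each stage is independently
reproducible and generation is fully deterministic.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from ._util import normalize_term, quarter_bounds
from .faers_io import DEMO_COLUMNS, DRUG_COLUMNS, OUTC_COLUMNS, REAC_COLUMNS, RawRecordSet
from .meddra_map import HierarchyTable, SocAssignment

logger = logging.getLogger(__name__)

__all__ = ["GeneratorConfig", "GroundTruth", "toy_hierarchy", "generate", "inject_duplicates",
           "default_drug_catalogue", "default_event_catalogue"]


def default_drug_catalogue() -> dict:
    """Non-target PS-eligible drugs with sampling weights (normalised at use)."""
    return {
        "GABAPENTIN": 1.0, "IMATINIB": 1.0, "DOXORUBICIN": 1.2, "CYCLOPHOSPHAMIDE": 1.2,
        "FLUOROURACIL": 1.0, "DOCETAXEL": 1.0, "PACLITAXEL": 1.0, "TAMOXIFEN": 0.8,
        "TRASTUZUMAB": 0.8, "CISPLATIN": 1.0, "CARBOPLATIN": 0.8, "METHOTREXATE": 1.0,
        "CARBIDOPA\\LEVODOPA": 0.5, "ASPIRIN": 1.5, "METFORMIN": 1.5,
    }


def default_event_catalogue() -> dict:
    """Reaction PTs with baseline per-case probabilities.

    Three tiers: common constitutional terms, mid-frequency treatment-related
    terms, and rare terms (baseline 0.002) that injected associations target.
    """
    return {
        # common
        "Nausea": 0.25, "Fatigue": 0.20, "Vomiting": 0.15, "Headache": 0.12,
        "Diarrhoea": 0.10, "Pyrexia": 0.10,
        # mid
        "Anaemia": 0.06, "Neutropenia": 0.05, "Alopecia": 0.045, "Rash": 0.04,
        "Dizziness": 0.035, "Dyspnoea": 0.03, "Pruritus": 0.028, "Cough": 0.025,
        "Insomnia": 0.022, "Arthralgia": 0.02, "Myalgia": 0.018, "Constipation": 0.016,
        "Oedema peripheral": 0.014, "Abdominal pain": 0.013, "Decreased appetite": 0.012,
        "Stomatitis": 0.011, "Febrile neutropenia": 0.010, "Palpitations": 0.009,
        "Mucosal inflammation": 0.0085, "Hypertension": 0.008,
        # rare
        "Gait apraxia": 0.002, "Hepatic artery stenosis": 0.002, "Hepatic artery occlusion": 0.002,
        "Endocardial fibrosis": 0.002, "Cardiac perfusion defect": 0.002, "Intestinal atresia": 0.002,
        "Miller Fisher syndrome": 0.002, "Merycism": 0.002, "Biliary fistula": 0.002,
        "Xerophthalmia": 0.002,
    }


def _default_sex_probs() -> dict:
    return {"F": 0.6532, "M": 0.1194, "UNK": 0.2274}


def _default_age_bin_probs() -> dict:
    return {
        "<20": 0.0222, "20-29": 0.0174, "30-39": 0.0638, "40-49": 0.1613,
        "50-59": 0.1972, "60-69": 0.1574, "70-79": 0.0760, ">=80": 0.0117,
        "Unknown": 0.2930,
    }


def _default_country_probs() -> dict:
    return {
        "CN": 0.2527, "IT": 0.1582, "FR": 0.1181, "GB": 0.1171, "DE": 0.0714,
        "US": 0.10, "JP": 0.06, "ES": 0.05, "CA": 0.04, "AU": 0.0325,
    }


def _default_outcome_probs() -> dict:
    return {"HO": 0.3345, "DE": 0.0564, "LT": 0.0564, "DS": 0.0283, "OT": 0.10}


_AGE_BIN_RANGES = {
    "<20": (0, 20), "20-29": (20, 30), "30-39": (30, 40), "40-49": (40, 50),
    "50-59": (50, 60), "60-69": (60, 70), "70-79": (70, 80), ">=80": (80, 95),
}


@dataclasses.dataclass
class GeneratorConfig:
    """Study conditions for one simulated reporting system."""

    seed: int
    n_cases: int = 20_000
    target_drug: str = "EPIRUBICIN"
    p_target_ps: float = 0.12
    other_drugs: dict = dataclasses.field(default_factory=default_drug_catalogue)
    p_second_drug: float = 0.40
    p_third_drug: float = 0.25
    events: dict = dataclasses.field(default_factory=default_event_catalogue)
    injected: tuple = ()  # of (drug name, pt name, odds multiplier theta)
    n_soc: int = 8
    duplicate_rate: float = 0.0
    sex_probs: dict = dataclasses.field(default_factory=_default_sex_probs)
    age_bin_probs: dict = dataclasses.field(default_factory=_default_age_bin_probs)
    country_probs: dict = dataclasses.field(default_factory=_default_country_probs)
    outcome_probs: dict = dataclasses.field(default_factory=_default_outcome_probs)
    window: tuple = ("2014Q1", "2023Q1")

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not (0 <= self.p_target_ps <= 1):
            raise ValueError("p_target_ps must be in [0, 1]")
        if not (0 <= self.duplicate_rate < 1):
            raise ValueError("duplicate_rate must be in [0, 1)")
        for pt, p in self.events.items():
            if not (0 < p < 1):
                raise ValueError(f"event baseline probability for {pt!r} must be in (0, 1)")
        drugs = {self.target_drug, *self.other_drugs}
        for drug, pt, theta in self.injected:
            if theta <= 0:
                raise ValueError(f"injected theta for ({drug}, {pt}) must be > 0")
            if drug not in drugs:
                raise ValueError(f"injected drug {drug!r} not in the catalogue")
            if pt not in self.events:
                raise ValueError(f"injected PT {pt!r} not in the event catalogue")


@dataclasses.dataclass
class GroundTruth:
    """Generator bookkeeping for recovery and calibration tests.

    ``expected_a[pt]`` is the expected exposed-with-PT case count given the
    realized number of target-exposed cases; ``realized_*`` counts are exact
    tallies of the emitted (pre-duplication) cases and are recomputable by
    brute force from the record set.
    """

    n_cases: int
    exposed_caseids: np.ndarray  # caseids with the target drug as PS
    injected: dict  # (drug, pt) -> theta
    expected_a: dict  # pt -> expected exposed-case count with the PT
    realized_a: dict  # pt -> exposed cases reporting the PT
    realized_event_total: dict  # pt -> all cases reporting the PT
    sex_counts: dict  # tallies among exposed cases, keyed like summarize()
    age_bin_counts: dict
    country_counts: dict
    outcome_counts: dict
    duplicated_caseids: np.ndarray = dataclasses.field(default_factory=lambda: np.array([], dtype=np.int64))

    @property
    def n_exposed(self) -> int:
        return len(self.exposed_caseids)

    def eligible_pts(self, min_expected_a: float = 5.0) -> list:
        return [pt for pt, e in self.expected_a.items() if e >= min_expected_a]

    def to_json_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_exposed": self.n_exposed,
            "injected": {f"{d}|{p}": t for (d, p), t in self.injected.items()},
            "expected_a": self.expected_a,
            "realized_a": self.realized_a,
            "realized_event_total": self.realized_event_total,
            "sex_counts": self.sex_counts,
            "age_bin_counts": self.age_bin_counts,
            "country_counts": self.country_counts,
            "outcome_counts": self.outcome_counts,
            "n_duplicated": int(len(self.duplicated_caseids)),
        }


def toy_hierarchy(n_soc: int, pts, seed: int) -> HierarchyTable:
    """Assign each PT to one of ``n_soc`` fabricated SOCs uniformly at random."""
    if n_soc < 1:
        raise ValueError("n_soc must be >= 1")
    pts = list(pts)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.integers(0, n_soc, size=len(pts))
    entries, display = {}, {}
    for pt, i in zip(pts, idx):
        key = normalize_term(pt)
        entries[key] = SocAssignment(f"System organ class {i + 1:02d}", 10_000_000 + int(i) + 1)
        display[key] = pt
    return HierarchyTable(entries, display)


def _choice(rng, options, probs, size):
    probs = np.asarray(probs, dtype=float)
    return rng.choice(len(options), size=size, p=probs / probs.sum())


def generate(config: GeneratorConfig) -> tuple[RawRecordSet, GroundTruth]:
    """Simulate one raw record set plus its exact ground truth."""
    config.validate()
    n = config.n_cases
    ss = np.random.SeedSequence(config.seed)
    rng_drug, rng_event, rng_demo, rng_date, _seed_dup = ss.spawn(5)
    rng_drug = np.random.default_rng(rng_drug)
    rng_event = np.random.default_rng(rng_event)
    rng_demo = np.random.default_rng(rng_demo)
    rng_date = np.random.default_rng(rng_date)

    caseid = 10_000_001 + np.arange(n, dtype=np.int64)
    caseversion = np.full(n, 2, dtype=np.int64)  # leaves room for injected earlier versions
    primaryid = caseid * 10 + caseversion

    # --- primary-suspect drug ---------------------------------------------
    other_names = list(config.other_drugs)
    other_weights = np.array([config.other_drugs[d] for d in other_names], dtype=float)
    is_target = rng_drug.random(n) < config.p_target_ps
    ps_name = np.where(
        is_target,
        config.target_drug,
        np.array(other_names, dtype=object)[_choice(rng_drug, other_names, other_weights, n)],
    ).astype(object)

    # --- reaction PTs ------------------------------------------------------
    pt_names = list(config.events)
    base = np.array([config.events[p] for p in pt_names], dtype=float)
    K = len(pt_names)
    Q = np.tile(base, (n, 1))
    theta_by_drug: dict = {}
    for drug, pt, theta in config.injected:
        theta_by_drug.setdefault(drug, {})[pt] = theta
    for drug, adjustments in theta_by_drug.items():
        rows = np.nonzero(ps_name == drug)[0]
        for pt, theta in adjustments.items():
            j = pt_names.index(pt)
            p = base[j]
            Q[rows, j] = theta * p / (1 - p + theta * p)
    draws = rng_event.random((n, K)) < Q
    empty = ~draws.any(axis=1)
    guard = 0
    while empty.any():  # every report lists at least one reaction
        idx = np.nonzero(empty)[0]
        draws[idx] = rng_event.random((len(idx), K)) < Q[idx]
        empty[idx] = ~draws[idx].any(axis=1)
        guard += 1
        if guard > 1000:
            raise RuntimeError("event redraw did not converge; baselines too small")

    # --- concomitant drugs -------------------------------------------------
    second = rng_drug.random(n) < config.p_second_drug
    third = rng_drug.random(n) < config.p_third_drug
    second_name = np.array(other_names, dtype=object)[_choice(rng_drug, other_names, other_weights, n)]
    third_name = np.array(other_names, dtype=object)[_choice(rng_drug, other_names, other_weights, n)]

    drug_rows = [pd.DataFrame({"primaryid": primaryid, "drug_seq": 1, "drugname": ps_name, "role_cod": "PS"})]
    for present, names, seq, role in ((second, second_name, 2, "SS"), (third, third_name, 3, "C")):
        keep = present & (names != ps_name)
        drug_rows.append(pd.DataFrame({
            "primaryid": primaryid[keep], "drug_seq": seq,
            "drugname": names[keep], "role_cod": role,
        }))
    drug = pd.concat(drug_rows, ignore_index=True).sort_values(
        ["primaryid", "drug_seq"], kind="mergesort").reset_index(drop=True)
    drug["drug_seq"] = drug["drug_seq"].astype(np.int64)

    rows_i, cols_j = np.nonzero(draws)
    reac = pd.DataFrame({
        "primaryid": primaryid[rows_i],
        "pt": np.array(pt_names, dtype=object)[cols_j],
    })

    # --- demographics, outcomes, dates ------------------------------------
    sex_labels = list(config.sex_probs)
    sex = np.array(sex_labels, dtype=object)[
        _choice(rng_demo, sex_labels, [config.sex_probs[s] for s in sex_labels], n)]
    bin_labels = list(config.age_bin_probs)
    bins = np.array(bin_labels, dtype=object)[
        _choice(rng_demo, bin_labels, [config.age_bin_probs[b] for b in bin_labels], n)]
    age = np.full(n, np.nan)
    age_cod = np.where(bins == "Unknown", "", "YR").astype(object)
    for label, (lo, hi) in _AGE_BIN_RANGES.items():
        mask = bins == label
        if mask.any():
            age[mask] = rng_demo.integers(lo, hi, size=int(mask.sum()))
    country_labels = list(config.country_probs)
    country = np.array(country_labels, dtype=object)[
        _choice(rng_demo, country_labels, [config.country_probs[c] for c in country_labels], n)]

    outc_parts = []
    outcome_hits = {}
    for code, p in config.outcome_probs.items():
        hit = rng_demo.random(n) < p
        outcome_hits[code] = hit
        outc_parts.append(pd.DataFrame({"primaryid": primaryid[hit], "outc_cod": code}))
    outc = pd.concat(outc_parts, ignore_index=True).sort_values(
        ["primaryid", "outc_cod"], kind="mergesort").reset_index(drop=True)

    start, end = quarter_bounds(config.window[0])[0], quarter_bounds(config.window[1])[1]
    span = (end - start).days
    offsets = rng_date.integers(0, span + 1, size=n)
    fda_dt = pd.to_datetime(start) + pd.to_timedelta(offsets, unit="D")

    demo = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "caseversion": caseversion,
        "fda_dt": fda_dt, "age": age, "age_cod": age_cod, "sex": sex,
        "occr_country": country,
    })[DEMO_COLUMNS]

    raw = RawRecordSet(demo, drug[DRUG_COLUMNS], reac[REAC_COLUMNS], outc[OUTC_COLUMNS])

    # --- ground truth ------------------------------------------------------
    exposed = ps_name == config.target_drug
    n_exp = int(exposed.sum())
    q_target = base.copy()
    for pt, theta in theta_by_drug.get(config.target_drug, {}).items():
        j = pt_names.index(pt)
        q_target[j] = theta * base[j] / (1 - base[j] + theta * base[j])
    # exact per-PT marginal given the at-least-one-reaction redraw:
    # P(pt_j | nonempty) = q_j / (1 - prod_k(1 - q_k))
    p_nonempty = 1.0 - float(np.prod(1.0 - q_target))
    expected_a = {pt: float(n_exp * q_target[j] / p_nonempty) for j, pt in enumerate(pt_names)}
    realized_a = {pt: int(draws[exposed, j].sum()) for j, pt in enumerate(pt_names)}
    realized_tot = {pt: int(draws[:, j].sum()) for j, pt in enumerate(pt_names)}

    sex_counts = {
        "Male": int((sex[exposed] == "M").sum()),
        "Female": int((sex[exposed] == "F").sum()),
        "Unknown": int(np.isin(sex[exposed], ["M", "F"], invert=True).sum()),
    }
    age_counts = {lab: int((bins[exposed] == lab).sum()) for lab in bin_labels}
    country_counts = {c: int((country[exposed] == c).sum()) for c in country_labels}
    outcome_labels = {"DE": "Death", "DS": "Disability", "HO": "Hospitalization", "LT": "Life-threatening"}
    outcome_counts = {
        label: int(outcome_hits[code][exposed].sum()) if code in outcome_hits else 0
        for code, label in outcome_labels.items()
    }

    truth = GroundTruth(
        n_cases=n,
        exposed_caseids=caseid[exposed],
        injected={(d, p): t for d, p, t in config.injected},
        expected_a=expected_a,
        realized_a=realized_a,
        realized_event_total=realized_tot,
        sex_counts=sex_counts,
        age_bin_counts=age_counts,
        country_counts=country_counts,
        outcome_counts=outcome_counts,
    )

    if config.duplicate_rate > 0:
        raw = inject_duplicates(raw, config.duplicate_rate, _seed_dup)
        truth.duplicated_caseids = np.sort(raw.demo.loc[raw.demo["caseversion"] < 2, "caseid"].unique())

    logger.info("generate: %d cases (%d exposed), %d reaction rows", n, n_exp, len(raw.reac))
    return raw, truth


def inject_duplicates(raw: RawRecordSet, duplicate_rate: float, seed) -> RawRecordSet:
    """Append earlier case versions for a seeded fraction of cases.

    Each duplicate gets a strictly lower ``caseversion``, an earlier
    ``fda_dt`` and a perturbed ``primaryid``; its drug rows are copied, its
    reaction list is truncated by one PT (when it has several) and its
    outcomes dropped, so deduplication must discard it.  The distinct-caseid
    count is unchanged.
    """
    if not (0 <= duplicate_rate < 1):
        raise ValueError("duplicate_rate must be in [0, 1)")
    if duplicate_rate == 0:
        return raw
    rng = np.random.default_rng(seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed))
    demo = raw.demo
    caseids = np.sort(demo["caseid"].unique())
    n_dup = int(round(duplicate_rate * len(caseids)))
    chosen = np.sort(rng.choice(caseids, size=n_dup, replace=False))

    orig = demo[demo["caseid"].isin(chosen)].sort_values("caseid", kind="mergesort")
    if (orig["caseversion"] < 2).any():
        raise ValueError("cannot inject a duplicate below caseversion 1")
    dup = orig.copy()
    dup["caseversion"] = orig["caseversion"] - 1
    new_pid = orig["primaryid"] - 1
    if new_pid.isin(demo["primaryid"]).any():
        raise ValueError("perturbed primaryid would collide with an existing report")
    back = rng.integers(30, 181, size=len(dup))
    dup["fda_dt"] = orig["fda_dt"] - pd.to_timedelta(back, unit="D")
    pid_map = dict(zip(orig["primaryid"], new_pid))
    dup["primaryid"] = new_pid.to_numpy()

    drug_dup = raw.drug[raw.drug["primaryid"].isin(pid_map)].copy()
    drug_dup["primaryid"] = drug_dup["primaryid"].map(pid_map)
    reac_dup = raw.reac[raw.reac["primaryid"].isin(pid_map)].copy()
    reac_dup["primaryid"] = reac_dup["primaryid"].map(pid_map)
    # drop the final PT of multi-reaction duplicates so content differs
    reac_dup = reac_dup.sort_values(["primaryid", "pt"], kind="mergesort")
    sizes = reac_dup.groupby("primaryid")["pt"].transform("size")
    pos_from_end = reac_dup.groupby("primaryid").cumcount(ascending=False)
    reac_dup = reac_dup[(sizes == 1) | (pos_from_end > 0)]

    demo_out = pd.concat([demo, dup], ignore_index=True).sort_values(
        ["caseid", "caseversion"], kind="mergesort").reset_index(drop=True)
    drug_out = pd.concat([raw.drug, drug_dup], ignore_index=True).sort_values(
        ["primaryid", "drug_seq"], kind="mergesort").reset_index(drop=True)
    reac_out = pd.concat([raw.reac, reac_dup], ignore_index=True).sort_values(
        ["primaryid", "pt"], kind="mergesort").reset_index(drop=True)
    logger.info("inject_duplicates: added %d earlier versions for %d cases", len(dup), len(caseids))
    return RawRecordSet(demo_out, drug_out, reac_out, raw.outc.copy(), dict(raw.warnings))
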