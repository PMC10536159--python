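import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from faersig import (ContingencyTable, SignalStats, build_contingency, chi_square,
                     classify, deduplicate_cases, ebgm_stat, flag_exposure, implied_point_from_ci,
                     information_component, prr_stat, reverse_screen, ror_stat, screen)
from faersig.synthetic_data import toy_hierarchy

from conftest import make_raw

cells = st.integers(min_value=1, max_value=500)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


# ---------------------------------------------------------------------------
# worked examples (expected values frozen from independent hand arithmetic)


def test_ror_balanced_table():
    ror, lo, hi = ror_stat(ContingencyTable(10, 10, 10, 10))
    assert ror == pytest.approx(1.0)
    assert lo == pytest.approx(0.2894963, rel=1e-6)  # exp(-1.96*sqrt(0.4))
    assert hi == pytest.approx(3.4542759, rel=1e-6)


def test_ror_skewed_table():
    ror, _, _ = ror_stat(ContingencyTable(3, 7, 97, 9893))
    assert ror == pytest.approx(43.7098675, rel=1e-6)  # 3*9893/(7*97)


def test_prr_examples():
    assert prr_stat(ContingencyTable(10, 10, 10, 10))[0] == pytest.approx(1.0)
    assert prr_stat(ContingencyTable(3, 7, 97, 9893))[0] == pytest.approx(30.8969072, rel=1e-6)


def test_chi_square_examples():
    assert chi_square(ContingencyTable(10, 10, 10, 10), yates=False) == pytest.approx(0.0)
    assert chi_square(ContingencyTable(10, 10, 10, 10), yates=True) == pytest.approx(0.0)
    assert chi_square(ContingencyTable(20, 10, 10, 20), yates=False) == pytest.approx(20 / 3, rel=1e-9)
    assert chi_square(ContingencyTable(20, 10, 10, 20), yates=True) == pytest.approx(5.4, rel=1e-9)


def test_information_component_examples():
    ic, _ = information_component(ContingencyTable(10, 10, 10, 10))
    assert ic == pytest.approx(0.0, abs=1e-12)


def test_ebgm_examples():
    ebgm, ebgm05 = ebgm_stat(ContingencyTable(3, 7, 97, 9893))
    assert ebgm == pytest.approx(30.0, rel=1e-9)  # 3*10000/(100*10)
    assert ebgm05 == pytest.approx(7.6443323, rel=1e-6)  # 30*exp(-1.96*sqrt(0.486600836))


def test_implied_point_from_published_intervals():
    assert implied_point_from_ci(6.56, 7.47) == pytest.approx(7.00, abs=0.005)
    assert implied_point_from_ci(3.05, 3.54) == pytest.approx(3.29, abs=0.005)
    assert implied_point_from_ci(4.0, 4.0) == 4.0
    with pytest.raises(ValueError):
        implied_point_from_ci(0.0, 2.0)
    with pytest.raises(ValueError):
        implied_point_from_ci(3.0, 2.0)


# ---------------------------------------------------------------------------
# algebraic invariants


@settings(max_examples=200, derandomize=True, deadline=None)
@given(tables)
def test_ic_identical_to_log2_ebgm(t):
    ic, _ = information_component(t)
    ebgm, _ = ebgm_stat(t)
    assert ic == pytest.approx(math.log2(ebgm), rel=1e-12, abs=1e-12)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(tables)
def test_sign_concordance_across_estimators(t):
    ror = ror_stat(t)[0]
    prr = prr_stat(t)[0]
    ebgm = ebgm_stat(t)[0]
    ic = information_component(t)[0]
    s = np.sign(round(ror - 1, 12))
    assert np.sign(round(prr - 1, 12)) == s
    assert np.sign(round(ebgm - 1, 12)) == s
    assert np.sign(round(ic, 12)) == s


@settings(max_examples=200, derandomize=True, deadline=None)
@given(tables)
def test_intervals_are_log_symmetric(t):
    for stat in (ror_stat, prr_stat):
        point, lo, hi = stat(t)
        assert math.sqrt(lo * hi) == pytest.approx(point, rel=1e-10)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(tables)
def test_label_swap_inverts_ror(t):
    swapped = ContingencyTable(t.b, t.a, t.d, t.c)
    assert ror_stat(swapped)[0] == pytest.approx(1.0 / ror_stat(t)[0], rel=1e-12)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(cells, cells, cells, cells)
def test_ror_strictly_increases_in_a(a, b, c, d):
    # the observed/expected ratio (EBGM) is NOT monotone in a, because a
    # also enters both margins; the odds ratio is
    t1, t2 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
    assert ror_stat(t2)[0] > ror_stat(t1)[0]


@settings(max_examples=200, derandomize=True, deadline=None)
@given(tables)
def test_yates_never_exceeds_uncorrected_chi_square(t):
    assert chi_square(t, yates=True) <= chi_square(t, yates=False) + 1e-12


@settings(max_examples=100, derandomize=True, deadline=None)
@given(tables)
def test_chi_square_matches_scipy(t):
    obs = [[t.a, t.b], [t.c, t.d]]
    for yates in (False, True):
        expected = chi2_contingency(obs, correction=yates)[0]
        assert chi_square(t, yates=yates) == pytest.approx(expected, rel=1e-10, abs=1e-12)


def test_ebgm_prr_ratio_limit():
    # EBGM/PRR = N·c/((a+c)(c+d)) -> c/(a+c) as d grows with a,b,c fixed,
    # hence -> 1 exactly in the rare-event regime a << c
    a, b, c = 5, 50, 20
    for d in (10 ** 3, 10 ** 5, 10 ** 7):
        t = ContingencyTable(a, b, c, d)
        ratio = ebgm_stat(t)[0] / prr_stat(t)[0]
    assert ratio == pytest.approx(c / (a + c), rel=1e-4)
    t = ContingencyTable(5, 50, 20_000, 10 ** 7)
    assert ebgm_stat(t)[0] / prr_stat(t)[0] == pytest.approx(1.0, abs=2e-3)


def test_bayes_variance_variant_changes_only_the_sd():
    t = ContingencyTable(12, 40, 300, 9000)
    ic_d, low_d = information_component(t, ic_variance="delta")
    ic_b, low_b = information_component(t, ic_variance="bayes")
    assert ic_d == ic_b
    assert low_d != low_b


# ---------------------------------------------------------------------------
# zero-cell policy and classification


def test_zero_cell_policies():
    stats = ror_stat(ContingencyTable(3, 0, 10, 100), zero_cell="correct")
    assert all(np.isfinite(stats))
    strict = ror_stat(ContingencyTable(3, 0, 10, 100), zero_cell="strict")
    assert all(np.isnan(strict))


def _stats(a=10, ror_lo=2.0, prr_lo=2.0, ic_low=1.0, ebgm05=3.0):
    return SignalStats("t", "PT", None, a, 3.0, ror_lo, 9.0, 3.0, prr_lo, 9.0,
                       10.0, 1.5, ic_low, 3.0, ebgm05)


@pytest.mark.parametrize(
    "ic_low, band, flagged",
    [(-0.5, "-", False), (0.0, "-", False), (0.4, "+", True), (1.5, "+", True),
     (1.6, "++", True), (3.0, "++", True), (3.01, "+++", True), (float("nan"), "-", False)],
)
def test_bcpnn_bands(ic_low, band, flagged):
    d = classify(_stats(ic_low=ic_low))
    assert d.bcpnn_band == band
    assert d.bcpnn_signal is flagged


def test_min_a_gate_blocks_ror_and_prr():
    d = classify(_stats(a=2, ror_lo=50.0, prr_lo=50.0))
    assert not d.ror_signal and not d.prr_signal and not d.consensus


def test_consensus_requires_all_four():
    assert classify(_stats()).consensus
    assert not classify(_stats(ebgm05=1.9)).consensus
    nan = float("nan")
    d = classify(_stats(ror_lo=nan, prr_lo=nan, ic_low=nan, ebgm05=nan))
    assert not any([d.ror_signal, d.prr_signal, d.bcpnn_signal, d.ebgm_signal])


# ---------------------------------------------------------------------------
# contingency construction and screens


def test_build_contingency_counts_case_term_units(four_case_raw):
    cohort = flag_exposure(deduplicate_cases(four_case_raw), ["epirubicin"])
    t = build_contingency(cohort, None, "PT1", "PT")
    assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 1)


def test_soc_level_counts_distinct_soc_per_case(four_case_raw, tmp_path):
    hier = tmp_path / "h.csv"
    hier.write_text("pt,soc_name,soc_code\nPT1,Shared SOC,10000001\nPT2,Shared SOC,10000001\n")
    from faersig import load_hierarchy

    h = load_hierarchy(hier)
    cohort = flag_exposure(deduplicate_cases(four_case_raw), ["epirubicin"])
    t = build_contingency(cohort, h, "Shared SOC", "SOC")
    # case 1 reports PT1+PT2 but contributes one unit to the shared SOC
    assert (t.a, t.b, t.c, t.d) == (2, 2, 0, 0)


def test_contingency_margins_equal_total_units(small_cohort):
    units = small_cohort.case_set.reac.copy()
    units["caseid"] = small_cohort.case_set.case_of(units)
    n_units = len(units.drop_duplicates(["caseid", "pt"]))
    t = build_contingency(small_cohort, None, "Nausea", "PT")
    assert t.N == n_units


def test_build_contingency_matches_brute_force(small_cohort):
    # independent recount from per-case report objects
    cases = small_cohort.case_set.to_report_cases()
    exposed = small_cohort.exposed_ids
    for term in ("Gait apraxia", "Nausea", "Anaemia"):
        a = b = c = d = 0
        for case in cases:
            is_exp = case.caseid in exposed
            for pt in case.reactions:
                has = pt == term
                if has and is_exp:
                    a += 1
                elif has:
                    b += 1
                elif is_exp:
                    c += 1
                else:
                    d += 1
        t = build_contingency(small_cohort, None, term, "PT")
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)


def test_screen_ranks_injected_pair_first(small_cohort):
    res = screen(small_cohort)
    assert res.entries[0][0].term == "Gait apraxia"
    ebgms = [s.ebgm for s, _ in res.entries]
    assert ebgms == sorted(ebgms, reverse=True)


def test_screen_consensus_is_subset_of_each_algorithm(small_cohort):
    res = screen(small_cohort)
    for s, d in res.entries:
        if d.consensus:
            assert d.ror_signal and d.prr_signal and d.bcpnn_signal and d.ebgm_signal
    c = res.cascade
    assert c["consensus"] <= c["ror_prr_bcpnn"] <= c["ror_prr"] <= c["n_terms"]


def test_screen_single_case_single_pt():
    demo = [(11, 1, 1, "20200101", 50, "YR", "F", "US")]
    cohort = flag_exposure(deduplicate_cases(make_raw(demo, [(11, 1, "EPIRUBICIN", "PS")], [(11, "Nausea")])), ["epirubicin"])
    res = screen(cohort)
    assert len(res) == 1 and res.entries[0][0].a == 1


def test_screen_soc_level_uses_hierarchy_codes(small_cohort, small_sim):
    cfg, _, _ = small_sim
    h = toy_hierarchy(4, list(cfg.events), seed=11)
    res = screen(small_cohort, h, "SOC")
    assert 1 <= len(res) <= 4
    assert all(s.code is not None for s, _ in res.entries)
    with pytest.raises(ValueError):
        screen(small_cohort, None, "SOC")


def _reverse_fixture():
    demo = [(i * 10 + 1, i, 1, "20200101", 50, "YR", "F", "US") for i in range(1, 9)]
    drug = [(11, 1, "DRUG X", "PS"), (21, 1, "DRUG X", "PS"), (31, 1, "DRUG X", "PS"),
            (41, 1, "CARBIDOPA\\LEVODOPA", "PS"), (51, 1, "OTHER", "PS"),
            (61, 1, "OTHER", "PS"), (71, 1, "OTHER", "PS"), (81, 1, "OTHER", "PS")]
    reac = [(11, "Event E"), (21, "Event E"), (31, "Event E"), (41, "Event E"),
            (51, "Nausea"), (61, "Nausea"), (71, "Nausea"), (81, "Nausea"),
            (11, "Nausea")]
    return deduplicate_cases(make_raw(demo, drug, reac))


def test_reverse_screen_counts_and_combination_exclusion():
    cases = _reverse_fixture()
    rows = reverse_screen(cases, None, "Event E")
    names = [r[0] for r in rows]
    assert "drug x" in names
    assert all("\\" not in n for n in names)
    x = dict((r[0], r[1]) for r in rows)["drug x"]
    assert x.a == 3
    rows_incl = reverse_screen(cases, None, "Event E", exclude_combination=False)
    assert any("\\" in r[0] for r in rows_incl)


def test_reverse_screen_unknown_event_is_empty():
    assert reverse_screen(_reverse_fixture(), None, "No such PT") == []
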