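import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faersig import SchemaError, deduplicate_cases, read_quarter, write_quarter
from faersig.faers_io import Dialect

from conftest import make_raw


def _write_files(tmp_path, demo_text, drug_text=None, reac_text=None, outc_text=None):
    drug_text = drug_text or "primaryid$drug_seq$drugname$role_cod\n"
    reac_text = reac_text or "primaryid$pt\n"
    outc_text = outc_text or "primaryid$outc_cod\n"
    paths = {}
    for name, text in (("DEMO", demo_text), ("DRUG", drug_text), ("REAC", reac_text), ("OUTC", outc_text)):
        p = tmp_path / f"{name}.txt"
        p.write_text(text)
        paths[name] = p
    return paths


def test_read_quarter_parses_records_and_defers_conversion(tmp_path):
    demo = (
        "PRIMARYID$CASEID$CASEVERSION$FDA_DT$AGE$AGE_COD$SEX$OCCR_COUNTRY\n"
        "11$1$1$20200101$24$MON$F$US\n"
        "21$2$1$notadate$oops$YR$M$\n"
    )
    p = _write_files(tmp_path, demo)
    raw = read_quarter(p["DEMO"], p["DRUG"], p["REAC"], p["OUTC"])
    assert len(raw.demo) == 2
    # age_cod MON stored raw; conversion deferred to the cohort stage
    assert raw.demo.loc[0, "age"] == 24 and raw.demo.loc[0, "age_cod"] == "MON"
    # unparseable age/date become null, never abort
    assert pd.isna(raw.demo.loc[1, "age"]) and pd.isna(raw.demo.loc[1, "fda_dt"])


def test_malformed_lines_are_skipped_with_counter(tmp_path):
    demo = (
        "primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$occr_country\n"
        "11$1$1$20200101$24$YR$F$US\n"
        "21$2$1$20200101\n"  # wrong field count
        "31$3$1$20200101$50$YR$M$DE\n"
    )
    p = _write_files(tmp_path, demo)
    raw = read_quarter(p["DEMO"], p["DRUG"], p["REAC"], p["OUTC"])
    assert len(raw.demo) == 2
    assert raw.warnings["DEMO.txt:malformed_lines"] == 1


def test_missing_mandatory_column_names_file_and_column(tmp_path):
    demo = "primaryid$caseversion$fda_dt$age$age_cod$sex$occr_country\n"
    p = _write_files(tmp_path, demo)
    with pytest.raises(SchemaError, match="caseid"):
        read_quarter(p["DEMO"], p["DRUG"], p["REAC"], p["OUTC"])


@pytest.mark.parametrize(
    "demo_rows, survivor",
    [
        # higher caseversion wins
        ([(11, 100, 1, "20200101", 50, "YR", "F", "US"),
          (12, 100, 2, "20190101", 50, "YR", "F", "US")], 12),
        # same version: latest fda_dt wins
        ([(11, 100, 2, "20200101", 50, "YR", "F", "US"),
          (12, 100, 2, "20210101", 50, "YR", "F", "US")], 12),
        # same version and date: highest primaryid wins
        ([(12, 100, 2, "20200101", 50, "YR", "F", "US"),
          (11, 100, 2, "20200101", 50, "YR", "F", "US")], 12),
        # null date sorts before any dated record
        ([(13, 100, 2, None, 50, "YR", "F", "US"),
          (11, 100, 2, "19990101", 50, "YR", "F", "US")], 11),
    ],
)
def test_dedup_keeps_fda_recommended_record(demo_rows, survivor):
    cases = deduplicate_cases(make_raw(demo_rows))
    assert len(cases) == 1
    assert cases.demo["primaryid"].iloc[0] == survivor


def test_dedup_is_idempotent_and_counts_distinct_caseids(small_sim):
    _, raw, truth = small_sim
    cases = deduplicate_cases(raw)
    assert len(cases) == truth.n_cases == raw.demo["caseid"].nunique()
    again = deduplicate_cases(type(raw)(cases.demo, cases.drug, cases.reac, cases.outc))
    pd.testing.assert_frame_equal(
        again.demo.reset_index(drop=True), cases.demo.reset_index(drop=True)
    )


def test_dedup_joins_satellites_by_surviving_primaryid():
    demo = [(11, 100, 1, "20200101", 50, "YR", "F", "US"),
            (12, 100, 2, "20200601", 50, "YR", "F", "US")]
    drug = [(11, 1, "OLD DRUG", "PS"), (12, 1, "NEW DRUG", "PS")]
    reac = [(11, "Old PT"), (12, "New PT")]
    cases = deduplicate_cases(make_raw(demo, drug, reac))
    assert list(cases.drug["drugname"]) == ["NEW DRUG"]
    assert list(cases.reac["pt"]) == ["New PT"]


def test_empty_record_set_round_trip(tmp_path):
    raw = make_raw([])
    paths = write_quarter(raw, tmp_path)
    for p in paths.values():
        assert len(p.read_text().splitlines()) == 1  # header only
    back = read_quarter(paths["DEMO"], paths["DRUG"], paths["REAC"], paths["OUTC"])
    assert len(back.demo) == 0


def test_write_quarter_cardinality(tmp_path, four_case_raw):
    paths = write_quarter(four_case_raw, tmp_path)
    assert len(paths["DRUG"].read_text().splitlines()) == 1 + 4
    assert len(paths["REAC"].read_text().splitlines()) == 1 + 5


def _assert_raw_equal(x, y):
    pd.testing.assert_frame_equal(x.demo, y.demo, check_dtype=False)
    for attr in ("drug", "reac", "outc"):
        a = getattr(x, attr)[getattr(y, attr).columns]
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), getattr(y, attr).reset_index(drop=True), check_dtype=False
        )


def test_generated_quarter_round_trips(tmp_path, small_sim):
    _, raw, _ = small_sim
    paths = write_quarter(raw, tmp_path)
    back = read_quarter(paths["DEMO"], paths["DRUG"], paths["REAC"], paths["OUTC"])
    _assert_raw_equal(back, raw)


_text = st.text(alphabet=st.sampled_from("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789 .-_"),
                min_size=1, max_size=20).map(str.strip).filter(bool)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.lists(st.tuples(st.integers(1, 10 ** 6), st.integers(1, 10 ** 4), st.integers(1, 9),
                          st.integers(0, 120), _text, _text), min_size=1, max_size=8, unique_by=lambda r: r[0]),
       st.sampled_from(["$", "\t", ","]))
def test_round_trip_preserves_field_values(tmp_path_factory, rows, delim):
    tmp = tmp_path_factory.mktemp("rt")
    demo = [(pid, cid, ver, "20200101", age, "YR", "F", "US") for pid, cid, ver, age, _, _ in rows]
    drug = [(pid, 1, name, "PS") for pid, _, _, _, name, _ in rows]
    reac = [(pid, pt) for pid, _, _, _, _, pt in rows]
    raw = make_raw(demo, drug, reac)
    dialect = Dialect(delimiter=delim)
    paths = write_quarter(raw, tmp, dialect)
    back = read_quarter(paths["DEMO"], paths["DRUG"], paths["REAC"], paths["OUTC"], dialect)
    _assert_raw_equal(back, raw)
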