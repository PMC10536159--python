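import numpy as np
import pandas as pd
import pytest

from faersig import deduplicate_cases, flag_exposure
from faersig.faers_io import RawRecordSet
from faersig.synthetic_data import GeneratorConfig, generate


def make_raw(demo_rows, drug_rows=(), reac_rows=(), outc_rows=()) -> RawRecordSet:
    """Build a RawRecordSet from plain tuples.

    demo: (primaryid, caseid, caseversion, fda_dt 'YYYYMMDD' or None, age, age_cod, sex, country)
    drug: (primaryid, drug_seq, drugname, role_cod)
    reac: (primaryid, pt);  outc: (primaryid, outc_cod)
    """
    demo = pd.DataFrame(demo_rows, columns=[
        "primaryid", "caseid", "caseversion", "fda_dt", "age", "age_cod", "sex", "occr_country"])
    demo["fda_dt"] = pd.to_datetime(demo["fda_dt"], format="%Y%m%d", errors="coerce")
    demo["age"] = pd.to_numeric(demo["age"], errors="coerce")
    for col in ("primaryid", "caseid", "caseversion"):
        demo[col] = demo[col].astype(np.int64)
    drug = pd.DataFrame(list(drug_rows), columns=["primaryid", "drug_seq", "drugname", "role_cod"])
    reac = pd.DataFrame(list(reac_rows), columns=["primaryid", "pt"])
    outc = pd.DataFrame(list(outc_rows), columns=["primaryid", "outc_cod"])
    return RawRecordSet(demo, drug, reac, outc)


@pytest.fixture()
def four_case_raw():
    """Two exposed and two unexposed cases; PT1 table is a=2,b=1,c=1,d=1."""
    demo = [
        (11, 1, 1, "20200101", 50, "YR", "F", "US"),
        (21, 2, 1, "20200102", 60, "YR", "M", "US"),
        (31, 3, 1, "20200103", 70, "YR", "F", "US"),
        (41, 4, 1, "20200104", 80, "YR", "F", "US"),
    ]
    drug = [
        (11, 1, "EPIRUBICIN", "PS"), (21, 1, "EPIRUBICIN", "PS"),
        (31, 1, "ASPIRIN", "PS"), (41, 1, "ASPIRIN", "PS"),
    ]
    reac = [(11, "PT1"), (11, "PT2"), (21, "PT1"), (31, "PT1"), (41, "PT2")]
    return make_raw(demo, drug, reac)


@pytest.fixture(scope="session")
def small_sim():
    """A moderate simulated record set with one strong injected association."""
    cfg = GeneratorConfig(
        seed=424242, n_cases=4000, duplicate_rate=0.2,
        injected=(("EPIRUBICIN", "Gait apraxia", 8.0),),
    )
    raw, truth = generate(cfg)
    return cfg, raw, truth


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    cfg, raw, truth = small_sim
    cases = deduplicate_cases(raw)
    return flag_exposure(cases, ["epirubicin"], ["PS"])
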