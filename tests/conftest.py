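import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from jaderpv import ReportDatabase, write_database

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_db() -> ReportDatabase:
    """Ten reports: 2 missing age, 1 missing sex, mixed roles and PTs.

    Report R03 is a case via TEN (PT 10044223) among three reactions; R01 and
    R05 are cases via SJS.  Allopurinol appears as suspected on five reports
    and concomitantly (role excluded) on one more.
    """
    demo = pd.DataFrame(
        {
            "report_id": [f"R{i:02d}" for i in range(1, 11)],
            "sex": ["male", "female", "male", "female", "male",
                    "female", "male", "", "female", "male"],
            "age_band": ["30s", "60s", "20s", "80s", "40s",
                         "", "10s", "50s", "", "70s"],
            "reporting_year": ["2010", "2008", "2012", "2005", "2014",
                               "2011", "2009", "2013", "2007", "2006"],
        }
    )
    drug = pd.DataFrame(
        {
            "report_id": ["R01", "R02", "R03", "R03", "R04", "R05",
                          "R06", "R07", "R08", "R09", "R10", "R10"],
            "drug_name": ["allopurinol", "allopurinol", "allopurinol",
                          "loxoprofen", "loxoprofen", "allopurinol",
                          "allopurinol", "carbamazepine", "loxoprofen",
                          "allopurinol", "loxoprofen", "allopurinol"],
            "role_code": ["suspected", "suspected", "suspected", "suspected",
                          "suspected", "suspected", "suspected", "suspected",
                          "suspected", "suspected", "suspected", "heiyouyaku"],
            "start_date": ["2010-03-01", "2008-02-10", "2012-05-01",
                           "2012-05-03", "2005-01-15", "2014-06-20",
                           "2011-02-01", "2009-04-04", "2013-07-07",
                           "2007-08-08", "2006-09-09", "2006-09-01"],
        }
    )
    reac = pd.DataFrame(
        {
            "report_id": ["R01", "R02", "R03", "R03", "R03",
                          "R04", "R05", "R06", "R07", "R08", "R09", "R10"],
            "pt_code": ["10042033", "PT900001", "10044223", "PT900002",
                        "PT900003", "PT900001", "10042033", "PT900004",
                        "PT900005", "PT900001", "PT900002", "PT900003"],
            "onset_date": ["2010-03-04", "2008-03-01", "2012-05-20",
                           "2012-05-21", "2012-05-22", "2005-02-01",
                           "2014-07-01", "2011-03-01", "2009-05-01",
                           "2013-08-01", "2007-09-01", "2006-10-01"],
        }
    )
    hist = pd.DataFrame(
        {"report_id": ["R01", "R04"], "primary_illness": ["gout", "fever"]}
    )
    return ReportDatabase(demo=demo, drug=drug, reac=reac, hist=hist)


@pytest.fixture
def tiny_db_paths(tiny_db, tmp_path):
    """The tiny database written out as four CSV files."""
    return write_database(tiny_db, tmp_path / "db")


def make_dataset(n, n_exposed, n_exposed_cases, n_unexposed_cases,
                 drug="drugx", rng=None):
    """Analysis dataset with exact 2x2 margins for counting tests."""
    rng = rng or np.random.default_rng(0)
    exposed = np.zeros(n, dtype=bool)
    exposed[:n_exposed] = True
    case = np.zeros(n, dtype=bool)
    case[:n_exposed_cases] = True
    case[n_exposed:n_exposed + n_unexposed_cases] = True
    ds = pd.DataFrame(
        {
            "report_id": [f"R{i:05d}" for i in range(n)],
            "sex": rng.choice(["male", "female"], size=n),
            "age_stratum": rng.choice(
                ["<=19", "20-39", "40-59", "60-79", ">=80"], size=n
            ),
            "reporting_year": pd.array(
                rng.integers(2004, 2016, size=n), dtype="Int64"
            ),
            "is_case": case,
            "suspected_drugs": [
                frozenset({drug}) if e else frozenset({"other"}) for e in exposed
            ],
        }
    )
    return ds
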