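"""Shared fixtures: tiny hand-built table sets and small synthetic datasets."""

from __future__ import annotations

import pandas as pd
import pytest

from aadsignal.faers_io import TableSet


def make_demo(rows: list[dict]) -> pd.DataFrame:
    cols = ["primaryid", "caseid", "event_dt", "rept_dt", "age", "age_cod",
            "sex", "occp_cod", "reporter_country"]
    return pd.DataFrame([{c: str(r.get(c, "")) for c in cols} for r in rows],
                        columns=cols, dtype=object)


def make_table_set(demo=None, drug=None, reac=None, outc=None, ther=None
                   ) -> TableSet:
    def frame(rows, cols):
        rows = rows or []
        return pd.DataFrame([{c: str(r.get(c, "")) for c in cols} for r in rows],
                            columns=cols, dtype=object)

    return TableSet(
        demo=make_demo(demo or []),
        drug=frame(drug, ["primaryid", "drug_seq", "drugname", "role_cod"]),
        reac=frame(reac, ["primaryid", "pt_cod", "pt"]),
        outc=frame(outc, ["primaryid", "outc_cod"]),
        ther=frame(ther, ["primaryid", "drug_seq", "start_dt"]),
    )


@pytest.fixture
def tiny_table_set() -> TableSet:
    """Three reports: one AAD case on ceftriaxone (PS), one non-case on
    ceftriaxone, one case on an unmapped comparator drug."""
    return make_table_set(
        demo=[
            {"primaryid": "101", "caseid": "11", "event_dt": "20190310",
             "rept_dt": "20190401", "age": "70", "age_cod": "YR", "sex": "F",
             "occp_cod": "MD", "reporter_country": "US"},
            {"primaryid": "201", "caseid": "21", "event_dt": "20180501",
             "rept_dt": "20180601", "age": "30", "age_cod": "YR", "sex": "M",
             "occp_cod": "PH", "reporter_country": "DE"},
            {"primaryid": "301", "caseid": "31", "event_dt": "20200701",
             "rept_dt": "20200801", "age": "", "age_cod": "", "sex": "",
             "occp_cod": "", "reporter_country": "JP"},
        ],
        drug=[
            {"primaryid": "101", "drug_seq": "1", "drugname": "CEFTRIAXONE",
             "role_cod": "PS"},
            {"primaryid": "201", "drug_seq": "1", "drugname": "ceftriaxone ",
             "role_cod": "PS"},
            {"primaryid": "301", "drug_seq": "1", "drugname": "WIDGETOL",
             "role_cod": "PS"},
        ],
        reac=[
            {"primaryid": "101", "pt_cod": "10037128",
             "pt": "Pseudomembranous colitis"},
            {"primaryid": "201", "pt_cod": "", "pt": "Nausea"},
            {"primaryid": "301", "pt_cod": "10061043",
             "pt": "Clostridial infection"},
        ],
        outc=[
            {"primaryid": "101", "outc_cod": "HO"},
            {"primaryid": "301", "outc_cod": "DE"},
        ],
        ther=[
            {"primaryid": "101", "drug_seq": "1", "start_dt": "20190301"},
            {"primaryid": "201", "drug_seq": "1", "start_dt": "20180420"},
            {"primaryid": "301", "drug_seq": "1", "start_dt": "20200620"},
        ],
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """A 2,000-report synthetic dataset with defaults (duplicates, partial
    dates) — shared across tests that only read it."""
    from aadsignal.synthetic_data import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(n_reports=2000, seed=7)
    ts, gt = generate_dataset(cfg)
    return cfg, ts, gt


@pytest.fixture(scope="session")
def noise_free_synthetic():
    """A 2,000-report dataset with no duplicates and no date degradation."""
    from aadsignal.synthetic_data import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(n_reports=2000, seed=11, duplicate_rate=0.0,
                          partial_date_rate=0.0, missing_date_rate=0.0)
    ts, gt = generate_dataset(cfg)
    return cfg, ts, gt
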