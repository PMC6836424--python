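import dataclasses

import numpy as np
import pandas as pd
import pytest

from pumpwatch.model import SPR_COLUMNS, DoseUnit, DrugLibraryEntry
from pumpwatch.simulate import generate_log, scenario_presets

# Published threshold-violation tallies: per-type yearly counts and per-type
# response counts. Internally consistent (rows, columns and responses all sum
# to the same totals), so a log fixture reproducing the cells must reproduce
# the marginals.
TABLE3 = {
    "soft_min": {
        "years": {2014: 2259, 2015: 1529, 2016: 1570},
        "responses": {"cancel": 1741, "override": 3500, "reprogram": 117},
    },
    "hard_min": {
        "years": {2014: 23, 2015: 5, 2016: 6},
        "responses": {"cancel": 34, "override": 0, "reprogram": 0},
    },
    "soft_max": {
        "years": {2014: 1556, 2015: 2973, 2016: 5639},
        "responses": {"cancel": 1724, "override": 8075, "reprogram": 369},
    },
    "hard_max": {
        "years": {2014: 50, 2015: 46, 2016: 64},
        "responses": {"cancel": 160, "override": 0, "reprogram": 0},
    },
}


def make_frame(n: int, **cols) -> pd.DataFrame:
    """Build a canonical SPR DataFrame with broadcast defaults."""
    defaults = dict(
        timestamp=pd.Timestamp("2014-06-01 12:00:00"),
        pump_unit_id="PCU001",
        module_id="M1",
        infusion_id=[f"I{i}" for i in range(n)],
        patient_id="P1",
        drug_name="drugA",
        dose_value=1.0,
        dose_unit="mg/kg/hr",
        rate_ml_hr=1.0,
        weight_kg=3.0,
        mode="DERS",
        event_type="infusion_start",
        alert_type="none",
        response_action="none",
    )
    defaults.update(cols)
    data = {
        k: (list(v) if isinstance(v, (list, tuple, np.ndarray, pd.Series, pd.Index)) else [v] * n)
        for k, v in defaults.items()
    }
    frame = pd.DataFrame(data, columns=list(SPR_COLUMNS))
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    return frame


def build_table3_frame() -> pd.DataFrame:
    """An event log whose alert cells match the published violation table.

    One single-alert infusion per alert; responses are allocated within each
    alert type sequentially across the year-ordered alerts (the published
    response counts are per type, pooled over years, so any within-type
    allocation yields the same marginals).
    """
    years, types, responses = [], [], []
    for at, spec in TABLE3.items():
        year_col, resp_col = [], []
        for year, count in spec["years"].items():
            year_col.extend([year] * count)
        for action, count in spec["responses"].items():
            resp_col.extend([action] * count)
        assert len(year_col) == len(resp_col)
        years.extend(year_col)
        types.extend([at] * len(year_col))
        responses.extend(resp_col)

    n = len(years)
    ts = pd.to_datetime([f"{y}-06-15 12:00:00" for y in years])
    ids = [f"A{i:06d}" for i in range(n)]
    alerts = make_frame(
        n, timestamp=ts, infusion_id=ids, event_type="alert", alert_type=types
    )
    resp = make_frame(
        n,
        timestamp=ts + pd.Timedelta(minutes=1),
        infusion_id=ids,
        event_type="response",
        response_action=responses,
    )
    return pd.concat([alerts, resp], ignore_index=True)


@pytest.fixture(scope="session")
def table3_frame() -> pd.DataFrame:
    return build_table3_frame()


@pytest.fixture(scope="session")
def toy_entry() -> DrugLibraryEntry:
    return DrugLibraryEntry(
        "drugA", DoseUnit.MG_KG_HR, soft_min=2.0, soft_max=8.0, hard_min=1.0, hard_max=10.0
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded baseline simulation shared across tests (1 year)."""
    cfg = dataclasses.replace(
        scenario_presets()["baseline"], n_years=1, admissions_per_year=25, seed=11
    )
    records, truth = generate_log(cfg)
    return cfg, records, truth
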