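import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sepscore.ehr_model import (
    EhrTables,
    load_concept_dictionary,
    load_score_definition,
)
from sepscore.synth_ehr import generate, site_config

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def dictionary():
    return load_concept_dictionary()


@pytest.fixture(scope="session")
def sepsis_sofa(dictionary):
    return load_score_definition("sepsis_sofa", dictionary)


@pytest.fixture(scope="session")
def sepsis_sofa_lmic(dictionary):
    return load_score_definition("sepsis_sofa_lmic", dictionary)


@pytest.fixture(scope="session")
def sofa_baseline_def(dictionary):
    return load_score_definition("sofa_baseline", dictionary)


@pytest.fixture(scope="session")
def synth_small():
    """A small but complete synthetic dataset shared across tests."""
    return generate(site_config("site_a", n_stays=400, seed=11))


def make_stays(rows):
    """Build a stays frame from (stay, subject, discharge, death, death_t, age)."""
    return pd.DataFrame(
        [
            {"stay_id": s, "subject_id": p, "icu_admit": 0.0, "icu_discharge": d,
             "hospital_death": hd, "death_time": dt, "age_years": a}
            for s, p, d, hd, dt, a in rows
        ]
    )


def make_measurements(rows):
    """(stay_id, concept_id, time, value) rows."""
    return pd.DataFrame(rows, columns=["stay_id", "concept_id", "time", "value"])


MED_COLUMNS = ["stay_id", "drug_id", "start", "end", "rate", "rate_unit",
               "route", "drug_class"]


def make_medications(rows):
    """(stay_id, drug_id, start, end, rate, drug_class) rows."""
    return pd.DataFrame(
        [
            {"stay_id": s, "drug_id": d, "start": a, "end": b, "rate": r,
             "rate_unit": "ug/kg/min", "route": "iv", "drug_class": c}
            for s, d, a, b, r, c in rows
        ],
        columns=MED_COLUMNS,
    )


def make_samplings(rows):
    return pd.DataFrame(rows, columns=["stay_id", "time", "specimen"])


def tiny_tables(stays, measurements=None, medications=None, samplings=None):
    empty_meas = make_measurements([])
    empty_meds = make_medications([])
    empty_samp = make_samplings([])
    return EhrTables(
        stays=stays,
        measurements=measurements if measurements is not None else empty_meas,
        medications=medications if medications is not None else empty_meds,
        samplings=samplings if samplings is not None else empty_samp,
    )
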