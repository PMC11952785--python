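"""Derived features: worst values, NEQ, adjusted MAP, sedation-adjusted GCS,
and the landmark feature matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sepscore.ehr_model import load_concept_dictionary, load_neq_table
from sepscore.features import (
    adjusted_map,
    build_feature_matrix,
    neq_at_times,
    neq_rate,
    sedation_adjusted_gcs,
    sedation_windows,
    worst_value,
)

from conftest import (
    make_measurements,
    make_medications,
    make_samplings,
    make_stays,
    tiny_tables,
)


@pytest.fixture(scope="module")
def neq():
    return load_neq_table()


# ---------------------------------------------------------------------------
# worst values


def test_worst_value_directions(dictionary):
    meas = make_measurements(
        [("s1", "lactate", t, v) for t, v in [(1, 1.2), (5, 3.4), (9, 2.0)]]
        + [("s1", "platelets", t, v) for t, v in [(1, 210), (5, 95), (9, 140)]]
    )
    assert worst_value(meas, "lactate", (0, 24), dictionary) == (3.4, False)
    assert worst_value(meas, "platelets", (0, 24), dictionary) == (95, False)


def test_worst_value_imputes_normal(dictionary):
    meas = make_measurements([])
    val, imputed = worst_value(meas, "lactate", (0, 24), dictionary)
    assert imputed and val == dictionary["lactate"].normal_value
    with pytest.raises(KeyError):
        worst_value(meas, "lactate_typo", (0, 24), dictionary)


def test_worst_value_window_is_half_open_below(dictionary):
    meas = make_measurements(
        [("s1", "lactate", 0.0, 9.0), ("s1", "lactate", 24.0, 2.0)]
    )
    # observation exactly at the window start is excluded, at the end included
    assert worst_value(meas, "lactate", (0, 24), dictionary) == (2.0, False)


def test_worst_value_order_independent(dictionary):
    rows = [("s1", "lactate", t, v) for t, v in [(1, 1.2), (5, 3.4), (9, 2.0)]]
    shuffled = make_measurements(rows[::-1])
    assert worst_value(shuffled, "lactate", (0, 24), dictionary) == (3.4, False)


# ---------------------------------------------------------------------------
# NEQ and adjusted MAP


def test_neq_rate_sums_converted_rates(neq):
    events = make_medications(
        [("s1", "norepinephrine", 0, 10, 0.1, "vasopressor"),
         ("s1", "epinephrine", 0, 10, 0.05, "vasopressor")]
    )
    assert neq_rate(events, neq) == pytest.approx(0.15)
    assert neq_rate(events.iloc[0:0], neq) == 0.0
    assert neq_rate(events.iloc[[0]], neq) == pytest.approx(0.1)


def test_neq_unknown_drug_fails(neq):
    events = make_medications([("s1", "milrinone", 0, 10, 0.3, "vasopressor")])
    with pytest.raises(KeyError, match="milrinone"):
        neq_rate(events, neq)


def test_neq_at_times_respects_active_interval(neq):
    events = make_medications(
        [("s1", "norepinephrine", 2.0, 6.0, 0.2, "vasopressor")]
    )
    out = neq_at_times(events, np.array([1.0, 2.0, 5.9, 6.0]), neq)
    # active iff start <= t < end
    assert out == pytest.approx([0.0, 0.2, 0.2, 0.0])


@pytest.mark.parametrize(
    "map_val,neq_val,beta,expected",
    [(70, 0.2, 200, 30.0), (80, 0.0, 200, 80.0), (65, 0.5, 200, -35.0)],
)
def test_adjusted_map_formula(map_val, neq_val, beta, expected):
    assert adjusted_map(map_val, neq_val, beta) == pytest.approx(expected)


@given(
    m=st.floats(20, 150), q=st.floats(0, 2), q2=st.floats(0, 2),
    beta=st.floats(0, 400),
)
def test_adjusted_map_linear_in_neq(m, q, q2, beta):
    a1 = adjusted_map(m, q, beta)
    a2 = adjusted_map(m, q2, beta)
    assert a1 - a2 == pytest.approx(-beta * (q - q2), abs=1e-6)


# ---------------------------------------------------------------------------
# sedation


def test_sedation_windows_drug_union():
    meds = make_medications(
        [("s1", "propofol", 2.0, 10.0, 30.0, "sedative")]
    )
    assert sedation_windows(meds) == [(2.0, 10.0)]
    meds = make_medications(
        [("s1", "midazolam", 3.0, 6.0, 2.0, "sedative"),
         ("s1", "fentanyl", 5.0, 9.0, 1.0, "sedative"),
         ("s1", "cefepime", 0.0, 1.0, np.nan, "antibiotic")]
    )
    assert sedation_windows(meds) == [(3.0, 9.0)]


def test_sedation_windows_rass_carry_forward():
    rass = pd.DataFrame({"time": [4.0, 8.0], "value": [-3.0, -1.0]})
    meds = make_medications([])
    assert sedation_windows(meds, rass, source="rass") == [(4.0, 8.0)]
    rass2 = pd.DataFrame({"time": [4.0], "value": [-2.0]})
    assert sedation_windows(meds, rass2, source="rass", stay_end=20.0) == [(4.0, 20.0)]
    rass3 = pd.DataFrame({"time": [4.0], "value": [0.0]})
    assert sedation_windows(meds, rass3, source="rass", stay_end=20.0) == []


def _gcs(rows):
    return pd.DataFrame(rows, columns=["time", "value"])


def test_gcs_set_max_15_inside_window():
    series = _gcs([(5.0, 6.0)])
    out = sedation_adjusted_gcs(series, [(2.0, 10.0)], "set_max_15")
    assert out["value"].tolist() == [15.0]


def test_gcs_carry_forward_uses_last_pre_window_reading():
    series = _gcs([(1.0, 14.0), (5.0, 6.0)])
    out = sedation_adjusted_gcs(series, [(2.0, 10.0)], "carry_forward")
    assert out["value"].tolist() == [14.0, 14.0]
    # with no pre-window reading the in-window reading is dropped
    out2 = sedation_adjusted_gcs(_gcs([(5.0, 6.0)]), [(2.0, 10.0)], "carry_forward")
    assert out2.empty


def test_gcs_raw_is_identity_and_bounds_enforced():
    series = _gcs([(1.0, 14.0), (5.0, 6.0)])
    out = sedation_adjusted_gcs(series, [(2.0, 10.0)], "raw")
    assert out["value"].tolist() == [14.0, 6.0]
    with pytest.raises(ValueError, match=r"\[3, 15\]"):
        sedation_adjusted_gcs(_gcs([(1.0, 2.0)]), [], "raw")


@given(
    readings=st.lists(
        st.tuples(st.floats(0, 48), st.integers(3, 15)), min_size=1, max_size=8
    ),
    win=st.tuples(st.floats(0, 48), st.floats(0, 24)),
)
def test_gcs_set_max_15_pointwise_dominates_raw(readings, win):
    series = _gcs([(t, float(v)) for t, v in readings])
    windows = [(win[0], win[0] + win[1])]
    adj = sedation_adjusted_gcs(series, windows, "set_max_15")
    raw = sedation_adjusted_gcs(series, windows, "raw")
    assert (adj["value"].to_numpy() >= raw["value"].to_numpy()).all()


# ---------------------------------------------------------------------------
# landmark feature matrix


def _matrix_fixture():
    stays = make_stays(
        [
            ("s1", "p1", 10.0, False, np.nan, 50.0),   # discharged before T=12
            ("s2", "p2", 100.0, True, 20.0, 50.0),     # dies at 20 h
            ("s3", "p3", 100.0, False, np.nan, 50.0),  # no measurements at all
            ("s4", "p4", 100.0, False, np.nan, 50.0),  # measured + on vasopressor
        ]
    )
    meas = make_measurements(
        [("s4", "map", 6.0, 70.0), ("s4", "map", 10.0, 90.0),
         ("s4", "lactate", 8.0, 4.5), ("s4", "gcs", 9.0, 6.0)]
    )
    meds = make_medications(
        [("s4", "norepinephrine", 5.0, 8.0, 0.2, "vasopressor"),
         ("s4", "propofol", 8.5, 11.0, 30.0, "sedative")]
    )
    cohort = pd.DataFrame(
        {"stay_id": ["s1", "s2", "s3", "s4"], "suspicion_time": 1.0,
         "included": True, "exclusion_reason": "none"}
    )
    return cohort, tiny_tables(stays, measurements=meas, medications=meds)


def test_landmark_rules_and_derived_features(dictionary, sepsis_sofa):
    cohort, tables = _matrix_fixture()
    X = build_feature_matrix(cohort, tables, dictionary, T=24.0, score_def=sepsis_sofa)
    assert set(X["stay_id"]) == {"s3", "s4"}  # s1 discharged, s2 dead by 24 h

    s3 = X.set_index("stay_id").loc["s3"]
    for cid in dictionary.concept_ids:
        assert s3[cid] == dictionary[cid].normal_value
        assert bool(s3[f"{cid}_imputed"])

    s4 = X.set_index("stay_id").loc["s4"]
    # MAP at 6 h is on norepinephrine 0.2 -> 70 - 200*0.2 = 30; at 10 h off -> 90
    assert s4["map_adjusted"] == pytest.approx(30.0)
    assert s4["map"] == pytest.approx(70.0)  # raw worst is the minimum
    # GCS 6 at 9 h falls in the propofol window -> set to 15
    assert s4["gcs"] == 15.0
    assert s4["lactate"] == 4.5
    assert s4["neq_max"] == pytest.approx(0.2)


def test_landmark_excludes_death_exactly_at_T(dictionary, sepsis_sofa):
    cohort, tables = _matrix_fixture()
    X = build_feature_matrix(cohort, tables, dictionary, T=20.0, score_def=sepsis_sofa)
    assert "s2" not in set(X["stay_id"])


def test_zero_vasopressor_adjusted_equals_raw_map(dictionary, sepsis_sofa, synth_small):
    from sepscore.cohort import build_cohort

    tables = synth_small.tables
    no_vaso = tables.medications[tables.medications["drug_class"] != "vasopressor"]
    stripped = tiny_tables(
        tables.stays, measurements=tables.measurements, medications=no_vaso,
        samplings=tables.samplings,
    )
    cohort = build_cohort(tables.stays, no_vaso, tables.samplings)
    X = build_feature_matrix(cohort, stripped, dictionary, 24.0, sepsis_sofa)
    measured = ~X["map_adjusted_imputed"]
    assert measured.any()
    assert np.allclose(
        X.loc[measured, "map_adjusted"], X.loc[measured, "map"]
    )
    assert (X["neq_max"] == 0).all()


def test_feature_matrix_row_order_invariance(dictionary, sepsis_sofa):
    cohort, tables = _matrix_fixture()
    shuffled = tiny_tables(
        tables.stays,
        measurements=tables.measurements.sample(frac=1, random_state=0),
        medications=tables.medications,
        samplings=tables.samplings,
    )
    a = build_feature_matrix(cohort, tables, dictionary, 24.0, sepsis_sofa)
    b = build_feature_matrix(cohort, shuffled, dictionary, 24.0, sepsis_sofa)
    pd.testing.assert_frame_equal(a, b)
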