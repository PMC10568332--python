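"""Covariate engineering: lookbacks, practice rates, prevalence join, encoding."""

import numpy as np
import pandas as pd
import pytest

import teletmle as t
from teletmle.cohort import ValidationError
from teletmle.covariates import (
    _REFERENCE_LEVELS,
    build_covariate_matrix,
    encode_design,
    join_prevalence,
    lookback_counts,
    practice_rates,
)
from conftest import make_consultations


def _episodes(index="2021-06-15", patient="PT000001", practice="P0001"):
    return pd.DataFrame(
        [{"episode_id": "E0", "patient_id": patient, "practice_id": practice,
          "index_date": pd.Timestamp(index)}]
    )


def _no_rx():
    return pd.DataFrame(columns=["prescription_id", "patient_id", "date",
                                 "antibiotic_flag", "consultation_id"])


def test_lookback_strictly_before_index():
    """An event on the index date is excluded from every lookback window;
    one 5 days earlier counts in both the 7- and 30-day windows."""
    cons = make_consultations([(0, "telephone")], start="2021-06-15")
    same_day = lookback_counts(_episodes(), cons, _no_rx())
    assert same_day[["cons_last_7d", "cons_last_30d", "cons_last_365d"]].iloc[0].sum() == 0

    cons5 = make_consultations([(0, "telephone")], start="2021-06-10")
    lb = lookback_counts(_episodes(), cons5, _no_rx())
    assert lb["cons_last_7d"].iloc[0] == 1
    assert lb["cons_last_30d"].iloc[0] == 1
    assert lb["cons_remote_last_7d"].iloc[0] == 1
    assert lb["cons_f2f_last_7d"].iloc[0] == 0


def test_lookback_no_events_all_zero():
    lb = lookback_counts(_episodes(), make_consultations([]), _no_rx())
    assert (lb.to_numpy() == 0).all()


def test_lookback_nesting_property(demo_study):
    ep = demo_study["episodes"]
    tab = demo_study["tables"]
    lb = lookback_counts(ep, tab.consultations, tab.prescriptions)
    for base in ("cons", "cons_remote", "cons_f2f", "ari", "ari_remote", "ari_f2f", "abx"):
        assert (lb[f"{base}_last_7d"] <= lb[f"{base}_last_30d"]).all()
        assert (lb[f"{base}_last_30d"] <= lb[f"{base}_last_365d"]).all()


def test_lookback_covid_flags_binary(demo_study):
    ep = demo_study["episodes"]
    tab = demo_study["tables"]
    lb = lookback_counts(ep, tab.consultations, tab.prescriptions)
    for w in (7, 30, 365):
        assert set(lb[f"covid_inf_last_{w}d"].unique()).issubset({0, 1})


def _rate_fixture(n_patients=2, n_rx=10, index="2021-06-15"):
    idx = pd.Timestamp(index)
    patients = pd.DataFrame(
        {
            "patient_id": [f"PT{i}" for i in range(n_patients)],
            "practice_id": "P0001",
            "registration_start": idx - pd.Timedelta(days=365),
            "registration_end": idx + pd.Timedelta(days=30),
        }
    )
    rx = pd.DataFrame(
        {
            "prescription_id": [f"R{i}" for i in range(n_rx)],
            "patient_id": "PT0",
            "date": idx - pd.Timedelta(days=10),
            "antibiotic_flag": 1,
            "consultation_id": None,
        }
    )
    cons = make_consultations([], patient_id="PT0")
    return _episodes(index=index, patient="PT0"), cons, rx, patients


def test_practice_rate_direct_arithmetic():
    """10 prescriptions over 2 x 365 patient-days -> 10,000 * 10 / 730."""
    ep, cons, rx, patients = _rate_fixture()
    rates = practice_rates(ep, cons, rx, patients)
    assert rates["practice_abx_rate_10k"].iloc[0] == pytest.approx(10_000 * 10 / 730)


def test_practice_rate_halves_when_list_doubles():
    _, cons, rx, _ = _rate_fixture()
    ep2, _, _, pat2 = _rate_fixture(n_patients=2)
    ep4, _, _, pat4 = _rate_fixture(n_patients=4)
    r2 = practice_rates(ep2, cons, rx, pat2)["practice_abx_rate_10k"].iloc[0]
    r4 = practice_rates(ep4, cons, rx, pat4)["practice_abx_rate_10k"].iloc[0]
    assert r4 == pytest.approx(r2 / 2)


def test_practice_rate_matches_brute_force(rng):
    """Random registration spans vs a day-by-day patient-day tally."""
    idx = pd.Timestamp("2021-08-01")
    n = 12
    starts = idx - pd.to_timedelta(rng.integers(50, 700, n), unit="D")
    ends = starts + pd.to_timedelta(rng.integers(100, 800, n), unit="D")
    patients = pd.DataFrame(
        {"patient_id": [f"PT{i}" for i in range(n)], "practice_id": "P0001",
         "registration_start": starts, "registration_end": ends}
    )
    rx_dates = idx - pd.to_timedelta(rng.integers(1, 500, 30), unit="D")
    rx = pd.DataFrame(
        {"prescription_id": [f"R{i}" for i in range(30)],
         "patient_id": "PT0", "date": rx_dates, "antibiotic_flag": 1,
         "consultation_id": None}
    )
    ep = _episodes(index=idx, patient="PT0")
    got = practice_rates(ep, make_consultations([]), rx, patients)["practice_abx_rate_10k"].iloc[0]

    days = pd.date_range(idx - pd.Timedelta(days=365), idx - pd.Timedelta(days=1))
    pdays = sum(((starts <= d) & (d <= ends)).sum() for d in days)
    n_rx = int(((rx_dates >= idx - pd.Timedelta(days=365)) & (rx_dates < idx)).sum())
    assert got == pytest.approx(10_000 * n_rx / pdays)


def test_practice_rate_zero_patient_days_is_error():
    ep, cons, rx, patients = _rate_fixture()
    patients["registration_start"] = pd.Timestamp("2021-06-16")  # after index
    patients["registration_end"] = pd.Timestamp("2021-06-20")
    with pytest.raises(ValidationError):
        practice_rates(ep, cons, rx, patients)


def _prev_series():
    return pd.DataFrame(
        {"region": "London",
         "date": pd.to_datetime(["2021-06-07", "2021-06-14", "2021-06-21"]),
         "infection_rate": [1.0, 1.64, 2.0]}
    )


def _practices():
    return pd.DataFrame({"practice_id": ["P0001"], "region": ["London"]})


def test_prevalence_exact_date_match():
    got = join_prevalence(_episodes(index="2021-06-14"), _prev_series(), _practices())
    assert got.iloc[0] == 1.64


def test_prevalence_between_dates_uses_earlier_value():
    got = join_prevalence(_episodes(index="2021-06-18"), _prev_series(), _practices())
    assert got.iloc[0] == 1.64


def test_prevalence_missing_region_is_error():
    prac = pd.DataFrame({"practice_id": ["P0001"], "region": ["Narnia"]})
    with pytest.raises(ValidationError):
        join_prevalence(_episodes(), _prev_series(), prac)


def test_prevalence_constant_series_constant_covariate(demo_study):
    tab = demo_study["tables"]
    prev = tab.prevalence.copy()
    prev["infection_rate"] = 2.5
    got = join_prevalence(demo_study["episodes"], prev, tab.practices)
    assert (got == 2.5).all()


def test_shift_invariance(demo_study):
    """Translating every date by a constant leaves all covariates unchanged."""
    import copy

    tab = demo_study["tables"]
    ep = demo_study["episodes"].head(200).reset_index(drop=True)
    base = build_covariate_matrix(ep, tab, stratum="all")

    shift = pd.Timedelta(days=37)
    tab2 = copy.deepcopy(tab)
    for frame, cols in (
        (tab2.patients, ["birth_date", "registration_start", "registration_end"]),
        (tab2.consultations, ["date"]),
        (tab2.prescriptions, ["date"]),
        (tab2.prevalence, ["date"]),
    ):
        for c in cols:
            frame[c] = frame[c] + shift
    ep2 = ep.copy()
    ep2["index_date"] = ep2["index_date"] + shift
    ep2["birth_date"] = ep2["birth_date"] + shift
    shifted = build_covariate_matrix(ep2, tab2, stratum="all")
    pd.testing.assert_frame_equal(base.frame, shifted.frame)


def test_covariate_matrix_shape_and_completeness(demo_study):
    ep = demo_study["episodes"]
    cov = build_covariate_matrix(ep, demo_study["tables"], stratum="all")
    assert len(cov.frame) == len(ep)
    X = encode_design(cov)
    assert not X.isna().any().any()
    assert X.select_dtypes(exclude="number").empty


def test_child_stratum_drops_adult_comorbidities(demo_study):
    ep = demo_study["episodes"]
    child = ep[ep["stratum"] == "child"]
    cov = build_covariate_matrix(child, demo_study["tables"], stratum="child")
    assert "copd" not in cov.numeric and "depression" not in cov.numeric
    assert "asthma" in cov.numeric


def test_encoding_round_trip(demo_study):
    """Decoding the one-hot block reproduces the raw categorical labels."""
    ep = demo_study["episodes"].head(100)
    cov = build_covariate_matrix(ep, demo_study["tables"], stratum="all")
    X = encode_design(cov)
    for col in cov.categorical:
        ref = _REFERENCE_LEVELS[col]
        onehots = [c for c in X.columns if c.startswith(f"{col}[")]
        decoded = []
        for _, row in X[onehots].iterrows():
            hits = [c[len(col) + 1 : -1] for c in onehots if row[c] == 1.0]
            decoded.append(hits[0] if hits else ref)
        raw = cov.frame[col].astype(str).tolist()
        assert decoded == raw
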