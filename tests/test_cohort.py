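"""Cohort rules: mode classification, filtering, grouping, linkage,
eligibility and the attrition flow."""

import numpy as np
import pandas as pd
import pytest

import teletmle as t
from teletmle.cohort import (
    ValidationError,
    apply_eligibility,
    build_cohort,
    classify_mode,
    filter_gp_ari,
    group_episodes,
    link_prescriptions,
)
from conftest import make_consultations


# -- mode classification -----------------------------------------------------

@pytest.mark.parametrize(
    "marker,expected",
    [
        ("telephone", "remote"),
        ("video", "remote"),
        ("sms", "remote"),
        ("internet", "remote"),
        ("surgery", "face_to_face"),
        ("home_visit", "face_to_face"),
        ("unknown", "face_to_face"),
    ],
)
def test_classify_mode(marker, expected):
    assert classify_mode(marker) == expected


def test_classify_mode_rejects_unrecognized_marker():
    with pytest.raises(ValidationError, match="carrier_pigeon"):
        classify_mode(pd.Series(["telephone", "carrier_pigeon"]))


# -- GP / ARI filter ----------------------------------------------------------

def test_filter_keeps_gp_ari_only():
    cons = make_consultations([(0, "surgery"), (1, "surgery"), (2, "surgery")])
    cons.loc[1, "clinician_role"] = "nurse"
    cons.loc[2, "diagnosis_codes"] = "OTHER"
    kept = filter_gp_ari(cons)
    assert list(kept["consultation_id"]) == ["C0000"]


def test_filter_requires_nonempty_code_set():
    with pytest.raises(ValidationError):
        filter_gp_ari(make_consultations([(0, "surgery")]), ari_code_set=[])


def test_filter_retains_all_codes_on_record():
    cons = make_consultations([(0, "surgery")], codes="URTI;OTHER;LRTI")
    kept = filter_gp_ari(cons)
    assert kept["diagnosis_codes"].iloc[0] == "URTI;OTHER;LRTI"


# -- episode grouping ---------------------------------------------------------

def test_group_days_0_3_6_single_episode():
    cons = make_consultations([(0, "telephone"), (3, "telephone"), (6, "video")])
    ep = group_episodes(cons)
    assert len(ep) == 1
    assert ep["index_date"].iloc[0] == pd.Timestamp("2021-06-01")
    assert ep["mode"].iloc[0] == "remote"
    assert ep["A"].iloc[0] == 1


def test_group_day_8_starts_new_episode():
    ep = group_episodes(make_consultations([(0, "surgery"), (8, "surgery")]))
    assert len(ep) == 2


def test_anchored_vs_rolling_grouping():
    cons = make_consultations([(0, "surgery"), (6, "surgery"), (12, "surgery")])
    assert len(group_episodes(cons, scheme="anchored")) == 2
    assert len(group_episodes(cons, scheme="rolling")) == 1


def test_mixed_modes_give_mixed_episode_in_arm_zero():
    ep = group_episodes(make_consultations([(0, "telephone"), (2, "surgery")]))
    assert len(ep) == 1
    assert ep["mode"].iloc[0] == "mixed"
    assert ep["A"].iloc[0] == 0


def test_same_day_records_share_an_episode():
    ep = group_episodes(make_consultations([(0, "surgery"), (0, "surgery")]))
    assert len(ep) == 1
    assert ep["n_consultations"].iloc[0] == 2


def test_subtypes_are_unioned():
    cons = make_consultations([(0, "surgery"), (2, "surgery")])
    cons.loc[1, "diagnosis_codes"] = "LRTI;COVID"
    ep = group_episodes(cons)
    assert ep["subtypes"].iloc[0] == "COVID;LRTI;URTI"


def test_unknown_grouping_scheme_rejected():
    with pytest.raises(ValidationError):
        group_episodes(make_consultations([(0, "surgery")]), scheme="sliding")


def test_grouping_partition_and_spacing(demo_study):
    """Every kept consultation lands in exactly one episode; within a patient
    consecutive anchored episodes start >= 7 days apart (idempotence)."""
    kept = filter_gp_ari(demo_study["tables"].consultations)
    episodes = group_episodes(kept)
    all_ids = [c for ids in episodes["consultation_ids"] for c in ids.split(";")]
    assert len(all_ids) == len(kept)
    assert len(set(all_ids)) == len(all_ids)
    for _, sub in episodes.groupby("patient_id"):
        gaps = sub["index_date"].sort_values().diff().dropna().dt.days
        assert (gaps >= 7).all()


# -- prescription linkage -----------------------------------------------------

def _episode_fixture():
    cons = make_consultations([(0, "telephone"), (3, "telephone")])
    return group_episodes(cons)


def _rx(date, consultation_id=None, patient="PT000001", flag=1):
    return pd.DataFrame(
        [{"prescription_id": "RX0", "patient_id": patient,
          "date": pd.Timestamp(date), "antibiotic_flag": flag,
          "consultation_id": consultation_id}]
    )


def test_link_by_id_any_date():
    ep = link_prescriptions(_episode_fixture(), _rx("2021-06-20", consultation_id="C0001"))
    assert ep["Y"].iloc[0] == 1


def test_link_by_same_date_without_id():
    ep = link_prescriptions(_episode_fixture(), _rx("2021-06-04"))
    assert ep["Y"].iloc[0] == 1


def test_no_link_three_days_later_without_id():
    ep = link_prescriptions(_episode_fixture(), _rx("2021-06-07"))
    assert ep["Y"].iloc[0] == 0


def test_non_antibiotic_prescriptions_ignored():
    ep = link_prescriptions(_episode_fixture(), _rx("2021-06-01", flag=0))
    assert ep["Y"].iloc[0] == 0


def test_unknown_patient_rejected():
    patients = pd.DataFrame({"patient_id": ["PT000001"]})
    with pytest.raises(ValidationError):
        link_prescriptions(_episode_fixture(), _rx("2021-06-01", patient="PT9"), patients)


# -- eligibility --------------------------------------------------------------

def _patients(sex="F", imd=3.0, birth="1990-01-01"):
    return pd.DataFrame(
        [{"patient_id": "PT000001", "practice_id": "P0001",
          "birth_date": pd.Timestamp(birth), "sex": sex, "imd_quintile": imd,
          "ethnicity": "white", "asthma": 0, "copd": 0, "depression": 0,
          "skin_condition": 0}]
    )


def test_missing_imd_drops_all_episodes():
    out = apply_eligibility(_episode_fixture(), _patients(imd=np.nan),
                            "2021-04-01", "2022-03-22")
    assert out.empty


def test_unrecorded_sex_drops_all_episodes():
    out = apply_eligibility(_episode_fixture(), _patients(sex="unknown"),
                            "2021-04-01", "2022-03-22")
    assert out.empty


def test_index_before_window_dropped():
    out = apply_eligibility(_episode_fixture(), _patients(), "2021-07-01", "2022-03-22")
    assert out.empty


def test_child_adult_boundary_at_16_years():
    # index date 2021-06-01: born 2005-07-01 -> 15.9y (child); 2005-06-01 -> 16.0y (adult)
    child = apply_eligibility(_episode_fixture(), _patients(birth="2005-07-01"),
                              "2021-04-01", "2022-03-22")
    adult = apply_eligibility(_episode_fixture(), _patients(birth="2005-06-01"),
                              "2021-04-01", "2022-03-22")
    assert child["stratum"].iloc[0] == "child"
    assert adult["stratum"].iloc[0] == "adult"


# -- full pipeline ------------------------------------------------------------

def test_attrition_flow_monotone_and_counts(demo_study):
    flow = demo_study["cohort"].flow
    vals = list(flow.values())
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    assert flow["episodes_grouped"] <= flow["same_day_groups"] <= flow["gp_ari_consultations"]


def test_drop_mixed_sensitivity(demo_study):
    tables = demo_study["tables"]
    cfg = demo_study["config"]
    main = demo_study["cohort"].episodes
    sens = build_cohort(tables, cfg.window_start, cfg.window_end, drop_mixed=True).episodes
    assert (main["mode"] == "mixed").any()
    assert not (sens["mode"] == "mixed").any()
    assert len(sens) < len(main)


def test_arm_coding(demo_study):
    ep = demo_study["episodes"]
    assert (ep.loc[ep["mode"] == "remote", "A"] == 1).all()
    assert (ep.loc[ep["mode"].isin(["face_to_face", "mixed"]), "A"] == 0).all()
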