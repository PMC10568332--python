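"""Consultation-episode cohort construction.

Turns raw event tables into analysis episodes: GP-only ARI consultations
are mode-classified, grouped into 7-day episodes per patient (retaining the
date of the first consultation), linked to antibiotic prescriptions, and
filtered by eligibility.  The analysis arm is A = 1 for fully remote
episodes and A = 0 for face-to-face or mixed episodes; a sensitivity flag
drops mixed episodes instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import (
    ARI_SUBTYPES,
    EventTables,
    F2F_MARKERS,
    GP_ROLES,
    REMOTE_MARKERS,
)

__all__ = [
    "ValidationError",
    "classify_mode",
    "filter_gp_ari",
    "group_episodes",
    "link_prescriptions",
    "apply_eligibility",
    "build_cohort",
    "CohortResult",
]


class ValidationError(ValueError):
    """Raised when input records violate the cohort contracts."""


DEFAULT_ARI_CODES = frozenset(ARI_SUBTYPES)
_REMOTE = frozenset(REMOTE_MARKERS)
_F2F = frozenset(F2F_MARKERS)

#: Child/adult boundary in years: child iff age at index < 16.
CHILD_AGE_LIMIT = 16.0


def classify_mode(mode_marker):
    """Classify raw mode markers as ``remote`` or ``face_to_face``.

    Telephone, video, SMS and internet contacts are remote; surgery and
    home-visit contacts are face-to-face.  A consultation whose mode is
    unclear (``unknown``) is assumed to be face-to-face.  Accepts a scalar
    or a pandas Series; unrecognized markers raise :class:`ValidationError`.
    """
    scalar = np.isscalar(mode_marker) or isinstance(mode_marker, str)
    markers = pd.Series([mode_marker]) if scalar else pd.Series(mode_marker)
    out = pd.Series(pd.NA, index=markers.index, dtype=object)
    out[markers.isin(_REMOTE)] = "remote"
    out[markers.isin(_F2F) | (markers == "unknown")] = "face_to_face"
    if out.isna().any():
        bad = sorted(set(markers[out.isna()].astype(str)))
        raise ValidationError(f"unrecognized mode marker(s): {bad}")
    if scalar:
        return out.iloc[0]
    out.index = mode_marker.index if isinstance(mode_marker, pd.Series) else out.index
    return out


def _split_codes(codes: pd.Series) -> pd.Series:
    return codes.fillna("").astype(str).str.split(";")


def filter_gp_ari(
    consultations: pd.DataFrame, ari_code_set: Iterable[str] = DEFAULT_ARI_CODES
) -> pd.DataFrame:
    """Keep GP consultations carrying at least one ARI diagnosis code.

    All recorded diagnosis codes stay on the record; only the clinician-role
    and any-ARI-code filters are applied.
    """
    ari = frozenset(ari_code_set)
    if not ari:
        raise ValidationError("ARI code set must not be empty")
    is_gp = consultations["clinician_role"].isin(GP_ROLES)
    has_ari = _split_codes(consultations["diagnosis_codes"]).map(
        lambda cs: any(c in ari for c in cs)
    )
    return consultations.loc[is_gp & has_ari].copy()


def _assign_groups(day_numbers: np.ndarray, window: int, scheme: str) -> np.ndarray:
    """Greedy episode ids for one patient's sorted consultation days."""
    gid = np.zeros(len(day_numbers), dtype=int)
    g = 0
    anchor = day_numbers[0]
    prev = day_numbers[0]
    for i in range(1, len(day_numbers)):
        d = day_numbers[i]
        ref = anchor if scheme == "anchored" else prev
        if d - ref >= window:
            g += 1
            anchor = d
        gid[i] = g
        prev = d
    return gid


def group_episodes(
    consultations: pd.DataFrame,
    window_days: int = 7,
    scheme: str = "anchored",
) -> pd.DataFrame:
    """Group a patient's ARI consultations within a 7-day period into episodes.

    Greedy chronological grouping: the first ungrouped consultation opens an
    episode at its date; under the default ``anchored`` scheme every later
    consultation with (date - index_date) < ``window_days`` joins it (so an
    episode spans at most ``window_days`` calendar days), and the first
    consultation beyond the window opens the next episode.  Under
    ``rolling``, the window restarts from each newly joined consultation.
    Same-day records always share an episode.  The episode keeps the date of
    its first consultation, the union of infection subtypes, the clinician
    role of the first consultation, and mode ``remote`` / ``face_to_face``
    when all contacts agree, else ``mixed``.
    """
    if scheme not in ("anchored", "rolling"):
        raise ValidationError(f"unknown grouping scheme {scheme!r}")
    cols = ["consultation_id", "patient_id", "date", "mode_marker", "diagnosis_codes",
            "clinician_role"]
    if consultations.empty:
        return pd.DataFrame(
            columns=["episode_id", "patient_id", "index_date", "mode", "A",
                     "subtypes", "clinician_role", "n_consultations",
                     "consultation_ids", "consultation_dates"]
        )
    df = consultations[cols].copy()
    df["mode_class"] = classify_mode(df["mode_marker"])
    df = df.sort_values(["patient_id", "date", "consultation_id"], kind="stable")
    df["_day"] = df["date"].values.astype("datetime64[D]").astype(int)

    gids = np.empty(len(df), dtype=int)
    pos = 0
    for _, idx in df.groupby("patient_id", sort=False).indices.items():
        days = df["_day"].to_numpy()[idx]
        gids[pos : pos + len(idx)] = _assign_groups(days, window_days, scheme)
        pos += len(idx)
    df["_gid"] = gids
    df["_remote"] = (df["mode_class"] == "remote").astype(int)
    df["_date_str"] = df["date"].dt.strftime("%Y-%m-%d")

    grp = df.groupby(["patient_id", "_gid"], sort=True)
    episodes = grp.agg(
        index_date=("date", "first"),
        clinician_role=("clinician_role", "first"),
        n_consultations=("consultation_id", "size"),
        consultation_ids=("consultation_id", ";".join),
        consultation_dates=("_date_str", ";".join),
        _n_remote=("_remote", "sum"),
    ).reset_index()
    episodes["mode"] = np.select(
        [
            episodes["_n_remote"] == episodes["n_consultations"],
            episodes["_n_remote"] == 0,
        ],
        ["remote", "face_to_face"],
        default="mixed",
    )

    # union of ARI subtypes across the grouped consultations
    codes = df[["patient_id", "_gid", "diagnosis_codes"]].copy()
    codes["code"] = _split_codes(codes["diagnosis_codes"])
    codes = codes.explode("code")
    codes = codes[codes["code"].isin(DEFAULT_ARI_CODES)]
    codes = codes.drop_duplicates(["patient_id", "_gid", "code"]).sort_values(
        ["patient_id", "_gid", "code"], kind="stable"
    )
    subtype_str = (
        codes.groupby(["patient_id", "_gid"], sort=True)["code"].agg(";".join).rename("subtypes")
    )
    episodes = episodes.merge(subtype_str, on=["patient_id", "_gid"], how="left")
    episodes["subtypes"] = episodes["subtypes"].fillna("")
    episodes = episodes.drop(columns=["_gid", "_n_remote"])
    episodes["A"] = (episodes["mode"] == "remote").astype(int)
    episodes = episodes.sort_values(["patient_id", "index_date"], kind="stable").reset_index(
        drop=True
    )
    episodes.insert(0, "episode_id", [f"E{i:06d}" for i in range(len(episodes))])
    return episodes


def link_prescriptions(
    episodes: pd.DataFrame,
    prescriptions: pd.DataFrame,
    patients: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Set the binary outcome Y from antibiotic prescriptions.

    Y = 1 when any antibiotic prescription links to any grouped consultation
    by linkage ID, or was issued on the same date as any grouped
    consultation of the episode.
    """
    rx = prescriptions.loc[prescriptions["antibiotic_flag"] == 1].copy()
    if patients is not None:
        unknown = ~rx["patient_id"].isin(patients["patient_id"])
        if unknown.any():
            bad = sorted(rx.loc[unknown, "patient_id"].astype(str).unique()[:5])
            raise ValidationError(f"prescriptions reference unknown patients: {bad}")
    out = episodes.copy()
    if out.empty or rx.empty:
        out["Y"] = 0 if "Y" not in out else out["Y"]
        out["Y"] = 0
        return out

    lut = out[["episode_id", "patient_id", "consultation_ids", "index_date"]].copy()
    lut["consultation_id"] = lut["consultation_ids"].str.split(";")
    expl = lut.explode("consultation_id")

    # path 1: linkage by consultation ID
    by_id = rx.dropna(subset=["consultation_id"]).merge(
        expl[["episode_id", "consultation_id"]], on="consultation_id", how="inner"
    )

    # path 2: same patient, same date as any grouped consultation
    # reconstruct each grouped consultation's date from the episode span is not
    # possible from episodes alone, so callers pass episodes built by
    # group_episodes, which carry consultation ids; dates come via the rx join
    # on (patient_id, date) against the consultation-level table if provided.
    by_date = pd.DataFrame(columns=["episode_id"])
    if "consultation_dates" in out.columns:
        dlut = out[["episode_id", "patient_id", "consultation_dates"]].copy()
        dlut["date"] = dlut["consultation_dates"].str.split(";")
        dlut = dlut.explode("date")
        dlut["date"] = pd.to_datetime(dlut["date"])
        by_date = rx.merge(dlut[["episode_id", "patient_id", "date"]],
                           on=["patient_id", "date"], how="inner")

    linked = set(by_id["episode_id"]) | set(by_date["episode_id"])
    out["Y"] = out["episode_id"].isin(linked).astype(int)
    return out


def apply_eligibility(
    episodes: pd.DataFrame,
    patients: pd.DataFrame,
    window_start,
    window_end,
    drop_mixed: bool = False,
) -> pd.DataFrame:
    """Apply patient- and window-level eligibility and assign age strata.

    Drops episodes of patients with unrecorded sex or missing IMD, restricts
    index dates to the analysis window, optionally drops mixed-mode episodes
    (sensitivity analysis), and assigns the adult/child stratum from age at
    the index date (child iff age < 16).
    """
    pat_cols = ["patient_id", "practice_id", "birth_date", "sex", "imd_quintile",
                "ethnicity"] + [c for c in patients.columns if c in
                                ("asthma", "copd", "depression", "skin_condition")]
    out = episodes.merge(patients[pat_cols], on="patient_id", how="left")
    out = out[out["sex"].isin(["M", "F"])]
    out = out[out["imd_quintile"].notna()]
    ws, we = pd.Timestamp(window_start), pd.Timestamp(window_end)
    out = out[(out["index_date"] >= ws) & (out["index_date"] <= we)]
    if drop_mixed:
        out = out[out["mode"] != "mixed"]
    out = out.copy()
    out["age_at_index"] = (out["index_date"] - out["birth_date"]).dt.days / 365.25
    out["stratum"] = np.where(out["age_at_index"] < CHILD_AGE_LIMIT, "child", "adult")
    return out.reset_index(drop=True)


@dataclass
class CohortResult:
    """Analysis episodes plus the attrition flow report."""

    episodes: pd.DataFrame
    flow: dict[str, int] = field(default_factory=dict)

    def assert_monotone(self) -> None:
        vals = list(self.flow.values())
        if any(b > a for a, b in zip(vals, vals[1:])):
            raise ValidationError(f"attrition flow is not monotone: {self.flow}")


def build_cohort(
    tables: EventTables,
    window_start=None,
    window_end=None,
    episode_window_days: int = 7,
    drop_mixed: bool = False,
    scheme: str = "anchored",
    ari_code_set: Iterable[str] = DEFAULT_ARI_CODES,
) -> CohortResult:
    """Full cohort pipeline: filter, group, link, apply eligibility.

    Returns the episode table with exposure arm A, outcome Y, stratum and
    patient/practice identifiers, plus a stage-by-stage attrition flow
    (raw consultations -> GP ARI -> same-day groups -> episodes -> eligible).
    """
    cons = tables.consultations
    if window_start is None:
        window_start = cons["date"].min()
    if window_end is None:
        window_end = cons["date"].max()
    flow: dict[str, int] = {"consultations_raw": len(cons)}

    kept = filter_gp_ari(cons, ari_code_set)
    flow["gp_ari_consultations"] = len(kept)
    flow["same_day_groups"] = int(kept.groupby(["patient_id", "date"]).ngroups)

    episodes = group_episodes(kept, window_days=episode_window_days, scheme=scheme)
    flow["episodes_grouped"] = len(episodes)

    episodes = link_prescriptions(episodes, tables.prescriptions, tables.patients)
    episodes = apply_eligibility(
        episodes, tables.patients, window_start, window_end, drop_mixed=drop_mixed
    )
    flow["eligible_episodes"] = len(episodes)
    episodes = episodes.drop(columns=["consultation_dates"], errors="ignore")
    result = CohortResult(episodes=episodes, flow=flow)
    result.assert_monotone()
    return result
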