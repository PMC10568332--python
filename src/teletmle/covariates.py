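"""Per-episode covariate engineering.

Builds the design matrix W used by both the treatment (propensity) and
outcome models: patient demographics, comorbidity, infection subtype,
clinician role, practice-level rates, regional COVID prevalence, and
lookback consultation / prescription counts.  Lookback windows are
half-open, [index - w, index): events on the index date never count
themselves.  Missingness is never imputed; for ethnicity it is an explicit
category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ValidationError, classify_mode
from .synthetic import ARI_SUBTYPES, COMORBIDITIES, EventTables

__all__ = [
    "CovariateMatrix",
    "lookback_counts",
    "practice_rates",
    "join_prevalence",
    "build_covariate_matrix",
    "encode_design",
]

LOOKBACK_WINDOWS = (7, 30, 365)

#: Comorbidity covariates per stratum (children carry a reduced set).
STRATUM_COMORBIDITIES = {
    "adult": ("asthma", "copd", "depression", "skin_condition"),
    "child": ("asthma", "skin_condition"),
    "all": COMORBIDITIES,
}

_REFERENCE_LEVELS = {
    "sex": "F",
    "imd_quintile": "1",
    "ethnicity": "white",
    "region": "London",
    "clinician_role": "general_medical_practitioner",
}


@dataclass
class CovariateMatrix:
    """One row per episode: cluster ids plus numeric and categorical blocks."""

    frame: pd.DataFrame
    numeric: list[str]
    categorical: list[str]

    @property
    def cluster_ids(self) -> pd.DataFrame:
        return self.frame[["episode_id", "practice_id", "patient_id"]]

    def schema(self) -> dict:
        sch = {"columns": {}, "reference_levels": {}}
        for c in self.numeric:
            sch["columns"][c] = "numeric"
        for c in self.categorical:
            sch["columns"][c] = "categorical"
            sch["reference_levels"][c] = _REFERENCE_LEVELS.get(c)
        return sch


def _day_numbers(dates) -> np.ndarray:
    return pd.DatetimeIndex(dates).values.astype("datetime64[D]").astype(np.int64)


_DAY_SHIFT = 2**21  # > any day-number span; packs (patient, day) into one int64


def _count_in_windows(
    episodes: pd.DataFrame, events: pd.DataFrame, windows=LOOKBACK_WINDOWS
) -> dict[int, np.ndarray]:
    """Events per episode in [index - w, index), per window, per patient.

    Vectorized by packing (patient code, day number) into a single sorted
    int64 key and counting with two searchsorted calls per window.
    """
    n = len(episodes)
    counts = {w: np.zeros(n, dtype=np.int64) for w in windows}
    if events.empty or episodes.empty:
        return counts
    pat_codes, uniques = pd.factorize(episodes["patient_id"], sort=False)
    ev_codes = pd.Index(uniques).get_indexer(events["patient_id"])
    keep = ev_codes >= 0
    ev_key = np.sort(
        ev_codes[keep].astype(np.int64) * _DAY_SHIFT + _day_numbers(events.loc[keep, "date"])
    )
    ep_base = pat_codes.astype(np.int64) * _DAY_SHIFT + _day_numbers(episodes["index_date"])
    hi = np.searchsorted(ev_key, ep_base, side="left")
    for w in windows:
        counts[w] = hi - np.searchsorted(ev_key, ep_base - w, side="left")
    return counts


def lookback_counts(
    episodes: pd.DataFrame,
    consultations: pd.DataFrame,
    prescriptions: pd.DataFrame,
    windows=LOOKBACK_WINDOWS,
    history_days: int = 365,
) -> pd.DataFrame:
    """The full lookback grid: consultation / ARI / antibiotic counts by mode
    and window, plus recorded-COVID flags.

    Raises :class:`ValidationError` when any index date precedes the
    available event history by less than the longest window.
    """
    if not episodes.empty and not consultations.empty:
        hist_start = consultations["date"].min()
        if (episodes["index_date"] - hist_start).dt.days.min() < max(windows) - history_days:
            raise ValidationError("index date precedes available event history")
    out = pd.DataFrame(index=episodes.index)
    cons = consultations.copy()
    cons["mode_class"] = classify_mode(cons["mode_marker"])
    codes = cons["diagnosis_codes"].fillna("").astype(str).str.split(";")
    cons["is_ari"] = codes.map(lambda cs: any(c in ARI_SUBTYPES for c in cs))
    cons["is_covid"] = codes.map(lambda cs: "COVID" in cs)

    event_sets = {
        "cons": cons,
        "cons_remote": cons[cons["mode_class"] == "remote"],
        "cons_f2f": cons[cons["mode_class"] == "face_to_face"],
        "ari": cons[cons["is_ari"]],
        "ari_remote": cons[cons["is_ari"] & (cons["mode_class"] == "remote")],
        "ari_f2f": cons[cons["is_ari"] & (cons["mode_class"] == "face_to_face")],
        "abx": prescriptions[prescriptions["antibiotic_flag"] == 1],
    }
    for name, ev in event_sets.items():
        cts = _count_in_windows(episodes, ev, windows)
        for w in windows:
            out[f"{name}_last_{w}d"] = cts[w]
    covid = _count_in_windows(episodes, cons[cons["is_covid"]], windows)
    for w in windows:
        out[f"covid_inf_last_{w}d"] = (covid[w] > 0).astype(int)
    return out


def practice_rates(
    episodes: pd.DataFrame,
    consultations: pd.DataFrame,
    prescriptions: pd.DataFrame,
    patients: pd.DataFrame,
    lookback: int = 365,
) -> pd.DataFrame:
    """Practice-level activity per 10,000 patient-days in the prior year.

    rate = 10,000 * (events at the practice in [index - 365, index)) /
    (registered patient-days at the practice over the same interval), for
    antibiotic prescriptions and for all consultations.
    """
    pat = patients[["patient_id", "practice_id", "registration_start", "registration_end"]]
    cons = consultations.merge(pat[["patient_id", "practice_id"]], on="patient_id", how="left")
    rx = prescriptions[prescriptions["antibiotic_flag"] == 1].merge(
        pat[["patient_id", "practice_id"]], on="patient_id", how="left"
    )
    cons_days = {p: np.sort(_day_numbers(s["date"])) for p, s in cons.groupby("practice_id")}
    rx_days = {p: np.sort(_day_numbers(s["date"])) for p, s in rx.groupby("practice_id")}
    reg = {
        p: (_day_numbers(s["registration_start"]), _day_numbers(s["registration_end"]))
        for p, s in pat.groupby("practice_id")
    }

    n = len(episodes)
    abx_rate = np.zeros(n)
    cons_rate = np.zeros(n)
    idx_days = _day_numbers(episodes["index_date"])
    for pid, rows in episodes.groupby("practice_id", sort=False).indices.items():
        t = idx_days[rows]
        rs, re = reg[pid]
        # patient-days: overlap of each registration span with [t-365, t)
        lo = np.maximum(rs[None, :], (t - lookback)[:, None])
        hi = np.minimum(re[None, :] + 1, t[:, None])  # registration_end inclusive
        pdays = np.clip(hi - lo, 0, None).sum(axis=1).astype(float)
        if np.any(pdays <= 0):
            raise ValidationError(f"zero patient-days at practice {pid}")
        for days, target in ((cons_days, cons_rate), (rx_days, abx_rate)):
            d = days.get(pid, np.empty(0, dtype=np.int64))
            cnt = np.searchsorted(d, t, "left") - np.searchsorted(d, t - lookback, "left")
            target[rows] = 10_000.0 * cnt / pdays
    return pd.DataFrame(
        {"practice_abx_rate_10k": abx_rate, "practice_cons_rate_10k": cons_rate},
        index=episodes.index,
    )


def join_prevalence(
    episodes: pd.DataFrame, prevalence: pd.DataFrame, practices: pd.DataFrame
) -> pd.Series:
    """Regional infection rate at the most recent series date <= index date.

    Last observation carried forward within region; a region missing from
    the series, or an index date before the series starts, is an error.
    """
    ep = episodes[["episode_id", "practice_id", "index_date"]].merge(
        practices[["practice_id", "region"]], on="practice_id", how="left"
    )
    missing = set(ep["region"].dropna().unique()) - set(prevalence["region"].unique())
    if missing or ep["region"].isna().any():
        raise ValidationError(f"regions absent from prevalence series: {sorted(missing)}")
    prev = prevalence.sort_values("date", kind="stable")
    ep = ep.sort_values("index_date", kind="stable")
    joined = pd.merge_asof(
        ep, prev, left_on="index_date", right_on="date", by="region", direction="backward"
    )
    if joined["infection_rate"].isna().any():
        raise ValidationError("prevalence series does not cover every (region, index date)")
    joined = joined.set_index(ep.index)
    return joined["infection_rate"].reindex(episodes.index)


def build_covariate_matrix(
    episodes: pd.DataFrame, tables: EventTables, stratum: str = "all"
) -> CovariateMatrix:
    """Assemble the full covariate matrix for one analysis stratum.

    One row per episode; no missing values after encoding (ethnicity
    missingness is its own level).  Column order is deterministic.
    """
    ep = episodes.reset_index(drop=True)
    frame = ep[["episode_id", "practice_id", "patient_id"]].copy()
    frame["age"] = ep["age_at_index"].to_numpy()
    frame["sex"] = ep["sex"].astype(str)
    frame["imd_quintile"] = ep["imd_quintile"].astype(int).astype(str)
    frame["ethnicity"] = ep["ethnicity"].astype(str)
    frame["clinician_role"] = ep["clinician_role"].astype(str)
    for s in ARI_SUBTYPES:
        frame[f"sub_{s.lower()}"] = (
            ep["subtypes"].fillna("").str.split(";").map(lambda cs: int(s in cs))
        )
    for c in STRATUM_COMORBIDITIES[stratum]:
        frame[c] = ep[c].astype(int).to_numpy()

    prac = tables.practices
    frame = frame.merge(
        prac[["practice_id", "region", "urban_flag", "list_size"]], on="practice_id", how="left"
    )

    lb = lookback_counts(ep, tables.consultations, tables.prescriptions)
    rates = practice_rates(ep, tables.consultations, tables.prescriptions, tables.patients)
    frame = pd.concat([frame, lb.reset_index(drop=True), rates.reset_index(drop=True)], axis=1)
    frame["ons_covid_rate"] = join_prevalence(ep, tables.prevalence, prac).to_numpy()

    numeric = (
        ["age", "list_size", "practice_abx_rate_10k", "practice_cons_rate_10k", "ons_covid_rate"]
        + list(lb.columns)
        + [f"sub_{s.lower()}" for s in ARI_SUBTYPES]
        + list(STRATUM_COMORBIDITIES[stratum])
        + ["urban_flag"]
    )
    categorical = ["sex", "imd_quintile", "ethnicity", "region", "clinician_role"]
    if frame[numeric].isna().any().any() or frame[categorical].isna().any().any():
        raise ValidationError("covariate matrix contains missing values")
    return CovariateMatrix(frame=frame, numeric=numeric, categorical=categorical)


def encode_design(cov: CovariateMatrix) -> pd.DataFrame:
    """One-hot encode the categorical block against recorded reference levels.

    Returns a fully numeric design frame indexed like ``cov.frame`` with a
    deterministic column order; decoding the indicator block against the
    schema reproduces the raw labels.
    """
    parts = [cov.frame[cov.numeric].astype(float)]
    for c in cov.categorical:
        ref = _REFERENCE_LEVELS.get(c)
        levels = sorted(cov.frame[c].astype(str).unique())
        for lev in levels:
            if lev == ref:
                continue
            parts.append(
                (cov.frame[c].astype(str) == lev).astype(float).rename(f"{c}[{lev}]")
            )
    X = pd.concat(parts, axis=1)
    X.index = cov.frame.index
    return X
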