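"""Synthetic primary-care EHR generator with known causal ground truth.

Emulates the structure of English primary-care event data for studying
antibiotic prescribing in acute respiratory infection (ARI) consultations:
patients nested in practices, repeated consultations, ARI diagnosis
subtypes, remote / face-to-face / unknown consultation-mode markers,
confounded mode assignment, and a binary prescribing outcome.

The generator is a structural causal model on the logit scale.  For each
ARI index consultation (episode) with covariate vector W:

    P(A = 1 | W)    = expit(gamma' f(W))          (mode model; A=1 remote)
    P(Y = 1 | A, W) = expit(beta' f(W) + beta_A A) (prescribing model)

where f(W) is a fixed named-feature map (age, sex, deprivation, ethnicity,
comorbidity, infection subtype, regional COVID prevalence, and a latent
practice-level random effect shared by both models).  Because the
coefficients are known, the marginal causal contrasts

    ATE = E[Y(1)] - E[Y(0)],
    OR  = [psi1 / (1 - psi1)] / [psi0 / (1 - psi0)],  psi_a = E[Y(a)],

are available to Monte-Carlo precision via :func:`true_marginal_effects`,
giving every downstream estimator a ground truth to recover.

Randomness flows from a single root seed through named
``numpy.random.SeedSequence`` spawns (one stream per generation stage), so
identical configs yield byte-identical output tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "TruthParams",
    "EventTables",
    "generate_study",
    "true_marginal_effects",
    "sample_population",
    "demo_config",
    "calibration_config",
    "confounded_null_config",
    "dr_config",
]


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


REGIONS = (
    "East Midlands",
    "East of England",
    "London",
    "North East",
    "North West",
    "South East",
    "South West",
    "West Midlands",
    "Yorkshire and the Humber",
)

ARI_SUBTYPES = ("URTI", "LRTI", "sinusitis", "otitis_externa", "otitis_media", "COVID")

#: GP job roles (all eligible for the analysis) and non-GP roles (dropped).
GP_ROLES = (
    "general_medical_practitioner",
    "gp_registrar",
    "salaried_gp",
    "locum_gp",
    "sessional_gp",
    "associate_gp",
)
GP_ROLE_PROBS = (0.695, 0.081, 0.139, 0.036, 0.046, 0.003)
NON_GP_ROLES = ("nurse", "pharmacist", "paramedic")

REMOTE_MARKERS = ("telephone", "video", "sms", "internet")
F2F_MARKERS = ("surgery", "home_visit")

COMORBIDITIES = ("asthma", "copd", "depression", "skin_condition")

_DEFAULT_SUBTYPE_PROBS = {
    "URTI": 0.55,
    "LRTI": 0.12,
    "sinusitis": 0.10,
    "otitis_externa": 0.05,
    "otitis_media": 0.08,
    "COVID": 0.10,
}

_DEFAULT_ETHNICITY_PROBS = {
    "white": 0.72,
    "asian": 0.07,
    "black": 0.03,
    "mixed": 0.02,
    "other": 0.02,
    "missing": 0.14,
}

_ADULT_COMORB_PREV = {"asthma": 0.17, "copd": 0.05, "depression": 0.25, "skin_condition": 0.45}
_CHILD_COMORB_PREV = {"asthma": 0.04, "copd": 0.0, "depression": 0.002, "skin_condition": 0.31}

# Demo-scale structural coefficients.  Mode model: remote consulting more
# common for URTI/sinusitis and adults, less for otitis media; outcome model:
# prescribing driven strongly by LRTI/otitis media, negatively by COVID.
DEFAULT_MODE_COEFS: Mapping[str, float] = {
    "intercept": 0.45,
    "age_std": 0.10,
    "child": -0.70,
    "sex_male": -0.08,
    "imd_c": 0.05,
    "sub_urti": 0.35,
    "sub_sinusitis": 0.45,
    "sub_otitis_media": -0.90,
    "sub_lrti": -0.20,
    "prevalence_c": -0.08,
    "asthma": 0.05,
    "practice_re": 1.0,
}

DEFAULT_OUTCOME_COEFS: Mapping[str, float] = {
    "intercept": -0.45,
    "A": 0.25,
    "age_std": 0.18,
    "child": -0.05,
    "sex_male": 0.03,
    "imd_c": 0.08,
    "sub_lrti": 1.90,
    "sub_otitis_media": 1.60,
    "sub_urti": -0.15,
    "sub_covid": -1.80,
    "asthma": 0.25,
    "copd": 0.30,
    "practice_re": 1.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic study.

    All proportions lie in [0, 1]; the study window must be non-empty.
    Identical configs (including ``seed``) produce byte-identical tables.
    """

    n_practices: int = 30
    patients_per_practice: int = 150
    window_start: str = "2021-04-01"
    window_end: str = "2022-03-22"
    mode_model_coefs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MODE_COEFS))
    outcome_model_coefs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_COEFS)
    )
    practice_random_effect_sd: float = 0.25
    repeat_consultation_rate: float = 0.20
    unknown_mode_fraction: float = 0.05
    mixed_episode_fraction: float = 0.05
    seed: int = 0
    # covariate-law parameters
    child_fraction: float = 0.30
    ari_episode_rate: float = 0.25
    second_subtype_fraction: float = 0.025
    subtype_probs: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SUBTYPE_PROBS))
    ethnicity_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ETHNICITY_PROBS)
    )
    missing_sex_fraction: float = 0.005
    missing_imd_fraction: float = 0.002
    # nuisance event rates (expected events per patient)
    background_consultation_rate: float = 3.0
    history_ari_rate: float = 0.15
    history_antibiotic_rate: float = 0.40
    noise_prescription_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_practices <= 0 or self.patients_per_practice <= 0:
            raise ConfigError("n_practices and patients_per_practice must be positive")
        if pd.Timestamp(self.window_start) >= pd.Timestamp(self.window_end):
            raise ConfigError("study window start must precede end")
        for name in (
            "unknown_mode_fraction",
            "mixed_episode_fraction",
            "child_fraction",
            "second_subtype_fraction",
            "missing_sex_fraction",
            "missing_imd_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in (
            "practice_random_effect_sd",
            "repeat_consultation_rate",
            "ari_episode_rate",
            "background_consultation_rate",
            "history_ari_rate",
            "history_antibiotic_rate",
            "noise_prescription_rate",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if "A" not in self.outcome_model_coefs:
            raise ConfigError("outcome_model_coefs must include the treatment coefficient 'A'")

    # -- convenience ---------------------------------------------------------
    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(self.window_start)

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(self.window_end)

    @property
    def history_start(self) -> pd.Timestamp:
        # 365 days of pre-window history so lookback covariates are always computable
        return self.start - pd.Timedelta(days=365)

    def to_json(self) -> str:
        d = asdict(self)
        d["mode_model_coefs"] = dict(self.mode_model_coefs)
        d["outcome_model_coefs"] = dict(self.outcome_model_coefs)
        return json.dumps(d, indent=2)


@dataclass(frozen=True)
class TruthParams:
    """Monte-Carlo ground truth for the generator's marginal estimands."""

    true_ate: float
    true_or: float
    psi1: float
    psi0: float
    mc_se: float
    n_mc: int


@dataclass
class EventTables:
    """The five raw event tables consumed by the cohort builder."""

    practices: pd.DataFrame
    patients: pd.DataFrame
    consultations: pd.DataFrame
    prescriptions: pd.DataFrame
    prevalence: pd.DataFrame

    _NAMES = ("practices", "patients", "consultations", "prescriptions", "prevalence")

    def write_csv(self, outdir: str | Path) -> None:
        """Write the five tables as CSV with ISO-8601 dates."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._NAMES:
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False, date_format="%Y-%m-%d")

    @classmethod
    def read_csv(cls, indir: str | Path) -> "EventTables":
        indir = Path(indir)
        kw: dict[str, pd.DataFrame] = {}
        date_cols = {
            "patients": ["birth_date", "registration_start", "registration_end"],
            "consultations": ["date"],
            "prescriptions": ["date"],
            "prevalence": ["date"],
        }
        for name in cls._NAMES:
            kw[name] = pd.read_csv(indir / f"{name}.csv", parse_dates=date_cols.get(name, False))
        return cls(**kw)


# ---------------------------------------------------------------------------
# feature map and structural models
# ---------------------------------------------------------------------------

def _features(frame: pd.DataFrame) -> dict[str, np.ndarray]:
    """Named feature map f(W) shared by the mode and outcome models."""
    age = frame["age"].to_numpy(float)
    out = {
        "intercept": np.ones(len(frame)),
        "age_std": (age - 40.0) / 25.0,
        "child": (age < 16.0).astype(float),
        "sex_male": frame["sex_male"].to_numpy(float),
        "imd_c": (frame["imd"].to_numpy(float) - 3.0) / 2.0,
        "eth_missing": (frame["ethnicity"] == "missing").to_numpy(float),
        "prevalence_c": frame["prevalence"].to_numpy(float) - 1.5,
        "practice_re": frame["practice_re"].to_numpy(float),
    }
    for c in COMORBIDITIES:
        out[c] = frame[c].to_numpy(float)
    for s in ARI_SUBTYPES:
        out[f"sub_{s.lower()}"] = frame[f"sub_{s.lower()}"].to_numpy(float)
    return out


def _linear_predictor(
    frame: pd.DataFrame, coefs: Mapping[str, float], A: np.ndarray | float | None = None
) -> np.ndarray:
    feats = _features(frame)
    lp = np.zeros(len(frame))
    for name, coef in coefs.items():
        if name == "A":
            if A is None:
                raise ConfigError("treatment value required for the outcome model")
            lp += coef * np.asarray(A, dtype=float)
            continue
        if name not in feats:
            raise ConfigError(f"unknown structural feature {name!r} in coefficient vector")
        lp += coef * feats[name]
    return lp


def prevalence_value(region_index: np.ndarray, dates: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Deterministic weekly regional COVID infection rate (% of population).

    A seasonal sinusoid with region-specific phase and level, held constant
    within each week (last observation carried forward), so the truth oracle
    can evaluate the same covariate law analytically.
    """
    days = (pd.DatetimeIndex(dates) - config.history_start).days.to_numpy()
    week_start = (days // 7) * 7
    t = week_start + (config.history_start - pd.Timestamp("2021-01-01")).days
    r = np.asarray(region_index, dtype=float)
    rate = 1.5 + 1.0 * np.sin(2 * np.pi * t / 365.0 + 0.6 * r) + 0.15 * ((r % 3) - 1)
    return np.clip(rate, 0.05, None)


def _draw_patient_core(rng: np.random.Generator, n: int, cfg: GeneratorConfig) -> pd.DataFrame:
    """Patient-level structural covariates, the marginal covariate law."""
    child = rng.random(n) < cfg.child_fraction
    age = np.where(child, rng.uniform(0.5, 16.0, n), rng.uniform(16.0, 88.0, n))
    sex_male = (rng.random(n) < 0.5).astype(int)
    imd = rng.integers(1, 6, n)
    eth_labels = list(cfg.ethnicity_probs)
    eth_p = np.array([cfg.ethnicity_probs[k] for k in eth_labels], float)
    ethnicity = rng.choice(eth_labels, size=n, p=eth_p / eth_p.sum())
    out = pd.DataFrame(
        {"age": age, "sex_male": sex_male, "imd": imd, "ethnicity": ethnicity}
    )
    for c in COMORBIDITIES:
        p_adult = _ADULT_COMORB_PREV[c]
        p_child = _CHILD_COMORB_PREV[c]
        p = np.where(child, p_child, p_adult)
        out[c] = (rng.random(n) < p).astype(int)
    return out


def _draw_episode_extras(rng: np.random.Generator, n: int, cfg: GeneratorConfig) -> pd.DataFrame:
    """Episode-level draws: index date, subtype indicator block, region."""
    n_days = (cfg.end - cfg.start).days + 1
    offsets = rng.integers(0, n_days, n)
    dates = cfg.start + pd.to_timedelta(offsets, unit="D")
    labels = list(cfg.subtype_probs)
    p = np.array([cfg.subtype_probs[k] for k in labels], float)
    primary = rng.choice(labels, size=n, p=p / p.sum())
    out = pd.DataFrame({"date": dates, "subtype_primary": primary})
    for s in ARI_SUBTYPES:
        out[f"sub_{s.lower()}"] = (primary == s).astype(int)
    second_mask = rng.random(n) < cfg.second_subtype_fraction
    secondary = rng.choice(labels, size=n, p=p / p.sum())
    out["subtype_secondary"] = np.where(second_mask & (secondary != primary), secondary, "")
    for s in ARI_SUBTYPES:
        out.loc[out["subtype_secondary"] == s, f"sub_{s.lower()}"] = 1
    out["region_index"] = rng.integers(0, len(REGIONS), n)
    return out


def _episode_frame_from_law(rng: np.random.Generator, n: int, cfg: GeneratorConfig) -> pd.DataFrame:
    """Draw n episode covariate vectors directly from the marginal law.

    Used by the Monte-Carlo truth oracle and by :func:`sample_population`.
    Matches the law induced by the hierarchical generator: episode counts per
    patient are covariate-independent, and practices are uniform over
    regions, so an episode's covariates follow the patient law plus
    independent episode-level draws and a N(0, sd) practice effect.
    """
    frame = _draw_patient_core(rng, n, cfg)
    extras = _draw_episode_extras(rng, n, cfg)
    frame = pd.concat([frame, extras], axis=1)
    frame["practice_re"] = rng.normal(0.0, cfg.practice_random_effect_sd, n)
    frame["prevalence"] = prevalence_value(
        frame["region_index"].to_numpy(), frame["date"].to_numpy(), cfg
    )
    return frame


def true_marginal_effects(
    config: GeneratorConfig, n_mc: int = 200_000, seed: int | None = None
) -> TruthParams:
    """Monte-Carlo evaluation of the generator's true marginal ATE and OR.

    Draws ``n_mc`` covariate vectors from the generator's covariate law,
    evaluates both potential-outcome probabilities per draw (setting A=1 and
    A=0 in the outcome model), and returns the mean difference, the marginal
    odds ratio formed from the two mean potential-outcome probabilities, and
    the Monte-Carlo standard error of the ATE.
    """
    if n_mc <= 0:
        raise ConfigError("n_mc must be positive")
    if seed is None:
        seed = int(np.random.SeedSequence(config.seed).spawn(7)[6].generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(seed)
    frame = _episode_frame_from_law(rng, n_mc, config)
    lp0 = _linear_predictor(frame, config.outcome_model_coefs, A=0.0)
    beta_a = float(config.outcome_model_coefs["A"])
    p0 = expit(lp0)
    p1 = expit(lp0 + beta_a)
    diff = p1 - p0
    psi1, psi0 = float(p1.mean()), float(p0.mean())
    true_or = (psi1 / (1 - psi1)) / (psi0 / (1 - psi0))
    mc_se = float(diff.std(ddof=1) / np.sqrt(n_mc)) if n_mc > 1 else 0.0
    return TruthParams(
        true_ate=float(diff.mean()), true_or=float(true_or), psi1=psi1, psi0=psi0,
        mc_se=mc_se, n_mc=int(n_mc),
    )


def sample_population(
    config: GeneratorConfig, n: int, seed: int | None = None
) -> pd.DataFrame:
    """Draw n analysis-ready episodes (W, A, Y) directly from the structural model.

    Bypasses the event-table representation; intended for estimator
    simulation studies where only the structural triple matters.  Returns the
    covariate frame with columns ``p_treat``, ``A``, ``p_outcome``, ``Y`` and
    the two potential-outcome probabilities ``p1``/``p0`` appended.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    frame = _episode_frame_from_law(rng, n, config)
    g = expit(_linear_predictor(frame, config.mode_model_coefs))
    A = (rng.random(n) < g).astype(int)
    lp0 = _linear_predictor(frame, config.outcome_model_coefs, A=0.0)
    beta_a = float(config.outcome_model_coefs["A"])
    frame["p_treat"] = g
    frame["A"] = A
    frame["p0"] = expit(lp0)
    frame["p1"] = expit(lp0 + beta_a)
    frame["p_outcome"] = np.where(A == 1, frame["p1"], frame["p0"])
    frame["Y"] = (rng.random(n) < frame["p_outcome"]).astype(int)
    return frame


# ---------------------------------------------------------------------------
# full event-table generation
# ---------------------------------------------------------------------------

def _streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ("practices", "patients", "episodes", "consultations", "prescriptions", "background")
    return dict(zip(names, (np.random.default_rng(s) for s in ss.spawn(len(names)))))


def generate_study(config: GeneratorConfig) -> EventTables:
    """Generate the five raw event tables for one synthetic study.

    Mode assignment follows the config's logistic mode model on generated
    covariates plus a practice random effect; the prescribing outcome follows
    the outcome model evaluated at the *true* assigned mode.  A configured
    fraction of consultation records carries an ``unknown`` mode marker, a
    configured fraction of episodes contains both modes (an extra
    opposite-mode contact within the 7-day window), and repeat same-episode
    records are injected at the configured rate.
    """
    rngs = _streams(config.seed)
    n_prac = config.n_practices
    n_pat = n_prac * config.patients_per_practice

    # practices ---------------------------------------------------------------
    rng = rngs["practices"]
    practices = pd.DataFrame(
        {
            "practice_id": [f"P{i:04d}" for i in range(n_prac)],
            "region_index": rng.integers(0, len(REGIONS), n_prac),
            "urban_flag": (rng.random(n_prac) < 0.85).astype(int),
            "list_size": np.round(rng.lognormal(np.log(12_000), 0.40, n_prac)).astype(int),
            "practice_re": rng.normal(0.0, config.practice_random_effect_sd, n_prac),
        }
    )
    practices["region"] = [REGIONS[i] for i in practices["region_index"]]

    # patients ----------------------------------------------------------------
    rng = rngs["patients"]
    core = _draw_patient_core(rng, n_pat, config)
    mid = config.start + (config.end - config.start) / 2
    patients = pd.DataFrame(
        {
            "patient_id": [f"PT{i:06d}" for i in range(n_pat)],
            "practice_id": np.repeat(practices["practice_id"].to_numpy(), config.patients_per_practice),
        }
    )
    patients["birth_date"] = (mid - pd.to_timedelta(core["age"] * 365.25, unit="D")).dt.normalize()
    sex = np.where(core["sex_male"] == 1, "M", "F")
    sex = np.where(rng.random(n_pat) < config.missing_sex_fraction, "unknown", sex)
    patients["sex"] = sex
    imd = core["imd"].astype(float).to_numpy()
    imd[rng.random(n_pat) < config.missing_imd_fraction] = np.nan
    patients["imd_quintile"] = imd
    patients["ethnicity"] = core["ethnicity"].to_numpy()
    for c in COMORBIDITIES:
        patients[c] = core[c].to_numpy()
    patients["registration_start"] = (
        config.history_start - pd.to_timedelta(rng.integers(0, 365, n_pat), unit="D")
    )
    patients["registration_end"] = config.end

    pat = patients.merge(
        practices[["practice_id", "region_index", "practice_re"]], on="practice_id", how="left"
    )

    # ARI index episodes ------------------------------------------------------
    rng = rngs["episodes"]
    n_ep_per_pat = rng.poisson(config.ari_episode_rate, n_pat)
    ep_pat_idx = np.repeat(np.arange(n_pat), n_ep_per_pat)
    n_ep = len(ep_pat_idx)
    ep = pd.DataFrame({"patient_idx": ep_pat_idx})
    ep["patient_id"] = pat["patient_id"].to_numpy()[ep_pat_idx]
    ep["practice_id"] = pat["practice_id"].to_numpy()[ep_pat_idx]
    ep["region_index"] = pat["region_index"].to_numpy()[ep_pat_idx]
    ep["practice_re"] = pat["practice_re"].to_numpy()[ep_pat_idx]
    extras = _draw_episode_extras(rng, n_ep, config)
    # episode covariates come from the hierarchy, not the i.i.d. extras draw
    extras = extras.drop(columns=["region_index"])
    ep = pd.concat([ep.reset_index(drop=True), extras], axis=1)
    ep["age"] = (
        (ep["date"] - pat["birth_date"].to_numpy()[ep_pat_idx]).dt.days / 365.25
    )
    # structural patient covariates (latent values, independent of recording gaps)
    for col in ("sex_male",):
        ep[col] = core["sex_male"].to_numpy()[ep_pat_idx]
    ep["imd"] = core["imd"].to_numpy()[ep_pat_idx]
    ep["ethnicity"] = core["ethnicity"].to_numpy()[ep_pat_idx]
    for c in COMORBIDITIES:
        ep[c] = core[c].to_numpy()[ep_pat_idx]
    ep["prevalence"] = prevalence_value(ep["region_index"].to_numpy(), ep["date"].to_numpy(), config)

    g = expit(_linear_predictor(ep, config.mode_model_coefs))
    ep["A"] = (rng.random(n_ep) < g).astype(int)
    lp0 = _linear_predictor(ep, config.outcome_model_coefs, A=0.0)
    beta_a = float(config.outcome_model_coefs["A"])
    p_y = expit(lp0 + beta_a * ep["A"].to_numpy())
    ep["Y"] = (rng.random(n_ep) < p_y).astype(int)

    # consultation records ----------------------------------------------------
    rng = rngs["consultations"]
    records = []

    def _markers(is_remote: np.ndarray, r: np.random.Generator) -> np.ndarray:
        m = np.empty(len(is_remote), dtype=object)
        rem = is_remote.astype(bool)
        m[rem] = r.choice(REMOTE_MARKERS, size=int(rem.sum()), p=(0.80, 0.10, 0.05, 0.05))
        m[~rem] = r.choice(F2F_MARKERS, size=int((~rem).sum()), p=(0.95, 0.05))
        return m

    codes = ep["subtype_primary"].astype(str)
    has2 = ep["subtype_secondary"] != ""
    codes = np.where(has2, codes + ";" + ep["subtype_secondary"].astype(str), codes)
    roles = rng.choice(GP_ROLES, size=n_ep, p=GP_ROLE_PROBS)
    index_rec = pd.DataFrame(
        {
            "patient_id": ep["patient_id"],
            "date": ep["date"],
            "clinician_role": roles,
            "mode_marker": _markers(ep["A"].to_numpy(), rng),
            "diagnosis_codes": codes,
            "episode_tag": np.arange(n_ep),
        }
    )
    records.append(index_rec)

    # repeat same-episode records (same mode, within 6 days of the index)
    n_rep = rng.poisson(config.repeat_consultation_rate, n_ep)
    rep_idx = np.repeat(np.arange(n_ep), n_rep)
    if len(rep_idx):
        offs = rng.integers(1, 7, len(rep_idx))
        records.append(
            pd.DataFrame(
                {
                    "patient_id": ep["patient_id"].to_numpy()[rep_idx],
                    "date": ep["date"].to_numpy()[rep_idx] + pd.to_timedelta(offs, unit="D"),
                    "clinician_role": rng.choice(GP_ROLES, size=len(rep_idx), p=GP_ROLE_PROBS),
                    "mode_marker": _markers(ep["A"].to_numpy()[rep_idx], rng),
                    "diagnosis_codes": np.asarray(codes, dtype=object)[rep_idx],
                    "episode_tag": rep_idx,
                }
            )
        )

    # mixed episodes: one extra opposite-mode contact inside the window
    mixed_mask = rng.random(n_ep) < config.mixed_episode_fraction
    mix_idx = np.flatnonzero(mixed_mask)
    if len(mix_idx):
        offs = rng.integers(1, 7, len(mix_idx))
        records.append(
            pd.DataFrame(
                {
                    "patient_id": ep["patient_id"].to_numpy()[mix_idx],
                    "date": ep["date"].to_numpy()[mix_idx] + pd.to_timedelta(offs, unit="D"),
                    "clinician_role": rng.choice(GP_ROLES, size=len(mix_idx), p=GP_ROLE_PROBS),
                    "mode_marker": _markers(1 - ep["A"].to_numpy()[mix_idx], rng),
                    "diagnosis_codes": np.asarray(codes, dtype=object)[mix_idx],
                    "episode_tag": mix_idx,
                }
            )
        )

    cons = pd.concat(records, ignore_index=True)
    unknown = rng.random(len(cons)) < config.unknown_mode_fraction
    cons.loc[unknown, "mode_marker"] = "unknown"

    # background non-ARI consultations (feed lookback covariates only)
    rng_bg = rngs["background"]
    full_days = (config.end - config.history_start).days + 1
    n_bg = rng_bg.poisson(config.background_consultation_rate, n_pat)
    bg_pat = np.repeat(np.arange(n_pat), n_bg)
    if len(bg_pat):
        bg = pd.DataFrame(
            {
                "patient_id": pat["patient_id"].to_numpy()[bg_pat],
                "date": config.history_start
                + pd.to_timedelta(rng_bg.integers(0, full_days, len(bg_pat)), unit="D"),
                "clinician_role": rng_bg.choice(
                    list(GP_ROLES) + list(NON_GP_ROLES),
                    size=len(bg_pat),
                    p=[0.42, 0.048, 0.084, 0.024, 0.027, 0.009, 0.24, 0.10, 0.048],
                ),
                "mode_marker": rng_bg.choice(
                    REMOTE_MARKERS + F2F_MARKERS, size=len(bg_pat),
                    p=(0.40, 0.05, 0.02, 0.03, 0.45, 0.05),
                ),
                "diagnosis_codes": "OTHER",
                "episode_tag": -1,
            }
        )
        cons = pd.concat([cons, bg], ignore_index=True)

    # pre-window GP ARI history (>= 8 days before the window so it never
    # chains into an in-window episode)
    hist_days = (config.start - pd.Timedelta(days=8) - config.history_start).days
    if hist_days > 0 and config.history_ari_rate > 0:
        n_h = rng_bg.poisson(config.history_ari_rate, n_pat)
        h_pat = np.repeat(np.arange(n_pat), n_h)
        if len(h_pat):
            labels = list(config.subtype_probs)
            p = np.array([config.subtype_probs[k] for k in labels], float)
            hist = pd.DataFrame(
                {
                    "patient_id": pat["patient_id"].to_numpy()[h_pat],
                    "date": config.history_start
                    + pd.to_timedelta(rng_bg.integers(0, hist_days, len(h_pat)), unit="D"),
                    "clinician_role": rng_bg.choice(GP_ROLES, size=len(h_pat), p=GP_ROLE_PROBS),
                    "mode_marker": rng_bg.choice(
                        REMOTE_MARKERS + F2F_MARKERS, size=len(h_pat),
                        p=(0.45, 0.05, 0.02, 0.03, 0.40, 0.05),
                    ),
                    "diagnosis_codes": rng_bg.choice(labels, size=len(h_pat), p=p / p.sum()),
                    "episode_tag": -1,
                }
            )
            cons = pd.concat([cons, hist], ignore_index=True)

    cons = cons.sort_values(["patient_id", "date", "episode_tag"], kind="stable").reset_index(
        drop=True
    )
    cons.insert(0, "consultation_id", [f"C{i:07d}" for i in range(len(cons))])

    # prescriptions -----------------------------------------------------------
    rng = rngs["prescriptions"]
    rx_parts = []
    ep_y1 = np.flatnonzero(ep["Y"].to_numpy() == 1)
    # map episode tag -> its index consultation id
    idx_cons = cons[cons["episode_tag"] >= 0].drop_duplicates("episode_tag", keep="first")
    tag_to_cid = dict(zip(idx_cons["episode_tag"], idx_cons["consultation_id"]))
    tag_to_date = dict(zip(idx_cons["episode_tag"], idx_cons["date"]))
    if len(ep_y1):
        by_id = rng.random(len(ep_y1)) < 0.5
        cid = np.where(by_id, [tag_to_cid[t] for t in ep_y1], None)
        base_dates = pd.to_datetime([tag_to_date[t] for t in ep_y1])
        dates = base_dates + pd.to_timedelta(np.where(by_id, rng.integers(0, 6, len(ep_y1)), 0), unit="D")
        rx_parts.append(
            pd.DataFrame(
                {
                    "patient_id": ep["patient_id"].to_numpy()[ep_y1],
                    "date": dates,
                    "antibiotic_flag": 1,
                    "consultation_id": cid,
                }
            )
        )
    # pre-window antibiotic history (no linkage IDs)
    pre_days = (config.start - pd.Timedelta(days=1) - config.history_start).days
    n_hx = rng.poisson(config.history_antibiotic_rate, n_pat)
    hx_pat = np.repeat(np.arange(n_pat), n_hx)
    if len(hx_pat) and pre_days > 0:
        rx_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pat["patient_id"].to_numpy()[hx_pat],
                    "date": config.history_start
                    + pd.to_timedelta(rng.integers(0, pre_days, len(hx_pat)), unit="D"),
                    "antibiotic_flag": 1,
                    "consultation_id": None,
                }
            )
        )
    # unlinked in-window antibiotic noise (optional misclassification source)
    if config.noise_prescription_rate > 0:
        n_nz = rng.poisson(config.noise_prescription_rate, n_pat)
        nz_pat = np.repeat(np.arange(n_pat), n_nz)
        if len(nz_pat):
            n_days = (config.end - config.start).days + 1
            rx_parts.append(
                pd.DataFrame(
                    {
                        "patient_id": pat["patient_id"].to_numpy()[nz_pat],
                        "date": config.start
                        + pd.to_timedelta(rng.integers(0, n_days, len(nz_pat)), unit="D"),
                        "antibiotic_flag": 1,
                        "consultation_id": None,
                    }
                )
            )
    # a sprinkle of non-antibiotic prescriptions (filtered out upstream)
    n_na = rng.poisson(0.3, n_pat)
    na_pat = np.repeat(np.arange(n_pat), n_na)
    if len(na_pat):
        rx_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pat["patient_id"].to_numpy()[na_pat],
                    "date": config.history_start
                    + pd.to_timedelta(rng.integers(0, full_days, len(na_pat)), unit="D"),
                    "antibiotic_flag": 0,
                    "consultation_id": None,
                }
            )
        )
    if rx_parts:
        rx = pd.concat(rx_parts, ignore_index=True)
    else:
        rx = pd.DataFrame(columns=["patient_id", "date", "antibiotic_flag", "consultation_id"])
    rx = rx.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)
    rx.insert(0, "prescription_id", [f"RX{i:07d}" for i in range(len(rx))])

    # prevalence series -------------------------------------------------------
    weeks = pd.date_range(config.history_start, config.end, freq="7D")
    prev_rows = []
    for ridx, rname in enumerate(REGIONS):
        prev_rows.append(
            pd.DataFrame(
                {
                    "region": rname,
                    "date": weeks,
                    "infection_rate": prevalence_value(
                        np.full(len(weeks), ridx), weeks.to_numpy(), config
                    ),
                }
            )
        )
    prevalence = pd.concat(prev_rows, ignore_index=True)

    cons = cons.drop(columns=["episode_tag"])
    practices_out = practices[
        ["practice_id", "region", "urban_flag", "list_size", "practice_re"]
    ].copy()
    return EventTables(
        practices=practices_out,
        patients=patients,
        consultations=cons,
        prescriptions=rx,
        prevalence=prevalence,
    )


# ---------------------------------------------------------------------------
# preset study designs
# ---------------------------------------------------------------------------

def demo_config(seed: int = 0) -> GeneratorConfig:
    """Small mixed-age demo study (~1,100 episodes) with all realism features on."""
    return GeneratorConfig(seed=seed)


def calibration_config(seed: int = 0, n_episodes: int = 2_000) -> GeneratorConfig:
    """Estimator-calibration design: adult-only, no exposure misclassification.

    The practice random effect enters the outcome model only, so the
    estimand is identified from observed covariates; the treatment
    coefficient is set so the true marginal odds ratio is 1.25 (solved
    against the Monte-Carlo truth oracle).
    """
    n_prac = max(20, round(np.sqrt(n_episodes / 0.8)))
    per = max(10, int(np.ceil(n_episodes / (0.4 * n_prac))))
    mode = dict(DEFAULT_MODE_COEFS)
    mode.pop("child", None)
    mode["practice_re"] = 0.0
    outcome = dict(DEFAULT_OUTCOME_COEFS)
    outcome.pop("child", None)
    outcome["A"] = BETA_A_OR125
    return GeneratorConfig(
        n_practices=n_prac,
        patients_per_practice=per,
        mode_model_coefs=mode,
        outcome_model_coefs=outcome,
        practice_random_effect_sd=0.25,
        repeat_consultation_rate=0.20,
        unknown_mode_fraction=0.0,
        mixed_episode_fraction=0.0,
        noise_prescription_rate=0.0,
        child_fraction=0.0,
        ari_episode_rate=0.4,
        seed=seed,
    )


#: Treatment coefficient giving a true marginal OR of 1.25 under the
#: calibration covariate law (solved once by bisection on the truth oracle).
BETA_A_OR125 = 0.27052


def confounded_null_config(seed: int = 0, n_episodes: int = 2_000) -> GeneratorConfig:
    """Null-effect design (beta_A = 0) with confounding intact.

    The crude remote-vs-face-to-face difference is nonzero while the true
    ATE is exactly zero -- the fixture that makes covariate adjustment
    testable.
    """
    cfg = calibration_config(seed=seed, n_episodes=n_episodes)
    outcome = dict(cfg.outcome_model_coefs)
    outcome["A"] = 0.0
    return replace(cfg, outcome_model_coefs=outcome)


def dr_config(seed: int = 0) -> GeneratorConfig:
    """Strongly confounded design for double-robustness simulations.

    No practice random effect, so a logistic model on the structural
    features is an exactly correct propensity specification.
    """
    mode = {
        "intercept": 0.0,
        "age_std": 1.0,
        "imd_c": 0.8,
        "sub_lrti": 1.2,
        "sub_urti": 0.6,
        "asthma": 0.7,
    }
    outcome = {
        "intercept": -0.8,
        "A": 0.3,
        "age_std": 1.2,
        "imd_c": 0.9,
        "sub_lrti": 2.0,
        "sub_urti": -0.4,
        "asthma": 0.8,
    }
    return GeneratorConfig(
        mode_model_coefs=mode,
        outcome_model_coefs=outcome,
        practice_random_effect_sd=0.0,
        unknown_mode_fraction=0.0,
        mixed_episode_fraction=0.0,
        child_fraction=0.0,
        seed=seed,
    )
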