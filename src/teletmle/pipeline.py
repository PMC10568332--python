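"""End-to-end orchestration: generate/load -> cohort -> covariates ->
diagnostics -> estimation, plus the simulation calibration harness.

A run is fully determined by a :class:`RunConfig` (serializable to YAML);
a persisted config re-runs to identical outputs apart from timestamps in
the manifest.  Stage-specific seeds derive deterministically from the
single root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .balance import balance_table, summary_table
from .cohort import build_cohort
from .covariates import build_covariate_matrix, encode_design
from .synthetic import EventTables, GeneratorConfig, TruthParams, true_marginal_effects
from .tmle import StratumResult, TmleConfig, run_tmle

__all__ = ["RunConfig", "run_all", "simulate_calibration"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    generator: GeneratorConfig | None = None
    tables_dir: str | None = None
    window_start: str | None = None
    window_end: str | None = None
    episode_window_days: int = 7
    drop_mixed: bool = False
    strata: tuple[str, ...] = ("adult", "child")
    learner_profile: str = "fast"
    K: int = 10
    seed: int = 0
    g_bounds: tuple[float, float] = (0.005, 0.995)
    variance: str = "individual"
    metalearner: str = "nnls"

    def tmle_config(self) -> TmleConfig:
        return TmleConfig(
            learner_profile=self.learner_profile,
            K=self.K,
            seed=_derive_seed(self.seed, "tmle"),
            g_bounds=self.g_bounds,
            variance=self.variance,
            metalearner=self.metalearner,
        )

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"]["mode_model_coefs"] = dict(self.generator.mode_model_coefs)
            d["generator"]["outcome_model_coefs"] = dict(self.generator.outcome_model_coefs)
        d["strata"] = list(self.strata)
        d["g_bounds"] = list(self.g_bounds)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        gen = d.pop("generator", None)
        if gen is not None:
            gen = GeneratorConfig(**gen)
        d["strata"] = tuple(d.get("strata", ("adult", "child")))
        d["g_bounds"] = tuple(d.get("g_bounds", (0.005, 0.995)))
        return cls(generator=gen, **{k: v for k, v in d.items() if k != "generator"})


def _derive_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _format_report(results: dict[str, StratumResult]) -> str:
    lines = []
    for stratum, r in results.items():
        e = r.estimates
        lines.append(
            f"[{stratum}] n={r.n}: {100 * e.psi0:.1f}% (95% CI: {100 * e.ci_psi0[0]:.1f}, "
            f"{100 * e.ci_psi0[1]:.1f}) would have been prescribed antibiotics if all seen "
            f"face-to-face vs {100 * e.psi1:.1f}% (95% CI: {100 * e.ci_psi1[0]:.1f}, "
            f"{100 * e.ci_psi1[1]:.1f}) if seen remotely; ATE {100 * e.ate:.1f}% "
            f"(95% CI: {100 * e.ci_ate[0]:.1f}, {100 * e.ci_ate[1]:.1f}); "
            f"OR {e.or_:.2f} (95% CI: {e.ci_or[0]:.2f}, {e.ci_or[1]:.2f})."
        )
        lines.append(
            f"[{stratum}] propensity extremes: min {r.positivity.minimum:.3f}, "
            f"max {r.positivity.maximum:.3f}."
        )
    return "\n".join(lines)


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Run the whole pipeline and write every artifact into ``outdir``.

    Artifacts: the event tables (when generated), episodes and attrition
    flow, the covariate matrix and schema, summary and balance tables, the
    positivity report, per-stratum estimates, a plain-text results report,
    and a manifest of seeds and timings.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.to_yaml())

    if config.generator is not None:
        gen = replace(config.generator, seed=_derive_seed(config.seed, "generate")
                      if config.generator.seed == 0 else config.generator.seed)
        tables = synthetic.generate_study(gen)
        tables.write_csv(outdir / "tables")
        truth = true_marginal_effects(gen)
        (outdir / "truth.json").write_text(json.dumps(
            {"config": json.loads(gen.to_json()), "truth": dataclasses.asdict(truth)}, indent=2))
        ws = config.window_start or gen.window_start
        we = config.window_end or gen.window_end
    elif config.tables_dir is not None:
        tables = EventTables.read_csv(config.tables_dir)
        ws, we = config.window_start, config.window_end
    else:
        raise ValueError("config must provide either a generator or a tables_dir")

    cohort = build_cohort(
        tables,
        window_start=ws,
        window_end=we,
        episode_window_days=config.episode_window_days,
        drop_mixed=config.drop_mixed,
    )
    episodes = cohort.episodes
    episodes.to_csv(outdir / "episodes.csv", index=False, date_format="%Y-%m-%d")
    (outdir / "attrition_flow.json").write_text(json.dumps(cohort.flow, indent=2))

    cov = build_covariate_matrix(episodes, tables, stratum="all")
    cov.frame.to_csv(outdir / "covariates.csv", index=False)
    (outdir / "covariate_schema.json").write_text(json.dumps(cov.schema(), indent=2))

    diag = cov.frame.copy()
    diag["A"] = episodes["A"].to_numpy()
    diag["Y"] = episodes["Y"].to_numpy()
    summary = summary_table(diag, by="A", numeric=["age"], categorical=["sex", "ethnicity"])
    summary.to_csv(outdir / "summary_table.csv", index=False)
    bal = balance_table(diag, arm="A", numeric=cov.numeric, categorical=cov.categorical)
    bal.to_csv(outdir / "balance.csv", index=False)

    results = run_tmle(episodes, tables, config.tmle_config(), strata=config.strata)
    (outdir / "estimates.json").write_text(
        json.dumps({s: r.to_dict() for s, r in results.items()}, indent=2)
    )
    (outdir / "report.txt").write_text(_format_report(results) + "\n")

    manifest = {
        "seed": config.seed,
        "derived_seeds": {s: _derive_seed(config.seed, s) for s in ("generate", "tmle")},
        "arm_counts": episodes["A"].value_counts().to_dict(),
        "flow": cohort.flow,
        "elapsed_s": round(time.time() - t0, 2),
        "config_hash": hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=int))
    return outdir


def _analyze_once(gen: GeneratorConfig, tmle_cfg: TmleConfig, strata=("all",)) -> StratumResult:
    tables = synthetic.generate_study(gen)
    cohort = build_cohort(tables, window_start=gen.window_start, window_end=gen.window_end)
    res = run_tmle(cohort.episodes, tables, tmle_cfg, strata=strata)
    return res[strata[0]]


def simulate_calibration(
    config: GeneratorConfig,
    n_reps: int,
    truth: TruthParams | None = None,
    tmle_config: TmleConfig | None = None,
    seed: int = 0,
    progress: bool = False,
) -> dict:
    """Repeated generate -> analyze replicates against the known truth.

    Returns a dict with the per-replicate table and summary metrics: bias,
    empirical SE, mean estimated SE, and 95% CI coverage for the ATE and
    the log marginal OR.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    if truth is None:
        truth = true_marginal_effects(config)
    if tmle_config is None:
        tmle_config = TmleConfig(learner_profile="fast", K=10)
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n_reps)
    ]
    rows = []
    for i, s in enumerate(child_seeds):
        gen_i = replace(config, seed=s)
        cfg_i = dataclasses.replace(tmle_config, seed=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = _analyze_once(gen_i, cfg_i)
        e = r.estimates
        rows.append(
            {
                "rep": i,
                "seed": s,
                "n": r.n,
                "ate": e.ate,
                "se_ate": e.se_ate,
                "or": e.or_,
                "se_log_or": e.se_log_or,
                "cover_ate": e.ci_ate[0] <= truth.true_ate <= e.ci_ate[1],
                "cover_log_or": e.ci_or[0] <= truth.true_or <= e.ci_or[1],
            }
        )
        if progress:
            print(f"rep {i + 1}/{n_reps}: ate={e.ate:.4f}", flush=True)
    reps = pd.DataFrame(rows)
    summary = {
        "n_reps": n_reps,
        "true_ate": truth.true_ate,
        "true_or": truth.true_or,
        "mean_ate": float(reps["ate"].mean()),
        "bias_ate": float(reps["ate"].mean() - truth.true_ate),
        "empirical_se_ate": float(reps["ate"].std(ddof=1)),
        "mean_estimated_se_ate": float(reps["se_ate"].mean()),
        "coverage_ate": float(reps["cover_ate"].mean()),
        "coverage_log_or": float(reps["cover_log_or"].mean()),
        "mean_or": float(reps["or"].mean()),
    }
    return {"replicates": reps, "summary": summary, "truth": truth}
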