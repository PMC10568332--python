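"""Targeted maximum likelihood estimation of the ATE and marginal odds ratio.

Given initial estimates Q0(A, W) of the outcome regression and g(W) of the
propensity score, the targeting step fluctuates Q0 along the one-parameter
logistic submodel

    logit Q*(A, W) = logit Q0(A, W) + eps * H(A, W),
    H(A, W) = A / g(W) - (1 - A) / (1 - g(W)),

with eps the Bernoulli-likelihood maximizer, so the efficient
influence-function estimating equation (1/n) sum_i H_i (Y_i - Q*_i) = 0 is
solved.  Plug-in counterfactual means psi_a = mean(Q*_a) give the ATE
psi1 - psi0 and marginal OR [psi1/(1-psi1)]/[psi0/(1-psi0)]; standard
errors come from the empirical influence curves (individual-level by
default, practice-cluster-summed on request), with OR inference on the log
scale by the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .balance import PositivityReport, positivity_report
from .covariates import build_covariate_matrix, encode_design
from .superlearner import (
    PROB_CLIP,
    FoldAssignment,
    SuperLearnerFit,
    cv_fit,
    learner_library,
    make_folds,
)

__all__ = [
    "TmleInputs",
    "TmleEstimates",
    "TmleConfig",
    "clever_covariate",
    "fluctuate",
    "fluctuate_weighted",
    "target_and_estimate",
    "tmle_from_inputs",
    "tmle_unadjusted",
    "run_tmle",
    "marginal_odds_ratio",
]

Z975 = 1.959963984540054


def marginal_odds_ratio(psi1: float, psi0: float) -> float:
    """[psi1 / (1 - psi1)] / [psi0 / (1 - psi0)] for means in (0, 1)."""
    if not (0 < psi1 < 1 and 0 < psi0 < 1):
        raise ValueError("counterfactual means must lie strictly inside (0, 1)")
    return (psi1 / (1 - psi1)) / (psi0 / (1 - psi0))


@dataclass
class TmleInputs:
    """Initial estimates feeding the targeting step.

    Probabilities are clipped into (0, 1) on construction; all vectors must
    share a length.
    """

    Y: np.ndarray
    A: np.ndarray
    Q0_A: np.ndarray
    Q0_1: np.ndarray
    Q0_0: np.ndarray
    g: np.ndarray
    cluster: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.Y)
        for name in ("A", "Q0_A", "Q0_1", "Q0_0", "g"):
            v = np.asarray(getattr(self, name), dtype=float)
            if len(v) != n:
                raise ValueError(f"{name} has length {len(v)}, expected {n}")
            if name != "A":
                v = np.clip(v, PROB_CLIP, 1 - PROB_CLIP)
            setattr(self, name, v)
        if not set(np.unique(self.Y)).issubset({0.0, 1.0}):
            raise ValueError("Y must be binary")
        if not set(np.unique(self.A)).issubset({0.0, 1.0}):
            raise ValueError("A must be binary")


@dataclass
class TmleEstimates:
    """Targeted estimates, influence curves and normal-theory 95% CIs."""

    epsilon: float | tuple[float, float]
    psi1: float
    psi0: float
    ate: float
    or_: float
    se_ate: float
    se_psi1: float
    se_psi0: float
    se_log_or: float
    ci_ate: tuple[float, float]
    ci_or: tuple[float, float]
    ci_psi1: tuple[float, float]
    ci_psi0: tuple[float, float]
    score: float
    n: int
    ic: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "psi1": self.psi1,
            "psi0": self.psi0,
            "ate": self.ate,
            "or": self.or_,
            "se_ate": self.se_ate,
            "se_log_or": self.se_log_or,
            "ci_ate": list(self.ci_ate),
            "ci_or": list(self.ci_or),
            "ci_psi1": list(self.ci_psi1),
            "ci_psi0": list(self.ci_psi0),
            "score": self.score,
            "n": self.n,
        }


def clever_covariate(A, g):
    """The clever covariate H = A/g - (1-A)/(1-g) and its arm versions.

    Returns ``(H, H1, H0)`` with H1 = 1/g and H0 = -1/(1-g) used to update
    the counterfactual predictions.  g must be strictly inside (0, 1).
    """
    A = np.asarray(A, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any((g <= 0.0) | (g >= 1.0)):
        raise ValueError("propensity scores must be strictly inside (0, 1); clip upstream")
    H1 = 1.0 / g
    H0 = -1.0 / (1.0 - g)
    H = A * H1 + (1.0 - A) * H0
    return H, H1, H0


def fluctuate(inputs: TmleInputs, tol: float = 1e-10, max_iter: int = 200) -> float:
    """Solve for the fluctuation coefficient eps by 1-D logistic MLE.

    Newton iteration with analytic gradient on the score
    s(eps) = mean(H (Y - expit(logit Q0 + eps H))); at the solution the
    score is zero within ``tol``.
    """
    H, _, _ = clever_covariate(inputs.A, inputs.g)
    off = logit(inputs.Q0_A)
    y = inputs.Y
    eps = 0.0
    for _ in range(max_iter):
        q = expit(off + eps * H)
        score = float(np.mean(H * (y - q)))
        if abs(score) < tol:
            return eps
        curv = float(np.mean(H * H * q * (1 - q)))
        if curv <= 0:
            break
        step = score / curv
        # damped Newton for stability at extreme H
        while abs(step) > 10:
            step /= 2
        eps += step
    q = expit(off + eps * H)
    score = float(np.mean(H * (y - q)))
    if abs(score) >= max(tol, 1e-8):
        raise RuntimeError(f"fluctuation did not converge; final score {score:.3e}")
    return eps


def fluctuate_weighted(
    inputs: TmleInputs, tol: float = 1e-10, max_iter: int = 200
) -> tuple[float, float]:
    """Alternative weighted-regression fluctuation: per-arm intercepts.

    Solves, for each arm a, the weighted logistic intercept update of Y on
    an offset logit Q0_a among units with A = a, using weights 1/g (arm 1)
    and 1/(1-g) (arm 0).  Componentwise this solves the same score system
    as the signed clever covariate; exposed behind the ``fluctuation``
    flag of :func:`tmle_from_inputs`.
    """
    out = []
    for arm, q0, w_all in (
        (1.0, inputs.Q0_1, 1.0 / inputs.g),
        (0.0, inputs.Q0_0, 1.0 / (1.0 - inputs.g)),
    ):
        mask = inputs.A == arm
        y, off, w = inputs.Y[mask], logit(q0[mask]), w_all[mask]
        eps = 0.0
        for _ in range(max_iter):
            q = expit(off + eps)
            score = float(np.mean(w * (y - q)))
            if abs(score) < tol:
                break
            curv = float(np.mean(w * q * (1 - q)))
            eps += score / curv
        else:
            raise RuntimeError(f"weighted fluctuation (arm {arm:g}) did not converge")
        out.append(eps)
    return out[0], out[1]


def _ic_se(ic: np.ndarray, cluster: np.ndarray | None, mode: str) -> float:
    n = len(ic)
    if mode == "individual" or cluster is None:
        return float(ic.std(ddof=1) / np.sqrt(n))
    sums = pd.Series(ic).groupby(pd.Series(np.asarray(cluster))).sum()
    return float(np.sqrt((sums.to_numpy() ** 2).sum()) / n)


def target_and_estimate(
    inputs: TmleInputs, eps: float, variance: str = "individual"
) -> TmleEstimates:
    """Targeted counterfactual means, ATE, marginal OR and IC inference."""
    H, H1, H0 = clever_covariate(inputs.A, inputs.g)
    q_star_a = expit(logit(inputs.Q0_A) + eps * H)
    q_star_1 = expit(logit(inputs.Q0_1) + eps * H1)
    q_star_0 = expit(logit(inputs.Q0_0) + eps * H0)
    return _estimates_from_qstar(inputs, eps, q_star_a, q_star_1, q_star_0, variance)


def _estimates_from_qstar(
    inputs: TmleInputs, eps, q_star_a, q_star_1, q_star_0, variance: str
) -> TmleEstimates:
    H, _, _ = clever_covariate(inputs.A, inputs.g)
    psi1 = float(q_star_1.mean())
    psi0 = float(q_star_0.mean())
    if min(psi1, psi0) <= 0.0 or max(psi1, psi0) >= 1.0:
        raise ValueError("degenerate targeted mean at 0 or 1")
    ate = psi1 - psi0
    or_ = marginal_odds_ratio(psi1, psi0)

    A, Y, g = inputs.A, inputs.Y, inputs.g
    D1 = (A / g) * (Y - q_star_a) + q_star_1 - psi1
    D0 = ((1 - A) / (1 - g)) * (Y - q_star_a) + q_star_0 - psi0
    D_ate = D1 - D0
    D_logor = D1 / (psi1 * (1 - psi1)) - D0 / (psi0 * (1 - psi0))

    n = len(Y)
    se1 = _ic_se(D1, inputs.cluster, variance)
    se0 = _ic_se(D0, inputs.cluster, variance)
    se_ate = _ic_se(D_ate, inputs.cluster, variance)
    se_logor = _ic_se(D_logor, inputs.cluster, variance)
    log_or = np.log(or_)
    score = float(np.mean(H * (Y - q_star_a)))
    return TmleEstimates(
        epsilon=eps if isinstance(eps, tuple) else float(eps),
        psi1=psi1,
        psi0=psi0,
        ate=float(ate),
        or_=float(or_),
        se_ate=se_ate,
        se_psi1=se1,
        se_psi0=se0,
        se_log_or=se_logor,
        ci_ate=(ate - Z975 * se_ate, ate + Z975 * se_ate),
        ci_or=(float(np.exp(log_or - Z975 * se_logor)), float(np.exp(log_or + Z975 * se_logor))),
        ci_psi1=(psi1 - Z975 * se1, psi1 + Z975 * se1),
        ci_psi0=(psi0 - Z975 * se0, psi0 + Z975 * se0),
        score=score,
        n=n,
        ic={"D1": D1, "D0": D0, "D_ate": D_ate, "D_logOR": D_logor},
    )


def tmle_from_inputs(
    inputs: TmleInputs, variance: str = "individual", fluctuation: str = "standard"
) -> TmleEstimates:
    """Fluctuate then estimate, in one call.

    ``fluctuation="standard"`` uses the one-parameter submodel with the
    signed clever covariate; ``"weighted"`` uses the per-arm weighted
    intercept update.
    """
    if fluctuation == "standard":
        eps = fluctuate(inputs)
        return target_and_estimate(inputs, eps, variance=variance)
    if fluctuation == "weighted":
        eps1, eps0 = fluctuate_weighted(inputs)
        q_star_1 = expit(logit(inputs.Q0_1) + eps1)
        q_star_0 = expit(logit(inputs.Q0_0) + eps0)
        q_star_a = np.where(inputs.A == 1, q_star_1, q_star_0)
        return _estimates_from_qstar(
            inputs, (eps1, eps0), q_star_a, q_star_1, q_star_0, variance
        )
    raise ValueError(f"unknown fluctuation form {fluctuation!r}")


def tmle_unadjusted(A, Y, variance: str = "individual") -> TmleEstimates:
    """The no-covariate closed-form path: arm-specific-mean Q0 and g = mean(A).

    With these inputs the fluctuation solves at eps = 0 exactly and the
    targeted means equal the arm-specific sample means, so the OR equals
    the crude 2x2 contingency odds ratio.
    """
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if A.min() == A.max():
        raise ValueError("need at least one episode in each arm")
    p1 = Y[A == 1].mean()
    p0 = Y[A == 0].mean()
    inputs = TmleInputs(
        Y=Y,
        A=A,
        Q0_A=np.where(A == 1, p1, p0),
        Q0_1=np.full(len(A), p1),
        Q0_0=np.full(len(A), p0),
        g=np.full(len(A), A.mean()),
    )
    return tmle_from_inputs(inputs, variance=variance)


# ---------------------------------------------------------------------------
# orchestration over superlearner fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TmleConfig:
    """Estimation settings for one stratum run."""

    learner_profile: str = "full"
    K: int = 10
    seed: int = 0
    g_bounds: tuple[float, float] = (0.005, 0.995)
    positivity_bounds: tuple[float, float] = (0.025, 0.975)
    variance: str = "individual"  # or "cluster"
    metalearner: str = "nnls"
    fluctuation: str = "standard"  # or "weighted"


@dataclass
class StratumResult:
    """Everything produced for one analysis stratum."""

    stratum: str
    estimates: TmleEstimates
    positivity: PositivityReport
    g_weights: dict[str, float]
    q_weights: dict[str, float]
    folds: FoldAssignment
    n: int

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "n": self.n,
            "estimates": self.estimates.to_dict(),
            "positivity": self.positivity.to_dict(),
            "g_weights": self.g_weights,
            "q_weights": self.q_weights,
        }


def run_tmle(
    episodes: pd.DataFrame,
    tables,
    config: TmleConfig = TmleConfig(),
    strata: tuple[str, ...] = ("adult", "child"),
) -> dict[str, StratumResult]:
    """End-to-end estimation: superlearner fits for g and Q, then targeting.

    All covariates enter both the treatment and the outcome model (the
    outcome model additionally takes A); folds are practice-clustered and
    outcome-stratified and shared between the two fits.  ``strata`` may be
    ``("adult", "child")`` for the stratified main analysis or ``("all",)``
    for a pooled run (e.g. simulation studies).
    """
    results: dict[str, StratumResult] = {}
    for stratum in strata:
        sub = episodes if stratum == "all" else episodes[episodes["stratum"] == stratum]
        sub = sub.reset_index(drop=True)
        if sub.empty or sub["A"].nunique() < 2:
            raise ValueError(f"stratum {stratum!r} needs at least one episode per arm")
        cov = build_covariate_matrix(sub, tables, stratum=stratum)
        X = encode_design(cov).to_numpy()
        A = sub["A"].to_numpy(float)
        Y = sub["Y"].to_numpy(float)
        folds = make_folds(cov.frame["practice_id"].to_numpy(), Y, K=config.K, seed=config.seed)
        lib = learner_library(config.learner_profile)

        fit_g = cv_fit(X, A, folds, lib, seed=config.seed, metalearner=config.metalearner)
        g_raw = fit_g.predict(X)
        pos = positivity_report(g_raw, bounds=config.positivity_bounds)
        g = np.clip(g_raw, *config.g_bounds)

        XA = np.column_stack([X, A])
        fit_q = cv_fit(XA, Y, folds, lib, seed=config.seed + 1, metalearner=config.metalearner)
        X1 = np.column_stack([X, np.ones(len(A))])
        X0 = np.column_stack([X, np.zeros(len(A))])
        inputs = TmleInputs(
            Y=Y,
            A=A,
            Q0_A=fit_q.predict(XA),
            Q0_1=fit_q.predict(X1),
            Q0_0=fit_q.predict(X0),
            g=g,
            cluster=cov.frame["practice_id"].to_numpy(),
        )
        est = tmle_from_inputs(inputs, variance=config.variance,
                               fluctuation=config.fluctuation)
        results[stratum] = StratumResult(
            stratum=stratum,
            estimates=est,
            positivity=pos,
            g_weights=fit_g.weights(),
            q_weights=fit_q.weights(),
            folds=folds,
            n=len(sub),
        )
    return results
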