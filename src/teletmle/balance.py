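"""Exchangeability and positivity diagnostics.

Standardized mean differences (SMD) between exposure arms, descriptive
summary tables with small-cell disclosure suppression, and propensity-score
extreme reporting for the positivity assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "smd_continuous",
    "smd_binary",
    "smd",
    "balance_table",
    "summary_table",
    "positivity_report",
    "SMD_FLAG_THRESHOLD",
    "SUPPRESSION_THRESHOLD",
]

#: An SMD above 10% is considered noteworthy imbalance.
SMD_FLAG_THRESHOLD = 0.10
#: Summary statistics are suppressed in groups with fewer than 10 episodes.
SUPPRESSION_THRESHOLD = 10


def smd_continuous(m1: float, s1: float, m0: float, s0: float) -> float:
    """|m1 - m0| / sqrt((s1^2 + s0^2) / 2), the two-group pooled-SD form."""
    denom = np.sqrt((s1**2 + s0**2) / 2.0)
    if denom == 0.0:
        if m1 == m0:
            return 0.0
        warnings.warn("zero pooled variance with unequal means; SMD is infinite")
        return float("inf")
    return abs(m1 - m0) / denom


def smd_binary(p1: float, p0: float) -> float:
    """|p1 - p0| / sqrt((p1(1-p1) + p0(1-p0)) / 2)."""
    denom = np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2.0)
    if denom == 0.0:
        if p1 == p0:
            return 0.0
        warnings.warn("zero pooled variance with unequal proportions; SMD is infinite")
        return float("inf")
    return abs(p1 - p0) / denom


def smd(x1, x0, kind: str = "continuous") -> float:
    """SMD between two sample vectors.

    ``continuous`` uses the pooled-SD form (ddof=1, needs n >= 2 per group);
    ``binary`` the proportion form; ``categorical`` reports the maximum over
    level-wise binary SMDs.
    """
    x1 = pd.Series(x1)
    x0 = pd.Series(x0)
    if kind == "continuous":
        if len(x1) < 2 or len(x0) < 2:
            raise ValueError("continuous SMD needs at least 2 observations per group")
        return smd_continuous(x1.mean(), x1.std(ddof=1), x0.mean(), x0.std(ddof=1))
    if kind == "binary":
        if len(x1) < 1 or len(x0) < 1:
            raise ValueError("binary SMD needs at least 1 observation per group")
        return smd_binary(x1.mean(), x0.mean())
    if kind == "categorical":
        levels = sorted(set(x1.astype(str)) | set(x0.astype(str)))
        return max(smd_binary((x1.astype(str) == l).mean(), (x0.astype(str) == l).mean())
                   for l in levels)
    raise ValueError(f"unknown SMD kind {kind!r}")


def balance_table(
    df: pd.DataFrame,
    arm: str,
    numeric: list[str],
    categorical: list[str],
    threshold: float = SMD_FLAG_THRESHOLD,
    suppression: int = SUPPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Per-covariate SMD report between arm 1 and arm 0.

    Multi-level categoricals contribute one row per level plus a pooled
    (max-over-levels) row.  ``flag`` marks SMD > threshold; ``suppressed``
    marks covariates where either group has fewer than ``suppression``
    episodes (the SMD is still computed; masking is presentational).
    """
    g1 = df[df[arm] == 1]
    g0 = df[df[arm] == 0]
    n1, n0 = len(g1), len(g0)
    suppressed = n1 < suppression or n0 < suppression
    rows = []

    def _add(name, level, value):
        rows.append(
            {"covariate": name, "level": level, "smd": value,
             "flag": bool(value > threshold), "n1": n1, "n0": n0,
             "suppressed": suppressed}
        )

    for c in numeric:
        uniq = df[c].dropna().unique()
        kind = "binary" if set(np.unique(uniq)).issubset({0, 1, 0.0, 1.0}) else "continuous"
        _add(c, "", smd(g1[c], g0[c], kind=kind))
    for c in categorical:
        levels = sorted(df[c].astype(str).unique())
        per_level = {
            l: smd_binary((g1[c].astype(str) == l).mean(), (g0[c].astype(str) == l).mean())
            for l in levels
        }
        for l, v in per_level.items():
            _add(c, l, v)
        _add(c, "(max)", max(per_level.values()))
    return pd.DataFrame(rows)


def _format_pct(p: float) -> str:
    if p >= 10:
        return f"{p:.0f}%"
    if p >= 0.1:
        return f"{p:.1f}%"
    return "<0.1%"


def summary_table(
    df: pd.DataFrame,
    by: str,
    numeric: list[str] = (),
    categorical: list[str] = (),
    suppression: int = SUPPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Descriptive table by arm and overall, with small-cell suppression.

    Categoricals report count and percentage per level; numerics report
    median (IQR).  Cells of any group with fewer than ``suppression``
    episodes are suppressed in the formatted column; numeric ``value``/
    ``pct`` columns are kept unmasked for downstream arithmetic, so
    suppression never alters unsuppressed cells.
    """
    groups: dict[str, pd.DataFrame] = {"overall": df}
    for val in sorted(df[by].unique()):
        groups[str(val)] = df[df[by] == val]
    rows = []
    for gname, g in groups.items():
        n = len(g)
        masked = n < suppression
        rows.append({"group": gname, "covariate": "N", "level": "", "n": n,
                     "pct": 100.0 * n / max(len(df), 1), "value": float(n),
                     "formatted": "—" if masked else f"{n}", "suppressed": masked})
        for c in categorical:
            for lev in sorted(g[c].astype(str).unique()):
                cnt = int((g[c].astype(str) == lev).sum())
                pct = 100.0 * cnt / n if n else float("nan")
                rows.append(
                    {"group": gname, "covariate": c, "level": lev, "n": cnt, "pct": pct,
                     "value": float(cnt),
                     "formatted": "—" if masked else f"{cnt} ({_format_pct(pct)})",
                     "suppressed": masked}
                )
        for c in numeric:
            med = g[c].median()
            q1, q3 = g[c].quantile(0.25), g[c].quantile(0.75)
            rows.append(
                {"group": gname, "covariate": c, "level": "median (IQR)", "n": n,
                 "pct": float("nan"), "value": float(med),
                 "formatted": "—" if masked else f"{med:.4g} ({q1:.4g}, {q3:.4g})",
                 "suppressed": masked}
            )
    return pd.DataFrame(rows)


@dataclass
class PositivityReport:
    minimum: float
    maximum: float
    share_below: float
    share_above: float
    bounds: tuple[float, float]
    histogram: tuple[np.ndarray, np.ndarray]

    def to_dict(self) -> dict:
        counts, edges = self.histogram
        return {
            "min": self.minimum,
            "max": self.maximum,
            "share_below": self.share_below,
            "share_above": self.share_above,
            "bounds": list(self.bounds),
            "histogram_counts": [int(c) for c in counts],
            "histogram_edges": [float(e) for e in edges],
        }


def positivity_report(
    propensities, bounds: tuple[float, float] = (0.025, 0.975), bins: int = 20
) -> PositivityReport:
    """Propensity-score extremes and the share outside configured bounds.

    A propensity at or outside (0, 1) is an error; extremes breaching the
    (configurable) soft bounds raise a warning, not an error, mirroring a
    positivity check that reports rather than truncates.
    """
    g = np.asarray(propensities, dtype=float)
    if g.size == 0:
        raise ValueError("empty propensity vector")
    if np.any((g <= 0.0) | (g >= 1.0)):
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    lo, hi = bounds
    rep = PositivityReport(
        minimum=float(g.min()),
        maximum=float(g.max()),
        share_below=float((g < lo).mean()),
        share_above=float((g > hi).mean()),
        bounds=(lo, hi),
        histogram=np.histogram(g, bins=bins, range=(0.0, 1.0)),
    )
    if rep.minimum < lo or rep.maximum > hi:
        warnings.warn(
            f"propensity extremes [{rep.minimum:.3f}, {rep.maximum:.3f}] breach "
            f"bounds [{lo}, {hi}]; inspect positivity before trusting the estimate"
        )
    return rep
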