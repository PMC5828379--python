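"""Group comparison of per-cell fitted parameters.

One-way ANOVA across channel groups followed by Dunnett's many-to-one post
hoc comparison against the wild-type control, with unequal group sizes
handled through the standard contrast variance.  The Dunnett family-wise
adjustment is computed by Monte-Carlo resampling of the joint null
distribution of the comparison t statistics (correlated multivariate t):
simple, seedable, and checkable by calibration, at the cost of Monte-Carlo
error of order 1/sqrt(n_mc).

Group summaries report mean +/- SEM per group (SEM = SD / sqrt(n)), the
ANOVA F and p, and the Dunnett-adjusted p per non-control group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "DunnettResult",
    "anova_oneway",
    "dunnett_vs_control",
    "summarize",
]


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int


@dataclass
class DunnettResult:
    label: str
    n: int
    mean_diff: float  # group mean minus control mean
    t: float
    p_unadjusted: float
    p_adjusted: float
    degenerate: bool = False  # pooled variance was zero


def anova_oneway(groups: dict) -> AnovaResult:
    """Classical one-way ANOVA over a mapping label -> samples."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    f, p = sps.f_oneway(*arrays)
    n_total = sum(len(a) for a in arrays)
    return AnovaResult(
        F=float(f), p=float(p),
        df_between=len(arrays) - 1, df_within=n_total - len(arrays),
    )


def dunnett_vs_control(
    groups: dict,
    control: str = "WT",
    n_mc: int = 100_000,
    seed: int = 12345,
) -> dict[str, DunnettResult]:
    """Dunnett's many-to-one comparisons against a control group.

    The family-wise adjusted p for comparison i is
    P(max_j |T_j| >= |t_i|) under the joint null, estimated from ``n_mc``
    Monte-Carlo draws of the correlated multivariate-t vector
    (T_j = (lam_j Z0 + sqrt(1-lam_j^2) Z_j) / sqrt(chi2_nu / nu),
    lam_j = sqrt(n_j / (n_j + n_0))), with the (count+1)/(n_mc+1) estimator.
    Adjusted p values are clipped to be >= the unadjusted two-sided t p.
    A zero pooled variance is flagged as degenerate (p = NaN).
    """
    if control not in groups:
        raise KeyError(f"control group {control!r} not present")
    others = [k for k in groups if k != control]
    if not others:
        raise ValueError("need at least one non-control group")
    x0 = np.asarray(groups[control], dtype=float)
    xs = [np.asarray(groups[k], dtype=float) for k in others]
    if len(x0) < 2 or any(len(x) < 2 for x in xs):
        raise ValueError("every group needs >= 2 observations")
    n0 = len(x0)
    ns = np.array([len(x) for x in xs])
    nu = int(n0 + ns.sum() - (1 + len(xs)))
    ss_within = np.sum((x0 - x0.mean()) ** 2) + sum(
        np.sum((x - x.mean()) ** 2) for x in xs
    )
    s2 = ss_within / nu
    diffs = np.array([x.mean() - x0.mean() for x in xs])
    if s2 == 0:
        return {
            k: DunnettResult(
                label=k, n=int(n), mean_diff=float(d), t=np.nan,
                p_unadjusted=np.nan, p_adjusted=np.nan, degenerate=True,
            )
            for k, n, d in zip(others, ns, diffs)
        }
    se = np.sqrt(s2 * (1.0 / ns + 1.0 / n0))
    t_obs = diffs / se
    p_unadj = 2.0 * sps.t.sf(np.abs(t_obs), nu)

    rng = np.random.default_rng(seed)
    lam = np.sqrt(ns / (ns + n0))
    z0 = rng.standard_normal(n_mc)
    zi = rng.standard_normal((len(xs), n_mc))
    w = np.sqrt(rng.chisquare(nu, n_mc) / nu)
    t_null = (lam[:, None] * z0 + np.sqrt(1.0 - lam**2)[:, None] * zi) / w
    max_abs = np.max(np.abs(t_null), axis=0)

    out = {}
    for k, n, d, t, pu in zip(others, ns, diffs, t_obs, p_unadj):
        p_adj = (np.count_nonzero(max_abs >= abs(t)) + 1.0) / (n_mc + 1.0)
        out[k] = DunnettResult(
            label=k, n=int(n), mean_diff=float(d), t=float(t),
            p_unadjusted=float(pu), p_adjusted=float(max(p_adj, pu)),
        )
    return out


def summarize(
    results: pd.DataFrame,
    control: str = "WT",
    n_mc: int = 100_000,
    seed: int = 12345,
) -> pd.DataFrame:
    """Per-quantity group summary with ANOVA and Dunnett post hoc.

    ``results`` is a long table with columns ``cell_id``, ``group``,
    ``quantity``, ``value``.  Returns one row per quantity x group with n,
    mean, SEM, the shared ANOVA F/p, and the Dunnett-adjusted p for
    non-control groups (NaN for the control).
    """
    rows = []
    for quantity, sub in results.groupby("quantity", sort=True):
        sub = sub.dropna(subset=["value"])
        groups = {g: s["value"].to_numpy() for g, s in sub.groupby("group")}
        testable = (
            control in groups
            and len(groups) >= 2
            and all(len(v) >= 2 for v in groups.values())
        )
        anova = anova_oneway(groups) if testable else None
        dunnett = (
            dunnett_vs_control(groups, control=control, n_mc=n_mc, seed=seed)
            if testable
            else {}
        )
        for g, vals in groups.items():
            sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            rows.append(
                {
                    "quantity": quantity,
                    "group": g,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "sem": sem,
                    "anova_F": anova.F if anova else np.nan,
                    "anova_p": anova.p if anova else np.nan,
                    "dunnett_p": dunnett[g].p_adjusted if g in dunnett else np.nan,
                }
            )
    return pd.DataFrame(rows)
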