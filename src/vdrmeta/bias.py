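"""Publication-bias diagnostics and leave-one-out sensitivity analysis.

Egger's test regresses the standardized effect (log OR / SE) on precision
(1 / SE) by unweighted OLS and t-tests the intercept with k - 2 degrees of
freedom.  Begg's test rank-correlates the variance-standardized deviations
from the inverse-variance mean with the per-study variances (Kendall tau
with tie correction).  Both require at least three studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association import EffectEstimate, Z975
from .genetic_models import ContrastTable
from .pooling import PoolResult, pool_auto


@dataclass
class BiasResult:
    k: int
    egger_intercept: float | None = None
    egger_se: float | None = None
    egger_p: float | None = None
    begg_tau: float | None = None
    begg_p: float | None = None


@dataclass
class LeaveOneOutResult:
    overall: PoolResult
    omitted: dict[str, PoolResult]  # study_id -> pooled result without it


def egger_test(effects: list[EffectEstimate]) -> BiasResult:
    """Classical Egger regression asymmetry test (intercept t, df = k-2)."""
    k = len(effects)
    if k < 3:
        raise ValueError("insufficient studies for Egger's test (need >= 3)")
    snd = np.array([e.log_or / e.se for e in effects])
    precision = np.array([1.0 / e.se for e in effects])
    fit = sm.OLS(snd, sm.add_constant(precision)).fit()
    return BiasResult(
        k=k,
        egger_intercept=float(fit.params[0]),
        egger_se=float(fit.bse[0]),
        egger_p=float(fit.pvalues[0]),
    )


def begg_test(effects: list[EffectEstimate]) -> BiasResult:
    """Begg-Mazumdar rank correlation asymmetry test."""
    k = len(effects)
    if k < 3:
        raise ValueError("insufficient studies for Begg's test (need >= 3)")
    y = np.array([e.log_or for e in effects])
    v = np.array([e.se**2 for e in effects])
    w = 1.0 / v
    theta = np.sum(w * y) / np.sum(w)
    v_pooled = 1.0 / np.sum(w)
    vstar = np.clip(v - v_pooled, 1e-12, None)
    t = (y - theta) / np.sqrt(vstar)
    if np.allclose(t, t[0]) or np.allclose(v, v[0]):
        return BiasResult(k=k, begg_tau=0.0, begg_p=1.0)
    tau, p = stats.kendalltau(t, v)
    return BiasResult(k=k, begg_tau=float(tau), begg_p=float(p))


def funnel_data(effects: list[EffectEstimate]) -> pd.DataFrame:
    """Funnel-plot coordinates plus the pseudo-95% envelope.

    Returns one row per study (kind = 'study') and a grid of envelope rows
    (kind = 'envelope') tracing pooled center +/- 1.96 * SE.
    """
    if not effects:
        raise ValueError("no effects")
    y = np.array([e.log_or for e in effects])
    se = np.array([e.se for e in effects])
    w = 1.0 / se**2
    center = float(np.sum(w * y) / np.sum(w))
    rows = [
        {"kind": "study", "study_id": e.study_id, "log_or": e.log_or,
         "se": e.se, "lower": np.nan, "upper": np.nan}
        for e in effects
    ]
    for s in np.linspace(0.0, float(se.max()) * 1.05, 25):
        rows.append(
            {"kind": "envelope", "study_id": None, "log_or": center, "se": s,
             "lower": center - Z975 * s, "upper": center + Z975 * s}
        )
    return pd.DataFrame(rows)


def leave_one_out(tables: list[ContrastTable]) -> LeaveOneOutResult:
    """Refit the (auto-selected) pooled OR omitting one study at a time."""
    usable = [t for t in tables if not t.excluded]
    if len(usable) < 2:
        raise ValueError("leave-one-out needs at least 2 contributing studies")
    overall = pool_auto(usable)
    omitted: dict[str, PoolResult] = {}
    for i, t in enumerate(usable):
        rest = usable[:i] + usable[i + 1:]
        omitted[t.study_id or f"study_{i}"] = pool_auto(rest)
    return LeaveOneOutResult(overall=overall, omitted=omitted)
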