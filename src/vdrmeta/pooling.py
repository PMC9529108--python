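"""Fixed-effect (Mantel-Haenszel) and random-effects (DerSimonian-Laird)
pooling of 2x2 tables, with Cochran Q / I-squared heterogeneity and the
heterogeneity-gated model-selection rule.

Conventions (those of the mainstream Cochrane tooling):

* per-study effects are Woolf log ORs with 0.5 added to all cells of any
  study containing a zero cell;
* Q and I2 use inverse-variance weights around the inverse-variance mean;
* the fixed-effect pooled estimate is Mantel-Haenszel with the
  Robins-Breslow-Greenland variance;
* DerSimonian-Laird tau2 is the moment estimator max(0, (Q - df)/C).

Model selection: fixed effect iff the heterogeneity p-value exceeds 0.10
and I2 < 50%; otherwise random effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .association import EffectEstimate, Z975, study_effect
from .genetic_models import ContrastTable

FIXED_MH = "fixed_MH"
RANDOM_DL = "random_DL"


class Heterogeneity(NamedTuple):
    q: float
    df: int
    p_het: float
    i2: float  # percent


@dataclass
class PoolResult:
    """A pooled odds ratio with heterogeneity bookkeeping."""

    pooled_or: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    q: float
    df: int
    p_het: float
    i2: float
    tau2: float
    k: int
    pooling: str  # FIXED_MH or RANDOM_DL
    per_study: list[EffectEstimate] = field(default_factory=list)
    weights_fixed: list[float] = field(default_factory=list)
    weights_random: list[float] = field(default_factory=list)
    n_cases: int = 0
    n_controls: int = 0
    snp: str | None = None
    model: str | None = None

    @property
    def log_or(self) -> float:
        return math.log(self.pooled_or)


def _usable(tables: Sequence[ContrastTable]) -> list[ContrastTable]:
    kept = [t for t in tables if not t.excluded]
    if not kept:
        raise ValueError("all tables excluded under this model")
    return kept


def _corrected_cells(t: ContrastTable) -> tuple[float, float, float, float]:
    a, b, c, d = (float(x) for x in t.cells)
    if any(x == 0 for x in (a, b, c, d)):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return a, b, c, d


def q_i2(effects: Sequence[EffectEstimate]) -> Heterogeneity:
    """Cochran Q around the inverse-variance mean, and I2 in percent."""
    if not effects:
        raise ValueError("no effects")
    k = len(effects)
    if k == 1:
        return Heterogeneity(0.0, 0, 1.0, 0.0)
    y = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    theta_iv = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - theta_iv) ** 2))
    df = k - 1
    p_het = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return Heterogeneity(q, df, p_het, i2)


def dl_tau2(effects: Sequence[EffectEstimate]) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance."""
    if len(effects) < 2:
        return 0.0
    het = q_i2(effects)
    w = np.array([1.0 / e.se**2 for e in effects])
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if c <= 0:
        return 0.0
    return max(0.0, (het.q - het.df) / c)


def _summarize(
    log_or: float,
    se: float,
    het: Heterogeneity,
    tau2: float,
    pooling: str,
    effects: list[EffectEstimate],
    tables: list[ContrastTable] | None,
) -> PoolResult:
    z = log_or / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    w_fixed = [1.0 / e.se**2 for e in effects]
    w_rand = [1.0 / (e.se**2 + tau2) for e in effects]
    n_cases = n_controls = 0
    if tables is not None:
        for t in tables:
            div = 2 if t.unit == "alleles" else 1
            n_cases += (t.case_exposed + t.case_unexposed) // div
            n_controls += (t.control_exposed + t.control_unexposed) // div
    return PoolResult(
        pooled_or=math.exp(log_or),
        ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se),
        z=z,
        p=p,
        q=het.q,
        df=het.df,
        p_het=het.p_het,
        i2=het.i2,
        tau2=tau2,
        k=len(effects),
        pooling=pooling,
        per_study=effects,
        weights_fixed=w_fixed,
        weights_random=w_rand,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def pool_fixed_mh(tables: Sequence[ContrastTable]) -> PoolResult:
    """Mantel-Haenszel fixed-effect pooled OR with the
    Robins-Breslow-Greenland variance of its log."""
    kept = _usable(tables)
    effects = [study_effect(t) for t in kept]
    het = q_i2(effects)

    R = S = 0.0
    sum_PR = sum_PSQR = sum_QS = 0.0
    for t in kept:
        a, b, c, d = _corrected_cells(t)
        n = a + b + c + d
        P, Q = (a + d) / n, (b + c) / n
        Ri, Si = a * d / n, b * c / n
        R += Ri
        S += Si
        sum_PR += P * Ri
        sum_PSQR += P * Si + Q * Ri
        sum_QS += Q * Si
    log_or = math.log(R / S)
    var = sum_PR / (2 * R * R) + sum_PSQR / (2 * R * S) + sum_QS / (2 * S * S)
    se = math.sqrt(var)
    return _summarize(log_or, se, het, 0.0, FIXED_MH, effects, kept)


def _as_effects(items) -> tuple[list[EffectEstimate], list[ContrastTable] | None]:
    if items and isinstance(items[0], ContrastTable):
        kept = _usable(items)
        return [study_effect(t) for t in kept], kept
    return list(items), None


def pool_random_dl(items: Sequence) -> PoolResult:
    """DerSimonian-Laird random-effects pooled OR.

    Accepts either contrast tables or precomputed effect estimates.  When
    tau2 = 0 the result coincides with inverse-variance fixed pooling.
    """
    effects, kept = _as_effects(list(items))
    if not effects:
        raise ValueError("no effects")
    het = q_i2(effects)
    tau2 = dl_tau2(effects)
    w = np.array([1.0 / (e.se**2 + tau2) for e in effects])
    y = np.array([e.log_or for e in effects])
    log_or = float(np.sum(w * y) / np.sum(w))
    se = 1.0 / math.sqrt(float(np.sum(w)))
    return _summarize(log_or, se, het, tau2, RANDOM_DL, effects, kept)


def select_model(p_het: float, i2: float) -> str:
    """Heterogeneity gate: fixed MH iff p_het > 0.10 and I2 < 50%."""
    if not 0 <= p_het <= 1:
        raise ValueError("p_het outside [0, 1]")
    if not 0 <= i2 <= 100:
        raise ValueError("i2 outside [0, 100]")
    return FIXED_MH if (p_het > 0.10 and i2 < 50.0) else RANDOM_DL


def pool_auto(tables: Sequence[ContrastTable]) -> PoolResult:
    """Pool with the method the heterogeneity gate selects."""
    kept = _usable(tables)
    effects = [study_effect(t) for t in kept]
    het = q_i2(effects)
    if select_model(het.p_het, het.i2) == FIXED_MH:
        return pool_fixed_mh(kept)
    return pool_random_dl(kept)
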