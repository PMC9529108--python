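"""Per-study effect estimates and Hardy-Weinberg equilibrium testing."""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .core_data import GenotypeCounts
from .genetic_models import ContrastTable

Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class EffectEstimate:
    """Log odds ratio and its standard error for one 2x2 table."""

    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    corrected: bool = False
    study_id: str | None = None


@dataclass(frozen=True)
class HWEResult:
    """Chi-square goodness-of-fit to Hardy-Weinberg proportions (df=1)."""

    chi2: float
    df: int
    p: float
    in_hwe: bool
    monomorphic: bool = False


def study_effect(table: ContrastTable) -> EffectEstimate:
    """Woolf odds-ratio estimate with 0.5 continuity correction.

    If any cell is zero, 0.5 is added to all four cells before both the
    estimate and the variance (the convention of mainstream meta-analysis
    software; double-zero tables are excluded upstream and rejected here).
    """
    if table.excluded:
        raise ValueError(
            f"study {table.study_id or '?'} excluded under model {table.model.value}"
        )
    a, b, c, d = (float(x) for x in table.cells)
    corrected = any(x == 0 for x in (a, b, c, d))
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se),
        corrected=corrected,
        study_id=table.study_id,
    )


def hwe_test(controls: GenotypeCounts) -> HWEResult:
    """Plain (uncorrected) chi-square HWE test on one arm's genotype counts.

    Expected counts come from the observed allele frequency; df = 1.
    Monomorphic arms (one allele absent) fit trivially: chi2 = 0, p = 1.
    """
    n = controls.n
    if n < 1:
        raise ValueError("empty arm")
    p1 = controls.allele1_count / (2 * n)
    if p1 in (0.0, 1.0):
        return HWEResult(chi2=0.0, df=1, p=1.0, in_hwe=True, monomorphic=True)
    q1 = 1.0 - p1
    expected = (n * p1 * p1, 2 * n * p1 * q1, n * q1 * q1)
    observed = (controls.n11, controls.n12, controls.n22)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(chi2=chi2, df=1, p=p, in_hwe=p >= 0.05)
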