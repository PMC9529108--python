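"""Trial sequential analysis for cumulative meta-analysis.

A meta-analysis updated as studies accrue is an unplanned group-sequential
trial: repeatedly testing at 1.96 inflates the type-I error.  TSA guards
against this with two ingredients:

* a required information size (RIS) -- the participant total a single
  adequately powered trial would need to detect an assumed relative risk
  reduction, optionally inflated by between-study diversity D2 via
  1 / (1 - D2);
* Lan-DeMets O'Brien-Fleming-type alpha-spending boundaries -- at
  information fraction t the cumulative two-sided type-I error spent is
  alpha(t) = 2 * (1 - Phi(z_{1-alpha/2} / sqrt(t))), and look-specific
  boundaries are solved recursively so the crossing probability under the
  null matches the spent alpha at every look.

The cumulative Z-curve pools studies in accrual order (ascending year,
ties broken by author) with the pooling method the heterogeneity gate
selects on the full study set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .genetic_models import ContrastTable
from .pooling import FIXED_MH, pool_auto, pool_fixed_mh, pool_random_dl


@dataclass(frozen=True)
class TSAConfig:
    """Assumptions behind the required information size.

    Defaults are the stated design: two-sided alpha 5%, power 80%, an
    assumed 20% relative risk reduction, and 0.5 continuity correction in
    zero-event tables.  ``control_event_proportion`` defaults to the
    pooled effect-allele frequency among control alleles of the analysed
    tables; ``diversity_d2`` defaults to no adjustment.
    """

    alpha: float = 0.05
    power: float = 0.80
    rrr: float = 0.20
    control_event_proportion: float | None = None
    diversity_d2: float = 0.0
    continuity: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if not 0 < self.rrr < 1:
            raise ValueError("rrr must lie in (0, 1)")
        if not 0 <= self.diversity_d2 < 1:
            raise ValueError("diversity_d2 must lie in [0, 1)")
        if self.control_event_proportion is not None and not (
            0 < self.control_event_proportion < 1
        ):
            raise ValueError("control_event_proportion must lie in (0, 1)")


@dataclass
class TSAStep:
    study_id: str | None
    cumulative_n: int
    information_fraction: float
    z: float
    boundary: float


@dataclass
class TSAResult:
    ris: int
    steps: list[TSAStep] = field(default_factory=list)
    conventional_crossed: bool = False
    boundary_crossed: bool = False
    ris_reached: bool = False
    pooling: str = FIXED_MH


def required_information_size(cfg: TSAConfig) -> int:
    """Two-arm-trial sample size for the assumed RRR, diversity-adjusted.

    With pC the control event proportion and pI = pC * (1 - RRR):
    N = 4 * (z_{1-alpha/2} + z_power)^2 * pbar * (1 - pbar) / (pC - pI)^2,
    divided by (1 - D2) and rounded to the nearest integer.
    """
    pc = cfg.control_event_proportion
    if pc is None:
        raise ValueError("control_event_proportion is required")
    pi = pc * (1.0 - cfg.rrr)
    delta = pc - pi
    if delta == 0:
        raise ValueError("zero risk difference: rrr * pC must be > 0")
    pbar = (pc + pi) / 2.0
    za = stats.norm.ppf(1.0 - cfg.alpha / 2.0)
    zb = stats.norm.ppf(cfg.power)
    n = 4.0 * (za + zb) ** 2 * pbar * (1.0 - pbar) / delta**2
    n /= 1.0 - cfg.diversity_d2
    return int(round(n))


def obf_spending(t: float, alpha: float = 0.05) -> float:
    """Cumulative two-sided alpha spent at information fraction t."""
    if t <= 0:
        return 0.0
    t = min(t, 1.0)
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    return 2.0 * float(stats.norm.sf(za / math.sqrt(t)))


def obf_boundary(t: float, alpha: float = 0.05) -> float:
    """Single-look O'Brien-Fleming-type boundary at fraction t.

    Solves 2 * (1 - Phi(z)) = alpha(t); equals z_{1-alpha/2} at t = 1.
    Fractions above 1 are clamped with a warning.
    """
    if t <= 0:
        raise ValueError("information fraction must be positive")
    if t > 1:
        warnings.warn("information fraction > 1 clamped to 1", stacklevel=2)
        t = 1.0
    spent = obf_spending(t, alpha)
    return float(stats.norm.isf(spent / 2.0))


def obf_boundaries(
    fractions: Sequence[float],
    alpha: float = 0.05,
    grid_points: int = 601,
) -> list[float]:
    """Symmetric alpha-spending boundaries for a sequence of looks.

    Uses the standard recursive numerical integration over the Brownian
    path: the sub-density of the cumulative sum among not-yet-crossed
    paths is propagated look to look on a grid, and each boundary is
    solved so the newly crossed mass equals the alpha-spending increment.
    Fractions must be strictly increasing in (0, 1].
    """
    fr = [min(float(t), 1.0) for t in fractions]
    if not fr:
        return []
    if any(t <= 0 for t in fr) or any(b <= a for a, b in zip(fr, fr[1:])):
        raise ValueError("fractions must be strictly increasing in (0, 1]")

    zmax = 10.0  # +/- range on the Brownian-sum scale, in sd units of t=1
    grid = np.linspace(-zmax, zmax, grid_points)
    dx = grid[1] - grid[0]
    edges_lo = grid - dx / 2.0
    edges_hi = grid + dx / 2.0
    boundaries: list[float] = []
    mass = None  # surviving probability mass of S_{i-1} at the grid points
    spent_prev = 0.0
    t_prev = 0.0
    for i, t in enumerate(fr):
        spend = obf_spending(t, alpha) - spent_prev
        spent_prev = obf_spending(t, alpha)
        if i == 0:
            # first look: the null distribution is exactly normal
            b = min(
                float(stats.norm.isf(max(spend, 1e-300) / 2.0)),
                zmax / math.sqrt(t),
            )
            cut = b * math.sqrt(t)
            sd0 = math.sqrt(t)
            lo = np.clip(edges_lo, -cut, cut)
            hi = np.clip(edges_hi, -cut, cut)
            mass = stats.norm.cdf(hi / sd0) - stats.norm.cdf(lo / sd0)
        else:
            sd = math.sqrt(t - t_prev)

            def crossing_mass(b: float) -> float:
                # P(no crossing before, |S_i| >= b sqrt(t)) via the exact
                # normal increment tail from each surviving source point
                c = b * math.sqrt(t)
                tail = stats.norm.sf((c - grid) / sd) + stats.norm.cdf(
                    (-c - grid) / sd
                )
                return float(np.sum(mass * tail))

            if spend <= 0 or crossing_mass(zmax / math.sqrt(t)) >= spend:
                b = zmax / math.sqrt(t)
            else:
                b = float(
                    optimize.brentq(
                        lambda x: crossing_mass(x) - spend,
                        1e-6,
                        zmax / math.sqrt(t),
                    )
                )
            cut = b * math.sqrt(t)
            # propagate: mass reaching each target cell without crossing
            lo = np.clip(edges_lo, -cut, cut)
            hi = np.clip(edges_hi, -cut, cut)
            inc = stats.norm.cdf(
                (hi[:, None] - grid[None, :]) / sd
            ) - stats.norm.cdf((lo[:, None] - grid[None, :]) / sd)
            mass = inc @ mass
        boundaries.append(b)
        t_prev = t
    return boundaries


def control_event_proportion_from_tables(tables: Sequence[ContrastTable]) -> float:
    """Pooled exposure proportion in the control arms (for allelic tables,
    the pooled effect-allele frequency among control alleles)."""
    exposed = sum(t.control_exposed for t in tables if not t.excluded)
    total = sum(
        t.control_exposed + t.control_unexposed for t in tables if not t.excluded
    )
    if total == 0:
        raise ValueError("no control observations")
    return exposed / total


def accumulation_order(dataset) -> list:
    """Study accrual order for the Z-curve: ascending year, then author."""
    return sorted(dataset, key=lambda s: (s.year, s.author))


def cumulative_z_curve(tables: Sequence[ContrastTable], cfg: TSAConfig) -> TSAResult:
    """Cumulative meta-analysis Z-curve against alpha-spending boundaries.

    ``tables`` must already be in accrual order.  The pooling method is
    chosen once, on the full set, and held fixed across steps.
    """
    usable = [t for t in tables if not t.excluded]
    if not usable:
        raise ValueError("no contributing studies")
    if cfg.control_event_proportion is None:
        cfg = TSAConfig(
            alpha=cfg.alpha,
            power=cfg.power,
            rrr=cfg.rrr,
            control_event_proportion=control_event_proportion_from_tables(usable),
            diversity_d2=cfg.diversity_d2,
            continuity=cfg.continuity,
        )
    ris = required_information_size(cfg)
    full = pool_auto(usable)
    pool = pool_fixed_mh if full.pooling == FIXED_MH else pool_random_dl

    cum_n = 0
    fractions: list[float] = []
    zs: list[float] = []
    ids: list[str | None] = []
    ns: list[int] = []
    for j in range(1, len(usable) + 1):
        step_pool = pool(usable[:j])
        cum_n += usable[j - 1].n_persons
        ns.append(cum_n)
        fractions.append(cum_n / ris)
        zs.append(step_pool.z)
        ids.append(usable[j - 1].study_id)

    # boundary recursion runs on the clamped, pre-full-information looks;
    # looks at or beyond full information use the conventional 1.96
    clamped = [min(f, 1.0) for f in fractions]
    inc = [i for i in range(len(clamped)) if clamped[i] < 1.0]
    bvals = obf_boundaries([clamped[i] for i in inc], alpha=cfg.alpha)
    z_conv = float(stats.norm.ppf(1.0 - cfg.alpha / 2.0))
    boundary = [z_conv] * len(clamped)
    for pos, i in enumerate(inc):
        boundary[i] = bvals[pos]

    steps = [
        TSAStep(ids[i], ns[i], fractions[i], zs[i], boundary[i])
        for i in range(len(zs))
    ]
    return TSAResult(
        ris=ris,
        steps=steps,
        conventional_crossed=abs(zs[-1]) >= z_conv,
        boundary_crossed=any(abs(z) >= b for z, b in zip(zs, boundary)),
        ris_reached=ns[-1] >= ris,
        pooling=full.pooling,
    )
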