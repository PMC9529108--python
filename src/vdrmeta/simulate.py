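"""Synthetic case-control genotype-count datasets with known truth.

Emulates the statistical world the pooling machinery assumes: per-study
allelic log odds ratios drawn around a common truth with between-study
variance tau2, control genotypes at a chosen effect-allele frequency with
an optional inbreeding coefficient F (Hardy-Weinberg departure), and case
genotypes in Hardy-Weinberg proportions at the allele frequency the
study's odds ratio implies.  Counts are multinomial with fixed arm totals,
matching the case-control design of the pooled studies.

Defaults mirror the realistic scale of the pooled literature: ten studies
of a few hundred persons per arm, control effect-allele frequency 0.35,
and a modest allelic odds ratio of 1.15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import GenotypeCounts, StudyDataset, StudyRecord


@dataclass(frozen=True)
class SyntheticConfig:
    n_studies: int = 10
    cases_per_study: int | tuple[int, int] = (100, 500)
    controls_per_study: int | tuple[int, int] = (100, 500)
    effect_allele_freq_controls: float = 0.35
    true_allelic_or: float = 1.15
    tau2: float = 0.0
    hwe_inbreeding_f: float = 0.0
    snp: str = "rs1544410"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        q = self.effect_allele_freq_controls
        if not 0 < q < 1:
            raise ValueError("effect_allele_freq_controls must lie in (0, 1)")
        if self.true_allelic_or <= 0:
            raise ValueError("true_allelic_or must be > 0")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        f = self.hwe_inbreeding_f
        if not -1 < f < 1:
            raise ValueError("hwe_inbreeding_f must lie in (-1, 1)")
        probs = _genotype_probs(q, f)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("q and F imply genotype probabilities outside [0, 1]")


def _genotype_probs(q: float, f: float) -> tuple[float, float, float]:
    """(P11, P12, P22) with allele-2 frequency q and inbreeding F."""
    p = 1.0 - q
    return (
        (1.0 - f) * p * p + f * p,
        (1.0 - f) * 2.0 * p * q,
        (1.0 - f) * q * q + f * q,
    )


def _arm_size(size: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(size, tuple):
        lo, hi = size
        return int(rng.integers(lo, hi + 1))
    return int(size)


def generate_meta_dataset(cfg: SyntheticConfig) -> StudyDataset:
    """Draw one reproducible synthetic meta-analysis dataset."""
    rng = np.random.default_rng(cfg.seed)
    q = cfg.effect_allele_freq_controls
    control_probs = _genotype_probs(q, cfg.hwe_inbreeding_f)
    records = []
    for i in range(cfg.n_studies):
        log_or = rng.normal(np.log(cfg.true_allelic_or), np.sqrt(cfg.tau2))
        odds_case = np.exp(log_or) * q / (1.0 - q)
        q_case = odds_case / (1.0 + odds_case)
        case_probs = _genotype_probs(q_case, 0.0)
        n_cases = _arm_size(cfg.cases_per_study, rng)
        n_controls = _arm_size(cfg.controls_per_study, rng)
        cg = rng.multinomial(n_cases, case_probs)
        kg = rng.multinomial(n_controls, control_probs)
        records.append(
            StudyRecord(
                study_id=f"sim-{i + 1:03d}",
                author=f"Sim{i + 1:03d}",
                year=2000 + i,
                country="China",
                race_group="Asian",
                genotyping_method="PCR-RFLP",
                snp=cfg.snp,
                cases=GenotypeCounts(*(int(x) for x in cg)),
                controls=GenotypeCounts(*(int(x) for x in kg)),
            )
        )
    return StudyDataset(cfg.snp, records)
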