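"""Multiple-testing adjustment and subgroup stratification.

The multiplicity family is the five genetic models within one
(SNP, stratum) cell: Bonferroni multiplies each raw p by 5 (capped at 1)
and Benjamini-Hochberg steps up across the same five.  Subgroup analyses
are always pooled with DerSimonian-Laird random effects, the conservative
choice the source analysis mandates for strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .association import hwe_test
from .core_data import StudyDataset
from .genetic_models import GENETIC_MODELS, GeneticModel, dataset_contrasts
from .pooling import PoolResult, pool_random_dl

SUBGROUP_AXES = ("race", "hwe", "sample_size", "genotyping_method")

#: persons (cases + controls) at or above which a study is "large"
SAMPLE_SIZE_THRESHOLD = 500


@dataclass(frozen=True)
class AdjustedPValues:
    raw: tuple[float, ...]
    bonferroni: tuple[float, ...]
    bh_fdr: tuple[float, ...]
    family_size: int


def adjust_pvalues(raw: Sequence[float], family_size: int | None = None) -> AdjustedPValues:
    """Bonferroni and Benjamini-Hochberg over one family of p-values.

    ``family_size`` defaults to ``len(raw)`` (five genetic models in the
    standard use); Bonferroni uses it as the multiplier even if fewer
    p-values are passed.
    """
    p = np.asarray(raw, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = family_size if family_size is not None else p.size
    bonf = np.minimum(p * m, 1.0)
    _, bh, _, _ = multipletests(p, method="fdr_bh")
    return AdjustedPValues(
        raw=tuple(p.tolist()),
        bonferroni=tuple(bonf.tolist()),
        bh_fdr=tuple(bh.tolist()),
        family_size=m,
    )


def _level_of(study, axis: str) -> str:
    if axis == "race":
        return study.race_group
    if axis == "genotyping_method":
        return study.genotyping_method
    if axis == "sample_size":
        return "large" if study.n_total >= SAMPLE_SIZE_THRESHOLD else "small"
    if axis == "hwe":
        return "in_HWE" if hwe_test(study.controls).in_hwe else "departure"
    raise ValueError(f"unknown axis {axis!r}")


def stratify(dataset: StudyDataset, axis: str) -> dict[str, StudyDataset]:
    """Partition a dataset along one stratification axis.

    Every study lands in exactly one level; empty levels are omitted.
    HWE membership is computed from the control genotype counts at
    p < 0.05, not read from any printed value.
    """
    levels: dict[str, list] = {}
    for s in dataset:
        levels.setdefault(_level_of(s, axis), []).append(s)
    return {lv: StudyDataset(dataset.snp, recs) for lv, recs in levels.items()}


@dataclass
class SubgroupCell:
    """Per-model random-effects results for one stratum, with the
    five-model multiplicity adjustment."""

    level: str
    results: dict[GeneticModel, PoolResult] = field(default_factory=dict)
    adjusted: AdjustedPValues | None = None


def subgroup_analysis(dataset: StudyDataset, axis: str) -> dict[str, SubgroupCell]:
    """Random-effects pooling per stratum and genetic model.

    Models under which every study of a stratum is excluded (double-zero
    tables) are omitted from that stratum's family.
    """
    out: dict[str, SubgroupCell] = {}
    for level, sub in stratify(dataset, axis).items():
        cell = SubgroupCell(level=level)
        for model in GENETIC_MODELS:
            tables = [t for t in dataset_contrasts(sub, model) if not t.excluded]
            if not tables:
                continue
            res = pool_random_dl(tables)
            res.snp = dataset.snp
            res.model = model.value
            cell.results[model] = res
        if cell.results:
            raws = [cell.results[m].p for m in cell.results]
            cell.adjusted = adjust_pvalues(raws, family_size=len(GENETIC_MODELS))
        out[level] = cell
    return out
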