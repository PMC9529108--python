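"""Genetic-model contrasts: genotype counts to 2x2 exposure tables.

Five standard reparameterizations of a three-genotype table.  Exposure is
always the effect (column-22, mutant) allele or the genotype(s) carrying
it, with the 11 homozygote as reference:

* allelic      -- allele 2 vs allele 1, counted in alleles
* dominant     -- (12 + 22) vs 11 carriers
* recessive    -- 22 vs (11 + 12) carriers
* heterozygote -- 12 vs 11 (22 carriers dropped)
* homozygote   -- 22 vs 11 (12 carriers dropped)
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .core_data import GenotypeCounts


class GeneticModel(str, enum.Enum):
    ALLELIC = "allelic"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    HETEROZYGOTE = "heterozygote"
    HOMOZYGOTE = "homozygote"


GENETIC_MODELS = tuple(GeneticModel)


@dataclass(frozen=True)
class ContrastTable:
    """A 2x2 exposure table for one study under one genetic model.

    ``excluded`` is set when both arms have zero exposed (or zero
    unexposed) counts: such a double-zero table carries no information
    about the odds ratio and is dropped from pooling rather than
    continuity-corrected.
    """

    case_exposed: int
    case_unexposed: int
    control_exposed: int
    control_unexposed: int
    unit: str  # "alleles" or "persons"
    model: GeneticModel
    excluded: bool = False
    study_id: str | None = None

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (
            self.case_exposed,
            self.case_unexposed,
            self.control_exposed,
            self.control_unexposed,
        )

    @property
    def n_persons(self) -> int:
        """Persons contributing to this contrast (alleles counted /2)."""
        total = sum(self.cells)
        return total // 2 if self.unit == "alleles" else total

    def flipped(self) -> "ContrastTable":
        """Swap exposure orientation (maps OR to 1/OR)."""
        return ContrastTable(
            self.case_unexposed,
            self.case_exposed,
            self.control_unexposed,
            self.control_exposed,
            self.unit,
            self.model,
            self.excluded,
            self.study_id,
        )


def genotype_to_contrast(
    cases: GenotypeCounts,
    controls: GenotypeCounts,
    model: GeneticModel,
    study_id: str | None = None,
) -> ContrastTable:
    """Build the 2x2 exposure table for one study under one genetic model."""
    model = GeneticModel(model)
    for name, arm in (("cases", cases), ("controls", controls)):
        if arm.n < 1:
            raise ValueError(f"empty {name} arm")

    if model is GeneticModel.ALLELIC:
        cells = (
            cases.allele2_count, cases.allele1_count,
            controls.allele2_count, controls.allele1_count,
        )
        unit = "alleles"
    elif model is GeneticModel.DOMINANT:
        cells = (cases.n12 + cases.n22, cases.n11,
                 controls.n12 + controls.n22, controls.n11)
        unit = "persons"
    elif model is GeneticModel.RECESSIVE:
        cells = (cases.n22, cases.n11 + cases.n12,
                 controls.n22, controls.n11 + controls.n12)
        unit = "persons"
    elif model is GeneticModel.HETEROZYGOTE:
        cells = (cases.n12, cases.n11, controls.n12, controls.n11)
        unit = "persons"
    else:  # homozygote
        cells = (cases.n22, cases.n11, controls.n22, controls.n11)
        unit = "persons"

    excluded = (cells[0] == 0 and cells[2] == 0) or (cells[1] == 0 and cells[3] == 0)
    return ContrastTable(*cells, unit=unit, model=model,
                         excluded=excluded, study_id=study_id)


def dataset_contrasts(dataset, model: GeneticModel) -> list[ContrastTable]:
    """Contrast tables for every study in a dataset (excluded ones kept,
    flagged)."""
    return [
        genotype_to_contrast(s.cases, s.controls, model, study_id=s.study_id)
        for s in dataset
    ]
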