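"""Domain types and I/O for per-study genotype-count tables.

The unit of analysis is a case-control study reporting the three genotype
counts (homozygote-11, heterozygote-12, homozygote-22) for each arm at one
VDR polymorphism.  A packaged fixture transcribes the genotype counts of
the thirteen publications (41 study rows across four SNPs) that the
upstream meta-analysis pooled; sub-cohorts published as separate strata
(Hossein-Nezhad 1-3, Ferrarezi 1-4) are kept as independent rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd

SNPS = ("rs2228570", "rs1544410", "rs7975232", "rs731236")
RACE_GROUPS = ("White", "Asian", "African")
GENOTYPING_METHODS = ("PCR-RFLP", "PCR-Taqman", "PCR-ABD")

#: Country -> race-group mapping used by the packaged fixture; it uniquely
#: reproduces the subgroup sizes of the source analysis (e.g. rs2228570
#: White N=7, Asian N=3, African N=1).
COUNTRY_RACE = {
    "Croatia": "White",
    "Poland": "White",
    "Iran": "White",
    "Brazil": "White",
    "Germany": "White",
    "China": "Asian",
    "Egypt": "African",
}

TSV_COLUMNS = [
    "study_id", "author", "year", "country", "race_group",
    "genotyping_method", "snp",
    "case_n11", "case_n12", "case_n22",
    "ctrl_n11", "ctrl_n12", "ctrl_n22",
    "quality_score",
]


class SchemaError(ValueError):
    """Input table does not match the documented TSV schema."""


class ValidationError(ValueError):
    """A study row violates a domain invariant."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts (persons) for one study arm.

    ``n11``/``n22`` are the two homozygote classes, ``n12`` the
    heterozygotes.  Allele 2 (the column-22, mutant allele) is the effect
    allele throughout the package.
    """

    n11: int
    n12: int
    n22: int

    def __post_init__(self) -> None:
        for name in ("n11", "n12", "n22"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValidationError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")

    @property
    def n(self) -> int:
        """Total persons in the arm."""
        return self.n11 + self.n12 + self.n22

    @property
    def allele2_count(self) -> int:
        """Copies of the effect (column-22) allele in the arm."""
        return 2 * self.n22 + self.n12

    @property
    def allele1_count(self) -> int:
        return 2 * self.n11 + self.n12


@dataclass(frozen=True)
class StudyRecord:
    """One study row: metadata plus case and control genotype counts."""

    study_id: str
    author: str
    year: int
    country: str
    race_group: str
    genotyping_method: str
    snp: str
    cases: GenotypeCounts
    controls: GenotypeCounts
    quality_score: int | None = None

    def __post_init__(self) -> None:
        if self.snp not in SNPS:
            raise ValidationError(f"unknown snp {self.snp!r} in study {self.study_id}")
        if self.race_group not in RACE_GROUPS:
            raise ValidationError(
                f"unknown race_group {self.race_group!r} in study {self.study_id}"
            )
        if self.genotyping_method not in GENOTYPING_METHODS:
            raise ValidationError(
                f"unknown genotyping_method {self.genotyping_method!r} "
                f"in study {self.study_id}"
            )
        if self.quality_score is not None and not 0 <= self.quality_score <= 9:
            raise ValidationError(
                f"quality_score out of range in study {self.study_id}"
            )

    @property
    def n_total(self) -> int:
        """Cases + controls, persons; drives the sample-size stratification."""
        return self.cases.n + self.controls.n


@dataclass
class StudyDataset:
    """All study rows for one SNP, in input order."""

    snp: str
    studies: list[StudyRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(
                f"duplicate study_id for snp {self.snp}: {sorted(dupes)}"
            )
        for s in self.studies:
            if s.snp != self.snp:
                raise ValidationError(
                    f"study {s.study_id} has snp {s.snp}, expected {self.snp}"
                )

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    @property
    def n_cases(self) -> int:
        """Total case persons, derived from the genotype columns."""
        return sum(s.cases.n for s in self.studies)

    @property
    def n_controls(self) -> int:
        return sum(s.controls.n for s in self.studies)

    def subset(self, study_ids: Iterable[str]) -> "StudyDataset":
        keep = set(study_ids)
        return StudyDataset(self.snp, [s for s in self.studies if s.study_id in keep])


def _records_from_frame(df: pd.DataFrame) -> list[StudyDataset]:
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    count_cols = ["case_n11", "case_n12", "case_n22", "ctrl_n11", "ctrl_n12", "ctrl_n22"]
    records: list[StudyRecord] = []
    for _, row in df.iterrows():
        sid = str(row["study_id"])
        for c in count_cols:
            v = row[c]
            if pd.isna(v) or float(v) != int(v):
                raise ValidationError(f"non-integer count {c} in study {sid}")
            if int(v) < 0:
                raise ValidationError(f"negative count {c} in study {sid}")
        qs = row["quality_score"]
        records.append(
            StudyRecord(
                study_id=sid,
                author=str(row["author"]),
                year=int(row["year"]),
                country=str(row["country"]),
                race_group=str(row["race_group"]),
                genotyping_method=str(row["genotyping_method"]),
                snp=str(row["snp"]),
                cases=GenotypeCounts(*(int(row[c]) for c in count_cols[:3])),
                controls=GenotypeCounts(*(int(row[c]) for c in count_cols[3:])),
                quality_score=None if pd.isna(qs) else int(qs),
            )
        )
    seen: dict[str, list[StudyRecord]] = {}
    for rec in records:
        seen.setdefault(rec.snp, []).append(rec)
    return [StudyDataset(snp, recs) for snp, recs in seen.items()]


def read_study_table(path) -> list[StudyDataset]:
    """Read a tab-separated study table into one dataset per SNP.

    Row order within each SNP is preserved.  Raises :class:`SchemaError`
    for header problems and :class:`ValidationError` for bad counts or
    duplicate ``(snp, study_id)`` pairs.
    """
    df = pd.read_csv(path, sep="\t", dtype={"study_id": str})
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    if df.empty:
        raise ValidationError(f"no study rows in {path}")
    return _records_from_frame(df)


def write_study_table(datasets: Iterable[StudyDataset], path) -> None:
    """Write datasets back to the TSV schema (round-trips with the reader)."""
    rows = []
    for ds in datasets:
        for s in ds:
            rows.append(
                {
                    "study_id": s.study_id,
                    "author": s.author,
                    "year": s.year,
                    "country": s.country,
                    "race_group": s.race_group,
                    "genotyping_method": s.genotyping_method,
                    "snp": s.snp,
                    "case_n11": s.cases.n11,
                    "case_n12": s.cases.n12,
                    "case_n22": s.cases.n22,
                    "ctrl_n11": s.controls.n11,
                    "ctrl_n12": s.controls.n12,
                    "ctrl_n22": s.controls.n22,
                    "quality_score": s.quality_score,
                }
            )
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def fixture_table1() -> list[StudyDataset]:
    """The packaged study table: 11/10/9/11 rows for the four SNPs.

    Genotype columns are transcribed verbatim from the source table and are
    authoritative; a handful of printed per-row N values are internally
    inconsistent with their own genotype counts (documented in
    docs/methods.md) and are ignored.
    """
    with resources.as_file(
        resources.files("vdrmeta.data").joinpath("table1.tsv")
    ) as p:
        return read_study_table(p)


def fixture_dataset(snp: str) -> StudyDataset:
    """Convenience accessor for one SNP's fixture dataset."""
    for ds in fixture_table1():
        if ds.snp == snp:
            return ds
    raise KeyError(snp)
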