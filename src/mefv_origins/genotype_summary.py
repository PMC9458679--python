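"""Genotype classification, carrier predicates and cohort summary statistics.

A referral's two allele calls place it in one of four genotype classes:

* ``NEGATIVE`` — both alleles wild type;
* ``HTZ(v)`` — heterozygous, exactly one variant allele;
* ``HMZ(v)`` — homozygous, two identical variant alleles;
* ``COMPOUND(v1, v2)`` — two distinct variant alleles.  The V726A + E148Q
  combination is flagged *apparent* compound heterozygous, since phase
  (cis/trans) is not verified by the screening assay.

Summaries mirror the referral-center prevalence table: per-class counts
split by sex with grand totals, plus per-variant carrier counts, compound
fractions, and the single-variant-type modeling subset used for the
logistic analysis (compound heterozygotes and the two rare variant types
are excluded there).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort_io import (
    WT,
    COMMON_VARIANTS,
    VARIANTS,
    Cohort,
    CohortError,
    ReferralRecord,
    canonical_allele_pair,
)

__all__ = [
    "GenotypeClass",
    "SummaryTable",
    "Prevalence",
    "CompoundStats",
    "classify_genotype",
    "carries",
    "summarize_cohort",
    "prevalence",
    "compound_stats",
    "modeling_subset",
]

#: Compound pair whose phase is unverified ("apparent" compound heterozygote).
_APPARENT_PAIRS = {("V726A", "E148Q")}


@dataclass(frozen=True, order=True)
class GenotypeClass:
    """A genotype class: ``kind`` in {NEGATIVE, HTZ, HMZ, COMPOUND} plus the
    variant(s) involved, in canonical order."""

    kind: str
    variants: tuple[str, ...] = ()

    @property
    def apparent(self) -> bool:
        """True for compound pairs whose phase is unverified."""
        return self.kind == "COMPOUND" and self.variants in _APPARENT_PAIRS

    @property
    def label(self) -> str:
        if self.kind == "NEGATIVE":
            return "negative"
        if self.kind in ("HTZ", "HMZ"):
            return f"{self.variants[0]} ({self.kind})"
        qualifier = "apparent compound heterozygous" if self.apparent else "compound heterozygous"
        return f"{self.variants[0]} + {self.variants[1]} ({qualifier})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


NEGATIVE = GenotypeClass("NEGATIVE")


def classify_genotype(a1: str, a2: str) -> GenotypeClass:
    """Classify an (unordered) allele pair; symmetric in its arguments."""
    a1, a2 = canonical_allele_pair(a1, a2)
    if a1 == WT:  # canonical order puts WT last, so both are WT
        return NEGATIVE
    if a2 == WT:
        return GenotypeClass("HTZ", (a1,))
    if a1 == a2:
        return GenotypeClass("HMZ", (a1,))
    return GenotypeClass("COMPOUND", (a1, a2))


def carries(record: ReferralRecord, variant: str) -> bool:
    """True iff either allele call equals ``variant``."""
    if variant not in VARIANTS:
        raise CohortError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return variant in record.alleles


@dataclass(frozen=True)
class SummaryTable:
    """Per-genotype-class counts by sex, with grand totals.

    ``counts`` is indexed by genotype-class label with columns
    ``female, male, missing_sex, total``, ordered by descending total.
    """

    counts: pd.DataFrame
    total_female: int
    total_male: int
    total_missing_sex: int
    total: int

    def to_frame(self, include_total_row: bool = True) -> pd.DataFrame:
        df = self.counts.copy()
        if include_total_row:
            df.loc["Total"] = [
                self.total_female,
                self.total_male,
                self.total_missing_sex,
                self.total,
            ]
        return df


def summarize_cohort(cohort: Cohort) -> SummaryTable:
    """Tabulate genotype classes by sex.

    Row sums equal the total column and column sums equal the grand totals
    by construction; records with missing sex are kept in a separate column.
    """
    rows: dict[str, list[int]] = {}
    tf = tm = tu = 0
    for rec in cohort:
        cls = classify_genotype(*rec.alleles)
        row = rows.setdefault(cls.label, [0, 0, 0, 0])
        j = {"female": 0, "male": 1, "": 2}[rec.sex]
        row[j] += 1
        row[3] += 1
        tf += rec.sex == "female"
        tm += rec.sex == "male"
        tu += rec.sex == ""
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["female", "male", "missing_sex", "total"]
    )
    df = df.loc[sorted(df.index, key=lambda lab: (-df.loc[lab, "total"], lab))]
    return SummaryTable(df, tf, tm, tu, len(cohort))


@dataclass(frozen=True)
class Prevalence:
    """Carrier count and percentage of a variant in a cohort."""

    variant: str
    count: int
    n: int

    @property
    def percent(self) -> float:
        """Percentage, full precision (format to one decimal for reporting)."""
        return 100.0 * self.count / self.n

    @property
    def percent_rounded(self) -> int:
        return round(self.percent)


def prevalence(cohort: Cohort, variant: str) -> Prevalence:
    """Carrier count and percentage of ``variant`` among all referrals."""
    if len(cohort) == 0:
        raise CohortError("prevalence undefined on an empty cohort")
    count = sum(carries(rec, variant) for rec in cohort)
    return Prevalence(variant, count, len(cohort))


@dataclass(frozen=True)
class CompoundStats:
    """Among carriers of a variant, how many carry a second, different one."""

    variant: str
    carriers: int
    compound: int

    @property
    def fraction(self) -> float | None:
        """Compound fraction among carriers; None when there are no carriers."""
        if self.carriers == 0:
            return None
        return self.compound / self.carriers


def compound_stats(cohort: Cohort, variant: str) -> CompoundStats:
    """Count carriers of ``variant`` whose other allele is a different
    (non-WT) variant."""
    if len(cohort) == 0:
        raise CohortError("compound_stats undefined on an empty cohort")
    carriers = compound = 0
    for rec in cohort:
        if not carries(rec, variant):
            continue
        carriers += 1
        cls = classify_genotype(*rec.alleles)
        compound += cls.kind == "COMPOUND"
    return CompoundStats(variant, carriers, compound)


def modeling_subset(cohort: Cohort) -> Cohort:
    """Records eligible for the per-variant logistic models: carriers of a
    single variant type (HTZ or HMZ) among the three common variants.

    Drops genotype-negative records, all compound heterozygotes, and
    single-type carriers of the two rare variants (M680I, M694I), which are
    too sparse to model.
    """

    def keep(rec: ReferralRecord) -> bool:
        cls = classify_genotype(*rec.alleles)
        return cls.kind in ("HTZ", "HMZ") and cls.variants[0] in COMMON_VARIANTS

    return cohort.subset(keep)
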