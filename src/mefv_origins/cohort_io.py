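"""Referral-cohort data model and delimited-text I/O.

A cohort is a sequence of referrals for MEFV genetic testing.  Each referral
carries the subject's sex, the countries of origin of the four grandparents
(two per parental side, any of which may be unknown), and the two allele
calls from screening for the five common MEFV founder variants.

The on-disk format is a delimited text file (comma or tab), UTF-8, with a
required header naming eight columns::

    subject_id, sex, gp_paternal_1, gp_paternal_2,
    gp_maternal_1, gp_maternal_2, allele_1, allele_2

Missing values (unknown sex, unknown grandparent origin) are empty strings.
Allele calls are one of ``WT, M694V, V726A, E148Q, M680I, M694I``; anything
else is rejected at parse time, mirroring the exclusion of referrals with
uncommon variants from the study's data model.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "WT",
    "VARIANTS",
    "COMMON_VARIANTS",
    "ALLELES",
    "SEXES",
    "COLUMNS",
    "CohortError",
    "ParseError",
    "ReferralRecord",
    "Cohort",
    "canonical_allele_pair",
    "read_cohort",
    "write_cohort",
]

WT = "WT"
#: The five screened founder variants, in canonical order.
VARIANTS = ("M694V", "V726A", "E148Q", "M680I", "M694I")
#: The three variant types common enough to model individually.
COMMON_VARIANTS = ("M694V", "V726A", "E148Q")
ALLELES = (WT,) + VARIANTS
_ALLELE_RANK = {a: i for i, a in enumerate(ALLELES)}

SEXES = ("female", "male", "")  # "" = missing

COLUMNS = (
    "subject_id",
    "sex",
    "gp_paternal_1",
    "gp_paternal_2",
    "gp_maternal_1",
    "gp_maternal_2",
    "allele_1",
    "allele_2",
)


class CohortError(ValueError):
    """A record or cohort violates a structural invariant."""


class ParseError(CohortError):
    """A delimited-text row could not be interpreted."""


def canonical_allele_pair(a1: str, a2: str) -> tuple[str, str]:
    """Order an unordered allele pair: non-WT alleles first, then by the
    canonical variant order.  ``(WT, M694V)`` becomes ``(M694V, WT)``."""
    for a in (a1, a2):
        if a not in _ALLELE_RANK:
            raise CohortError(f"unknown allele symbol {a!r}; expected one of {ALLELES}")
    return tuple(sorted((a1, a2), key=lambda a: (a == WT, _ALLELE_RANK[a])))  # type: ignore[return-value]


@dataclass(frozen=True)
class ReferralRecord:
    """One referral: sex, four grandparent origin slots, two allele calls.

    Grandparent slots hold a country code or ``""`` when unknown.  The allele
    pair is unordered and stored canonically (variants before WT, variants in
    canonical order), so two records differing only in allele order compare
    equal.
    """

    subject_id: str
    sex: str = ""
    gp_paternal_1: str = ""
    gp_paternal_2: str = ""
    gp_maternal_1: str = ""
    gp_maternal_2: str = ""
    allele_1: str = WT
    allele_2: str = WT

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise CohortError("subject_id must be a non-empty string")
        if self.sex not in SEXES:
            raise CohortError(
                f"subject {self.subject_id!r}: sex {self.sex!r} not in {SEXES}"
            )
        a1, a2 = canonical_allele_pair(self.allele_1, self.allele_2)
        object.__setattr__(self, "allele_1", a1)
        object.__setattr__(self, "allele_2", a2)
        for slot in ("gp_paternal_1", "gp_paternal_2", "gp_maternal_1", "gp_maternal_2"):
            object.__setattr__(self, slot, getattr(self, slot).strip())

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_1, self.allele_2)

    @property
    def paternal(self) -> tuple[str, str]:
        return (self.gp_paternal_1, self.gp_paternal_2)

    @property
    def maternal(self) -> tuple[str, str]:
        return (self.gp_maternal_1, self.gp_maternal_2)

    @property
    def grandparents(self) -> tuple[str, str, str, str]:
        return self.paternal + self.maternal

    def countries(self) -> set[str]:
        """Distinct known grandparent countries of this referral."""
        return {c for c in self.grandparents if c}

    def with_slots(self, paternal: tuple[str, str], maternal: tuple[str, str]) -> "ReferralRecord":
        return replace(
            self,
            gp_paternal_1=paternal[0],
            gp_paternal_2=paternal[1],
            gp_maternal_1=maternal[0],
            gp_maternal_2=maternal[1],
        )


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of referrals plus a registry of country codes.

    The registry always covers every country mentioned in any record; extra
    codes (countries known to the study but absent from this file) may be
    registered explicitly.
    """

    referrals: tuple[ReferralRecord, ...]
    country_registry: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.referrals:
            if rec.subject_id in seen:
                raise CohortError(f"duplicate subject_id {rec.subject_id!r}")
            seen.add(rec.subject_id)
        mentioned = set()
        for rec in self.referrals:
            mentioned |= rec.countries()
        object.__setattr__(
            self, "country_registry", frozenset(self.country_registry) | mentioned
        )

    @classmethod
    def from_records(
        cls, records: Iterable[ReferralRecord], extra_countries: Iterable[str] = ()
    ) -> "Cohort":
        return cls(tuple(records), frozenset(extra_countries))

    def __len__(self) -> int:
        return len(self.referrals)

    def __iter__(self):
        return iter(self.referrals)

    def __getitem__(self, i):
        return self.referrals[i]

    def subset(self, predicate) -> "Cohort":
        """New cohort keeping the records for which ``predicate`` is true;
        the registry is carried over unchanged."""
        return Cohort(
            tuple(r for r in self.referrals if predicate(r)), self.country_registry
        )


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_cohort(
    path: str | Path,
    delimiter: str | None = None,
    extra_countries: Iterable[str] = (),
) -> Cohort:
    """Read a cohort from delimited text.

    The delimiter defaults to tab for ``.tsv``/``.tab`` files and comma
    otherwise.  Raises :class:`ParseError` naming the offending row for
    unknown allele symbols, bad sex codes, or malformed rows, and
    :class:`CohortError` for duplicate subject ids.
    """
    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return _read_cohort_stream(fh, delim, extra_countries, str(path))


def _read_cohort_stream(
    fh: io.TextIOBase, delim: str, extra_countries: Iterable[str], name: str
) -> Cohort:
    reader = csv.reader(fh, delimiter=delim)
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError(f"{name}: empty file (header row required)") from None
    header = [h.strip() for h in header]
    if set(header) != set(COLUMNS) or len(header) != len(COLUMNS):
        raise ParseError(
            f"{name}: header must name exactly the columns {COLUMNS}, got {tuple(header)}"
        )
    col = {c: header.index(c) for c in COLUMNS}
    records = []
    for rownum, row in enumerate(reader, start=2):
        if not row or all(not cell.strip() for cell in row):
            continue
        if len(row) != len(COLUMNS):
            raise ParseError(
                f"{name} row {rownum}: expected {len(COLUMNS)} fields, got {len(row)}"
            )
        get = lambda c: row[col[c]].strip()
        try:
            records.append(
                ReferralRecord(
                    subject_id=get("subject_id"),
                    sex=get("sex"),
                    gp_paternal_1=get("gp_paternal_1"),
                    gp_paternal_2=get("gp_paternal_2"),
                    gp_maternal_1=get("gp_maternal_1"),
                    gp_maternal_2=get("gp_maternal_2"),
                    allele_1=get("allele_1"),
                    allele_2=get("allele_2"),
                )
            )
        except CohortError as exc:
            raise ParseError(f"{name} row {rownum}: {exc}") from exc
    return Cohort.from_records(records, extra_countries)


def write_cohort(
    cohort: Cohort, path: str | Path, delimiter: str | None = None
) -> Path:
    """Write a cohort as delimited text readable by :func:`read_cohort`.

    Missing fields are written as empty strings; an empty cohort yields a
    header-only file.
    """
    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(COLUMNS)
        for rec in cohort:
            writer.writerow([getattr(rec, c) for c in COLUMNS])
    return path
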