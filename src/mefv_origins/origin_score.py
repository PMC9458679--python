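"""Origin-score encoding of grandparent ancestry.

Each eligible referral is encoded as a row of ancestry fractions over
countries: every grandparent contributes 0.25 to the cell of their country
of origin, so entries are exact multiples of 0.25 and each row sums to 1.

Two rules govern missing pedigree information:

* **Imputation** — if exactly one grandparent on a parental side is known,
  the missing grandparent is assumed to share that country.
* **Eligibility** — a referral with no known grandparent on either parental
  side cannot be encoded and is excluded (ineligibility is a value, not an
  error).

Countries contributing fewer than a minimum number of referrals (default 15,
counting referrals with *any* positive ancestry fraction) are dropped from
the feature matrix; rows are deliberately **not** renormalized afterwards,
so a retained entry always means "this fraction of grandparents", and
post-filter row sums may be below 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import Cohort, CohortError, ReferralRecord

__all__ = [
    "CountryFilter",
    "impute_grandparents",
    "encode_origin",
    "build_matrix",
    "filter_countries",
    "origin_score_sums",
]

#: Valid origin-score entries (exact in binary floating point).
FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)


def _impute_side(side: tuple[str, str]) -> tuple[str, str] | None:
    """Fill a one-known side; None when neither grandparent is known."""
    a, b = side
    if a and b:
        return (a, b)
    if a:
        return (a, a)
    if b:
        return (b, b)
    return None


def impute_grandparents(record: ReferralRecord) -> ReferralRecord | None:
    """Apply the single-known-grandparent imputation rule.

    Returns the (possibly) completed record, or ``None`` when the record is
    ineligible because some parental side has no known grandparent.  Known
    slots are never altered.
    """
    paternal = _impute_side(record.paternal)
    maternal = _impute_side(record.maternal)
    if paternal is None or maternal is None:
        return None
    if paternal == record.paternal and maternal == record.maternal:
        return record
    return record.with_slots(paternal, maternal)


def encode_origin(record: ReferralRecord) -> dict[str, float]:
    """Ancestry fractions of a fully imputed record: 0.25 per grandparent.

    Raises :class:`CohortError` if any slot is still missing (the record
    must have passed :func:`impute_grandparents` first).
    """
    row: dict[str, float] = {}
    for country in record.grandparents:
        if not country:
            raise CohortError(
                f"subject {record.subject_id!r}: cannot encode a record with "
                "missing grandparent slots; impute or exclude it first"
            )
        row[country] = row.get(country, 0.0) + 0.25
    return row


def build_matrix(cohort: Cohort) -> tuple[pd.DataFrame, dict[str, str]]:
    """Encode a cohort into a subjects x countries origin-score matrix.

    Returns the matrix (one row per eligible referral, in cohort order,
    indexed by subject id; columns sorted alphabetically) and a mapping of
    excluded subject ids to the reason for exclusion.  Every matrix row sums
    to exactly 1.0.
    """
    rows: dict[str, dict[str, float]] = {}
    excluded: dict[str, str] = {}
    for rec in cohort:
        imputed = impute_grandparents(rec)
        if imputed is None:
            missing = [
                side
                for side, slots in (("paternal", rec.paternal), ("maternal", rec.maternal))
                if not any(slots)
            ]
            excluded[rec.subject_id] = (
                "no known grandparent on the " + " or ".join(missing) + " side"
            )
            continue
        rows[rec.subject_id] = encode_origin(imputed)
    countries = sorted({c for row in rows.values() for c in row})
    matrix = pd.DataFrame(0.0, index=list(rows), columns=countries)
    for sid, row in rows.items():
        for country, frac in row.items():
            matrix.at[sid, country] = frac
    matrix.index.name = "subject_id"
    return matrix, excluded


@dataclass(frozen=True)
class CountryFilter:
    """Result of thresholding countries on referral support."""

    min_referrals: int
    counts: pd.Series  # per-country referral counts (any positive fraction)
    retained: tuple[str, ...]

    @property
    def dropped(self) -> tuple[str, ...]:
        return tuple(c for c in self.counts.index if c not in self.retained)


def filter_countries(
    matrix: pd.DataFrame, min_referrals: int = 15
) -> tuple[pd.DataFrame, CountryFilter]:
    """Drop countries represented by fewer than ``min_referrals`` referrals.

    A referral supports a country when its ancestry fraction there is
    positive, whatever the fraction.  Rows are not renormalized; a row that
    loses columns sums to less than 1.
    """
    if min_referrals < 1:
        raise ValueError("min_referrals must be >= 1")
    counts = (matrix > 0).sum(axis=0)
    counts.name = "referrals"
    retained = tuple(c for c in matrix.columns if counts[c] >= min_referrals)
    if not retained:
        raise CohortError(
            f"no country reaches {min_referrals} referrals; nothing to analyse"
        )
    return matrix.loc[:, list(retained)], CountryFilter(min_referrals, counts, retained)


def origin_score_sums(matrix: pd.DataFrame) -> pd.Series:
    """Per-country sums of origin scores (column sums).

    On an unfiltered matrix these conserve mass: the grand total equals the
    number of rows.
    """
    sums = matrix.sum(axis=0)
    sums.name = "origin_score_sum"
    return sums
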