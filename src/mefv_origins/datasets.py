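"""Packaged reference dataset: the referral-center genotype prevalence table.

The study center screened 1781 Jewish FMF referrals (2001-2017) positive for
at least one of the five common MEFV founder variants.  The published
prevalence table gives, for each genotype class, the number of female and
male referrals.  :func:`table1_counts` returns those counts; :func:`table1_cohort`
expands them into an explicit cohort of 1781 referral records (grandparent
origins are not published per subject, so origin slots are left empty — the
fixture supports genotype summaries, not origin analysis).

The sex split of the two rarest compound classes is printed ambiguously in
the source table; the split used here (2 female / 0 male and 1 female /
0 male) is the unique assignment consistent with the printed sex marginals
(920 female, 861 male, 1781 total), which :func:`table1_counts` re-verifies
on every call.
"""

from __future__ import annotations

import pandas as pd

from .cohort_io import WT, Cohort, ReferralRecord

__all__ = ["table1_counts", "table1_cohort", "TABLE1_TOTALS"]

# (allele_1, allele_2, female, male); order follows the published table.
_TABLE1 = (
    ("M694V", WT, 421, 403),       # M694V heterozygous
    ("E148Q", WT, 142, 119),       # E148Q heterozygous
    ("M694V", "M694V", 122, 100),  # M694V homozygous
    ("V726A", WT, 88, 72),         # V726A heterozygous
    ("M694V", "E148Q", 58, 63),    # compound heterozygous
    ("M694V", "V726A", 49, 67),    # compound heterozygous
    ("V726A", "V726A", 16, 21),    # V726A homozygous
    ("V726A", "E148Q", 15, 14),    # apparent compound heterozygous
    ("E148Q", "E148Q", 6, 2),      # E148Q homozygous
    ("M694V", "M680I", 2, 0),      # compound heterozygous
    ("M694V", "M694I", 1, 0),      # compound heterozygous
)

#: Published grand totals: (female, male, overall).
TABLE1_TOTALS = (920, 861, 1781)


def table1_counts() -> pd.DataFrame:
    """The published genotype-class counts as a DataFrame with columns
    ``allele_1, allele_2, female, male, total``; marginals re-verified."""
    df = pd.DataFrame(_TABLE1, columns=["allele_1", "allele_2", "female", "male"])
    df["total"] = df["female"] + df["male"]
    tf, tm, tt = TABLE1_TOTALS
    if not (df["female"].sum() == tf and df["male"].sum() == tm and df["total"].sum() == tt):
        raise AssertionError("packaged counts do not reproduce the published marginals")
    return df


def table1_cohort() -> Cohort:
    """Expand the published counts into a cohort of individual records.

    Record ids are deterministic (``T1-0001`` ...); within each genotype
    class, female records precede male records.
    """
    records = []
    i = 0
    for a1, a2, nf, nm in _TABLE1:
        for sex, n in (("female", nf), ("male", nm)):
            for _ in range(n):
                i += 1
                records.append(
                    ReferralRecord(
                        subject_id=f"T1-{i:04d}", sex=sex, allele_1=a1, allele_2=a2
                    )
                )
    return Cohort.from_records(records)
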