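"""Country-group formation and prevalence-by-grandparent-dose tables.

From a per-variant country ranking, two groups of four countries are
formed: the four most positively associated origins and the four most
negatively associated.  For each referral the *grandparent dose* of a group
is the fraction of grandparents (0, 0.25, 0.5, 0.75 or 1) originating from
any group member; binning carriers and non-carriers by dose gives the
prevalence-versus-dose tables behind the study's bar charts.

Doses are computed from the *unfiltered* origin matrix: the dose is a
property of the pedigree, so countries dropped from the feature matrix by
the referral-count threshold must not deflate it.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .cohort_io import Cohort
from .evaluation import CountryRanking
from .genotype_summary import carries

__all__ = ["DOSE_LEVELS", "select_groups", "group_dose", "dose_prevalence"]

DOSE_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


def select_groups(
    ranking: CountryRanking, size: int = 4
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """The ``size`` highest- and lowest-ranked countries.

    The top group is ordered strongest-positive first, the bottom group
    strongest-negative first.  With exactly ``size`` countries the two
    groups are the same set in reverse order.
    """
    return ranking.top(size), ranking.bottom(size)


def group_dose(row: pd.Series, group: Iterable[str]) -> float:
    """A referral's grandparent dose for a country group: the sum of the
    origin-matrix row over group members (countries absent from the row
    contribute 0)."""
    return float(sum(row.get(c, 0.0) for c in group))


def dose_prevalence(
    cohort: Cohort,
    matrix: pd.DataFrame,
    group: Iterable[str],
    variant: str,
) -> pd.DataFrame:
    """Carrier and non-carrier counts, and carrier prevalence, by dose level.

    ``matrix`` must be the unfiltered origin matrix; its rows define the
    eligible referrals.  Every eligible referral lands in exactly one dose
    bin, so bin totals conserve the eligible cohort.  Empty bins keep zero
    counts and an undefined (NaN) prevalence.
    """
    group = tuple(group)
    cols = [c for c in group if c in matrix.columns]
    doses = matrix[cols].sum(axis=1) if cols else pd.Series(0.0, index=matrix.index)
    by_id = {rec.subject_id: rec for rec in cohort}
    table = pd.DataFrame(
        0, index=pd.Index(DOSE_LEVELS, name="dose"), columns=["carriers", "non_carriers"]
    )
    for sid, dose in doses.items():
        rec = by_id.get(sid)
        if rec is None:
            raise KeyError(f"matrix row {sid!r} has no matching cohort record")
        level = round(dose * 4) / 4
        if not np.isclose(dose, level) or level not in DOSE_LEVELS:
            raise ValueError(f"subject {sid!r}: dose {dose} is not a multiple of 0.25")
        col = "carriers" if carries(rec, variant) else "non_carriers"
        table.loc[level, col] += 1
    table["total"] = table["carriers"] + table["non_carriers"]
    with np.errstate(invalid="ignore"):
        table["prevalence"] = np.where(
            table["total"] > 0, table["carriers"] / table["total"].replace(0, np.nan), np.nan
        )
    return table
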