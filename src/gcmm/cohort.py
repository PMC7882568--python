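"""Cohort comparisons across survey years.

Participation in each game type is compared across survey years with an
asymptotic chi-square test (no continuity correction) and Cramér's V; ordinal
and metric variables with the Kruskal-Wallis test (tie-corrected H) and the
eta-squared effect size (H - k + 1) / (n - k). Participation-rate growth is
summarized as last-year/first-year ratios with unweighted means per game mode
(offline / online). These statistics inform the analyst's judgment on whether
the merged surveys may be treated as one homogeneous population; the package
reports effect sizes and leaves that judgment to the analyst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import GameTypeCatalog
from .features import derive_participation, pgsi_group
from .survey import SurveyTable

__all__ = [
    "ContingencyResult",
    "KruskalResult",
    "GrowthSummary",
    "contingency_from_counts",
    "participation_table",
    "kruskal_by_year",
    "growth_ratios",
    "group_distribution",
]


@dataclass
class ContingencyResult:
    """2 x k participation-by-year table with chi-square and Cramér's V."""

    type_id: str
    years: list[int]
    participants: np.ndarray  # per-year participant counts
    totals: np.ndarray  # per-year respondent counts
    chi2: float
    df: int
    p: float
    cramers_v: float
    min_expected_cell: float
    sparse_flag: bool

    @property
    def rates(self) -> np.ndarray:
        return self.participants / self.totals


@dataclass
class KruskalResult:
    """Kruskal-Wallis comparison of one variable across survey years."""

    variable: str
    H: float
    df: int
    p: float
    eta_squared: float
    group_sizes: list[int] = field(default_factory=list)


@dataclass
class GrowthSummary:
    """Per-type last/first-year participation-rate ratios and mode means."""

    ratios: dict  # type_id -> ratio (absent when first-year rate is 0)
    excluded: list  # type_ids with undefined ratio
    mean_offline: float
    mean_online: float
    first_year: int
    last_year: int


def contingency_from_counts(participants, totals, type_id: str = "", years=None) -> ContingencyResult:
    """Chi-square test of a 2 x k participant/non-participant table.

    ``participants`` are per-year participant counts, ``totals`` the per-year
    sample sizes (so non-participants are ``totals - participants``).
    """
    part = np.asarray(participants, dtype=float)
    tot = np.asarray(totals, dtype=float)
    if part.shape != tot.shape or part.ndim != 1 or part.size < 2:
        raise ValueError("need per-year participant and total counts for >= 2 years")
    if (part > tot).any() or (part < 0).any():
        raise ValueError("participant counts must lie in [0, total] per year")
    table = np.vstack([part, tot - part])
    chi2, p, df, expected = sps.chi2_contingency(table, correction=False)
    n = tot.sum()
    k = min(table.shape[0] - 1, table.shape[1] - 1)
    v = float(np.sqrt(chi2 / (n * k))) if n > 0 and k > 0 else np.nan
    return ContingencyResult(
        type_id=type_id,
        years=list(years) if years is not None else list(range(part.size)),
        participants=part.astype(int),
        totals=tot.astype(int),
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        cramers_v=v,
        min_expected_cell=float(expected.min()),
        sparse_flag=bool(expected.min() < 5),
    )


def participation_table(table: SurveyTable, type_id: str) -> ContingencyResult:
    """Participation-by-year contingency test for one game type."""
    years = table.years
    if len(years) < 2:
        raise ValueError("need at least two survey years")
    col = table.catalog.get(type_id).frequency_column
    participants, totals = [], []
    for yr in years:
        sub = table.df.loc[table.df["year"] == yr, col].to_numpy(dtype=float)
        if sub.size == 0:
            raise ValueError(f"survey year {yr} has no rows")
        participants.append(int(derive_participation(sub).sum()))
        totals.append(sub.size)
    return contingency_from_counts(participants, totals, type_id=type_id, years=years)


def kruskal_by_year(values, year_labels, variable: str = "") -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H across survey years with eta-squared.

    ``eta_squared = (H - k + 1) / (n - k)`` where k is the number of groups.
    A variable identical across all rows yields H = 0 (not an error).
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(year_labels)
    keep = ~np.isnan(values)
    values, years = values[keep], years[keep]
    labels = np.unique(years)
    groups = [values[years == y] for y in labels]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty year groups")
    n, k = values.size, len(groups)
    if np.ptp(values) == 0:
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*groups)
    eta2 = (H - k + 1) / (n - k)
    return KruskalResult(
        variable=variable,
        H=float(H),
        df=k - 1,
        p=float(p),
        eta_squared=float(eta2),
        group_sizes=[len(g) for g in groups],
    )


def growth_ratios(results, catalog: GameTypeCatalog) -> GrowthSummary:
    """Last-year / first-year participation-rate ratio per type, with
    unweighted mean ratios for the offline and online groups.

    Types whose first-year rate is zero have an undefined ratio and are
    excluded from the group means (listed under ``excluded``).
    """
    ratios, excluded = {}, []
    first_year = last_year = None
    for res in results:
        rates = res.rates
        first_year, last_year = res.years[0], res.years[-1]
        if rates[0] == 0:
            excluded.append(res.type_id)
            continue
        ratios[res.type_id] = float(rates[-1] / rates[0])
    means = {}
    for mode in ("offline", "online"):
        ids = [e.type_id for e in catalog.by_mode(mode) if e.type_id in ratios]
        means[mode] = float(np.mean([ratios[t] for t in ids])) if ids else np.nan
    return GrowthSummary(
        ratios=ratios,
        excluded=excluded,
        mean_offline=means["offline"],
        mean_online=means["online"],
        first_year=first_year,
        last_year=last_year,
    )


def group_distribution(table: SurveyTable) -> pd.DataFrame:
    """Counts and fractions of the four problem-gambling risk groups."""
    labels = pgsi_group(table.df["pgsi_raw"].to_numpy(dtype=int))
    counts = pd.Series(labels).value_counts()
    from .features import PGSI_GROUP_LABELS

    out = pd.DataFrame(
        {
            "group": PGSI_GROUP_LABELS,
            "count": [int(counts.get(g, 0)) for g in PGSI_GROUP_LABELS],
        }
    )
    out["fraction"] = out["count"] / len(table) if len(table) else np.nan
    return out


def cohort_report(table: SurveyTable) -> pd.DataFrame:
    """Participation-by-year statistics for every catalog type (tidy table)."""
    rows = []
    for e in table.catalog:
        row = {"type_id": e.type_id, "label": e.label, "mode": e.mode}
        try:
            res = participation_table(table, e.type_id)
        except ValueError as exc:  # e.g. no participants in any year
            row.update(chi2=np.nan, df=np.nan, p=np.nan, cramers_v=np.nan,
                       sparse_flag=True, note=str(exc))
        else:
            row.update(
                chi2=res.chi2, df=res.df, p=res.p,
                cramers_v=res.cramers_v, sparse_flag=res.sparse_flag,
            )
            for yr, cnt, tot in zip(res.years, res.participants, res.totals):
                row[f"count_{yr}"] = cnt
                row[f"pct_{yr}"] = cnt / tot
        rows.append(row)
    return pd.DataFrame(rows)
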