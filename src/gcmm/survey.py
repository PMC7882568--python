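"""Respondent-level survey table: container, validation, CSV round trip, filtering.

A :class:`SurveyTable` wraps a pandas DataFrame holding one row per respondent
with demographics, per-game-type frequency (ordinal 0-5) and usual spending
(non-negative currency), the problem-gambling severity sum score (0-27) and
the survey year. Missing responses are empty cells in CSV and NaN in memory;
the replacement of missing depth responses by zero is *not* done here -- it is
an analysis step applied later, only among last-year gamblers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import GameTypeCatalog, default_catalog
from .errors import SchemaError

DEMOGRAPHIC_COLUMNS = ["year", "gender", "age", "education", "partnered"]
REQUIRED_COLUMNS = DEMOGRAPHIC_COLUMNS + ["pgsi_raw"]

GENDER_LEVELS = ("male", "female")
PARTNER_LEVELS = ("partnered", "single")  # single = single/divorced/widowed
FREQ_MIN, FREQ_MAX = 0, 5
PGSI_MIN, PGSI_MAX = 0, 27


@dataclass
class SurveyTable:
    """Typed respondent-level microdata bound to a game-type catalog."""

    df: pd.DataFrame
    catalog: GameTypeCatalog = field(default_factory=default_catalog)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        if "respondent_id" not in self.df.columns:
            self.df.insert(0, "respondent_id", [f"r{i:06d}" for i in range(len(self.df))])
        self.validate()

    # -- schema -------------------------------------------------------------
    def validate(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.df.columns:
                raise SchemaError(f"survey table is missing required column {col!r}")
        self.catalog.validate_columns(self.df.columns)

        freq = self.df[self.catalog.frequency_columns].to_numpy(dtype=float)
        present = ~np.isnan(freq)
        if present.any():
            vals = freq[present]
            if (vals != np.round(vals)).any() or vals.min() < FREQ_MIN or vals.max() > FREQ_MAX:
                bad = np.argwhere(present & ((freq < FREQ_MIN) | (freq > FREQ_MAX) | (freq != np.round(freq))))
                r, c = bad[0]
                raise SchemaError(
                    f"frequency value {freq[r, c]!r} out of ordinal range "
                    f"{FREQ_MIN}-{FREQ_MAX} (row {r}, column "
                    f"{self.catalog.frequency_columns[c]!r})"
                )
        spend = self.df[self.catalog.spending_columns].to_numpy(dtype=float)
        if np.nanmin(spend, initial=0.0) < 0:
            bad = np.argwhere(spend < 0)
            r, c = bad[0]
            raise SchemaError(
                f"negative spending (row {r}, column "
                f"{self.catalog.spending_columns[c]!r})"
            )
        pgsi = self.df["pgsi_raw"].to_numpy(dtype=float)
        ok = np.isnan(pgsi) | ((pgsi >= PGSI_MIN) & (pgsi <= PGSI_MAX) & (pgsi == np.round(pgsi)))
        if not ok.all():
            r = int(np.argmax(~ok))
            raise SchemaError(f"pgsi_raw value {pgsi[r]!r} outside 0-27 (row {r})")
        for col, levels in (("gender", GENDER_LEVELS), ("partnered", PARTNER_LEVELS)):
            vals = self.df[col].dropna()
            bad = ~vals.isin(levels)
            if bad.any():
                r = int(bad.idxmax())
                raise SchemaError(f"invalid {col} value {vals.loc[r]!r} (row {r})")
        edu = self.df["education"].to_numpy(dtype=float)
        ok = np.isnan(edu) | np.isin(edu, (1, 2, 3))
        if not ok.all():
            r = int(np.argmax(~ok))
            raise SchemaError(f"education value {edu[r]!r} not an ordered level 1-3 (row {r})")

    # -- conveniences -------------------------------------------------------
    def __len__(self):
        return len(self.df)

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].dropna().unique().astype(int))

    def copy(self) -> "SurveyTable":
        return SurveyTable(self.df.copy(), self.catalog, dict(self.meta))

    def participation_matrix(self) -> np.ndarray:
        """Binary (n, n_types) matrix: frequency >= 1; missing counts as 0."""
        freq = self.df[self.catalog.frequency_columns].to_numpy(dtype=float)
        return (np.nan_to_num(freq, nan=0.0) >= 1).astype(int)


def read_survey(path, catalog: GameTypeCatalog | None = None) -> SurveyTable:
    """Read a survey CSV into a typed :class:`SurveyTable`.

    Empty cells are missing. Out-of-range ordinal frequencies, negative
    spending and malformed numeric cells are rejected with the offending row
    named.
    """
    catalog = catalog or default_catalog()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace("", np.nan)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"survey CSV is missing required column {missing[0]!r}")
    catalog.validate_columns(df.columns)

    numeric_cols = (
        ["year", "age", "education", "pgsi_raw"]
        + catalog.frequency_columns
        + catalog.spending_columns
    )
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"unparseable value {df[col].iloc[row]!r} in column {col!r} at row {row}"
            )
        df[col] = parsed
    df["year"] = df["year"].astype(int)
    df["pgsi_raw"] = df["pgsi_raw"].astype(int)
    return SurveyTable(df, catalog)


def write_survey(table: SurveyTable, path) -> None:
    """Write the table to CSV (UTF-8, empty cell = missing)."""
    table.df.to_csv(path, index=False)


def filter_last_year_gamblers(table: SurveyTable) -> SurveyTable:
    """Keep respondents who played at least one game type in the last year.

    A respondent qualifies when any non-missing frequency is >= 1. The
    retained fraction is recorded under ``meta['retained_fraction']``.
    Idempotent: filtering a filtered table changes nothing.
    """
    freq = table.df[table.catalog.frequency_columns].to_numpy(dtype=float)
    keep = (np.nan_to_num(freq, nan=0.0) >= 1).any(axis=1)
    out = table.df.loc[keep].reset_index(drop=True)
    meta = dict(table.meta)
    meta["retained_fraction"] = float(keep.mean()) if len(keep) else 0.0
    return SurveyTable(out, table.catalog, meta)
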