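"""Country-year rate panels: reading, validation, writing, rate arithmetic.

The common currency of every analysis stage is a long-format ("tidy") table
with one row per (country, year, age_group) carrying event counts and/or a
pre-computed outcome rate per 1000 women.  Rates are either supplied directly
(official published rates) or derived from counts as

    rate = 1000 * (births + abortions) / population

with abortions omitted in birth-rate mode (e.g. under-18 births, where
abortion counts are not comparable across countries).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUPS",
    "PANEL_COLUMNS",
    "AnalysisWindow",
    "RatePanel",
    "PanelSchemaError",
    "PanelIntegrityError",
    "read_panel",
    "write_panel",
    "compute_rate",
    "percent_reduction",
]

AGE_GROUPS = ("U16", "U18", "U20")

#: canonical column order for on-disk CSV panels
PANEL_COLUMNS = ("country", "year", "age_group", "births", "abortions",
                 "population", "rate")

KEY = ["country", "year", "age_group"]
COUNT_COLS = ("births", "abortions", "population")


class PanelSchemaError(ValueError):
    """A required column is missing or a cell has the wrong type."""


class PanelIntegrityError(ValueError):
    """Duplicate keys, gaps, or value constraints violated."""


@dataclass(frozen=True)
class AnalysisWindow:
    """Pre/post analysis window around a known intervention year.

    ``pre_start .. intervention_year-1`` is the fitting (pre) period and
    ``intervention_year .. post_end`` the post period.
    """

    pre_start: int
    intervention_year: int = 1999
    post_end: int = 2013

    def __post_init__(self) -> None:
        if not (self.pre_start < self.intervention_year <= self.post_end):
            raise ValueError(
                f"require pre_start < intervention_year <= post_end, got "
                f"({self.pre_start}, {self.intervention_year}, {self.post_end})"
            )

    @property
    def pre_years(self) -> range:
        return range(self.pre_start, self.intervention_year)

    @property
    def post_years(self) -> range:
        return range(self.intervention_year, self.post_end + 1)

    @property
    def years(self) -> range:
        return range(self.pre_start, self.post_end + 1)


def compute_rate(births: float, abortions: float | None,
                 population: float) -> float:
    """Events per 1000 women: ``1000 * (births + abortions) / population``.

    ``abortions=None`` selects birth-rate mode (the under-18 births measure,
    where abortion counts are unavailable); a count of 0 is a real zero.
    """
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    if births < 0:
        raise ValueError(f"births must be non-negative, got {births}")
    events = float(births)
    if abortions is not None:
        if abortions < 0:
            raise ValueError(f"abortions must be non-negative, got {abortions}")
        events += float(abortions)
    return 1000.0 * events / float(population)


def percent_reduction(rate_start: float, rate_end: float) -> int:
    """Percentage fall from ``rate_start`` to ``rate_end``, nearest integer.

    This is the headline descriptive statistic for a rate series:
    ``round(100 * (start - end) / start)``.
    """
    if rate_start <= 0:
        raise ValueError(f"rate_start must be positive, got {rate_start}")
    frac = 100.0 * (rate_start - rate_end) / rate_start
    # round half away from zero so 62.5% -> 62... no: banker's rounding on
    # percentages surprises people; use the conventional half-up.
    return int(np.floor(frac + 0.5)) if frac >= 0 else -int(np.floor(-frac + 0.5))


@dataclass
class RatePanel:
    """Validated long-format country-year-age panel.

    Wraps a DataFrame with columns ``country, year, age_group`` plus any of
    ``births, abortions, population, rate``.  Each key appears at most once;
    counts are non-negative; population, where present, is positive.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        for col in KEY:
            if col not in df.columns:
                raise PanelSchemaError(f"missing required column: {col}")
        if "rate" not in df.columns and not all(
            c in df.columns for c in ("births", "population")
        ):
            raise PanelSchemaError(
                "panel needs a 'rate' column or 'births' + 'population'"
            )
        df = df.copy()
        df["year"] = _as_int(df["year"], "year")
        bad_age = set(df["age_group"].unique()) - set(AGE_GROUPS)
        if bad_age:
            raise PanelSchemaError(
                f"unknown age_group values {sorted(bad_age)}; "
                f"expected one of {AGE_GROUPS}"
            )
        dup = df.duplicated(subset=KEY)
        if dup.any():
            first = df.loc[dup, KEY].iloc[0]
            raise PanelIntegrityError(
                f"duplicate (country, year, age_group) key: "
                f"({first['country']}, {first['year']}, {first['age_group']})"
            )
        for col in ("births", "abortions", "population", "rate"):
            if col in df.columns:
                df[col] = _as_float(df[col], col)
                if col in COUNT_COLS and (df[col].dropna() < 0).any():
                    raise PanelIntegrityError(f"negative values in '{col}'")
        if "population" in df.columns and (df["population"].dropna() <= 0).any():
            raise PanelIntegrityError("non-positive population")
        self.data = df.sort_values(KEY).reset_index(drop=True)

    # -- access ------------------------------------------------------------

    @property
    def countries(self) -> list[str]:
        return sorted(self.data["country"].unique())

    def series(self, country: str, age_group: str = "U18",
               years: Iterable[int] | None = None) -> pd.Series:
        """Rate series (indexed by year) for one unit, gap-checked.

        Years inside the requested span must be consecutive: both analysis
        engines assume complete series, so an interior gap is an error rather
        than something to impute.
        """
        df = self.data
        sub = df[(df["country"] == country) & (df["age_group"] == age_group)]
        if sub.empty:
            raise PanelIntegrityError(
                f"no rows for ({country}, {age_group})")
        sub = sub.set_index("year").sort_index()
        rate = self._rates(sub)
        if years is not None:
            years = list(years)
            missing = [y for y in years if y not in rate.index]
            if missing:
                raise PanelIntegrityError(
                    f"{country}/{age_group}: missing year(s) {missing}")
            rate = rate.loc[years]
        yrs = rate.index.to_numpy()
        if len(yrs) > 1 and not np.array_equal(
            yrs, np.arange(yrs[0], yrs[-1] + 1)
        ):
            raise PanelIntegrityError(
                f"{country}/{age_group}: year gaps inside series")
        if rate.isna().any():
            bad = rate.index[rate.isna()].tolist()
            raise PanelIntegrityError(
                f"{country}/{age_group}: rate undefined for year(s) {bad}")
        rate.name = country
        return rate.astype(float)

    def _rates(self, sub: pd.DataFrame) -> pd.Series:
        if "rate" in sub.columns and sub["rate"].notna().all():
            return sub["rate"]
        # derive from counts where the rate cell is empty
        if "births" not in sub.columns or "population" not in sub.columns:
            return sub.get("rate", pd.Series(np.nan, index=sub.index))
        ab = sub["abortions"] if "abortions" in sub.columns else 0.0
        ab = pd.Series(ab, index=sub.index).fillna(0.0)
        derived = 1000.0 * (sub["births"] + ab) / sub["population"]
        if "rate" in sub.columns:
            return sub["rate"].fillna(derived)
        return derived

    def wide(self, age_group: str, countries: Sequence[str],
             years: Iterable[int]) -> pd.DataFrame:
        """Year x country matrix of rates for the given units and span."""
        years = list(years)
        cols = {c: self.series(c, age_group, years) for c in countries}
        return pd.DataFrame(cols, index=pd.Index(years, name="year"))

    def merge_units(self, parts: Sequence[str], new_label: str) -> "RatePanel":
        """Pool several countries into one unit by summing counts.

        Used to form combined units (e.g. "England and Wales") when only the
        aggregate is the exposed population.  Requires count columns; the
        pooled rate is re-derived from pooled counts.
        """
        df = self.data
        need = {"births", "population"}
        if not need.issubset(df.columns):
            raise PanelSchemaError("merge_units needs count columns")
        part_df = df[df["country"].isin(parts)].copy()
        if set(part_df["country"].unique()) != set(parts):
            missing = set(parts) - set(part_df["country"].unique())
            raise PanelIntegrityError(f"units not in panel: {sorted(missing)}")
        agg_cols = [c for c in COUNT_COLS if c in df.columns]
        pooled = (part_df.groupby(["year", "age_group"])[agg_cols]
                  .sum(min_count=len(parts)).reset_index())
        pooled["country"] = new_label
        ab = pooled["abortions"] if "abortions" in pooled.columns else 0.0
        pooled["rate"] = 1000.0 * (pooled["births"] + pd.Series(
            ab, index=pooled.index).fillna(0.0)) / pooled["population"]
        rest = df[~df["country"].isin(parts)]
        return RatePanel(pd.concat([rest, pooled], ignore_index=True))

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RatePanel):
            return NotImplemented
        a, b = self.data, other.data
        if sorted(a.columns) != sorted(b.columns):
            return False
        return a[sorted(a.columns)].equals(b[sorted(a.columns)])


def _as_int(s: pd.Series, name: str) -> pd.Series:
    try:
        out = pd.to_numeric(s, errors="raise")
    except (ValueError, TypeError) as exc:
        raise PanelSchemaError(f"non-numeric cell in '{name}': {exc}") from exc
    if not np.allclose(out, np.round(out)):
        raise PanelSchemaError(f"non-integer value in '{name}'")
    return out.astype(int)


def _as_float(s: pd.Series, name: str) -> pd.Series:
    try:
        return pd.to_numeric(s, errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise PanelSchemaError(f"non-numeric cell in '{name}': {exc}") from exc


def read_panel(path: str | Path | io.TextIOBase,
               schema: Mapping[str, str] | None = None) -> RatePanel:
    """Read a CSV panel, optionally renaming columns via ``schema``.

    ``schema`` maps file column names to canonical names, e.g.
    ``{"nation": "country"}``.  Validation (duplicates, negative counts,
    types) happens in the RatePanel constructor.
    """
    if isinstance(path, (str, Path)):
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"panel file not found: {p}")
        df = pd.read_csv(p, float_precision="round_trip")
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        df = df.rename(columns=dict(schema))
    keep = [c for c in PANEL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in PANEL_COLUMNS]
    return RatePanel(df[keep + extra])


def write_panel(panel: RatePanel, path: str | Path | io.TextIOBase) -> None:
    """Write a panel as CSV such that ``read_panel`` round-trips exactly.

    Numeric cells use repr-style shortest float formatting (bit-stable);
    missing cells are written empty, never as the text "NaN".
    """
    df = panel.data
    cols = [c for c in PANEL_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in PANEL_COLUMNS]
    out = df[cols].copy()
    for c in cols:
        if out[c].dtype == float:
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False)
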