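"""City-year exposure and socioeconomic panel: data model and CSV I/O.

A panel row holds, for one city in one calendar year, the annual mean
PM2.5 concentration (µg/m³), the exposed (resident) population, per-capita
disposable income (USD/yr) and per-capita GDP (USD/yr). All monetary
fields are USD at input; currency conversion is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import MissingDataError, SchemaError, ValidationError

__all__ = [
    "PANEL_COLUMNS",
    "CityYearRecord",
    "CityPanel",
    "read_panel",
    "write_panel",
    "annualize_concentrations",
]

PANEL_COLUMNS = [
    "city_id",
    "year",
    "concentration",
    "population",
    "income",
    "gdp_per_capita",
]

MONTHLY_COLUMNS = ["city_id", "year", "month", "concentration"]


@dataclass(frozen=True)
class CityYearRecord:
    """One city in one year: exposure and socioeconomic covariates."""

    city_id: str
    year: int
    concentration: float  # annual mean PM2.5, µg/m³
    population: float  # exposed persons
    income: float  # per-capita disposable income, USD/yr
    gdp_per_capita: float  # per-capita GDP, USD/yr

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValidationError(
                f"{self.city_id}/{self.year}: concentration must be >= 0"
            )
        if self.population < 0:
            raise ValidationError(
                f"{self.city_id}/{self.year}: population must be >= 0"
            )
        if self.income <= 0:
            raise ValidationError(f"{self.city_id}/{self.year}: income must be > 0")
        if self.gdp_per_capita <= 0:
            raise ValidationError(
                f"{self.city_id}/{self.year}: gdp_per_capita must be > 0"
            )


class CityPanel:
    """Validated collection of city-year records, backed by a DataFrame."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in PANEL_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"panel missing column(s) {missing}")
        frame = frame.loc[:, PANEL_COLUMNS].copy()
        for col in ("concentration", "population", "income", "gdp_per_capita"):
            values = pd.to_numeric(frame[col], errors="coerce")
            bad = frame.index[values.isna() & frame[col].notna()]
            if len(bad):
                raise ValidationError(
                    f"non-numeric {col} at row(s) {list(bad[:5])}"
                )
            if values.isna().any():
                raise ValidationError(f"missing {col} value(s) — no partial rows")
            frame[col] = values.astype(float)
        frame["year"] = pd.to_numeric(frame["year"], errors="raise").astype(int)
        frame["city_id"] = frame["city_id"].astype(str)

        dup = frame.duplicated(subset=["city_id", "year"])
        if dup.any():
            keys = frame.loc[dup, ["city_id", "year"]].itertuples(index=False)
            raise ValidationError(
                f"duplicate (city_id, year) keys: {[tuple(k) for k in keys][:5]}"
            )
        if (frame["concentration"] < 0).any():
            raise ValidationError("concentration must be >= 0")
        if (frame["population"] < 0).any():
            raise ValidationError("population must be >= 0")
        if (frame["income"] <= 0).any() or (frame["gdp_per_capita"] <= 0).any():
            raise ValidationError("income and gdp_per_capita must be > 0")

        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[CityYearRecord]) -> "CityPanel":
        rows = [
            (r.city_id, r.year, r.concentration, r.population, r.income, r.gdp_per_capita)
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=PANEL_COLUMNS))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique().tolist())

    @property
    def cities(self) -> list[str]:
        return sorted(self.frame["city_id"].unique().tolist())

    def records(self) -> list[CityYearRecord]:
        return [
            CityYearRecord(
                city_id=row.city_id,
                year=int(row.year),
                concentration=float(row.concentration),
                population=float(row.population),
                income=float(row.income),
                gdp_per_capita=float(row.gdp_per_capita),
            )
            for row in self.frame.itertuples(index=False)
        ]

    def gdp_total_by_year(self) -> pd.Series:
        """Total GDP (USD) per year: Σ_cities population × per-capita GDP."""
        f = self.frame
        return (f["population"] * f["gdp_per_capita"]).groupby(f["year"]).sum()

    def national_mean_concentration(self) -> pd.Series:
        """Unweighted cross-city mean concentration per year."""
        return self.frame.groupby("year")["concentration"].mean()


def read_panel(path: str | Path) -> CityPanel:
    """Read and validate a panel CSV with the documented header."""
    frame = pd.read_csv(path, dtype={"city_id": str})
    return CityPanel(frame)


def write_panel(panel: CityPanel, path: str | Path) -> None:
    """Write a panel to CSV (inverse of :func:`read_panel` on valid panels)."""
    panel.frame.to_csv(path, index=False)


def annualize_concentrations(
    monthly: pd.DataFrame, min_months: int = 9
) -> pd.DataFrame:
    """Collapse monthly city concentrations to annual arithmetic means.

    Parameters
    ----------
    monthly
        Long table with columns ``city_id, year, month, concentration``.
        Missing months are simply absent (or NaN) rows.
    min_months
        City-years with fewer available months are flagged ``complete=False``
        (annual mean still computed over available months). Default 9 of 12,
        a common air-quality completeness screen.

    Returns
    -------
    DataFrame with columns ``city_id, year, concentration, n_months, complete``.

    Raises
    ------
    MissingDataError
        If a present city-year has zero non-missing monthly values.
    """
    missing = [c for c in MONTHLY_COLUMNS if c not in monthly.columns]
    if missing:
        raise SchemaError(f"monthly table missing column(s) {missing}")
    if (pd.to_numeric(monthly["concentration"], errors="coerce").dropna() < 0).any():
        raise ValidationError("monthly concentrations must be >= 0")

    grouped = monthly.groupby(["city_id", "year"])["concentration"]
    out = grouped.agg(concentration="mean", n_months="count").reset_index()
    empty = out[out["n_months"] == 0]
    if len(empty):
        keys = list(empty[["city_id", "year"]].itertuples(index=False, name=None))
        raise MissingDataError(f"no monthly values for city-year(s) {keys[:5]}")
    out["n_months"] = out["n_months"].astype(int)
    out["complete"] = out["n_months"] >= min_months
    return out
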