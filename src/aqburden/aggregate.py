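"""City and national rollups, summary ratios, temporal change, rankings.

The total economic loss in a scope-year is

    EC_total = EC_mortality + EC_morbidity,

where EC_mortality counts *only* the all-cause mortality endpoint:
cause-specific mortalities (cardiovascular, respiratory, lung cancer)
overlap with all-cause deaths, so they are reported per endpoint but
excluded from totals. Likewise the affected population sums attributable
cases over the five non-overlapping endpoints (all-cause mortality plus
the four morbidity endpoints).

Money is carried in nominal USD throughout; the hundred-million-USD
report scale is applied only when rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .endpoints import EndpointSet
from .errors import AggregationError
from .valuation import BOUNDS

__all__ = [
    "LossResult",
    "rollup",
    "losses_to_frame",
    "summary_stats",
    "yoy_changes",
    "mean_annual_decline",
    "rank_cities",
    "HUNDRED_MILLION",
]

HUNDRED_MILLION = 1e8  # report scale for money columns


@dataclass
class LossResult:
    """Aggregated burden for one scope (a city or the nation) in one year."""

    scope: str  # city_id, or "national"
    year: int
    bound: str
    ec_by_endpoint: dict[str, float]  # USD, includes cause-specific mortality
    ec_mortality: float  # USD, all-cause endpoint only
    ec_morbidity: float  # USD, the four morbidity endpoints
    affected_population: float  # cases over the non-overlapping endpoint set
    tel_gdp_ratio: float | None = None  # EC_total / total GDP, when GDP known

    @property
    def ec_total(self) -> float:
        return self.ec_mortality + self.ec_morbidity


def rollup(
    losses: pd.DataFrame,
    endpoints: EndpointSet,
    gdp_total_by_year: pd.Series | None = None,
) -> tuple[list[LossResult], list[LossResult]]:
    """Aggregate per-row losses to city-year and national-year results.

    Parameters
    ----------
    losses
        Output of :func:`aqburden.valuation.loss_table` (single bound,
        or several bounds concatenated).
    endpoints
        Defines which endpoints enter totals and the affected population.
    gdp_total_by_year
        Optional year-indexed total GDP (USD) for TEL/GDP ratios on
        national results.

    Returns
    -------
    (city_results, national_results)
        National values are exact sums of city values per endpoint.

    Raises
    ------
    AggregationError
        If any city-year lacks a loss row for some endpoint.
    """
    expected = set(endpoints.names)
    city_results: list[LossResult] = []
    national_acc: dict[tuple[int, str], dict] = {}

    affected_names = set(endpoints.affected_total_names)
    all_cause = endpoints.all_cause.name
    morbidity_names = {e.name for e in endpoints if not e.is_mortality}

    for (city, year, bound), grp in losses.groupby(
        ["city_id", "year", "bound"], sort=True
    ):
        present = set(grp["endpoint"])
        if present != expected:
            raise AggregationError(
                f"city {city!r} year {year} bound {bound}: missing endpoint(s) "
                f"{sorted(expected - present)}"
            )
        ec = dict(zip(grp["endpoint"], grp["economic_loss"]))
        cases = dict(zip(grp["endpoint"], grp["attributable_cases"]))
        result = LossResult(
            scope=str(city),
            year=int(year),
            bound=bound,
            ec_by_endpoint=ec,
            ec_mortality=ec[all_cause],
            ec_morbidity=sum(ec[n] for n in morbidity_names),
            affected_population=sum(cases[n] for n in affected_names),
        )
        city_results.append(result)

        key = (int(year), bound)
        acc = national_acc.setdefault(
            key,
            {
                "ec": {n: 0.0 for n in expected},
                "mort": 0.0,
                "morb": 0.0,
                "affected": 0.0,
            },
        )
        for n in expected:
            acc["ec"][n] += ec[n]
        acc["mort"] += result.ec_mortality
        acc["morb"] += result.ec_morbidity
        acc["affected"] += result.affected_population

    national_results = []
    for (year, bound), acc in sorted(national_acc.items()):
        ratio = None
        if gdp_total_by_year is not None and year in gdp_total_by_year.index:
            total = acc["mort"] + acc["morb"]
            ratio = total / float(gdp_total_by_year.loc[year])
        national_results.append(
            LossResult(
                scope="national",
                year=year,
                bound=bound,
                ec_by_endpoint=acc["ec"],
                ec_mortality=acc["mort"],
                ec_morbidity=acc["morb"],
                affected_population=acc["affected"],
                tel_gdp_ratio=ratio,
            )
        )
    return city_results, national_results


def losses_to_frame(results: list[LossResult]) -> pd.DataFrame:
    """Tabulate LossResults: one row per scope-year-bound, money in USD."""
    rows = []
    for r in results:
        row = {
            "scope": r.scope,
            "year": r.year,
            "bound": r.bound,
            "ec_mortality": r.ec_mortality,
            "ec_morbidity": r.ec_morbidity,
            "ec_total": r.ec_total,
            "affected_population": r.affected_population,
            "tel_gdp_ratio": r.tel_gdp_ratio,
        }
        for name, value in r.ec_by_endpoint.items():
            row[f"ec__{name}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def summary_stats(
    national: list[LossResult],
    gdp_total_by_year: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-year headline ratios across the two bounds.

    Emits, per year: total loss per bound (USD), the AHC/VSL total ratio,
    the mortality share of the total per bound, and (when GDP is
    supplied or carried on the results) TEL/GDP per bound. Ratios are
    computed from unrounded totals; round only when rendering.
    """
    by_year: dict[int, dict[str, LossResult]] = {}
    for r in national:
        by_year.setdefault(r.year, {})[r.bound] = r

    rows = []
    for year in sorted(by_year):
        pair = by_year[year]
        if set(pair) != set(BOUNDS):
            raise AggregationError(
                f"year {year}: need both bounds for summary, have {sorted(pair)}"
            )
        lo, hi = pair["lower_AHC"], pair["upper_VSL"]
        row = {
            "year": year,
            "tel_lower_AHC": lo.ec_total,
            "tel_upper_VSL": hi.ec_total,
            "ahc_vsl_ratio": lo.ec_total / hi.ec_total if hi.ec_total else np.nan,
            "mortality_share_lower_AHC": (
                lo.ec_mortality / lo.ec_total if lo.ec_total else np.nan
            ),
            "mortality_share_upper_VSL": (
                hi.ec_mortality / hi.ec_total if hi.ec_total else np.nan
            ),
        }
        for bound_name, r in (("lower_AHC", lo), ("upper_VSL", hi)):
            ratio = r.tel_gdp_ratio
            if ratio is None and gdp_total_by_year is not None:
                if year in gdp_total_by_year.index:
                    ratio = r.ec_total / float(gdp_total_by_year.loc[year])
            row[f"tel_gdp_ratio_{bound_name}"] = ratio
        rows.append(row)
    return pd.DataFrame(rows)


def yoy_changes(
    values: pd.DataFrame,
    value_col: str,
    group_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Year-over-year absolute and percent changes per group.

    ``values`` needs a ``year`` column plus ``value_col`` (and any group
    keys). Percent change is signed: negative means decline. A
    single-year input yields an empty table.
    """
    keys = list(group_cols)
    out = []
    grouped = values.groupby(keys) if keys else [((), values)]
    for key, grp in grouped:
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        vals = grp[value_col].to_numpy(dtype=float)
        for i in range(1, len(vals)):
            prev, cur = vals[i - 1], vals[i]
            out.append(
                dict(
                    zip(keys, key if isinstance(key, tuple) else (key,)),
                    year_from=int(years[i - 1]),
                    year_to=int(years[i]),
                    absolute_change=cur - prev,
                    percent_change=100.0 * (cur - prev) / prev if prev else np.nan,
                )
            )
    cols = keys + ["year_from", "year_to", "absolute_change", "percent_change"]
    return pd.DataFrame(out, columns=cols)


def _truncate(x: float, decimals: int) -> float:
    factor = 10.0**decimals
    return math.trunc(x * factor) / factor


def mean_annual_decline(
    series: pd.Series | list[float],
    truncate_decimals: int | None = 1,
) -> float:
    """Mean annual percent decline over a year-ordered series.

    Computed as the arithmetic mean of the year-over-year percent
    declines (positive = decline), truncated — not rounded — to
    ``truncate_decimals`` places for reporting; pass ``None`` for the
    unrounded value. A declining national mortality series such as
    278,444 → 238,622 → 216,164 gives declines of 14.3016% and 9.4116%,
    hence a mean annual decline of 11.8%.
    """
    vals = np.asarray(series, dtype=float)
    if len(vals) < 2:
        raise AggregationError("need at least two years for a decline rate")
    declines = 100.0 * (vals[:-1] - vals[1:]) / vals[:-1]
    mean = float(np.mean(declines))
    if truncate_decimals is None:
        return mean
    return _truncate(mean, truncate_decimals)


def rank_cities(
    city_results: list[LossResult],
    years: list[int] | None = None,
    bound: str = "upper_VSL",
) -> pd.DataFrame:
    """Cities ordered by summed total loss over a year range, descending.

    Ties are broken by lexicographic city id, so the ranking is a pure
    function of the values (invariant to input order). Returns columns
    ``rank, city_id, total_loss``.
    """
    totals: dict[str, float] = {}
    for r in city_results:
        if r.bound != bound:
            continue
        if years is not None and r.year not in years:
            continue
        totals[r.scope] = totals.get(r.scope, 0.0) + r.ec_total
    ordered = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [
            {"rank": i + 1, "city_id": city, "total_loss": value}
            for i, (city, value) in enumerate(ordered)
        ],
        columns=["rank", "city_id", "total_loss"],
    )
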