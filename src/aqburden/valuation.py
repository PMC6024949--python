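"""Monetary valuation of attributable cases.

Mortality is valued under two bounds:

* **Upper bound — VSL benefit transfer.** The value of a statistical life
  in city j scales a reference VSL by relative income:
  ``VSL_j = VSL_0 * (Income_j / Income_0)^elasticity``.
* **Lower bound — amended human capital (AHC).** A premature death costs
  the discounted stream of per-capita GDP over the life-years lost:
  ``HCL_j = GDP_j * sum_{y=1..t} ((1+a)/(1+r))^y``.

Morbidity is valued by cost of illness: either a fixed USD cost per case
(medical + hospitalization + productivity loss), or a disability-weighted
fraction of the city VSL (chronic bronchitis, weight 0.055). Morbidity
costs are identical under both bounds; only mortality distinguishes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .endpoints import EndpointSet, HealthEndpoint
from .errors import ConfigError, PairingError, ValidationError
from .exposure import AssessmentParams, ImpactResult
from .panel import CityPanel, CityYearRecord

__all__ = [
    "BOUNDS",
    "UnitCost",
    "vsl",
    "ahc_multiplier",
    "ahc",
    "unit_cost",
    "unit_cost_table",
    "economic_loss",
    "loss_table",
]

BOUNDS = ("lower_AHC", "upper_VSL")

COST_COLUMNS = ["city_id", "year", "endpoint", "bound", "cost_per_case", "basis"]


@dataclass(frozen=True)
class UnitCost:
    """USD cost of one case of one endpoint in one city-year, per bound."""

    city_id: str
    year: int
    endpoint_name: str
    bound: str
    cost_per_case: float
    basis: str  # vsl | ahc | coi_fixed | vsl_fraction


def vsl(income, params: AssessmentParams):
    """City VSL (USD) by income benefit transfer. Accepts scalars or arrays."""
    if np.any(np.asarray(income, dtype=float) <= 0):
        raise ValidationError("income must be > 0 for VSL transfer")
    out = params.vsl_reference * (
        np.asarray(income, dtype=float) / params.income_reference
    ) ** params.elasticity
    return float(out) if out.ndim == 0 else out


def ahc_multiplier(gdp_growth: float, discount_rate: float, life_years: int) -> float:
    """Discount-sum multiplier sum_{y=1..t} ((1+a)/(1+r))^y, by direct summation."""
    if life_years < 0:
        raise ValidationError("life_years must be >= 0")
    if discount_rate <= -1:
        raise ValidationError("discount rate must exceed -1")
    q = (1.0 + gdp_growth) / (1.0 + discount_rate)
    return float(sum(q**y for y in range(1, int(life_years) + 1)))


def ahc(gdp_per_capita, params: AssessmentParams):
    """Discounted human-capital value of a premature death (USD)."""
    if np.any(np.asarray(gdp_per_capita, dtype=float) <= 0):
        raise ValidationError("gdp_per_capita must be > 0 for AHC valuation")
    mult = ahc_multiplier(
        params.gdp_growth, params.discount_rate, params.life_years_lost
    )
    out = np.asarray(gdp_per_capita, dtype=float) * mult
    return float(out) if out.ndim == 0 else out


def unit_cost(
    record: CityYearRecord,
    endpoint: HealthEndpoint,
    bound: str,
    params: AssessmentParams,
) -> UnitCost:
    """Per-case cost of an endpoint in one city-year under one bound.

    Mortality endpoints switch between the city VSL (upper bound) and the
    AHC value (lower bound). Cost-of-illness and VSL-fraction morbidity
    costs do not depend on the bound.
    """
    if bound not in BOUNDS:
        raise ConfigError(f"unknown bound {bound!r}; expected one of {BOUNDS}")
    if endpoint.cost_rule == "mortality_bound":
        if bound == "upper_VSL":
            value, basis = vsl(record.income, params), "vsl"
        else:
            value, basis = ahc(record.gdp_per_capita, params), "ahc"
    elif endpoint.cost_rule == "per_case_fixed":
        value, basis = endpoint.unit_cost, "coi_fixed"
    elif endpoint.cost_rule == "vsl_fraction":
        value, basis = endpoint.vsl_weight * vsl(record.income, params), "vsl_fraction"
    else:  # pragma: no cover - rejected at endpoint construction
        raise ConfigError(f"unknown cost_rule {endpoint.cost_rule!r}")
    return UnitCost(
        city_id=record.city_id,
        year=record.year,
        endpoint_name=endpoint.name,
        bound=bound,
        cost_per_case=float(value),
        basis=basis,
    )


def unit_cost_table(
    panel: CityPanel,
    endpoints: EndpointSet,
    bound: str,
    params: AssessmentParams,
    cost_scale: float = 1.0,
) -> pd.DataFrame:
    """Vectorized per-case costs for every (city, year, endpoint) under a bound.

    ``cost_scale`` is a multiplicative perturbation applied to VSL-based
    and cost-of-illness values (used by the Monte Carlo propagation);
    AHC values are never scaled, since their input (per-capita GDP) is
    treated as known.
    """
    if bound not in BOUNDS:
        raise ConfigError(f"unknown bound {bound!r}; expected one of {BOUNDS}")
    f = panel.frame
    city_vsl = vsl(f["income"].to_numpy(), params)
    city_ahc = ahc(f["gdp_per_capita"].to_numpy(), params)

    blocks = []
    for e in endpoints:
        if e.cost_rule == "mortality_bound":
            if bound == "upper_VSL":
                cost, basis = city_vsl * cost_scale, "vsl"
            else:
                cost, basis = city_ahc, "ahc"
        elif e.cost_rule == "per_case_fixed":
            cost, basis = np.full(len(f), e.unit_cost * cost_scale), "coi_fixed"
        else:
            cost, basis = e.vsl_weight * city_vsl * cost_scale, "vsl_fraction"
        blocks.append(
            pd.DataFrame(
                {
                    "city_id": f["city_id"].to_numpy(),
                    "year": f["year"].to_numpy(),
                    "endpoint": e.name,
                    "bound": bound,
                    "cost_per_case": cost,
                    "basis": basis,
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)[COST_COLUMNS]


def economic_loss(impact: ImpactResult, cost: UnitCost) -> float:
    """EC = HI * cost-per-case for one matched (city, year, endpoint)."""
    if (impact.city_id, impact.year, impact.endpoint_name) != (
        cost.city_id,
        cost.year,
        cost.endpoint_name,
    ):
        raise PairingError(
            f"impact key ({impact.city_id}, {impact.year}, {impact.endpoint_name}) "
            f"does not match cost key ({cost.city_id}, {cost.year}, "
            f"{cost.endpoint_name})"
        )
    return impact.attributable_cases * cost.cost_per_case


def loss_table(impacts: pd.DataFrame, costs: pd.DataFrame) -> pd.DataFrame:
    """Join impacts with unit costs and compute per-row economic losses.

    Returns columns ``city_id, year, endpoint, bound, attributable_cases,
    cost_per_case, economic_loss``. Every impact row must find exactly one
    cost row (same bound table); unmatched keys raise
    :class:`~aqburden.errors.PairingError`.
    """
    merged = impacts.merge(
        costs, on=["city_id", "year", "endpoint"], how="left", validate="one_to_one"
    )
    if merged["cost_per_case"].isna().any():
        gaps = merged.loc[
            merged["cost_per_case"].isna(), ["city_id", "year", "endpoint"]
        ]
        raise PairingError(
            "no unit cost for impact key(s) "
            f"{list(gaps.itertuples(index=False, name=None))[:5]}"
        )
    merged["economic_loss"] = merged["attributable_cases"] * merged["cost_per_case"]
    return merged[
        [
            "city_id",
            "year",
            "endpoint",
            "bound",
            "attributable_cases",
            "cost_per_case",
            "economic_loss",
        ]
    ]
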