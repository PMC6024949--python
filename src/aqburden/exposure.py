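"""Log-linear exposure-response model: concentrations to attributable cases.

Disease and death counts are rare-event (Poisson) outcomes, so the
incidence of endpoint i at annual PM2.5 concentration C follows the
log-linear relative-risk form

    E_i(C) = E_0i * exp(beta_i * (C - C0)),

with C0 the baseline (counterfactual) concentration, 10 µg/m³ by default
per the WHO air-quality guideline. The attributable burden in city j is
the excess over baseline scaled by the exposed population:

    HI_ij = P_j * E_0i * (exp(beta_i * (C - C0)) - 1).

Concentrations below C0 are clamped to zero excess (flagged, not an
error): the model quantifies burden above the guideline, not hypothetical
benefits below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .endpoints import EndpointSet, HealthEndpoint
from .errors import ValidationError
from .panel import CityPanel, CityYearRecord

__all__ = [
    "AssessmentParams",
    "ImpactResult",
    "incidence_at",
    "attributable_cases",
    "impact_table",
    "EXPONENT_CAP",
]

#: Guard against mis-scaled coefficients (beta is per-µg/m³, typically
#: well below 0.1); |beta * (C - C0)| above this cap raises instead of
#: silently overflowing.
EXPONENT_CAP = 50.0

IMPACT_COLUMNS = [
    "city_id",
    "year",
    "endpoint",
    "attributable_cases",
    "incidence_at_C",
    "concentration_used",
    "clamped",
]


@dataclass(frozen=True)
class AssessmentParams:
    """Global constants of the assessment.

    Attributes
    ----------
    baseline_concentration
        C0, the counterfactual PM2.5 level (µg/m³); WHO guideline 10.
    vsl_reference, income_reference
        VSL_0 (USD) and Income_0 (USD/yr): the benefit-transfer anchor
        pair — the value of a statistical life at the reference income.
    elasticity
        Income elasticity of the VSL transfer (dimensionless).
    gdp_growth, discount_rate
        a and r: per-capita GDP growth and social discount rates used in
        the discounted human-capital (AHC) valuation.
    life_years_lost
        t, average life-years lost per premature death (years).
    """

    baseline_concentration: float = 10.0
    vsl_reference: float = 248_172.0
    income_reference: float = 1_939.0
    elasticity: float = 0.8
    gdp_growth: float = 0.07
    discount_rate: float = 0.08
    life_years_lost: int = 10

    def __post_init__(self) -> None:
        if self.baseline_concentration < 0:
            raise ValidationError("baseline_concentration must be >= 0")
        if self.vsl_reference <= 0 or self.income_reference <= 0:
            raise ValidationError("VSL and income references must be > 0")
        if self.elasticity < 0:
            raise ValidationError("elasticity must be >= 0")
        if self.life_years_lost < 0 or self.life_years_lost != int(self.life_years_lost):
            raise ValidationError("life_years_lost must be a non-negative integer")
        if self.discount_rate <= -1 or self.gdp_growth <= -1:
            raise ValidationError("rates must exceed -1")


@dataclass(frozen=True)
class ImpactResult:
    """Attributable burden of one endpoint in one city-year."""

    city_id: str
    year: int
    endpoint_name: str
    incidence_at_C: float  # E_i(C), annual cases per person
    attributable_cases: float  # HI_ij, continuous (rounded only in reports)
    concentration_used: float  # µg/m³ after clamping
    clamped: bool


def _checked_exponent(beta, delta):
    x = np.asarray(beta, dtype=float) * np.asarray(delta, dtype=float)
    if np.any(np.abs(x) > EXPONENT_CAP):
        raise ValidationError(
            f"|beta * (C - C0)| exceeds {EXPONENT_CAP}; check coefficient units "
            f"(max exponent {float(np.max(np.abs(x))):.3g})"
        )
    return x


def incidence_at(concentration, baseline_concentration, beta, baseline_incidence):
    """Endpoint incidence at concentration C: E0 * exp(beta * (C - C0)).

    Accepts scalars or numpy arrays (broadcasting). No clamping is applied
    here; callers decide how to treat C < C0.
    """
    if np.any(np.asarray(baseline_incidence, dtype=float) < 0):
        raise ValidationError("baseline_incidence must be >= 0")
    x = _checked_exponent(beta, np.asarray(concentration, dtype=float) - baseline_concentration)
    out = np.asarray(baseline_incidence, dtype=float) * np.exp(x)
    return float(out) if np.isscalar(concentration) and out.ndim == 0 else out


def attributable_cases(
    record: CityYearRecord,
    endpoint: HealthEndpoint,
    params: AssessmentParams,
) -> ImpactResult:
    """Excess cases of one endpoint in one city-year (scalar path).

    Implements HI = P * E0 * (exp(beta * (C - C0)) - 1), clamping C at C0
    from below; the clamp is recorded on the result, not raised.
    """
    c0 = params.baseline_concentration
    c = record.concentration
    clamped = c < c0
    c_used = max(c, c0)
    e_at_c = incidence_at(c_used, c0, endpoint.beta, endpoint.baseline_incidence)
    x = _checked_exponent(endpoint.beta, c_used - c0)
    cases = record.population * endpoint.baseline_incidence * float(np.expm1(x))
    return ImpactResult(
        city_id=record.city_id,
        year=record.year,
        endpoint_name=endpoint.name,
        incidence_at_C=float(e_at_c),
        attributable_cases=cases,
        concentration_used=c_used,
        clamped=bool(clamped),
    )


def impact_table(
    panel: CityPanel,
    endpoints: EndpointSet,
    params: AssessmentParams,
) -> pd.DataFrame:
    """Attributable cases for every (city, year, endpoint), vectorized.

    Returns a DataFrame with columns
    ``city_id, year, endpoint, attributable_cases, incidence_at_C,
    concentration_used, clamped`` — one row per panel record per endpoint,
    ordered panel-major. Agrees with the scalar
    :func:`attributable_cases` loop to floating-point accuracy.
    """
    f = panel.frame
    c0 = params.baseline_concentration
    c_used = np.maximum(f["concentration"].to_numpy(), c0)
    clamped = f["concentration"].to_numpy() < c0
    pop = f["population"].to_numpy()

    blocks = []
    for e in endpoints:
        x = _checked_exponent(e.beta, c_used - c0)
        cases = pop * e.baseline_incidence * np.expm1(x)
        blocks.append(
            pd.DataFrame(
                {
                    "city_id": f["city_id"].to_numpy(),
                    "year": f["year"].to_numpy(),
                    "endpoint": e.name,
                    "attributable_cases": cases,
                    "incidence_at_C": e.baseline_incidence * np.exp(x),
                    "concentration_used": c_used,
                    "clamped": clamped,
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)[IMPACT_COLUMNS]


def national_impacts(impacts: pd.DataFrame) -> pd.DataFrame:
    """Sum attributable cases over cities: one row per (year, endpoint)."""
    return (
        impacts.groupby(["year", "endpoint"], as_index=False)["attributable_cases"]
        .sum()
    )
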