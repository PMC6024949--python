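"""Health-endpoint taxonomy and coefficient-table I/O.

A :class:`HealthEndpoint` bundles everything the pipeline needs to know
about one disease or death category: the exposure-response coefficient
``beta`` (per µg/m³), the baseline incidence ``E0`` (annual cases per
person at the baseline concentration), and how one case is monetized.

Three cost rules exist:

``mortality_bound``
    The endpoint is a death category; a case is valued by the value of a
    statistical life (upper bound) or discounted human capital (lower
    bound), computed city-by-city at valuation time.
``per_case_fixed``
    Cost-of-illness: a fixed USD amount per case, identical under both
    bounds (medical, hospitalization, and productivity costs).
``vsl_fraction``
    A disability-weighted fraction of the city VSL per case, identical
    under both bounds (used for chronic bronchitis).

Double counting: cause-specific mortality (cardiovascular, respiratory,
lung cancer) overlaps with all-cause mortality, so only the all-cause
endpoint and the four morbidity endpoints carry
``in_affected_total=True`` and enter affected-population and total-loss
rollups. Cause-specific endpoints are still computed and reported.

The packaged default coefficient table carries *illustrative* beta/E0
values in the ranges typical of the Chinese PM2.5 health-impact
literature; studies with access to a pooled meta-analysis should supply
their own table via :func:`load_endpoint_set`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .errors import SchemaError, ValidationError

__all__ = [
    "HealthEndpoint",
    "EndpointSet",
    "load_endpoint_set",
    "write_endpoint_set",
    "default_endpoint_set",
    "validate_affected_partition",
    "AFFECTED_TOTAL_ENDPOINTS",
]

CATEGORIES = ("mortality", "morbidity")
DURATIONS = ("chronic", "acute")
COST_RULES = ("per_case_fixed", "vsl_fraction", "mortality_bound")

CONFIG_COLUMNS = [
    "name",
    "category",
    "duration",
    "beta",
    "baseline_incidence",
    "cost_rule",
    "unit_cost",
    "vsl_weight",
    "in_affected_total",
]

#: The five non-overlapping endpoints whose attributable cases sum to the
#: affected population (all-cause deaths plus the four morbidity endpoints).
AFFECTED_TOTAL_ENDPOINTS = frozenset(
    {
        "all_cause_mortality",
        "cardiovascular_hospitalization",
        "chronic_bronchitis",
        "acute_bronchitis",
        "asthma_attack",
    }
)

ALL_CAUSE_NAME = "all_cause_mortality"


@dataclass(frozen=True)
class HealthEndpoint:
    """One health endpoint with its exposure-response and cost parameters."""

    name: str
    category: str
    duration: str
    beta: float
    baseline_incidence: float
    cost_rule: str
    unit_cost: float = 0.0
    vsl_weight: float = 0.0
    in_affected_total: bool = True

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"endpoint {self.name!r}: category must be one of {CATEGORIES}, "
                f"got {self.category!r}"
            )
        if self.duration not in DURATIONS:
            raise ValidationError(
                f"endpoint {self.name!r}: duration must be one of {DURATIONS}, "
                f"got {self.duration!r}"
            )
        if self.cost_rule not in COST_RULES:
            raise ValidationError(
                f"endpoint {self.name!r}: unknown cost_rule {self.cost_rule!r}"
            )
        if not math.isfinite(self.beta):
            raise ValidationError(f"endpoint {self.name!r}: beta must be finite")
        if self.baseline_incidence < 0:
            raise ValidationError(
                f"endpoint {self.name!r}: baseline_incidence must be >= 0, "
                f"got {self.baseline_incidence}"
            )
        if self.unit_cost < 0:
            raise ValidationError(
                f"endpoint {self.name!r}: unit_cost must be >= 0, got {self.unit_cost}"
            )
        if not 0.0 <= self.vsl_weight <= 1.0:
            raise ValidationError(
                f"endpoint {self.name!r}: vsl_weight must lie in [0, 1], "
                f"got {self.vsl_weight}"
            )

    @property
    def is_mortality(self) -> bool:
        return self.category == "mortality"

    @property
    def is_all_cause(self) -> bool:
        return self.is_mortality and self.name == ALL_CAUSE_NAME


@dataclass
class EndpointSet:
    """Ordered, name-unique collection of health endpoints."""

    endpoints: list[HealthEndpoint]
    provenance: str = ""
    _by_name: dict[str, HealthEndpoint] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        names = [e.name for e in self.endpoints]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate endpoint names: {sorted(dupes)}")
        all_cause = [e for e in self.endpoints if e.is_all_cause]
        if len(all_cause) != 1:
            raise ValidationError(
                "an EndpointSet must contain exactly one all-cause mortality "
                f"endpoint named {ALL_CAUSE_NAME!r}; found {len(all_cause)}"
            )
        self._by_name = {e.name: e for e in self.endpoints}

    def __iter__(self) -> Iterator[HealthEndpoint]:
        return iter(self.endpoints)

    def __len__(self) -> int:
        return len(self.endpoints)

    def __getitem__(self, name: str) -> HealthEndpoint:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.endpoints]

    @property
    def all_cause(self) -> HealthEndpoint:
        return next(e for e in self.endpoints if e.is_all_cause)

    @property
    def affected_total_names(self) -> list[str]:
        """Names of endpoints counted in the affected-population sum."""
        return [e.name for e in self.endpoints if e.in_affected_total]

    @property
    def total_loss_names(self) -> list[str]:
        """Endpoints entering the total economic loss: all-cause + morbidity."""
        return [
            e.name for e in self.endpoints if e.is_all_cause or not e.is_mortality
        ]


def _parse_bool(raw: str, *, row: int) -> bool:
    v = raw.strip().lower()
    if v in {"true", "1", "yes"}:
        return True
    if v in {"false", "0", "no"}:
        return False
    raise ValidationError(f"row {row}: cannot parse boolean from {raw!r}")


def _parse_float(raw: str, column: str, *, row: int) -> float:
    try:
        return float(raw)
    except ValueError as exc:
        raise ValidationError(
            f"row {row}: non-numeric {column} value {raw!r}"
        ) from exc


def load_endpoint_set(path: str | Path, provenance: str | None = None) -> EndpointSet:
    """Load and validate an endpoint coefficient table from CSV.

    The CSV header must contain the columns
    ``name,category,duration,beta,baseline_incidence,cost_rule,unit_cost,
    vsl_weight,in_affected_total``. Invariant violations raise
    :class:`~aqburden.errors.ValidationError` naming the offending row;
    a missing column raises :class:`~aqburden.errors.SchemaError`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        missing = [c for c in CONFIG_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        endpoints = []
        for i, row in enumerate(reader, start=1):
            endpoints.append(
                HealthEndpoint(
                    name=row["name"].strip(),
                    category=row["category"].strip(),
                    duration=row["duration"].strip(),
                    beta=_parse_float(row["beta"], "beta", row=i),
                    baseline_incidence=_parse_float(
                        row["baseline_incidence"], "baseline_incidence", row=i
                    ),
                    cost_rule=row["cost_rule"].strip(),
                    unit_cost=_parse_float(row["unit_cost"], "unit_cost", row=i),
                    vsl_weight=_parse_float(row["vsl_weight"], "vsl_weight", row=i),
                    in_affected_total=_parse_bool(row["in_affected_total"], row=i),
                )
            )
    return EndpointSet(endpoints, provenance=provenance or str(path))


def write_endpoint_set(endpoint_set: EndpointSet, path: str | Path) -> None:
    """Write an endpoint set back to the documented CSV schema."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CONFIG_COLUMNS)
        for e in endpoint_set:
            writer.writerow(
                [
                    e.name,
                    e.category,
                    e.duration,
                    repr(e.beta),
                    repr(e.baseline_incidence),
                    e.cost_rule,
                    repr(e.unit_cost),
                    repr(e.vsl_weight),
                    "true" if e.in_affected_total else "false",
                ]
            )


def default_endpoint_set() -> EndpointSet:
    """The packaged default taxonomy: 4 mortality + 4 morbidity endpoints.

    beta / baseline-incidence values are illustrative placeholders in
    literature-typical ranges, not pooled estimates; replace them with
    study-specific coefficients for substantive use.
    """
    ref = resources.files("aqburden").joinpath("data/endpoints_default.csv")
    with resources.as_file(ref) as path:
        return load_endpoint_set(
            path, provenance="packaged default (illustrative coefficients)"
        )


def validate_affected_partition(endpoint_set: EndpointSet) -> bool:
    """Check that the affected-population partition is the canonical one.

    Returns True iff exactly the five endpoints {all-cause mortality,
    cardiovascular hospitalization, chronic bronchitis, acute bronchitis,
    asthma attack} are flagged ``in_affected_total``. Order-independent;
    never raises — misflagged sets return False.
    """
    flagged = set(endpoint_set.affected_total_names)
    return flagged == set(AFFECTED_TOTAL_ENDPOINTS)


def affected_partition_diagnostic(endpoint_set: EndpointSet) -> str:
    """Human-readable account of which endpoints are misflagged."""
    flagged = set(endpoint_set.affected_total_names)
    extra = sorted(flagged - AFFECTED_TOTAL_ENDPOINTS)
    absent = sorted(AFFECTED_TOTAL_ENDPOINTS - flagged)
    if not extra and not absent:
        return "partition valid"
    parts = []
    if extra:
        parts.append(f"unexpectedly flagged: {extra}")
    if absent:
        parts.append(f"missing from partition: {absent}")
    return "; ".join(parts)
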