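"""Monte Carlo propagation of input uncertainty to economic losses.

Three input quantities carry uncertainty: the exposure concentrations,
the exposure-response coefficients beta, and the per-case costs. Each is
perturbed by a multiplicative factor drawn from a configurable
distribution (point, normal, lognormal, or triangular, optionally
truncated below); a point distribution at 1 switches a quantity off. For
every draw the full deterministic pipeline — exposure-response, valuation,
aggregation — is re-run with the perturbed inputs and the national total
economic loss recorded per bound.

The AHC per-death value is never perturbed: it derives from per-capita
GDP, whose uncertainty is unknown, so the lower-bound mortality valuation
is held fixed (cost factors apply to VSL-based and cost-of-illness values
only). Concentration and beta uncertainty still reach the lower bound
through the attributable cases.

Outputs per scope/bound: the sample mean, a percentile 95% confidence
interval, the relative CI half-width (ci_high - ci_low) / (2 * mean), and
the fraction of draws within ±5% of the sample mean. The headline
uncertainty percentage is the mass *outside* that ±5% acceptable-error
band, ``100 * (1 - prob_within_5pct)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .endpoints import EndpointSet
from .errors import DistributionError, ValidationError
from .exposure import EXPONENT_CAP, AssessmentParams
from .panel import CityPanel
from .valuation import BOUNDS, vsl, ahc

__all__ = [
    "InputDistribution",
    "UncertaintyResult",
    "sample_inputs",
    "propagate",
    "uncertainty_percent",
    "default_distributions",
]

QUANTITIES = ("concentration", "beta", "unit_cost")
FAMILIES = ("normal", "lognormal", "triangular", "point")

_MAX_REJECT_FRACTION = 0.01


@dataclass(frozen=True)
class InputDistribution:
    """Sampling law for one uncertain quantity.

    Parameters by family: ``point`` uses ``value``; ``normal`` uses
    ``loc``/``scale``; ``lognormal`` uses ``loc``/``scale`` on the log
    scale (median exp(loc)); ``triangular`` uses ``left``/``mode``/
    ``right``. ``truncate_lower`` resamples draws below the bound.
    """

    quantity: str
    family: str
    value: float = 1.0
    loc: float = 0.0
    scale: float = 0.0
    left: float = 0.0
    mode: float = 1.0
    right: float = 2.0
    truncate_lower: float | None = None

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES:
            raise DistributionError(
                f"unknown quantity {self.quantity!r}; expected one of {QUANTITIES}"
            )
        if self.family not in FAMILIES:
            raise DistributionError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.family in ("normal", "lognormal") and self.scale < 0:
            raise DistributionError(f"{self.quantity}: scale must be >= 0")
        if self.family == "triangular" and not (
            self.left <= self.mode <= self.right and self.left < self.right
        ):
            raise DistributionError(
                f"{self.quantity}: triangular bounds must satisfy left <= mode "
                "<= right with left < right"
            )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "point":
            draws = np.full(n, self.value, dtype=float)
        elif self.family == "normal":
            draws = rng.normal(self.loc, self.scale, size=n)
        elif self.family == "lognormal":
            draws = rng.lognormal(self.loc, self.scale, size=n)
        else:
            draws = rng.triangular(self.left, self.mode, self.right, size=n)
        if self.truncate_lower is not None:
            # truncation by resampling, so the retained law is conditional
            for _ in range(1000):
                bad = draws < self.truncate_lower
                if not bad.any():
                    break
                draws[bad] = self.sample_untruncated(rng, int(bad.sum()))
            else:
                raise DistributionError(
                    f"{self.quantity}: truncation at {self.truncate_lower} "
                    "rejects essentially all mass"
                )
        return draws

    def sample_untruncated(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "point":
            return np.full(n, self.value, dtype=float)
        if self.family == "normal":
            return rng.normal(self.loc, self.scale, size=n)
        if self.family == "lognormal":
            return rng.lognormal(self.loc, self.scale, size=n)
        return rng.triangular(self.left, self.mode, self.right, size=n)


def default_distributions(
    concentration_sd_log: float = 0.05,
    beta_rel_sd: float = 0.15,
    cost_spread: float = 0.25,
) -> list[InputDistribution]:
    """Unit-median factor distributions for the three uncertain inputs.

    Lognormal for concentration (positive, right-skewed measurement
    error), normal truncated at 0 for beta (pooled-estimate intervals are
    symmetric), triangular for costs (bounded expert ranges around 1).
    """
    return [
        InputDistribution("concentration", "lognormal", loc=0.0, scale=concentration_sd_log),
        InputDistribution("beta", "normal", loc=1.0, scale=beta_rel_sd, truncate_lower=0.0),
        InputDistribution(
            "unit_cost", "triangular", left=1.0 - cost_spread, mode=1.0, right=1.0 + cost_spread
        ),
    ]


def sample_inputs(
    dists: list[InputDistribution], n: int, seed: int | np.random.Generator
) -> dict[str, np.ndarray]:
    """n independent joint draws, one array per quantity.

    Quantities are sampled independently. A quantity with no configured
    distribution gets point mass at 1 (no perturbation). Reproducible
    given the seed.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    seen = [d.quantity for d in dists]
    if len(set(seen)) != len(seen):
        raise DistributionError(f"duplicate distribution for quantity in {seen}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {q: np.ones(n) for q in QUANTITIES}
    for d in dists:
        out[d.quantity] = d.sample(rng, n)
    return out


@dataclass
class UncertaintyResult:
    """MC summary of one output (national or city total loss, one bound)."""

    scope: str
    bound: str
    n_draws: int
    mean: float
    ci95: tuple[float, float]
    relative_halfwidth: float
    prob_within_5pct: float
    seed: int
    n_rejected: int = 0
    draws: np.ndarray = field(default=None, repr=False)


class _PipelineArrays:
    """Flattened (record x endpoint) arrays for fast per-draw evaluation.

    Cell order is endpoint-major over the panel frame, matching
    exposure.impact_table. Only endpoints entering EC_total (all-cause
    mortality + morbidity) are retained, since the propagated output is
    the total economic loss.
    """

    def __init__(self, panel: CityPanel, endpoints: EndpointSet, params: AssessmentParams):
        f = panel.frame
        keep = [endpoints[name] for name in endpoints.total_loss_names]
        n_rec = len(f)

        conc = f["concentration"].to_numpy(dtype=float)
        pop = f["population"].to_numpy(dtype=float)
        city_vsl = vsl(f["income"].to_numpy(), params)
        city_ahc = ahc(f["gdp_per_capita"].to_numpy(), params)

        self.c0 = params.baseline_concentration
        self.conc = np.tile(conc, len(keep))
        self.pop_e0 = np.concatenate(
            [pop * e.baseline_incidence for e in keep]
        )
        self.beta = np.concatenate([np.full(n_rec, e.beta) for e in keep])

        cost_scaled = {}  # per bound: cost component multiplied by the cost factor
        cost_fixed = {}  # per bound: cost component immune to the cost factor (AHC)
        for bound in BOUNDS:
            scaled_blocks, fixed_blocks = [], []
            for e in keep:
                if e.cost_rule == "mortality_bound":
                    if bound == "upper_VSL":
                        scaled_blocks.append(np.asarray(city_vsl, dtype=float))
                        fixed_blocks.append(np.zeros(n_rec))
                    else:
                        scaled_blocks.append(np.zeros(n_rec))
                        fixed_blocks.append(np.asarray(city_ahc, dtype=float))
                elif e.cost_rule == "per_case_fixed":
                    scaled_blocks.append(np.full(n_rec, e.unit_cost))
                    fixed_blocks.append(np.zeros(n_rec))
                else:  # vsl_fraction
                    scaled_blocks.append(e.vsl_weight * np.asarray(city_vsl, dtype=float))
                    fixed_blocks.append(np.zeros(n_rec))
            cost_scaled[bound] = np.concatenate(scaled_blocks)
            cost_fixed[bound] = np.concatenate(fixed_blocks)
        self.cost_scaled = cost_scaled
        self.cost_fixed = cost_fixed

    def total_loss(self, bound: str, c_factor: float, b_factor: float, u_factor: float) -> float:
        """National EC_total for one draw of the three factors."""
        delta = np.maximum(self.conc * c_factor, self.c0) - self.c0
        x = self.beta * b_factor * delta
        if np.any(np.abs(x) > EXPONENT_CAP):
            return float("nan")
        cases = self.pop_e0 * np.expm1(x)
        cost = self.cost_scaled[bound] * u_factor + self.cost_fixed[bound]
        return float(np.sum(cases * cost))


def propagate(
    panel: CityPanel,
    endpoints: EndpointSet,
    params: AssessmentParams,
    dists: list[InputDistribution],
    n: int = 10_000,
    seed: int = 0,
    bounds: tuple[str, ...] = BOUNDS,
    keep_draws: bool = False,
) -> dict[str, UncertaintyResult]:
    """Run the pipeline under n joint input draws; summarize per bound.

    Every draw perturbs concentrations, betas, and VSL/COI unit costs by
    its sampled factors and recomputes the national total economic loss.
    Non-finite draw outputs are rejected and counted; more than 1%
    rejections is a failure. Fixing the seed fixes every statistic.

    Returns a dict bound -> :class:`UncertaintyResult` (scope national).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    factors = sample_inputs(dists, n, seed)
    arrays = _PipelineArrays(panel, endpoints, params)

    results: dict[str, UncertaintyResult] = {}
    for bound in bounds:
        draws = np.array(
            [
                arrays.total_loss(
                    bound,
                    factors["concentration"][i],
                    factors["beta"][i],
                    factors["unit_cost"][i],
                )
                for i in range(n)
            ]
        )
        finite = np.isfinite(draws)
        n_rejected = int(n - finite.sum())
        if n_rejected > _MAX_REJECT_FRACTION * n:
            raise DistributionError(
                f"{bound}: {n_rejected}/{n} draws rejected as non-finite"
            )
        draws = draws[finite]
        mean = float(draws.mean())
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rel_hw = float((hi - lo) / (2.0 * mean)) if mean else 0.0
        within = (
            float(np.mean(np.abs(draws - mean) <= 0.05 * abs(mean)))
            if mean
            else 1.0
        )
        results[bound] = UncertaintyResult(
            scope="national",
            bound=bound,
            n_draws=len(draws),
            mean=mean,
            ci95=(float(lo), float(hi)),
            relative_halfwidth=rel_hw,
            prob_within_5pct=within,
            seed=seed if isinstance(seed, int) else -1,
            n_rejected=n_rejected,
            draws=draws if keep_draws else None,
        )
    return results


def uncertainty_percent(result: UncertaintyResult) -> float:
    """Share of simulated outcomes outside the ±5% acceptable-error band (%)."""
    if result.n_draws < 100:
        raise ValidationError("need at least 100 draws for an uncertainty percent")
    return 100.0 * (1.0 - result.prob_within_5pct)


def results_to_frame(results: dict[str, UncertaintyResult]) -> pd.DataFrame:
    """Tabulate propagation results, one row per bound."""
    rows = []
    for bound, r in results.items():
        rows.append(
            {
                "scope": r.scope,
                "bound": bound,
                "n_draws": r.n_draws,
                "mean": r.mean,
                "ci95_low": r.ci95[0],
                "ci95_high": r.ci95[1],
                "relative_halfwidth": r.relative_halfwidth,
                "prob_within_5pct": r.prob_within_5pct,
                "uncertainty_percent": 100.0 * (1.0 - r.prob_within_5pct),
                "n_rejected": r.n_rejected,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(rows)
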