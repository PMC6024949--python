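"""End-to-end assessment runner: config in, report files out.

Wires the pipeline stages together: read panel -> load endpoints ->
attributable cases -> unit costs (both bounds) -> losses -> rollups ->
summary statistics, year-over-year changes, city ranking -> optional
Monte Carlo uncertainty. Reports are plain CSVs plus a JSON manifest
(config hash, seed, package version); identical config + seed yields
byte-identical outputs. Any stage error removes partial outputs before
propagating.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .aggregate import (
    HUNDRED_MILLION,
    losses_to_frame,
    rank_cities,
    rollup,
    summary_stats,
    yoy_changes,
)
from .endpoints import default_endpoint_set, load_endpoint_set
from .errors import AqBurdenError, ConfigError
from .exposure import AssessmentParams, impact_table
from .panel import read_panel
from .uncertainty import default_distributions, propagate, results_to_frame
from .valuation import BOUNDS, loss_table, unit_cost_table

__all__ = ["RunConfig", "run_assessment", "REPORT_FILES"]

REPORT_FILES = [
    "impact_table.csv",
    "unit_costs.csv",
    "city_losses.csv",
    "national_summary.csv",
    "yoy_changes.csv",
    "city_ranking.csv",
    "manifest.json",
]


@dataclass
class RunConfig:
    """Everything one assessment run needs."""

    panel_path: str
    output_dir: str
    endpoint_config_path: str | None = None  # None -> packaged default
    params: AssessmentParams = dataclasses.field(default_factory=AssessmentParams)
    bounds: tuple[str, ...] = BOUNDS
    mc_draws: int = 0  # 0 disables the Monte Carlo stage
    seed: int = 0

    def digest(self) -> str:
        payload = {
            "panel_path": str(self.panel_path),
            "endpoint_config_path": (
                str(self.endpoint_config_path) if self.endpoint_config_path else None
            ),
            "params": dataclasses.asdict(self.params),
            "bounds": list(self.bounds),
            "mc_draws": self.mc_draws,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


def _money_to_report_scale(frame: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    out = frame.copy()
    for col in columns:
        if col in out.columns:
            out[col] = out[col] / HUNDRED_MILLION
    return out


def run_assessment(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full assessment and write the report files.

    Returns a mapping report-name -> written path. On any stage failure,
    files written so far are removed and the error re-raised with the
    stage name prepended.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write_csv(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / name
        frame.to_csv(path, index=False, float_format="%.10g")
        written[name] = path

    stage = "setup"
    try:
        stage = "panel"
        panel = read_panel(cfg.panel_path)

        stage = "endpoints"
        if cfg.endpoint_config_path:
            endpoints = load_endpoint_set(cfg.endpoint_config_path)
        else:
            endpoints = default_endpoint_set()

        stage = "exposure_response"
        impacts = impact_table(panel, endpoints, cfg.params)
        _write_csv("impact_table.csv", impacts)

        stage = "valuation"
        cost_frames, loss_frames = [], []
        for bound in cfg.bounds:
            costs = unit_cost_table(panel, endpoints, bound, cfg.params)
            cost_frames.append(costs)
            loss_frames.append(loss_table(impacts, costs))
        _write_csv("unit_costs.csv", pd.concat(cost_frames, ignore_index=True))
        losses = pd.concat(loss_frames, ignore_index=True)

        stage = "aggregation"
        gdp = panel.gdp_total_by_year()
        city_results, national_results = rollup(losses, endpoints, gdp)
        city_frame = _money_to_report_scale(
            losses_to_frame(city_results),
            ["ec_mortality", "ec_morbidity", "ec_total"]
            + [f"ec__{n}" for n in endpoints.names],
        )
        _write_csv("city_losses.csv", city_frame)

        summary = summary_stats(national_results, gdp)
        _write_csv(
            "national_summary.csv",
            _money_to_report_scale(summary, ["tel_lower_AHC", "tel_upper_VSL"]),
        )

        national_frame = losses_to_frame(national_results)
        changes = yoy_changes(national_frame, "ec_total", ("bound",))
        _write_csv("yoy_changes.csv", changes)

        ranking = rank_cities(city_results, bound=cfg.bounds[-1])
        _write_csv(
            "city_ranking.csv", _money_to_report_scale(ranking, ["total_loss"])
        )

        if cfg.mc_draws:
            stage = "uncertainty_mc"
            mc = propagate(
                panel,
                endpoints,
                cfg.params,
                default_distributions(),
                n=cfg.mc_draws,
                seed=cfg.seed,
                bounds=cfg.bounds,
            )
            _write_csv("uncertainty.csv", results_to_frame(mc))

        stage = "manifest"
        manifest = {
            "package": "aqburden",
            "version": __version__,
            "config_sha256": cfg.digest(),
            "seed": cfg.seed,
            "n_records": len(panel),
            "years": panel.years,
            "bounds": list(cfg.bounds),
            "endpoint_provenance": endpoints.provenance,
            "reports": sorted(written) + ["manifest.json"],
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written["manifest.json"] = path
    except Exception as exc:
        for path in written.values():
            path.unlink(missing_ok=True)
        if isinstance(exc, AqBurdenError):
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        raise ConfigError(f"[stage {stage}] {exc}") from exc

    return written
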