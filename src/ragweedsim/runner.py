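"""Orchestration over site × scenario grids and result writers."""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Optional

import pandas as pd

from .config import RunConfig
from .errors import InputError
from .population import SiteResult, pollen_change, run_site

__all__ = ["run_grid", "write_results", "RESULT_COLUMNS"]

log = logging.getLogger("ragweedsim")

RESULT_COLUMNS = ("site_id", "latitude", "longitude", "scenario", "capital_lambda",
                  "category", "mean_pollen", "mean_season_end_doy",
                  "pollen_change_log10", "n_sim", "seed")


def _result_row(site, result: SiteResult, seed: int,
                change: Optional[float]) -> dict:
    return {
        "site_id": result.site_id,
        "latitude": site.latitude,
        "longitude": site.longitude,
        "scenario": result.scenario,
        "capital_lambda": result.capital_lambda,
        "category": result.category,
        "mean_pollen": result.mean_pollen,
        "mean_season_end_doy": result.mean_season_end_doy,
        "pollen_change_log10": change,
        "n_sim": result.n_replicates,
        "seed": seed,
    }


def run_grid(config: RunConfig) -> tuple[pd.DataFrame, list[str]]:
    """Run every site under every scenario.

    The baseline scenario is always run first per site so the pollen
    change of each perturbed scenario can be computed against it.  Per-site
    failures are logged and collected; the run continues and the failure
    messages are returned alongside the results table.
    """
    scenarios = sorted(config.scenarios, key=lambda s: not s.is_baseline)
    rows: list[dict] = []
    failures: list[str] = []
    for site in config.sites:
        baseline_pollen: Optional[float] = None
        for scenario in scenarios:
            try:
                result = run_site(site, scenario, n_sim=config.n_sim,
                                  seed=config.seed, scale=config.scale,
                                  params=config.params,
                                  pool_years=config.pool_years)
            except Exception as exc:  # keep the grid going
                msg = f"{site.site_id} × {scenario.label}: {exc}"
                failures.append(msg)
                log.error("FAILED %s", msg)
                continue
            if scenario.is_baseline:
                baseline_pollen = result.mean_pollen
                change = None
            elif baseline_pollen is not None:
                change = pollen_change(result.mean_pollen, baseline_pollen)
            else:
                change = None
            rows.append(_result_row(site, result, config.seed, change))
            log.info("site=%s scenario=%s Lambda=%.4f category=%s n_sim=%d seed=%d",
                     result.site_id, result.scenario, result.capital_lambda,
                     result.category, result.n_replicates, config.seed)
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS)), failures


def write_results(results: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write a results table as CSV or a GeoJSON FeatureCollection of points."""
    if len(results) == 0:
        raise InputError("results table is empty")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        results.to_csv(path, index=False, float_format="%.10g")
    elif format == "geojson":
        features = []
        for _, row in results.iterrows():
            change = row["pollen_change_log10"]
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [float(row["longitude"]),
                                             float(row["latitude"])]},
                "properties": {
                    "site_id": row["site_id"],
                    "scenario": row["scenario"],
                    "category": row["category"],
                    "capital_lambda": float(row["capital_lambda"]),
                    "pollen_change": None if change is None or
                    (isinstance(change, float) and math.isnan(change))
                    else float(change),
                },
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
    else:
        raise InputError(f"unknown output format {format!r}")
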