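"""Run configuration: YAML config files and CSV site tables.

A run config names the sites (presets and/or a CSV site table), the
scenario perturbations, the master seed, replicate count and output
options, plus optional per-module parameter overrides.  Unknown keys are
rejected everywhere so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from .errors import ConfigurationError
from .germination import DormancyParams, GerminationParams, SeedFateParams
from .growth import GrowthParams, PhenologyParams
from .population import SimulationParams, SuitabilityScale
from .presets import SITE_PRESETS
from .reproduction import AllometryParams
from .soil import SoilParams
from .weather import ScenarioDelta, SiteClimate

__all__ = ["RunConfig", "load_config", "read_site_table", "write_site_table"]

_TOP_KEYS = {"sites", "site_table", "scenarios", "seed", "n_sim", "pool_years",
             "output_dir", "formats", "params", "suitability_cuts"}
_PARAM_SECTIONS = {
    "dormancy": DormancyParams,
    "germination": GerminationParams,
    "seed_fate": SeedFateParams,
    "soil": SoilParams,
    "phenology": PhenologyParams,
    "growth": GrowthParams,
    "allometry": AllometryParams,
    "simulation": SimulationParams,
}
_SCENARIO_KEYS = {"label", "temp_offset", "precip_multiplier"}
_FORMATS = {"csv", "geojson"}

_MONTH_SUFFIXES = [f"{m:02d}" for m in range(1, 13)]
_SITE_VECTORS = {
    "tmin_mean": "monthly_tmin_mean",
    "tmax_mean": "monthly_tmax_mean",
    "wet_prob": "monthly_wet_day_prob",
    "wet_rain": "monthly_wet_day_mean_rain",
}
_SITE_SCALARS = {
    "site_id": str, "latitude": float, "longitude": float,
    "temp_residual_sd": float, "temp_residual_autocorr": float,
    "wet_persistence": float, "rain_shape": float, "soil_profile_ref": str,
}


@dataclass
class RunConfig:
    """Fully validated run configuration with all defaults materialised."""

    sites: list[SiteClimate]
    scenarios: list[ScenarioDelta]
    seed: int = 42
    n_sim: int = 1000
    pool_years: int = 100
    output_dir: Path = Path("results")
    formats: tuple[str, ...] = ("csv",)
    params: SimulationParams = field(default_factory=SimulationParams)
    scale: SuitabilityScale = field(default_factory=SuitabilityScale)

    def describe(self) -> str:
        """Echo of every materialised parameter, for the run log."""
        lines = [f"seed={self.seed} n_sim={self.n_sim} pool_years={self.pool_years}",
                 f"sites: {[s.site_id for s in self.sites]}",
                 f"scenarios: {[s.label for s in self.scenarios]}",
                 f"suitability cuts: {self.scale.cuts}"]
        for name in ("dormancy", "germination", "seed_fate", "soil",
                     "phenology", "growth", "allometry"):
            lines.append(f"{name}: {getattr(self.params, name)}")
        lines.append(f"reference_seedbank={self.params.reference_seedbank} "
                     f"emergence_trigger_fraction={self.params.emergence_trigger_fraction}")
        return "\n".join(lines)


def _reject_unknown(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)} in {context}; "
                                 f"allowed: {sorted(allowed)}")


def _build_params(overrides: dict[str, Any]) -> SimulationParams:
    _reject_unknown(overrides, set(_PARAM_SECTIONS), "params")
    kwargs: dict[str, Any] = {}
    sim_over: dict[str, Any] = {}
    for section, values in overrides.items():
        cls = _PARAM_SECTIONS[section]
        if not isinstance(values, dict):
            raise ConfigurationError(f"params.{section} must be a mapping")
        names = {f.name for f in dataclasses.fields(cls)}
        if section == "simulation":
            allowed = {"reference_seedbank", "emergence_trigger_fraction"}
            _reject_unknown(values, allowed, "params.simulation")
            sim_over = dict(values)
            continue
        _reject_unknown(values, names, f"params.{section}")
        if section == "phenology" and "flowering_onset" in values:
            values = dict(values)
            values["flowering_onset"] = tuple(values["flowering_onset"])
        kwargs[section] = cls(**values)
    return SimulationParams(**kwargs, **sim_over)


def _build_scenario(entry: dict[str, Any]) -> ScenarioDelta:
    if not isinstance(entry, dict) or "label" not in entry:
        raise ConfigurationError("each scenario needs at least a 'label'")
    _reject_unknown(entry, _SCENARIO_KEYS, f"scenario {entry.get('label')!r}")
    off = entry.get("temp_offset", 0.0)
    mult = entry.get("precip_multiplier", 1.0)
    offs = tuple(float(o) for o in off) if isinstance(off, (list, tuple)) \
        else (float(off),) * 12
    mults = tuple(float(m) for m in mult) if isinstance(mult, (list, tuple)) \
        else (float(mult),) * 12
    return ScenarioDelta(label=str(entry["label"]), temp_offset_monthly=offs,
                         precip_multiplier_monthly=mults)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a YAML mapping")
    _reject_unknown(raw, _TOP_KEYS, "config")

    sites: list[SiteClimate] = []
    for name in raw.get("sites", []):
        if name not in SITE_PRESETS:
            raise ConfigurationError(f"unknown site preset {name!r}")
        sites.append(SITE_PRESETS[name])
    if "site_table" in raw:
        table_path = path.parent / raw["site_table"]
        if not table_path.exists():
            raise ConfigurationError(f"site table not found: {table_path}")
        sites.extend(read_site_table(table_path))
    if not sites:
        raise ConfigurationError("config names no sites")

    scenarios = [_build_scenario(s) for s in raw.get("scenarios", [])]
    if not any(s.is_baseline for s in scenarios):
        scenarios.insert(0, ScenarioDelta.baseline())

    seed = raw.get("seed", 42)
    n_sim = raw.get("n_sim", 1000)
    pool_years = raw.get("pool_years", 100)
    for name, value in (("seed", seed), ("n_sim", n_sim), ("pool_years", pool_years)):
        if not isinstance(value, int) or value < 1:
            raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")

    formats = tuple(raw.get("formats", ["csv"]))
    bad = set(formats) - _FORMATS
    if bad:
        raise ConfigurationError(f"unknown output format(s) {sorted(bad)}")

    params = _build_params(raw.get("params", {}))
    scale = SuitabilityScale(cuts=tuple(float(c) for c in raw["suitability_cuts"])) \
        if "suitability_cuts" in raw else SuitabilityScale()

    return RunConfig(sites=sites, scenarios=scenarios, seed=seed, n_sim=n_sim,
                     pool_years=pool_years,
                     output_dir=Path(raw.get("output_dir", "results")),
                     formats=formats, params=params, scale=scale)


def read_site_table(path: str | Path) -> list[SiteClimate]:
    """Read sites from a CSV table (monthly vectors as 12 suffixed columns)."""
    df = pd.read_csv(path)
    required = {"site_id", "latitude"} | {
        f"{stem}_{sfx}" for stem in _SITE_VECTORS for sfx in _MONTH_SUFFIXES}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"site table missing columns: {sorted(missing)[:6]} ...")
    sites = []
    for _, row in df.iterrows():
        kwargs: dict[str, Any] = {}
        for col, conv in _SITE_SCALARS.items():
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = conv(row[col])
        for stem, fieldname in _SITE_VECTORS.items():
            kwargs[fieldname] = tuple(float(row[f"{stem}_{sfx}"]) for sfx in _MONTH_SUFFIXES)
        sites.append(SiteClimate(**kwargs))
    return sites


def write_site_table(sites: list[SiteClimate], path: str | Path) -> None:
    """Write sites to the CSV layout read by :func:`read_site_table`."""
    rows = []
    for s in sites:
        row: dict[str, Any] = {
            "site_id": s.site_id, "latitude": s.latitude, "longitude": s.longitude,
            "temp_residual_sd": s.temp_residual_sd,
            "temp_residual_autocorr": s.temp_residual_autocorr,
            "wet_persistence": s.wet_persistence, "rain_shape": s.rain_shape,
            "soil_profile_ref": s.soil_profile_ref,
        }
        for stem, fieldname in _SITE_VECTORS.items():
            for sfx, value in zip(_MONTH_SUFFIXES, getattr(s, fieldname)):
                row[f"{stem}_{sfx}"] = value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
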