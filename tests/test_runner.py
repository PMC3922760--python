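"""Configuration loading, grid orchestration, writers and the CLI layer."""

import json

import pandas as pd
import pytest
from click.testing import CliRunner

import ragweedsim as r
from ragweedsim.cli import main as cli_main
from ragweedsim.errors import ConfigurationError

from conftest import make_constant_site

MINIMAL = """
sites: [temperate_favourable]
"""

SMALL_GRID = """
sites: [temperate_favourable, mediterranean_dry]
scenarios:
  - label: baseline
  - label: warm2
    temp_offset: 2.0
seed: 11
n_sim: 8
pool_years: 6
formats: [csv, geojson]
"""


def write_config(tmp_path, text):
    path = tmp_path / "run.yaml"
    path.write_text(text)
    return path


class TestConfig:
    def test_minimal_config_materialises_defaults(self, tmp_path):
        cfg = r.load_config(write_config(tmp_path, MINIMAL))
        assert [s.site_id for s in cfg.sites] == ["temperate_favourable"]
        assert cfg.n_sim == 1000 and cfg.seed == 42 and cfg.pool_years == 100
        assert cfg.scenarios[0].is_baseline  # baseline auto-inserted
        assert "maturity_tt" in cfg.describe()

    def test_negative_n_sim_rejected_by_name(self, tmp_path):
        path = write_config(tmp_path, MINIMAL + "n_sim: -5\n")
        with pytest.raises(ConfigurationError, match="n_sim"):
            r.load_config(path)

    def test_unknown_keys_rejected(self, tmp_path):
        path = write_config(tmp_path, MINIMAL + "n_simm: 10\n")
        with pytest.raises(ConfigurationError, match="n_simm"):
            r.load_config(path)
        path = write_config(tmp_path, MINIMAL +
                            "params:\n  phenology:\n    maturity_ttt: 500\n")
        with pytest.raises(ConfigurationError, match="maturity_ttt"):
            r.load_config(path)

    def test_parameter_override_is_echoed(self, tmp_path):
        path = write_config(tmp_path, MINIMAL +
                            "params:\n  phenology:\n    maturity_tt: 500\n")
        cfg = r.load_config(path)
        assert cfg.params.phenology.maturity_tt == 500.0
        assert "maturity_tt=500" in cfg.describe().replace(".0", "")

    def test_missing_config_file(self, tmp_path):
        with pytest.raises(ConfigurationError):
            r.load_config(tmp_path / "absent.yaml")

    def test_site_table_round_trip(self, tmp_path):
        sites = [r.get_preset("temperate_favourable"), r.get_preset("boreal_cold")]
        path = tmp_path / "sites.csv"
        r.write_site_table(sites, path)
        back = r.read_site_table(path)
        assert back == sites


@pytest.fixture(scope="module")
def grid_run(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("grid")
    cfg = r.load_config(write_config(tmp, SMALL_GRID))
    results, failures = r.run_grid(cfg)
    return cfg, results, failures, tmp


class TestGrid:
    def test_one_row_per_site_scenario(self, grid_run):
        _, results, failures, _ = grid_run
        assert failures == []
        assert len(results) == 4  # 2 sites x 2 scenarios
        warm = results[results["scenario"] == "warm2"]
        assert warm["pollen_change_log10"].notna().all() or \
            (warm["pollen_change_log10"].isna() & (warm["mean_pollen"] <= 1.0)).any()
        assert results[results["scenario"] == "baseline"]["pollen_change_log10"].isna().all()

    def test_rerun_is_byte_identical(self, grid_run, tmp_path):
        cfg, results, _, _ = grid_run
        results2, _ = r.run_grid(cfg)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        r.write_results(results, p1)
        r.write_results(results2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_csv_round_trip_preserves_values(self, grid_run, tmp_path):
        _, results, _, _ = grid_run
        path = tmp_path / "out.csv"
        r.write_results(results, path)
        back = pd.read_csv(path)
        assert len(back) == len(results)
        for a, b in zip(back["capital_lambda"], results["capital_lambda"]):
            assert a == pytest.approx(b, rel=1e-9)

    def test_geojson_is_a_valid_feature_collection(self, grid_run, tmp_path):
        _, results, _, _ = grid_run
        path = tmp_path / "out.geojson"
        r.write_results(results, path, format="geojson")
        doc = json.loads(path.read_text())
        assert doc["type"] == "FeatureCollection"
        assert len(doc["features"]) == len(results)
        feat = doc["features"][0]
        assert feat["geometry"]["type"] == "Point"
        assert {"category", "capital_lambda", "pollen_change"} <= set(feat["properties"])

    def test_rainless_site_completes_as_unsuitable(self):
        # mild enough for chilling and germination, but not a drop of rain:
        # every cohort emerges into a drying profile and dies of drought
        site = make_constant_site(site_id="dustbowl", tmin=3.0, tmax=13.0,
                                  wet_prob=0.0, sd=1.0)
        result = r.run_site(site, n_sim=10, seed=3, pool_years=5)
        assert result.category in ("U.0", "U.1")


class TestCli:
    def test_simulate_site_prints_lambda_and_category(self):
        runner = CliRunner()
        out = runner.invoke(cli_main, ["simulate-site", "--preset", "boreal_cold",
                                       "--n-sim", "5", "--seed", "1"])
        assert out.exit_code == 0
        assert "Lambda=" in out.output and "category=" in out.output

    def test_make_weather_writes_csv(self, tmp_path):
        runner = CliRunner()
        dest = tmp_path / "w.csv"
        out = runner.invoke(cli_main, ["make-weather", "--preset",
                                       "temperate_favourable", "--years", "1",
                                       "--seed", "2", "--out", str(dest)])
        assert out.exit_code == 0
        df = pd.read_csv(dest)
        assert len(df) == 365
        assert set(df.columns) == set(r.weather.WEATHER_COLUMNS)

    def test_pollen_change_verb(self):
        runner = CliRunner()
        out = runner.invoke(cli_main, ["pollen-change", "--future", "1e10",
                                       "--baseline", "1e9"])
        assert out.exit_code == 0
        assert out.output.strip() == "1.0000"
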