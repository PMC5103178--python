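"""Model/Results surface, configuration schema, file round trips and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from sourmon.cli import default_deselection, main, run_pipeline
from sourmon.config import load_config, preset_config
from sourmon.io import (
    do_wide,
    read_do_csv,
    read_grid,
    read_mask,
    read_tiles,
    write_do_csv,
    write_grid,
    write_mask,
    write_tiles,
    write_truth_csv,
)
from sourmon.model import PerfusedCultureModel, simulate_run
from sourmon.segmentation import build_grid, deselect_regions


@pytest.fixture(scope="module")
def short_cho():
    """A short CHO-like run kept cheap for model-level tests."""
    cfg = preset_config("cho_culture")
    cfg.seed = 21
    cfg.duration_h = 12.0
    return cfg


class TestConfig:
    def test_presets_encode_study_conditions(self):
        cho = preset_config("cho_culture")
        assert cho.culture.seeding_density == 3e4
        assert cho.culture.mu_max == pytest.approx(0.041)
        assert cho.culture.flow_rate_uL_h == 300.0
        mesc = preset_config("mesc_culture")
        assert mesc.culture.seeding_density == 5e4
        assert mesc.culture.lag_h == 72.0
        assert mesc.culture.mu_max == pytest.approx(0.035)
        assay = preset_config("respiratory_assay")
        assert assay.protocol.segments == ((0.0, 1.0), (2.5, 0.2), (6.0, 3.0))

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("cultur: {}\n")
        with pytest.raises(ValueError, match="unknown top-level"):
            load_config(p)
        p.write_text("culture: {seeding_densty: 1}\n")
        with pytest.raises(ValueError, match="unknown keys"):
            load_config(p)

    def test_yaml_round_trip(self, tmp_path):
        cfg = preset_config("mesc_culture")
        cfg.seed = 9
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = load_config(p)
        assert back.culture.seeding_density == cfg.culture.seeding_density
        assert back.culture.lag_h == cfg.culture.lag_h
        assert back.seed == 9
        assert back.preset == "mesc_culture"

    def test_seed_override(self, tmp_path):
        cfg = preset_config("cho_culture")
        cfg.to_yaml(tmp_path / "c.yaml")
        assert load_config(tmp_path / "c.yaml", seed=77).seed == 77

    def test_packaged_deselection_yields_printed_counts(self):
        d = default_deselection()
        grid = build_grid((470, 150), rows=d["rows"], cols=d["cols"])
        out = deselect_regions(grid, border=d["border"], blocks=d["blocks"])
        assert out.n_retained == 507
        assert out.n_discarded == 198


class TestIO:
    def test_tile_round_trip(self, tmp_path, rendered_frames):
        fr = rendered_frames[0.3]
        sheet = write_tiles(tmp_path, fr.tiles)
        tiles = read_tiles(sheet)
        assert len(tiles) == len(fr.tiles)
        assert np.allclose(tiles[0].pixels, fr.tiles[0]["pixels"], atol=1e-6)
        assert tiles[2].stage_x_um == fr.tiles[2]["stage_x_um"]

    def test_mask_round_trip(self, tmp_path, rendered_frames):
        fr = rendered_frames[0.3]
        write_mask(tmp_path / "m.tif", fr.mask)
        assert np.array_equal(read_mask(tmp_path / "m.tif"), fr.mask)

    def test_do_csv_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "t_h": [0.0, 0.25, 0.0, 0.25],
                "channel": ["inlet", "inlet", "outlet", "outlet"],
                "conc_uM": [215.0, 214.5, 200.0, 199.5],
            }
        )
        write_do_csv(tmp_path / "do.csv", df)
        back = read_do_csv(tmp_path / "do.csv")
        wide = do_wide(back)
        assert np.allclose(wide["inlet"], [215.0, 214.5])
        assert np.allclose(wide["outlet"], [200.0, 199.5])

    def test_grid_round_trip(self, tmp_path):
        grid = deselect_regions(build_grid((470, 150), 47, 15), border=1)
        write_grid(tmp_path / "g.json", grid)
        back = read_grid(tmp_path / "g.json")
        assert back.n_retained == grid.n_retained
        assert np.array_equal(back.retained, grid.retained)

    def test_truth_csv_round_trip(self, tmp_path, short_cho):
        from sourmon.io import read_truth_csv
        from sourmon.simulate import simulate_growth

        truth = simulate_growth(short_cho.culture, np.arange(0, 12.1, 0.5))
        write_truth_csv(tmp_path / "t.csv", truth)
        back = read_truth_csv(tmp_path / "t.csv")
        assert np.allclose(back["density_cells_cm2"], truth.density)
        assert np.allclose(back["sour_true_amol_cell_s"], truth.sour_true)


class TestModel:
    def test_fit_recovers_constant_sour(self, short_cho):
        model = PerfusedCultureModel.from_simulation(short_cho)
        res = model.fit()
        sel = ~res.sour.negative_flag
        med = float(res.sour.loc[sel, "sour_amol_cell_s"].median())
        assert med == pytest.approx(20.0, rel=0.15)

    def test_report_schema(self, short_cho):
        res = PerfusedCultureModel.from_simulation(short_cho).fit()
        rep = res.to_report()
        for key in (
            "mu_max_per_h",
            "doubling_time_h",
            "lag_h",
            "plateau_sour_amol_cell_s",
            "events",
            "qc",
        ):
            assert key in rep
        assert rep["qc"]["regions_total"] == 705

    def test_summary_prints_estimates(self, short_cho):
        res = PerfusedCultureModel.from_simulation(short_cho).fit()
        text = res.summary()
        assert "mu_max" in text and "sOUR" in text

    def test_same_seed_same_report(self, short_cho):
        a = PerfusedCultureModel.from_simulation(short_cho).fit().to_report()
        b = PerfusedCultureModel.from_simulation(short_cho).fit().to_report()
        assert json.dumps(a, sort_keys=True, default=str) == json.dumps(
            b, sort_keys=True, default=str
        )

    def test_from_files_matches_in_memory(self, tmp_path, short_cho):
        # write the fixture set to disk, re-read, and check the density stage
        run = simulate_run(short_cho, keep_tiles=True)
        sheets = []
        for i in (0, len(run.images) // 2, len(run.images) - 1):
            sheet = write_tiles(tmp_path / f"t{i}", run.tiles_by_frame[i])
            sheets.append(sheet)
        from sourmon.simulate import default_sim_calibration

        cal = default_sim_calibration()
        write_do_csv(tmp_path / "do.csv", run.traces.to_frame(cal))
        model = PerfusedCultureModel.from_files(sheets, tmp_path / "do.csv", short_cho)
        assert len(model.images) == 3
        assert model.do["inlet_uM"].notna().all()
        # stitched images reproduce the rendered canvases
        idx = [0, len(run.images) // 2, len(run.images) - 1]
        for img, i in zip(model.images, idx):
            assert np.allclose(img, run.images[i], atol=1e-5)


class TestCli:
    def test_version(self):
        result = CliRunner().invoke(main, ["--version"])
        assert result.exit_code == 0

    def test_run_pipeline_writes_bundle(self, tmp_path, short_cho):
        code = run_pipeline(short_cho, tmp_path)
        assert code == 0
        report = json.loads((tmp_path / "report.json").read_text())
        assert "mu_max_per_h" in report
        assert (tmp_path / "density.csv").exists()
        assert (tmp_path / "sour.csv").exists()
        assert (tmp_path / "classifier.json").exists()

    def test_missing_input_fails_with_name(self, tmp_path, short_cho):
        short_cho.paths = {"sensor_csv": str(tmp_path / "nope.csv")}
        code = run_pipeline(short_cho, tmp_path / "out")
        assert code == 1

    def test_assay_command(self, tmp_path):
        result = CliRunner().invoke(
            main, ["assay", "--seed", "5", "--out", str(tmp_path)]
        )
        assert result.exit_code == 0
        assert "uptake_decrease" in result.output
        assert "uptake_increase" in result.output

    def test_kinetics_command(self, tmp_path):
        t = np.arange(0, 40.5, 0.5)
        pd.DataFrame({"t_h": t, "density_cells_cm2": 3e4 * np.exp(0.041 * t)}).to_csv(
            tmp_path / "d.csv", index=False
        )
        result = CliRunner().invoke(main, ["kinetics", "--density-csv", str(tmp_path / "d.csv")])
        assert result.exit_code == 0
        out = json.loads(result.output)
        assert out["mu_max_per_h"] == pytest.approx(0.041, rel=1e-6)
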