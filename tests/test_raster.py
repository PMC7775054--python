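import datetime as dt
import json

import numpy as np
import pytest

import phenorisk as pr
from phenorisk.raster import NODATA_INT, WeatherGapError, _doy_label, _tile_layout
from conftest import constant_cube


class TestGeoTiff:
    def test_roundtrip(self, tmp_path):
        geom = pr.GridGeometry(-120.0, 48.0, 0.5, 0.25)
        data = np.arange(24, dtype=np.float32).reshape(2, 3, 4)
        data[0, 0, 0] = np.nan
        p = pr.write_geotiff(tmp_path / "x.tif", data, geom,
                             band_labels=["2018-01-01", "2018-01-02"],
                             meta={"units": "C"})
        arr, g2, labels, meta = pr.read_geotiff(p)
        assert g2 == geom
        assert labels == ["2018-01-01", "2018-01-02"]
        assert meta == {"units": "C"}
        assert np.isnan(arr[0, 0, 0])
        np.testing.assert_allclose(arr.ravel()[1:], data.ravel()[1:])

    def test_window_from_extent(self):
        geom = pr.GridGeometry(-100.0, 45.0, 0.25, 0.25)
        r0, r1, c0, c1 = geom.window((-99.5, 42.5, -98.5, 43.5), 20, 20)
        assert (c0, c1) == (2, 6)
        assert (r0, r1) == (6, 10)
        with pytest.raises(ValueError, match="intersect"):
            geom.window((0, 0, 1, 1), 20, 20)


class TestWeatherCube:
    def test_save_and_read_roundtrip(self, tmp_path):
        cube = pr.generate(pr.SynthSpec(n_rows=5, n_cols=4, n_days=10, seed=1))
        cube.save(tmp_path)
        back = pr.read_weather(tmp_path)
        assert back.dates == cube.dates
        assert back.geometry == cube.geometry
        np.testing.assert_allclose(back.tmin, cube.tmin, atol=1e-4)

    def test_crop_is_a_window(self, tmp_path):
        cube = pr.generate(pr.SynthSpec(n_rows=10, n_cols=10, n_days=5, seed=2))
        ext = (-99.0, 43.0, -98.0, 44.0)
        crop = cube.crop(ext)
        r0, r1, c0, c1 = cube.geometry.window(ext, 10, 10)
        np.testing.assert_array_equal(crop.tmax, cube.tmax[:, r0:r1, c0:c1])
        assert crop.geometry.x0 == cube.geometry.x0 + c0 * cube.geometry.dx

    def test_fahrenheit_source_converted(self, tmp_path):
        cube = constant_cube(50.0, n_days=3, n_rows=2, n_cols=2)  # already C
        labels = [d.isoformat() for d in cube.dates]
        for name in ("tmin", "tmax"):
            pr.write_geotiff(tmp_path / f"{name}.tif",
                             getattr(cube, name).astype(np.float32), cube.geometry,
                             band_labels=labels, meta={"units": "F", "variable": name})
        back = pr.read_weather(tmp_path)
        assert back.units == "C"
        np.testing.assert_allclose(back.tmin, (50 - 32) * 5 / 9, atol=1e-4)

    def test_missing_dates_listed(self, tmp_path):
        cube = pr.generate(pr.SynthSpec(n_rows=2, n_cols=2, n_days=5, seed=0))
        cube.save(tmp_path)
        with pytest.raises(WeatherGapError, match="2018-01-07"):
            pr.read_weather(tmp_path, dates=(dt.date(2018, 1, 1), dt.date(2018, 1, 8)))

    def test_swapped_extremes_repaired(self):
        dates = [dt.date(2018, 1, 1), dt.date(2018, 1, 2)]
        tmin = np.full((2, 1, 1), 20.0)
        tmax = np.full((2, 1, 1), 10.0)
        cube = pr.WeatherCube(dates, tmin, tmax,
                              pr.GridGeometry(-100, 45, 0.25, 0.25))
        assert np.all(cube.tmin <= cube.tmax)

    def test_nonconsecutive_dates_rejected(self):
        dates = [dt.date(2018, 1, 1), dt.date(2018, 1, 5)]
        with pytest.raises(WeatherGapError, match="consecutive"):
            pr.WeatherCube(dates, np.zeros((2, 1, 1)), np.ones((2, 1, 1)),
                           pr.GridGeometry(-100, 45, 0.25, 0.25))


class TestRunGrid:
    def test_single_cell_matches_point_engine(self, epos):
        cube = constant_cube(17.2)
        config = pr.RunConfig(n_cohorts=7, sample_every=30)
        out = pr.run_grid(cube, epos, config)
        cohorts = pr.make_cohorts(epos, 7)
        trajs = [pr.run_cohort(cube.cell_series(0, 0), epos, e, sample_every=30)
                 for e in cohorts.emergence_dd]
        summary = pr.combine_cohorts(trajs, cohorts)
        assert out.voltinism[0, 0] == summary.middle_voltinism == 5
        np.testing.assert_array_equal(out.mid_stage_code[:, 0, 0],
                                      summary.middle_stage_codes)
        np.testing.assert_allclose(out.accum_dd[:, 0, 0], trajs[0].cum_dd)
        for key, val in summary.events_earliest.items():
            assert out.events_earliest[key][0, 0] == val
            assert out.events_average[key][0, 0] == summary.events_average[key]
        for key, frac in summary.fractions.items():
            np.testing.assert_allclose(out.fractions[key][:, 0, 0], frac)

    def test_fraction_layers_sum_to_one(self, gradient_run):
        _, _, out = gradient_run
        total = sum(out.fractions.values())
        valid = ~out.nodata_mask
        np.testing.assert_allclose(total[:, valid], 1.0, atol=1e-9)

    def test_all_missing_cube_gives_nodata(self, epos):
        cube = constant_cube(17.2, n_days=30, n_rows=2, n_cols=2)
        cube.tmin[:] = np.nan
        cube.tmax[:] = np.nan
        out = pr.run_grid(cube, epos, pr.RunConfig(n_cohorts=2, sample_every=30))
        assert np.all(out.nodata_mask)
        assert np.all(out.voltinism == NODATA_INT)
        assert np.all(out.mid_stage_code == NODATA_INT)
        assert np.all(np.isnan(out.accum_dd))

    def test_band_count_with_30_day_sampling(self, gradient_run):
        _, _, out = gradient_run
        assert len(out.sample_days) == 14  # days 1, 31, ..., 361 plus day 365
        assert out.sample_days[-1] == 365
        assert out.accum_dd.shape[0] == 14

    def test_config_validation(self, epos):
        with pytest.raises(ValueError, match="sample_every"):
            pr.RunConfig(sample_every=5).validate(epos)
        with pytest.raises(ValueError, match="generation"):
            pr.RunConfig(events=[("egg", 9)]).validate(epos)
        with pytest.raises(ValueError, match="stage"):
            pr.RunConfig(events=[("imago", 0)]).validate(epos)


class TestTiling:
    def test_layouts(self):
        assert _tile_layout(1) == (1, 1)
        assert _tile_layout(4) == (2, 2)
        assert _tile_layout(9) == (3, 3)
        assert _tile_layout(6) == (2, 3)
        assert _tile_layout(5) == (1, 5)

    @pytest.mark.parametrize("n_tiles", [4, 9])
    def test_mosaic_bit_identical(self, gradient_run, epos, n_tiles):
        cube, config, ref = gradient_run
        mosaic = pr.tile_and_mosaic(cube, epos, config, n_tiles)
        assert mosaic.voltinism.tobytes() == ref.voltinism.tobytes()
        assert mosaic.accum_dd.tobytes() == ref.accum_dd.tobytes()
        assert mosaic.mid_stage_code.tobytes() == ref.mid_stage_code.tobytes()
        assert mosaic.cold_accum.tobytes() == ref.cold_accum.tobytes()
        assert mosaic.all_class.tobytes() == ref.all_class.tobytes()
        assert set(mosaic.fractions) == set(ref.fractions)
        for key in ref.fractions:
            assert mosaic.fractions[key].tobytes() == ref.fractions[key].tobytes()
        for key in ref.events_average:
            assert mosaic.events_average[key].tobytes() == ref.events_average[key].tobytes()
            assert mosaic.events_earliest[key].tobytes() == ref.events_earliest[key].tobytes()


@pytest.fixture(scope="module")
def written(gradient_run, tmp_path_factory):
    _, config, out = gradient_run
    d = tmp_path_factory.mktemp("outputs")
    files = pr.write_outputs(out, d, config, point_cells=[(0, 0)])
    return d, files


class TestWriteOutputs:
    def test_families_and_masked_variants(self, written):
        d, files = written
        assert (d / "accumdd.tif").exists()
        # accumulated degree-days are never masked
        assert "accumdd_masked-severe" not in files
        for fam in ("stage_midcohort", "voltinism"):
            assert (d / f"{fam}.tif").exists()
            assert (d / f"{fam}_masked-severe.tif").exists()
            assert (d / f"{fam}_masked-all.tif").exists()

    def test_band_labels_are_dates(self, written):
        d, _ = written
        arr, _, labels, _ = pr.read_geotiff(d / "accumdd.tif")
        assert arr.shape[0] == len(labels) == 14
        assert labels[0] == "2018-01-01" and labels[-1] == "2018-12-31"

    def test_masked_variant_uses_sentinels(self, written, gradient_run):
        d, _ = written
        _, _, out = gradient_run
        arr, _, _, _ = pr.read_geotiff(d / "voltinism_masked-all.tif")
        severe = out.all_class[-1] == 2
        moderate = out.all_class[-1] == 1
        assert np.all(arr[0][severe] == -2)
        assert np.all(arr[0][moderate] == -1)
        keep = ~(severe | moderate)
        np.testing.assert_array_equal(arr[0][keep], out.voltinism[keep])

    def test_manifest_and_pngs(self, written):
        d, files = written
        manifest = json.loads((d / "manifest.json").read_text())
        assert manifest["species"]["name"] == "Epiphyas postvittana"
        assert manifest["stage_code_legend"]["stage_index"]["egg"] == 1
        assert len(manifest["cohort_weights"]) == 7
        assert (d / "voltinism.png").exists()
        assert (d / "suitability.png").exists()
        assert (d / "point_trajectories.csv").exists()

    def test_calendar_labels(self):
        assert _doy_label(60, 2018) == "Mar-01"
        assert _doy_label(1, 2018) == "Jan-01"
        assert _doy_label(float("nan"), 2018) == "n/a"


class TestGradientGeography:
    """The qualitative continental pattern: cold limits the north,
    heat limits the south, voltinism grows southward."""

    def test_cold_band_contiguous_north(self, gradient_run):
        _, _, out = gradient_run
        cold = out.cold_class[-1]
        for c in range(cold.shape[1]):
            col = (cold[:, c] > 0).astype(int)
            assert np.all(np.diff(col) <= 0)  # once suitable, stays suitable southward
        assert (cold[0] > 0).all() and (cold[-1] == 0).all()

    def test_heat_band_contiguous_south(self, gradient_run):
        _, _, out = gradient_run
        heat = out.heat_class[-1]
        for c in range(heat.shape[1]):
            col = (heat[:, c] > 0).astype(int)
            assert np.all(np.diff(col) >= 0)
        assert (heat[-1] > 0).all() and (heat[0] == 0).all()

    def test_voltinism_nonincreasing_northward(self, gradient_run):
        _, _, out = gradient_run
        v = out.voltinism
        assert np.all(np.diff(v, axis=0) >= 0)  # row 0 = north
        assert v[-1].min() > v[0].max()
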