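"""Synthetic-scenario generator: determinism, bounds, bias construction."""

import numpy as np
import pytest

import biomefusion as bf
from biomefusion.grid import VARIABLES
from biomefusion.synthetic import bias_fields


SMALL_GEOM = bf.GridGeometry(lon_min=-75, lon_max=-55, lat_min=-12, lat_max=2, resolution=1.0)


def small_scenario(**kwargs):
    defaults = dict(seed=0, n_sites=12, geometry=SMALL_GEOM)
    defaults.update(kwargs)
    return bf.default_scenario(**defaults)


def test_same_seed_bit_identical():
    a, b = bf.generate_truth(small_scenario()), bf.generate_truth(small_scenario())
    for v in VARIABLES:
        np.testing.assert_array_equal(a.fields[v], b.fields[v])


def test_different_seed_differs():
    a = bf.generate_truth(small_scenario(seed=1))
    b = bf.generate_truth(small_scenario(seed=2))
    assert not np.allclose(a.fields["fpc"], b.fields["fpc"])


@pytest.mark.parametrize("seed", range(20))
def test_physical_bounds_for_any_seed(seed):
    truth = bf.generate_truth(small_scenario(seed=seed))
    truth.validate_bounds()
    model = bf.apply_bias(truth, small_scenario(seed=seed))
    model.validate_bounds()


def test_zero_noise_equals_trend(transforms):
    params = {
        v: bf.TrendParams(base=p.base, grad_lon=p.grad_lon, grad_lat=p.grad_lat, noise_sd=0.0)
        for v, p in small_scenario().field_params.items()
    }
    scenario = small_scenario(field_params=params)
    truth = bf.generate_truth(scenario)
    # deterministic trend for fpc, computed independently
    nx, ny = SMALL_GEOM.n_lon, SMALL_GEOM.n_lat
    x = (np.arange(nx) + 0.5) / nx - 0.5
    y = (np.arange(ny) + 0.5) / ny - 0.5
    xx, yy = np.meshgrid(x, y)
    p = params["fpc"]
    expected = transforms["fpc"].invert(p.base + p.grad_lon * xx + p.grad_lat * yy)
    np.testing.assert_allclose(truth.fields["fpc"], expected, rtol=1e-12)


def test_constant_trend_yields_single_biome(scheme):
    params = {v: bf.TrendParams(base=0.0) for v in VARIABLES}
    params["fpc"] = bf.TrendParams(base=float(np.log(0.9 / 0.1)))  # FPC = 0.9
    params["height"] = bf.TrendParams(base=float(np.log((20 / 130) / (1 - 20 / 130))))  # H = 20
    params["tropical"] = bf.TrendParams(base=1.0)
    params["evergreen"] = bf.TrendParams(base=1.0)
    params["gdd"] = bf.TrendParams(base=8.0)
    truth = bf.generate_truth(small_scenario(field_params=params))
    bmap = bf.biomise(truth, scheme)
    assert set(bmap.scheme_codes[i] for i in np.unique(bmap.codes)) == {"Thf"}


class TestApplyBias:
    def test_zero_amplitude_identity(self):
        scenario = small_scenario(bias_params={v: bf.BiasSpec() for v in VARIABLES})
        truth = bf.generate_truth(scenario)
        model = bf.apply_bias(truth, scenario)
        for v in VARIABLES:
            np.testing.assert_array_equal(model.fields[v], truth.fields[v])

    def test_constant_offset_shifts_logit_exactly(self, transforms):
        bias = {v: bf.BiasSpec() for v in VARIABLES}
        bias["fpc"] = bf.BiasSpec(offset=0.7)
        scenario = small_scenario(bias_params=bias)
        truth = bf.generate_truth(scenario)
        model = bf.apply_bias(truth, scenario)
        shift = transforms["fpc"].apply(model.fields["fpc"]) - transforms["fpc"].apply(
            truth.fields["fpc"]
        )
        np.testing.assert_allclose(shift, 0.7, rtol=1e-9)

    def test_positive_height_bias_turns_savanna_to_forest(self, scheme):
        """A big height bias makes the biomised model forest where truth is savanna."""
        params = {v: bf.TrendParams(base=0.0) for v in VARIABLES}
        params["fpc"] = bf.TrendParams(base=2.0)
        params["height"] = bf.TrendParams(base=-3.8)  # ~2.8 m: tropical savanna
        params["tropical"] = bf.TrendParams(base=1.0)
        params["gdd"] = bf.TrendParams(base=8.0)
        bias = {v: bf.BiasSpec() for v in VARIABLES}
        bias["height"] = bf.BiasSpec(offset=1.6)  # pushes height above 10 m
        scenario = small_scenario(field_params=params, bias_params=bias)
        truth = bf.generate_truth(scenario)
        model = bf.apply_bias(truth, scenario)
        assert bf.biomise(truth, scheme).code_at(3, 3) == "Ts"
        assert bf.biomise(model, scheme).code_at(3, 3) in {"Thf", "Tdf"}

    def test_bias_fields_have_requested_scale(self):
        scenario = small_scenario(seed=6)
        b = bias_fields(scenario)["height"]
        assert b.std() == pytest.approx(1.0, rel=1e-6)
        assert abs(b.mean()) < 1e-9


class TestSamplePollenSites:
    def test_labels_equal_truth_biomisation(self, scheme):
        scenario = small_scenario(seed=4)
        truth = bf.generate_truth(scenario)
        sites = bf.sample_pollen_sites(truth, scheme, scenario)
        bmap = bf.biomise(truth, scheme)
        for s in sites:
            r, c = truth.geometry.cell_of(s.lon, s.lat)
            assert s.observed_biome == bmap.code_at(r, c)

    def test_fixed_seed_reproducible(self, scheme):
        scenario = small_scenario(seed=4)
        truth = bf.generate_truth(scenario)
        s1 = bf.sample_pollen_sites(truth, scheme, scenario)
        s2 = bf.sample_pollen_sites(truth, scheme, scenario)
        assert s1 == s2

    def test_sites_are_distinct_cells_at_centres(self, scheme):
        scenario = small_scenario(seed=4, n_sites=30)
        truth = bf.generate_truth(scenario)
        sites = bf.sample_pollen_sites(truth, scheme, scenario)
        cells = {truth.geometry.cell_of(s.lon, s.lat) for s in sites}
        assert len(cells) == 30
        for s in sites:
            assert s.lon in truth.geometry.lons and s.lat in truth.geometry.lats

    def test_every_cell_when_n_sites_equals_cells(self, scheme):
        n_cells = SMALL_GEOM.n_lat * SMALL_GEOM.n_lon
        scenario = small_scenario(n_sites=n_cells)
        truth = bf.generate_truth(scenario)
        sites = bf.sample_pollen_sites(truth, scheme, scenario)
        assert len(sites) == n_cells

    def test_too_many_sites_rejected(self, scheme):
        scenario = small_scenario(n_sites=SMALL_GEOM.n_lat * SMALL_GEOM.n_lon + 1)
        truth = bf.generate_truth(scenario)
        with pytest.raises(ValueError, match="exceeds"):
            bf.sample_pollen_sites(truth, scheme, scenario)


def test_roundtrip_zero_bias_dense_sites(scheme):
    """Zero bias + a site at every cell: pipeline correction returns the truth."""
    geom = bf.GridGeometry(lon_min=-70, lon_max=-60, lat_min=-8, lat_max=0, resolution=1.0)
    scenario = bf.default_scenario(
        seed=2, geometry=geom, n_sites=geom.n_lat * geom.n_lon,
        bias_params={v: bf.BiasSpec() for v in VARIABLES},
    )
    truth = bf.generate_truth(scenario)
    model = bf.apply_bias(truth, scenario)
    sites = bf.sample_pollen_sites(truth, scheme, scenario)
    corrected = bf.correct_grid(model, sites, scheme, lam=0.0)
    for v in VARIABLES:
        np.testing.assert_allclose(corrected.fields[v], truth.fields[v], atol=1e-8)


def test_scenario_validation():
    with pytest.raises(Exception):
        small_scenario(n_sites=2)
    with pytest.raises(Exception):
        small_scenario(bias_params={"fpc": bf.BiasSpec(amplitude=np.inf)})


def test_netcdf_roundtrip(tmp_path):
    truth = bf.generate_truth(small_scenario())
    path = tmp_path / "truth.nc"
    truth.to_netcdf(path)
    loaded = bf.BioclimGrid.from_netcdf(path)
    assert loaded.geometry.shape == truth.geometry.shape
    for v in VARIABLES:
        np.testing.assert_allclose(loaded.fields[v], truth.fields[v], rtol=1e-6)
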