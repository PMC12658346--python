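"""Dose-map metrics: normalization invariance, PDD, contours, comparisons."""
import numpy as np
import pytest

from hamdose.engine import DoseMap, GridSpec
from hamdose.metrics import compare_maps, isodose_contours, pdd, prescription_dose
from hamdose.tg43 import tg43_dose_map


def _mk_map(grid, dose, nb=6):
    batches = np.repeat(dose[None], nb, axis=0)
    return DoseMap(grid, dose, np.zeros_like(dose), batches, 1000)


@pytest.fixture(scope="module")
def rx_map():
    grid = GridSpec.prescription_column(0.1)
    rng = np.random.default_rng(3)
    dose = 1.0 + 0.01 * rng.standard_normal(grid.shape)
    return _mk_map(grid, dose)


def test_prescription_dose_self_normalization(rx_map):
    mask = rx_map.prescription_region_mask()
    norm = rx_map.dose[mask].mean()
    pct, se = prescription_dose(rx_map, norm)
    assert pct == pytest.approx(100.0, abs=1e-9)
    assert se == pytest.approx(0.0, abs=1e-12)


def test_prescription_dose_linearity(rx_map):
    mask = rx_map.prescription_region_mask()
    norm = rx_map.dose[mask].mean()
    doubled = _mk_map(rx_map.grid, 2 * rx_map.dose)
    assert prescription_dose(doubled, norm)[0] == pytest.approx(200.0)


def test_prescription_region_outside_grid_is_error():
    grid = GridSpec((5.0, 5.0, 5.0), (0.1, 0.1, 0.1), (3, 3, 3))
    m = _mk_map(grid, np.ones(grid.shape))
    with pytest.raises(ValueError):
        prescription_dose(m, 1.0)


def test_pdd_reference_depth_is_100(dataset_small, template):
    grid = GridSpec.lateral_plane(0.2)
    vals = tg43_dose_map(dataset_small, template, grid, subsample=2)
    m = _mk_map(grid, vals)
    norm = vals[m.prescription_region_mask()].mean()
    table = pdd(m, norm)
    at_1cm = table.loc[np.isclose(table.depth_cm, 1.0), "dose_pct"].iloc[0]
    assert at_1cm == pytest.approx(100.0, rel=1e-9)


def test_pdd_strictly_decreasing_beyond_prescription(dataset_small, template):
    """Physical monotonicity of the depth dose in water past 1 cm."""
    grid = GridSpec.lateral_plane(0.2)
    vals = tg43_dose_map(dataset_small, template, grid, subsample=2)
    m = _mk_map(grid, vals)
    norm = vals[m.prescription_region_mask()].mean()
    table = pdd(m, norm)
    deep = table[table.depth_cm >= 1.0]
    assert np.all(np.diff(deep.dose_pct) < 0)


def test_isodose_constant_map_has_no_contours():
    grid = GridSpec((-2.0, 0.0, -0.05), (0.1, 0.1, 0.1), (40, 40, 1))
    m = _mk_map(grid, np.ones(grid.shape))
    out = isodose_contours(m, 1.0, levels=(0.5,))
    assert out[0.5] == []


def test_isodose_radial_symmetry_and_scale_equivariance():
    grid = GridSpec((-2.0, -2.0, -0.05), (0.1, 0.1, 0.1), (40, 40, 1))
    cx = grid.centers(0)
    cy = grid.centers(1)
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    dose = np.exp(-(X**2 + Y**2))[:, :, None]
    m = _mk_map(grid, dose)
    polys = isodose_contours(m, 1.0, levels=(0.5,))[0.5]
    assert len(polys) == 1
    r = np.hypot(polys[0][:, 0], polys[0][:, 1])
    assert np.abs(r - np.sqrt(np.log(2))).max() < 0.05
    # contour of level L on map M == contour of level L on k*M with norm k
    m2 = _mk_map(grid, 3.0 * dose)
    polys2 = isodose_contours(m2, 3.0, levels=(0.5,))[0.5]
    assert np.allclose(polys[0], polys2[0])


def test_compare_identical_maps_is_zero(rx_map):
    out = compare_maps(rx_map, rx_map.dose, 1.0, 1.0, floor=0.05)
    assert out["max_rel_dev_pct"] == 0.0


def test_compare_constructed_offset(rx_map):
    out = compare_maps(rx_map, rx_map.dose / 1.01, 1.0, 1.0, floor=0.05)
    assert out["max_rel_dev_pct"] == pytest.approx(1.0, rel=1e-9)


def test_compare_grid_mismatch_is_error(rx_map):
    with pytest.raises(ValueError):
        compare_maps(rx_map, np.ones((2, 2, 2)), 1.0, 1.0)


def test_metrics_invariant_under_common_rescaling(rx_map):
    mask = rx_map.prescription_region_mask()
    norm = rx_map.dose[mask].mean()
    k = 7.3
    scaled = _mk_map(rx_map.grid, k * rx_map.dose)
    assert prescription_dose(scaled, k * norm)[0] == pytest.approx(
        prescription_dose(rx_map, norm)[0])
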