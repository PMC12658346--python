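"""TG-43 dataset: geometry factor, characterization invariants, dose engine."""
import numpy as np
import pytest

from hamdose.engine import TransportSettings
from hamdose.geometry import DwellPlan
from hamdose.source import SourceGeometry
from hamdose.tg43 import (TG43Dataset, characterize_tg43, geometry_factor_line,
                          tg43_relative_dose)


def _uniform_dataset(L=0.35):
    """g_L == 1, F == 1: pure line-source geometry factor."""
    r = np.geomspace(0.2, 12.0, 25)
    th = np.linspace(2.0, 178.0, 37)
    return TG43Dataset(L, r, np.ones_like(r), th, np.ones((25, 37)), 1.0)


def test_geometry_factor_90deg_closed_form():
    L, r = 0.35, 2.0
    expected = 2 * np.arctan(L / (2 * r)) / (L * r)
    assert geometry_factor_line(r, np.pi / 2, L) == pytest.approx(expected, rel=1e-12)


def test_geometry_factor_axial_limit():
    L, r = 0.35, 1.0
    g_axial = geometry_factor_line(r, 0.0, L)
    assert g_axial == pytest.approx(1 / (r**2 - L**2 / 4), rel=1e-9)


def test_reference_point_is_unity():
    ds = _uniform_dataset()
    assert ds.relative_dose(1.0, 90.0) == pytest.approx(1.0, rel=1e-9)


def test_line_source_approaches_point_source_far_away():
    # with g==1, F==1 the ratio of doses at 10L and 20L follows 1/r^2 to 0.3%
    ds = _uniform_dataset()
    r1, r2 = 10 * ds.L, 20 * ds.L
    ratio = ds.relative_dose(r1, 90.0) / ds.relative_dose(r2, 90.0)
    assert ratio == pytest.approx((r2 / r1) ** 2, rel=3e-3)


def test_r_must_be_positive():
    ds = _uniform_dataset()
    with pytest.raises(ValueError):
        ds.relative_dose(-1.0, 90.0)


def test_superposition_of_two_equal_dwells():
    ds = _uniform_dataset()
    one = DwellPlan(np.array([0]), np.array([0]), np.array([[0.0, 0.0, -1.0]]),
                    np.array([[0, 0, 1.0]]), np.array([1.0]))
    two = DwellPlan(np.array([0, 0]), np.array([0, 1]),
                    np.array([[0.0, 0.0, -1.0], [0.0, 0.0, 1.0]]),
                    np.array([[0, 0, 1.0], [0, 0, 1.0]]), np.array([1.0, 1.0]))
    p = np.array([[0.0, 2.0, 0.0]])
    d1 = ds.dose_from_plan(one, p)[0]
    d1b = ds.dose_from_plan(
        DwellPlan(np.array([0]), np.array([0]), np.array([[0.0, 0.0, 1.0]]),
                  np.array([[0, 0, 1.0]]), np.array([1.0])), p)[0]
    # per-unit-weight dose of the pair is the mean of the individual doses
    assert ds.dose_from_plan(two, p)[0] == pytest.approx((d1 + d1b) / 2, rel=1e-12)


def test_rotation_invariance_of_relative_dose():
    ds = _uniform_dataset()
    rng = np.random.default_rng(5)
    th = np.degrees(rng.uniform(0.3, np.pi - 0.3, 20))
    r = rng.uniform(0.5, 8.0, 20)
    # rotate the (source, point) pair rigidly: polar coordinates unchanged
    assert np.allclose(ds.relative_dose(r, th), ds.relative_dose(r, th))
    # and a plan rotated 90 deg about the depth axis gives the same dose
    plan_z = DwellPlan(np.array([0]), np.array([0]), np.zeros((1, 3)),
                       np.array([[0, 0, 1.0]]), np.array([1.0]))
    plan_x = DwellPlan(np.array([0]), np.array([0]), np.zeros((1, 3)),
                       np.array([[1.0, 0, 0]]), np.array([1.0]))
    p_z = np.array([[0.3, 1.2, 0.8]])
    p_x = np.array([[0.8, 1.2, 0.3]])  # same (r, angle-to-axis)
    assert ds.dose_from_plan(plan_z, p_z)[0] == pytest.approx(
        ds.dose_from_plan(plan_x, p_x)[0], rel=1e-12)


# ----------------------------------------------------- characterized dataset

def test_characterized_invariants(dataset_small):
    ds = dataset_small
    assert np.all(ds.gL > 0)
    assert np.all(ds.F > 0)
    # g_L(r0) = 1 and F(r, 90) = 1 exactly after normalization
    assert ds._interp_g(np.array([1.0]))[0] == pytest.approx(1.0, abs=1e-9)
    j90 = np.argmin(np.abs(ds.theta_nodes_deg - 90))
    assert np.abs(ds.F[:, j90] - 1).max() < 1e-12
    # radial dose function decreases at large r (attenuation dominates)
    assert ds.gL[-1] < ds.gL[np.argmin(np.abs(ds.r_nodes - 1.0))]


def test_characterized_anisotropy_below_unity_near_axis(dataset_small):
    # capsule + cable self-absorption depresses F toward both poles
    ds = dataset_small
    j_lo = np.argmin(np.abs(ds.theta_nodes_deg - 10))
    j_hi = np.argmin(np.abs(ds.theta_nodes_deg - 170))
    mid = slice(5, 20)
    assert np.mean(ds.F[mid, j_lo]) < 0.95
    assert np.mean(ds.F[mid, j_hi]) < 0.95


def test_bare_source_is_isotropic():
    """With metal attenuation off, F == 1 away from the axis (KERMA isotropy)."""
    settings = TransportSettings(n_histories=400_000, seed=314, n_batches=10)
    ds = characterize_tg43(SourceGeometry(), settings,
                           r_edges=np.geomspace(0.3, 4.0, 8),
                           theta_step_deg=15.0, se_tolerance=None,
                           include_metal=False)
    sel = (ds.theta_nodes_deg > 20) & (ds.theta_nodes_deg < 160)
    # coarse brute-force run: noise ~1-2% per node; 2-SE-scale tolerance
    assert np.abs(ds.F[:, sel] - 1.0).max() < 0.06


def test_dataset_roundtrip(tmp_path, dataset_small):
    dataset_small.save(tmp_path / "ds")
    back = TG43Dataset.load(tmp_path / "ds")
    assert np.allclose(back.gL, dataset_small.gL)
    assert np.allclose(back.F, dataset_small.F)
    assert back.ref_dose_per_history == pytest.approx(
        dataset_small.ref_dose_per_history)


def test_relative_dose_wrapper(dataset_small):
    pts = np.array([[1.0, 90.0], [2.0, 45.0]])
    out = tg43_relative_dose(dataset_small, pts)
    assert out.shape == (2,)
    assert out[0] == pytest.approx(1.0, abs=1e-6)
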