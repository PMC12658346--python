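"""Applicator template, parabola arc-length machinery, bending, grid deformation."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar

from hamdose.geometry import (ApplicatorSpec, CurvatureSpec, DwellPlan,
                              arclength_to_x, bend_plan, build_flat_plan_template,
                              cable_polylines, deform_scoring_grid,
                              parabola_arclength, project_to_parabola,
                              radius_of_curvature)
from hamdose.source import SourceGeometry


def _arc_quad(a, x):
    return quad(lambda t: math.sqrt(1 + 4 * a * a * t * t), 0, x, limit=200)[0]


# ------------------------------------------------------------- plan template

def test_default_template_has_102_dwells(template, app_spec):
    assert template.n_dwells == 102
    assert app_spec.dwells_per_catheter == 17
    counts = np.bincount(template.catheter_index)
    assert np.all(counts == 17)


def test_template_symmetric_about_origin(template):
    assert np.abs(template.positions.mean(axis=0)).max() < 1e-12


def test_degenerate_single_dwell_template():
    spec = ApplicatorSpec(n_catheters=1, treatment_length=0.0)
    plan = build_flat_plan_template(spec)
    assert plan.n_dwells == 1
    assert np.allclose(plan.positions[0], 0.0)


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        ApplicatorSpec(flap_thickness=0.9)  # offsets no longer sum to thickness
    with pytest.raises(ValueError):
        ApplicatorSpec(treatment_length=8.3)  # not a multiple of the dwell step
    with pytest.raises(ValueError):
        ApplicatorSpec(catheter_spacing=0.15)  # catheters would overlap


# ---------------------------------------------------------------- arc length

@pytest.mark.parametrize("a,x", [(0.09, 4.0), (0.25, -3.0), (0.54, 2.5)])
def test_arclength_closed_form_vs_quadrature(a, x):
    assert parabola_arclength(a, x) == pytest.approx(_arc_quad(a, x), abs=1e-8)


def test_arclength_flat_limit():
    assert parabola_arclength(0.0, 3.7) == 3.7


@settings(deadline=None, derandomize=True, max_examples=60)
@given(a=st.floats(0.0, 1.0), x=st.floats(-5.0, 5.0))
def test_arclength_roundtrip_and_oddness(a, x):
    s = parabola_arclength(a, x)
    assert arclength_to_x(a, s) == pytest.approx(x, abs=1e-9)
    assert parabola_arclength(a, -x) == pytest.approx(-s, abs=1e-12)


def test_radius_of_curvature_values():
    assert radius_of_curvature(0.54) == pytest.approx(0.926, abs=5e-4)
    assert radius_of_curvature(0.09) == pytest.approx(1 / 0.18)
    assert radius_of_curvature(0.0) == math.inf
    aa = np.linspace(0.05, 1.0, 10)
    rr = [radius_of_curvature(a) for a in aa]
    assert np.all(np.diff(rr) < 0)
    with pytest.raises(ValueError):
        radius_of_curvature(-0.1)


# ------------------------------------------------------------------- bending

def test_bend_identity_at_zero_curvature(template):
    bent = bend_plan(template, CurvatureSpec(0.0, "lateral"))
    assert np.abs(bent.positions - template.positions).max() < 1e-12


@pytest.mark.parametrize("orient", ["lateral", "longitudinal"])
def test_bend_preserves_arc_separation(template, orient):
    a = 0.54
    bent = bend_plan(template, CurvatureSpec(a, orient))
    iu = 0 if orient == "lateral" else 2
    s = parabola_arclength(a, bent.positions[:, iu])
    flat_u = template.positions[:, iu]
    assert np.abs(s - flat_u).max() < 1e-9


def test_bend_negative_curvature_rejected(template):
    with pytest.raises(ValueError):
        CurvatureSpec(-0.1, "lateral")


def test_outermost_catheter_depth_displacement_oracle(template):
    # flat lateral offset 2.5 cm is arc length; invert with an independent
    # quadrature + root-finding oracle and check the depth drop y = a x(s)^2
    a = 0.54
    bent = bend_plan(template, CurvatureSpec(a, "lateral"))
    outer = bent.positions[template.positions[:, 0] == 2.5]
    x_star = brentq(lambda x: _arc_quad(a, x) - 2.5, 0, 2.5)
    assert outer[0, 0] == pytest.approx(x_star, abs=1e-8)
    assert outer[0, 1] == pytest.approx(-a * x_star**2, abs=1e-8)


def test_longitudinal_axes_follow_tangent(template):
    a = 0.25
    bent = bend_plan(template, CurvatureSpec(a, "longitudinal"))
    t = bent.positions[:, 2]
    tang = np.column_stack([np.zeros_like(t), -2 * a * t, np.ones_like(t)])
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    assert np.abs(bent.axes - tang).max() < 1e-12


def test_cable_polyline_follows_bent_curve(template):
    a, src = 0.54, SourceGeometry()
    cables = cable_polylines(template, CurvatureSpec(a, "longitudinal"), src)
    pts = cables[0]  # most proximal dwell
    # every cable point lies on the parabola y = -a z^2 at its catheter's x
    assert np.abs(pts[:, 1] + a * pts[:, 2] ** 2).max() < 1e-9
    assert np.allclose(pts[:, 0], template.positions[0, 0])
    # arc step between consecutive points is the requested 0.5 cm
    s = parabola_arclength(a, pts[:, 2])
    assert np.abs(np.diff(s) + 0.5).max() < 1e-9


# ----------------------------------------------------------- grid deformation

def test_deform_identity_at_zero_curvature():
    pts = np.random.default_rng(0).uniform(-3, 3, (50, 3))
    mapped, excl = deform_scoring_grid(pts, CurvatureSpec(0.0, "lateral"))
    assert np.abs(mapped - pts).max() == 0.0
    assert not excl.any()


def test_deformed_surface_points_lie_on_parabola():
    a = 0.25
    u = np.linspace(-3, 3, 13)
    pts = np.column_stack([u, np.zeros_like(u), np.full_like(u, 0.7)])
    mapped, _ = deform_scoring_grid(pts, CurvatureSpec(a, "lateral"))
    assert np.abs(mapped[:, 1] + a * mapped[:, 0] ** 2).max() < 1e-9
    assert np.abs(mapped[:, 2] - 0.7).max() < 1e-12


def test_deformation_preserves_distance_to_bent_surface():
    # (u=2, d=1) must land exactly 1 cm from the curve (nearest-point oracle)
    a = 0.25
    mapped, _ = deform_scoring_grid(np.array([[2.0, 1.0, 0.0]]),
                                    CurvatureSpec(a, "lateral"))
    px, py = mapped[0, 0], mapped[0, 1]

    def dist(t):
        return math.hypot(t - px, -a * t * t - py)

    res = minimize_scalar(dist, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-12})
    assert res.fun == pytest.approx(1.0, abs=1e-6)


def test_fold_over_voxels_flagged():
    # far on the concave (upstream) side, beyond the radius of curvature
    a = 0.54  # R = 0.926 cm
    pts = np.array([[0.0, -3.0, 0.0], [0.0, 1.0, 0.0]])
    _, excl = deform_scoring_grid(pts, CurvatureSpec(a, "lateral"))
    assert excl.tolist() == [True, False]


@settings(deadline=None, derandomize=True, max_examples=60)
@given(a=st.floats(0.01, 0.8), u=st.floats(-4, 4), w=st.floats(-4, 4))
def test_projection_reconstructs_the_point(a, u, w):
    t, s, d = project_to_parabola(a, u, w)
    q = 2 * a * t
    sn = math.sqrt(1 + q * q)
    # P(t) + d * nhat(t) must reproduce (u, w)
    ur = t + d * q / sn
    wr = -a * t * t + d / sn
    assert ur == pytest.approx(u, abs=1e-7)
    assert wr == pytest.approx(w, abs=1e-7)
    # and d must be the true minimum distance (scan oracle)
    tt = np.linspace(-8, 8, 4001)
    dmin = np.min(np.hypot(tt - u, -a * tt * tt - w))
    assert abs(d) <= dmin + 1e-3
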