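"""MC engine: transport oracles (inverse-square, Beer-Lambert) and contracts
(determinism, allocation, symmetry, backscatter sign, error scaling)."""
import numpy as np
import pytest

from hamdose.engine import (GridSpec, PhantomSpec, Scene, TransportSettings,
                            allocate_histories, characterization_run,
                            run_simulation)
from hamdose.geometry import ApplicatorSpec, DwellPlan
from hamdose.materials import Material, MaterialLibrary
from hamdose.spectrum import GammaSpectrum
from hamdose.source import SourceGeometry
from hamdose import _kernels


def _single_dwell_plan():
    return DwellPlan(np.array([0]), np.array([0]), np.zeros((1, 3)),
                     np.array([[0.0, 0.0, 1.0]]), np.array([1.0]))


def _vacuum_library():
    rho = 1e-12
    return MaterialLibrary(
        water=Material("w", {"H": 0.1119, "O": 0.8881}, rho),
        air=Material("a", {"N": 0.7552, "O": 0.2320, "Ar": 0.0128}, rho),
        silicone=Material("s", {"O": 1.0}, rho),
        hdpe=Material("p", {"C": 1.0}, rho),
        iridium=Material("i", {"Ir": 1.0}, rho),
        steel=Material("f", {"Fe": 1.0}, rho),
    )


def test_zero_length_traversal_scores_nothing():
    acc = np.zeros((3, 3, 3))
    _kernels._score_grid(0.1, 0.1, 0.1, 1.0, 0.0, 0.0, 0.0, 5.0,
                        0.0, 0.0, 0.0, 0.1, 0.1, 0.1, 3, 3, 3, acc)
    assert acc.sum() == 0.0


def test_inverse_square_in_vacuum():
    """Energy fluence from an isotropic point-like source follows 1/(4 pi r^2)."""
    lib = _vacuum_library()
    scene = Scene(phantom=PhantomSpec("infinite"), applicator=None,
                  water_only=True, library=lib)
    spec = GammaSpectrum(np.array([316.51]), np.array([1.0]))
    r_edges = np.geomspace(0.3, 6.0, 12)
    th_edges = np.linspace(0.0, np.pi, 10)
    settings = TransportSettings(n_histories=100_000, seed=27, n_batches=5)
    geom = SourceGeometry(active_length=1e-4, active_radius=1e-5,
                          capsule_outer_radius=2e-5, capsule_length=2e-4)
    dose, _, _ = characterization_run(_single_dwell_plan(), scene, r_edges,
                                      th_edges, settings, spectrum=spec,
                                      source=geom, include_metal=False)
    # volume-weighted shell mean ~ 1/r_eff^2 by construction of the node radii
    ct = np.cos(th_edges)
    shell = (2 * np.pi / 3) * (r_edges[1:] ** 3 - r_edges[:-1] ** 3)
    vol = shell[:, None] * (ct[:-1] - ct[1:])[None, :]
    d_r = (dose * vol).sum(axis=1) / vol.sum(axis=1)
    r1, r2 = r_edges[:-1], r_edges[1:]
    r_eff2 = (r1 * r1 + r1 * r2 + r2 * r2) / 3.0
    flat = d_r * r_eff2
    assert flat.max() / flat.min() - 1 < 0.01


def test_primary_beam_attenuates_per_beer_lambert(library):
    """Never-scattered fluence beyond t cm of water decays as exp(-mu t)."""
    scene = Scene(phantom=PhantomSpec("infinite"), applicator=None, water_only=True)
    grid = GridSpec((-0.1, 0.0, -0.1), (0.2, 0.5, 0.2), (1, 20, 1))
    settings = TransportSettings(n_histories=400_000, seed=91, n_batches=5)
    m = run_simulation(_single_dwell_plan(), scene, [grid], settings,
                       include_metal=False,
                       pencil=((0.0, -2.0, 0.0), (0.0, 1.0, 0.0), 316.51),
                       primary_only=True)[0]
    d = m.dose[0, :, 0]
    y = m.grid.centers(1)
    slope = np.polyfit(y, np.log(d), 1)[0]
    mu = library.water.mu_linear(316.51)
    assert slope == pytest.approx(-mu, rel=0.01)


def test_history_allocation_largest_remainder():
    t = np.array([1.0, 2.0, 1.0])
    n = allocate_histories(t, 10)
    assert n.sum() == 10
    assert np.all(np.abs(n - 10 * t / t.sum()) <= 1.0)
    with pytest.raises(ValueError):
        allocate_histories(np.zeros(3), 10)
    with pytest.raises(ValueError):
        allocate_histories(np.array([-1.0, 2.0]), 10)


@pytest.fixture(scope="module")
def small_scene(app_spec):
    return Scene(phantom=PhantomSpec("infinite"), applicator=app_spec,
                 water_only=True)


def test_fixed_seed_is_bit_reproducible(template, small_scene):
    st = TransportSettings(n_histories=100_000, seed=5, n_batches=5)
    g = GridSpec.prescription_column(0.1)
    a = run_simulation(template, small_scene, [g], st)[0]
    b = run_simulation(template, small_scene, [g], st)[0]
    assert np.array_equal(a.batch_doses, b.batch_doses)


def test_doubling_all_dwell_times_changes_nothing(template, small_scene):
    st = TransportSettings(n_histories=100_000, seed=6, n_batches=5)
    g = GridSpec.prescription_column(0.1)
    a = run_simulation(template, small_scene, [g], st)[0]
    b = run_simulation(template.with_times(2 * template.times), small_scene,
                       [g], st)[0]
    assert np.array_equal(a.dose, b.dose)


def test_single_active_dwell_gets_full_budget(small_scene, template):
    st = TransportSettings(n_histories=80_000, seed=8, n_batches=4)
    g = GridSpec.prescription_column(0.1)
    times = np.zeros(template.n_dwells)
    times[30] = 1.0
    a = run_simulation(template.with_times(times), small_scene, [g], st)[0]
    solo = DwellPlan(np.array([0]), np.array([0]),
                     template.positions[[30]], template.axes[[30]],
                     np.array([1.0]))
    b = run_simulation(solo, small_scene, [g], st)[0]
    assert np.array_equal(a.dose, b.dose)


def test_central_plane_mirror_symmetry(template, small_scene):
    """A symmetric flat plan yields laterally mirror-symmetric dose."""
    st = TransportSettings(n_histories=1_000_000, seed=12, n_batches=20)
    g = GridSpec.lateral_plane(0.2)
    m = run_simulation(template, small_scene, [g], st)[0]
    d, s = m.dose[:, :, 0], m.se[:, :, 0]
    z = np.abs(d - d[::-1]) / np.sqrt(s**2 + s[::-1] ** 2 + 1e-300)
    assert np.mean(z > 3.0) < 0.01
    assert z.mean() < 1.5


def test_semi_infinite_dose_never_exceeds_infinite(template, app_spec):
    """Backscatter can only add dose: paired runs, 3 SE per voxel."""
    st = TransportSettings(n_histories=600_000, seed=13, n_batches=20)
    g = GridSpec.prescription_column(0.1)
    inf = run_simulation(template, Scene(PhantomSpec("infinite"), app_spec), [g], st)[0]
    semi = run_simulation(template, Scene(PhantomSpec("semi_infinite"), app_spec),
                          [g], st)[0]
    diff = inf.batch_doses - semi.batch_doses  # common random numbers
    mean = diff.mean(axis=0)
    se = diff.std(axis=0, ddof=1) / np.sqrt(diff.shape[0])
    assert np.all(mean > -3 * se)


def test_standard_error_scales_as_inverse_sqrt_n(template, small_scene):
    g = GridSpec.prescription_column(0.1)
    budgets = [200_000, 1_200_000, 6_400_000]
    ses = []
    for n in budgets:
        st = TransportSettings(n_histories=n, seed=14, n_batches=50)
        m = run_simulation(template, small_scene, [g], st)[0]
        ses.append(m.region_mean(m.prescription_region_mask())[1])
    slope = np.polyfit(np.log(budgets), np.log(ses), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.1)


def test_rayleigh_channel_is_a_small_perturbation(template, small_scene):
    g = GridSpec.prescription_column(0.1)
    vals = []
    for ray in (False, True):
        st = TransportSettings(n_histories=2_000_000, seed=15, n_batches=20,
                               rayleigh=ray)
        m = run_simulation(template, small_scene, [g], st)[0]
        vals.append(m.region_mean(m.prescription_region_mask())[0])
    assert abs(vals[1] / vals[0] - 1) < 0.015


def test_dwell_outside_world_is_geometry_error(template, app_spec):
    scene = Scene(PhantomSpec("infinite", world_half=3.0), app_spec)
    st = TransportSettings(n_histories=1000, seed=1, n_batches=2)
    with pytest.raises(ValueError):
        run_simulation(template, scene, [GridSpec.prescription_column()], st)
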