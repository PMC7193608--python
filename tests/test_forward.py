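import numpy as np
import pytest

from shuntfield import forward, geometry as g
from shuntfield.geometry import ConfigurationError

from conftest import BENCH_RADII, axial_pair_montage, fibonacci_sphere


@pytest.fixture(scope="module")
def slab():
    cs = g.optimized_conductivities().with_updates(brain=0.0988)
    return g.build_slab([("scalp", 4.0), ("skull", 4.0), ("brain", 40.0)], cs)


def test_slab_series_resistor(slab):
    sol = forward.solve_slab(slab, 1.0)  # J = 1 A/m^2
    assert sol.field_in("brain") == pytest.approx(1.0 / 0.0988, rel=1e-12)
    assert sol.field_in("scalp") == pytest.approx(1.0 / 0.0004, rel=1e-12)
    # interface potentials drop monotonically from outside to inside
    assert np.all(np.diff(sol.interface_potentials_V) < 0)
    assert sol.interface_potentials_V[-1] == pytest.approx(0.0)
    with pytest.raises(ConfigurationError):
        sol.field_in("csf")


def test_shell_series_matches_homogeneous_closed_form():
    sources = [forward.ShellPointSource((0, 0, 1.0), 45.0, 2.0),
               forward.ShellPointSource((1.0, 0, 0), 45.0, -2.0)]
    pts = fibonacci_sphere(30, 25.0)
    v_series, ok = forward.analytic_shell_potential([45.0], [0.3], sources, pts,
                                                    n_max=400)
    assert ok
    v_closed = forward.homogeneous_sphere_potential(45.0, 0.3, sources, pts)
    assert np.linalg.norm(v_series - v_closed) <= 1e-6 * np.linalg.norm(v_closed)


def test_shell_series_interior_source_via_shell_split():
    # a source strictly inside a shell is handled by splitting the shell with
    # an equal-conductivity interface; a homogeneous sphere is the oracle
    src = [forward.ShellPointSource((0, 0, 1.0), 20.0, 1.0),
           forward.ShellPointSource((0, 0, -1.0), 20.0, -1.0)]
    pts = fibonacci_sphere(30, 10.0)
    v_split, ok = forward.analytic_shell_potential([45.0], [0.5], src, pts,
                                                   n_max=400)
    assert ok
    # oracle: same sphere described as two concentric equal-sigma shells
    v_two, ok2 = forward.analytic_shell_potential([20.0, 45.0], [0.5, 0.5],
                                                  src, pts, n_max=400)
    assert ok2
    assert np.allclose(v_split, v_two, rtol=1e-10, atol=1e-12)


def test_shell_solution_linearity_and_superposition(shell_model):
    montage = g.place_montage(shell_model, [
        g.ElectrodePatch((0, 0, 45.0), 0.5, "scalp-surface", "active", 1.0),
        g.ElectrodePatch((0, 0, -45.0), 0.5, "scalp-surface", "reference", -1.0),
    ])
    sol = forward.solve_potential(shell_model, montage)
    doubled = g.place_montage(shell_model, [
        g.ElectrodePatch((0, 0, 45.0), 0.5, "scalp-surface", "active", 2.0),
        g.ElectrodePatch((0, 0, -45.0), 0.5, "scalp-surface", "reference", -2.0),
    ])
    sol2 = forward.solve_potential(shell_model, doubled)
    pts = fibonacci_sphere(20, 30.0)
    assert np.allclose(sol2.potential_at(pts), 2 * sol.potential_at(pts),
                       rtol=1e-12)


def test_skull_surface_sources_sit_on_skull_interface(shell_model):
    montage = g.place_montage(shell_model, [
        g.ElectrodePatch((0, 0, 41.0), 0.5, "skull-surface", "active", 1.0),
        g.ElectrodePatch((0, 0, -41.0), 0.5, "skull-surface", "reference", -1.0),
    ])
    sol = forward.solve_shell_montage(shell_model, montage)
    assert all(s.radius_mm == 41.0 for s in sol.sources)


def test_voxel_solver_requirements(phantom_h2):
    montage = axial_pair_montage(phantom_h2, "scalp-surface", BENCH_RADII[-1])
    with pytest.raises(ConfigurationError):
        forward.solve_voxel_potential(
            g.build_shell_model(list(BENCH_RADII), phantom_h2.conductivities),
            montage)
    symbolic = g.Montage(model=phantom_h2, patches=montage.patches,
                         footprints=None)
    with pytest.raises(ConfigurationError):
        forward.solve_voxel_potential(phantom_h2, symbolic)


def test_voxel_solution_residual_and_gauge(tes_solution_h2):
    # CG converges on the Jacobi-scaled system at rtol 1e-8; the reported
    # residual is re-measured on the unscaled system, so allow the
    # conductivity-contrast factor
    assert tes_solution_h2.residual <= 1e-6
    # the potential is NaN in air, finite inside the conductor (which, with
    # partial-volume fractions, extends slightly past the centre labels)
    assert np.all(np.isfinite(
        tes_solution_h2.potential[tes_solution_h2.model.labels > 0]))
    conducting = tes_solution_h2.model.conductivity_grid() > 0
    assert np.all(~np.isfinite(tes_solution_h2.potential[~conducting]))
    # reference gauge: some node near the reference patch reads ~0
    assert np.nanmin(np.abs(tes_solution_h2.potential)) == 0.0


def test_masked_gradient_of_linear_ramp():
    # potential ramp of 1 mV per mm along x -> uniform 1 mV/mm field
    cs = g.default_conductivities()
    model = g.build_voxel_head((20, 20, 20), {"scalp": 4, "skull": 4, "csf": 4},
                               2.0, cs, gray_thickness_mm=None)
    xs, _, _ = model.voxel_centers()
    ramp = np.broadcast_to(xs[:, None, None] * 1e-3,
                           model.labels.shape).copy()  # volts
    ramp[model.labels == 0] = np.nan
    sol = forward.VoxelSolution(model, None, ramp, residual=0.0, iterations=0)
    ex, ey, ez = sol.field
    inside = model.labels > 0
    assert np.allclose(ex[inside], -1.0, atol=1e-9)
    assert np.allclose(ey[inside], 0.0, atol=1e-9)
    assert np.allclose(sol.field_magnitude[inside], 1.0, atol=1e-9)
    assert np.allclose(sol.field_component((1, 0, 0))[inside], -1.0, atol=1e-9)


def test_strip_pair_fields_uniform_field():
    # uniform 1 mV/mm along the strip -> 5 mV between adjacent contacts
    pots_V = np.arange(8) * 5.0 * 1e-3
    pairs = forward.strip_pair_fields(pots_V, spacing_mm=5.0)
    assert np.allclose(pairs, 1.0)


def test_field_along_strip_voxel_vs_shell(phantom_h2, tes_solution_h2,
                                          shell_model):
    strip = g.StripSpec((-17.5, 0.0, 30.0), (1.0, 0.0, 0.0))
    pots = forward.field_along_strip(tes_solution_h2, strip)
    assert pots.shape == (8,)
    montage = g.place_montage(shell_model, [
        g.ElectrodePatch((0, 0, 45.0), 0.5, "scalp-surface", "active", 1.0),
        g.ElectrodePatch((0, 0, -45.0), 0.5, "scalp-surface", "reference", -1.0),
    ])
    sol = forward.solve_potential(shell_model, montage)
    pots_shell = forward.field_along_strip(sol, strip)
    assert pots_shell.shape == (8,)
    # the montage is symmetric about the strip's midpoint, so the sampled
    # profile must be mirror symmetric (exactly for the series solution)
    assert np.allclose(pots_shell, pots_shell[::-1], rtol=1e-8)
    assert np.allclose(pots, pots[::-1], rtol=0.05, atol=1e-6)


def test_sample_potential_outside_grid_raises(tes_solution_h2):
    with pytest.raises(ConfigurationError):
        forward.sample_potential(tes_solution_h2, [(0.0, 0.0, 60.0)])


def test_depth_profile_validation(ses_solution_h2):
    profile = forward.depth_profile(ses_solution_h2, (0, 0, 30.0), (0, 0, -1.0),
                                    20.0, step_mm=2.0)
    assert len(profile.depths_mm) == len(profile.values_mV_per_mm)
    with pytest.raises(ConfigurationError):
        forward.DepthProfile(np.array([0.0, 0.0, 1.0]), np.zeros(3))


def test_plane_current_is_zero_outside_the_dipole(tes_solution_h2):
    # a plane above both electrodes crosses no net current
    nz = tes_solution_h2.model.labels.shape[2]
    top = forward.plane_current(tes_solution_h2, 2, nz - 2)
    assert abs(top) <= 1e-3 * 0.01
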