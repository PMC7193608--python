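"""Shared fixtures: the benchmark phantom and its forward solutions.

The voxel solves at 1 mm are the expensive pieces of the suite, so every
solution is session-scoped and shared between the module tests and the
acceptance tests.
"""

import numpy as np
import pytest

from shuntfield import forward, geometry


BENCH_RADII = (33.0, 37.0, 41.0, 45.0)  # brain / csf / skull / scalp outer radii
BENCH_THICKNESS = {"scalp": 4.0, "skull": 4.0, "csf": 4.0}


def fibonacci_sphere(n: int, radius_mm: float) -> np.ndarray:
    """Deterministic, roughly uniform points on a sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return radius_mm * np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def build_benchmark_phantom(voxel_size_mm: float,
                            conductivities=None) -> geometry.TissueModel:
    """Spherical 4-shell voxel phantom matching the analytic shell oracle."""
    cs = conductivities or geometry.optimized_conductivities()
    return geometry.build_voxel_head(
        (BENCH_RADII[-1],) * 3, dict(BENCH_THICKNESS), voxel_size_mm, cs,
        gray_thickness_mm=None,
    )


def axial_pair_montage(model, attachment: str, radius_mm: float,
                       current_mA: float = 1.0, axis=(0.0, 0.0, 1.0),
                       area_cm2: float = 0.5) -> geometry.Montage:
    """Opposed active/reference patch pair along ``axis``."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    return geometry.place_montage(model, [
        geometry.ElectrodePatch(tuple(radius_mm * u), area_cm2, attachment,
                                "active", current_mA),
        geometry.ElectrodePatch(tuple(-radius_mm * u), area_cm2, attachment,
                                "reference", -current_mA),
    ])


@pytest.fixture(scope="session")
def phantom_h2():
    return build_benchmark_phantom(2.0)


@pytest.fixture(scope="session")
def phantom_h1():
    return build_benchmark_phantom(1.0)


@pytest.fixture(scope="session")
def tes_montage_h2(phantom_h2):
    return axial_pair_montage(phantom_h2, "scalp-surface", BENCH_RADII[-1])


@pytest.fixture(scope="session")
def ses_montage_h2(phantom_h2):
    return axial_pair_montage(phantom_h2, "skull-surface", BENCH_RADII[-2])


@pytest.fixture(scope="session")
def tes_solution_h2(phantom_h2, tes_montage_h2):
    return forward.solve_voxel_potential(phantom_h2, tes_montage_h2)


@pytest.fixture(scope="session")
def ses_solution_h2(phantom_h2, ses_montage_h2):
    return forward.solve_voxel_potential(phantom_h2, ses_montage_h2)


@pytest.fixture(scope="session")
def tes_solution_h1(phantom_h1):
    montage = axial_pair_montage(phantom_h1, "scalp-surface", BENCH_RADII[-1])
    return forward.solve_voxel_potential(phantom_h1, montage)


@pytest.fixture(scope="session")
def ses_solution_h1(phantom_h1):
    montage = axial_pair_montage(phantom_h1, "skull-surface", BENCH_RADII[-2])
    return forward.solve_voxel_potential(phantom_h1, montage)


@pytest.fixture(scope="session")
def shell_model():
    return geometry.build_shell_model(list(BENCH_RADII),
                                      geometry.default_conductivities())


@pytest.fixture(scope="session")
def oracle_points():
    return fibonacci_sphere(50, 30.0)
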