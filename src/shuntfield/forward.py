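"""Quasi-static volume-conduction forward solvers.

Solves the resistive Laplace problem ``div(sigma grad V) = 0`` with
current-injection sources, on three geometries:

* layered slab — closed-form series-resistor solution (1-D oracle),
* concentric spherical shells — Legendre-series transfer-matrix solution with
  point monopole sources on shell interfaces,
* voxel grid — 7-point finite-difference discretization with harmonic-mean
  face conductivities, solved by preconditioned conjugate gradients.

The model is purely resistive, so solutions are frequency independent and
exactly linear in the injected current.  Potentials are in volts, electric
fields in mV/mm (1 V/m == 1 mV/mm), distances in mm, currents in mA at the
interface and amperes internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg
from scipy.special import eval_legendre

from .geometry import (
    ConfigurationError,
    Montage,
    StripSpec,
    TissueModel,
)

__all__ = [
    "SolverError",
    "SlabSolution",
    "ShellSolution",
    "VoxelSolution",
    "DepthProfile",
    "ShellPointSource",
    "solve_potential",
    "solve_slab",
    "solve_voxel_potential",
    "solve_shell_montage",
    "analytic_shell_potential",
    "montage_point_sources",
    "homogeneous_sphere_potential",
    "sample_potential",
    "sample_field_magnitude",
    "field_along_strip",
    "strip_pair_fields",
    "depth_profile",
    "plane_current",
]


class SolverError(RuntimeError):
    """Raised when a forward solve cannot be completed."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# Slab (1-D series-resistor) solution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlabSolution:
    """Uniform current density through a layered slab.

    ``layer_fields_mV_per_mm[l] = J / sigma_l`` and the potential drops
    linearly within each layer; the gauge is V = 0 at the innermost boundary.
    """

    model: TissueModel
    current_density_A_m2: float
    layer_fields_mV_per_mm: np.ndarray
    interface_potentials_V: np.ndarray  # outermost boundary first, length n+1

    def field_in(self, tissue: str) -> float:
        for (name, _), e in zip(self.model.layers, self.layer_fields_mV_per_mm):
            if name == tissue:
                return float(e)
        raise ConfigurationError(f"slab has no layer {tissue!r}")


def solve_slab(model: TissueModel, current_density_A_m2: float) -> SlabSolution:
    """Closed-form solve for a uniform normal current density J (A/m²)."""
    if model.kind != "slab":
        raise ConfigurationError("solve_slab requires a slab model")
    sig = np.array([model.sigma(t) for t, _ in model.layers])
    th = np.array([t for _, t in model.layers], dtype=float)
    fields = current_density_A_m2 / sig  # V/m == mV/mm
    # V drop across layer l: E_l (V/m) * thickness (m)
    drops = fields * th * 1e-3
    pot = np.concatenate([[drops.sum()], drops.sum() - np.cumsum(drops)])
    return SlabSolution(model, current_density_A_m2, fields, pot)


# ---------------------------------------------------------------------------
# Analytic N-shell Legendre-series solution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShellPointSource:
    """Point current monopole on a shell interface (or the outer surface)."""

    direction: tuple  # unit-ish vector from the origin
    radius_mm: float
    current_mA: float

    @property
    def unit(self) -> np.ndarray:
        u = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(u)
        if n == 0:
            raise ConfigurationError("source direction must be non-zero")
        return u / n

    @property
    def position_mm(self) -> np.ndarray:
        return self.unit * self.radius_mm


def _interface_step(n, rho, sig_from, sig_to, A, B):
    """Continuity of V and sigma dV/dr across an interface at normalized
    radius rho: coefficients (A, B) in the `from` shell -> (A', B') in `to`."""
    rn = rho ** n
    rm = rho ** (-(n + 1.0))
    u = A * rn + B * rm
    # sigma * rho * dV/drho per mode (common 1/r factors cancel in the 2x2)
    w = sig_from * (n * A * rn - (n + 1.0) * B * rm)
    # solve [rn, rm; sig_to*n*rn, -sig_to*(n+1)*rm] [A'; B'] = [u; w]
    det = -sig_to * (2.0 * n + 1.0) * rn * rm
    A2 = (u * (-sig_to * (n + 1.0) * rm) - rm * w) / det
    B2 = (rn * w - sig_to * n * rn * u) / det
    return A2, B2


class _ShellSeries:
    """Per-source Legendre coefficients for an N-shell conductor."""

    def __init__(self, radii_mm, sigmas, source_radius_mm, current_mA,
                 n_max=300, series_tol=1e-10):
        radii = np.asarray(radii_mm, dtype=float)
        sigmas = np.asarray(sigmas, dtype=float)
        if np.any(np.diff(radii) <= 0) or radii[0] <= 0:
            raise ConfigurationError("shell radii must be positive, strictly increasing")
        if np.any(sigmas <= 0):
            raise ConfigurationError("shell conductivities must be > 0")
        self.radii = radii
        self.sigmas = sigmas
        self.n_max = int(n_max)
        self.series_tol = float(series_tol)
        k = int(np.argmin(np.abs(radii - source_radius_mm)))
        if abs(radii[k] - source_radius_mm) > 1e-9 * radii[-1]:
            raise ConfigurationError(
                f"source radius {source_radius_mm} mm must lie on a shell interface "
                f"(radii {radii.tolist()})"
            )
        self.source_shell = k  # source sits on the outer surface of shell k
        N = len(radii)
        R = radii[-1]
        n = np.arange(1, self.n_max + 1, dtype=float)
        I_A = current_mA * 1e-3
        R_m = R * 1e-3

        coef = np.zeros((N, self.n_max, 2))
        if k == N - 1:
            # source on the outer surface
            A, B = np.ones_like(n), np.zeros_like(n)
            coef[0, :, 0], coef[0, :, 1] = A, B
            for j in range(N - 1):
                rho = radii[j] / R
                A, B = _interface_step(n, rho, sigmas[j], sigmas[j + 1], A, B)
                s = np.maximum(np.abs(A), np.abs(B))
                s[s == 0] = 1.0
                A, B = A / s, B / s
                coef[: j + 1] /= s[None, :, None]
                coef[j + 1, :, 0], coef[j + 1, :, 1] = A, B
            denom = sigmas[-1] * (n * A - (n + 1.0) * B)
            c = I_A * (2.0 * n + 1.0) / (4.0 * np.pi * R_m * denom)
            coef *= c[None, :, None]
        else:
            # source on the interface between shells k and k+1
            inner = np.zeros((k + 1, self.n_max, 2))
            A, B = np.ones_like(n), np.zeros_like(n)
            inner[0, :, 0], inner[0, :, 1] = A, B
            for j in range(k):
                rho = radii[j] / R
                A, B = _interface_step(n, rho, sigmas[j], sigmas[j + 1], A, B)
                s = np.maximum(np.abs(A), np.abs(B))
                s[s == 0] = 1.0
                A, B = A / s, B / s
                inner[: j + 1] /= s[None, :, None]
                inner[j + 1, :, 0], inner[j + 1, :, 1] = A, B
            a_in, b_in = A, B

            outer = np.zeros((N - 1 - k, self.n_max, 2))  # shells k+1 .. N-1
            # outer boundary: zero radial current at rho = 1
            Ao, Bo = (n + 1.0), n.copy()
            outer[-1, :, 0], outer[-1, :, 1] = Ao, Bo
            for j in range(N - 2, k, -1):
                rho = radii[j] / R
                Ao, Bo = _interface_step(n, rho, sigmas[j + 1], sigmas[j], Ao, Bo)
                s = np.maximum(np.abs(Ao), np.abs(Bo))
                s[s == 0] = 1.0
                Ao, Bo = Ao / s, Bo / s
                outer[j - k:] /= s[None, :, None]
                outer[j - k - 1, :, 0], outer[j - k - 1, :, 1] = Ao, Bo
            a_out, b_out = Ao, Bo

            rho_k = radii[k] / R
            rn = rho_k ** n
            rm = rho_k ** (-(n + 1.0))
            u_in = a_in * rn + b_in * rm
            u_out = a_out * rn + b_out * rm
            r_k_m = radii[k] * 1e-3
            dv = lambda a, b: (n * a * rn / rho_k - (n + 1.0) * b * rm / rho_k) / R_m
            s_n = I_A * (2.0 * n + 1.0) / (4.0 * np.pi * r_k_m ** 2)
            # alpha * u_in = beta * u_out ; sig_k dVin - sig_{k+1} dVout = s_n
            p = sigmas[k] * dv(a_in, b_in)
            q = sigmas[k + 1] * dv(a_out, b_out)
            det = u_in * q - u_out * p
            with np.errstate(divide="ignore", invalid="ignore"):
                alpha = -u_out * s_n / det
                beta = -u_in * s_n / det
            coef[: k + 1] = inner * alpha[None, :, None]
            coef[k + 1:] = outer * beta[None, :, None]

        self.coef = coef  # (N_shells, n_max, 2)
        self.R = R

    def shell_of(self, r: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.radii, r, side="left").clip(0, len(self.radii) - 1)

    def evaluate(self, r_mm: np.ndarray, cos_gamma: np.ndarray):
        """Potential (V) at radius r and polar angle gamma from the source.

        Returns ``(V, converged)`` where ``converged`` is False if the last
        series term still contributes more than ``series_tol`` relatively.
        """
        r = np.asarray(r_mm, dtype=float)
        mu = np.asarray(cos_gamma, dtype=float)
        if np.any(r > self.radii[-1] * (1 + 1e-9)):
            raise ConfigurationError("evaluation point outside the outer shell")
        n = np.arange(1, self.n_max + 1, dtype=float)
        rho = (r / self.R).clip(0.0, 1.0)
        shell = self.shell_of(r)
        A = self.coef[shell][:, :, 0]  # (P, n_max)
        B = self.coef[shell][:, :, 1]
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            rad = A * rho[:, None] ** n[None, :]
            centre = rho == 0
            rm = np.zeros_like(rad)
            rm[~centre] = rho[~centre, None] ** (-(n[None, :] + 1.0))
            # where B is exactly zero (regularity at the centre) the growing
            # term is absent even if rho**-(n+1) overflows
            rad = rad + np.where(B == 0.0, 0.0, B * rm)
        P = eval_legendre(np.arange(1, self.n_max + 1)[None, :], mu[:, None])
        terms = rad * P
        V = terms.sum(axis=1)
        tail = np.abs(terms[:, -1])
        scale = np.maximum(np.abs(V), 1e-300)
        converged = bool(np.all(tail / scale < max(self.series_tol, 1e-14) * 1e2) or
                         np.all(tail < 1e-15))
        return V, converged


def analytic_shell_potential(
    radii_mm: Sequence[float],
    sigmas: Sequence[float],
    sources: Sequence[ShellPointSource],
    points_mm: np.ndarray,
    n_max: int = 300,
    series_tol: float = 1e-10,
):
    """Superposed Legendre-series potential of point monopoles on an N-shell
    sphere, evaluated at arbitrary interior points.

    Returns ``(V, converged)``; ``V`` in volts.  Raises if a point coincides
    with a source.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    V = np.zeros(len(pts))
    converged = True
    radii = np.asarray(radii_mm, dtype=float)
    sig = np.asarray(sigmas, dtype=float)
    for src in sources:
        d = np.linalg.norm(pts - src.position_mm, axis=1)
        if np.any(d < 1e-9):
            raise ConfigurationError("evaluation point coincides with a source")
        with np.errstate(invalid="ignore"):
            mu = np.where(r > 0, pts @ src.unit / np.where(r > 0, r, 1.0), 0.0)
        rs = float(src.radius_mm)
        if np.min(np.abs(radii - rs)) <= 1e-9 * radii[-1]:
            radii_s, sig_s = radii, sig
        else:
            # source strictly inside a shell: split that shell with an
            # artificial equal-conductivity interface at the source radius
            if rs >= radii[-1]:
                raise ConfigurationError("source radius outside the outer shell")
            k = int(np.searchsorted(radii, rs, side="left"))
            radii_s = np.insert(radii, k, rs)
            sig_s = np.insert(sig, k, sig[k])
        series = _ShellSeries(radii_s, sig_s, rs, src.current_mA,
                              n_max=n_max, series_tol=series_tol)
        v, ok = series.evaluate(r, mu)
        V += v
        converged = converged and ok
    return V, converged


def montage_point_sources(model: TissueModel, montage: Montage
                          ) -> list[ShellPointSource]:
    """Analytic point sources matching a voxel montage's rasterized footprints.

    Each footprint voxel becomes one monopole at the voxel centre with its
    share of the patch current, so an analytic shell reference solves the
    same discrete source configuration as the finite-difference system.
    """
    if model.kind != "voxels" or montage.footprints is None:
        raise ConfigurationError("montage_point_sources requires a voxel "
                                 "montage with rasterized footprints")
    xs, ys, zs = model.voxel_centers()
    shape = model.labels.shape
    sources = []
    for vox, cur in montage.footprints.values():
        ii = np.unravel_index(vox, shape)
        p = np.stack([xs[ii[0]], ys[ii[1]], zs[ii[2]]], axis=1)
        rad = np.linalg.norm(p, axis=1)
        for pos, rs, c in zip(p, rad, cur):
            if rs < 1e-9:
                raise ConfigurationError("footprint voxel at the origin")
            sources.append(ShellPointSource(tuple(pos / rs), float(rs),
                                            float(c) * 1e3))
    return sources


def homogeneous_sphere_potential(
    radius_mm: float,
    sigma: float,
    sources: Sequence[ShellPointSource],
    points_mm: np.ndarray,
) -> np.ndarray:
    """Closed-form interior potential of surface monopoles on a homogeneous
    sphere (independent oracle for the series solution)."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    rho = r / radius_mm
    R_m = radius_mm * 1e-3
    V = np.zeros(len(pts))
    for src in sources:
        if abs(src.radius_mm - radius_mm) > 1e-9 * radius_mm:
            raise ConfigurationError("closed form requires sources on the outer surface")
        with np.errstate(invalid="ignore"):
            mu = np.where(r > 0, pts @ src.unit / np.where(r > 0, r, 1.0), 0.0)
        d = np.sqrt(1.0 - 2.0 * rho * mu + rho ** 2)
        if np.any(d < 1e-12):
            raise ConfigurationError("evaluation point coincides with a source")
        I_A = src.current_mA * 1e-3
        V += I_A / (4 * np.pi * sigma * R_m) * (
            2.0 / d - 2.0 + np.log(2.0 / (1.0 - rho * mu + d))
        )
    return V


class ShellSolution:
    """Forward solution on a concentric-shell model (lazy series evaluation)."""

    def __init__(self, model: TissueModel, montage: Montage,
                 sources: Sequence[ShellPointSource],
                 n_max: int = 300, series_tol: float = 1e-10):
        self.model = model
        self.montage = montage
        self.sources = tuple(sources)
        self.n_max = n_max
        self.series_tol = series_tol
        self.converged = True
        self._series = [
            _ShellSeries(model.shell_radii(), model.shell_sigmas(),
                         s.radius_mm, s.current_mA, n_max, series_tol)
            for s in self.sources
        ]

    def potential_at(self, points_mm) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        r = np.linalg.norm(pts, axis=1)
        V = np.zeros(len(pts))
        for src, series in zip(self.sources, self._series):
            d = np.linalg.norm(pts - src.position_mm, axis=1)
            if np.any(d < 1e-9):
                raise ConfigurationError("evaluation point coincides with a source")
            mu = np.where(r > 0, pts @ src.unit / np.where(r > 0, r, 1.0), 0.0)
            v, ok = series.evaluate(r, mu)
            V += v
            self.converged = self.converged and ok
        return V

    def field_at(self, points_mm, step_mm: float = 0.05) -> np.ndarray:
        """Electric field vector (mV/mm) by central differencing the series."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        E = np.zeros_like(pts)
        for ax in range(3):
            d = np.zeros(3)
            d[ax] = step_mm
            E[:, ax] = -(self.potential_at(pts + d) - self.potential_at(pts - d)) \
                / (2 * step_mm) * 1e3
        return E

    def field_magnitude_at(self, points_mm) -> np.ndarray:
        return np.linalg.norm(self.field_at(points_mm), axis=1)


def _shell_source_radius(model: TissueModel, attachment: str) -> float:
    names = [t for t, _ in model.shells]
    radii = model.shell_radii()
    if attachment == "scalp-surface":
        if names[-1] != "scalp":
            raise ConfigurationError("scalp-surface patch on a model without outer scalp")
        return float(radii[-1])
    if "skull" not in names:
        raise ConfigurationError("skull-surface patch on a model without a skull shell")
    return float(radii[names.index("skull")])


def solve_shell_montage(model: TissueModel, montage: Montage,
                        n_max: int = 300, series_tol: float = 1e-10) -> ShellSolution:
    """Analytic solve of a patch montage on a shell model.

    Patches are reduced to point monopoles at their centre directions:
    scalp-surface patches inject on the outer surface, skull-surface patches
    on the outer skull interface (under the scalp when the scalp is present).
    """
    sources = [
        ShellPointSource(
            direction=tuple(p.direction),
            radius_mm=_shell_source_radius(model, p.attachment),
            current_mA=p.current_mA,
        )
        for p in montage.patches
    ]
    return ShellSolution(model, montage, sources, n_max=n_max, series_tol=series_tol)


# ---------------------------------------------------------------------------
# Voxel finite-difference solver
# ---------------------------------------------------------------------------

@dataclass
class VoxelSolution:
    """FDM potential on a voxel grid (volts; NaN outside the conductor)."""

    model: TissueModel
    montage: Montage
    potential: np.ndarray
    residual: float
    iterations: int

    @cached_property
    def field(self) -> tuple:
        """(Ex, Ey, Ez) in mV/mm from masked central differences."""
        return _masked_gradient_field(self.potential, self.model.voxel_size_mm)

    @cached_property
    def field_magnitude(self) -> np.ndarray:
        ex, ey, ez = self.field
        return np.sqrt(ex ** 2 + ey ** 2 + ez ** 2)

    def field_component(self, direction) -> np.ndarray:
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        ex, ey, ez = self.field
        return ex * u[0] + ey * u[1] + ez * u[2]

    def scaled(self, factor: float) -> "VoxelSolution":
        """Solution for the same montage with every patch current multiplied
        by ``factor``; the problem is linear so the potential scales exactly."""
        return VoxelSolution(self.model, self.montage.scaled(factor),
                             self.potential * factor,
                             self.residual, self.iterations)


def _masked_gradient_field(V: np.ndarray, h_mm: float) -> tuple:
    """E = -grad V with central differences inside the conductor and
    one-sided differences against the air boundary.  Potential in volts,
    output in mV/mm."""
    valid = np.isfinite(V)
    Vf = np.where(valid, V, 0.0)
    comps = []
    for ax in range(3):
        fwd_v = np.roll(valid, -1, axis=ax)
        bwd_v = np.roll(valid, 1, axis=ax)
        # roll wraps around; kill wrapped entries at the array edges
        edge_hi = [slice(None)] * 3
        edge_hi[ax] = -1
        edge_lo = [slice(None)] * 3
        edge_lo[ax] = 0
        fwd_v[tuple(edge_hi)] = False
        bwd_v[tuple(edge_lo)] = False
        fwd = np.roll(Vf, -1, axis=ax)
        bwd = np.roll(Vf, 1, axis=ax)
        grad = np.full(V.shape, np.nan)
        both = valid & fwd_v & bwd_v
        grad[both] = (fwd[both] - bwd[both]) / (2 * h_mm)
        only_f = valid & fwd_v & ~bwd_v
        grad[only_f] = (fwd[only_f] - Vf[only_f]) / h_mm
        only_b = valid & ~fwd_v & bwd_v
        grad[only_b] = (Vf[only_b] - bwd[only_b]) / h_mm
        isolated = valid & ~fwd_v & ~bwd_v
        grad[isolated] = 0.0
        comps.append(-grad * 1e3)
    return tuple(comps)


def _face_conductance(sigma: np.ndarray, axis: int, h_m: float,
                      model: TissueModel | None = None):
    """Conductance of the faces between consecutive cells along ``axis``.

    With face area fractions on the model the conductivity is the mixture
    sampled on the face plane itself (staggered-grid coefficient sampling:
    series composition emerges from successive faces along a column while
    thin conductive sheets stay fully connected tangentially); otherwise
    the harmonic mean of the two adjacent cell conductivities.
    """
    sl1 = [slice(None)] * 3
    sl2 = [slice(None)] * 3
    sl1[axis] = slice(None, -1)
    sl2[axis] = slice(1, None)
    s1 = sigma[tuple(sl1)]
    s2 = sigma[tuple(sl2)]
    both = (s1 > 0) & (s2 > 0)
    if model is not None and model.face_fractions is not None:
        sf = model.face_conductivity_grids()[axis]
        both = both & (sf > 0)
        g = np.where(both, sf * h_m, 0.0)
    else:
        g = np.zeros_like(s1)
        g[both] = 2.0 * s1[both] * s2[both] / (s1[both] + s2[both]) * h_m
    return g, both, tuple(sl1), tuple(sl2)


def solve_voxel_potential(
    model: TissueModel,
    montage: Montage,
    tolerance: float = 1e-8,
    max_iterations: int = 5000,
) -> VoxelSolution:
    """Finite-difference solve on a voxel model.

    Air (sigma = 0) is excluded from the system rather than given a tiny
    conductivity.  Face conductances come from the conductivity sampled on
    the face plane when the model stores face area fractions (accurate for
    thin curved layers); otherwise from the harmonic mean of the adjacent
    cell conductivities, which respects series composition across layer
    boundaries.  The gauge pins a current-free interior node (exact for
    balanced sources) and the reported potentials are shifted so the node
    nearest the reference patch centroid reads zero; the SPD system is
    solved by Jacobi-scaled conjugate gradients to a relative residual of
    ``tolerance`` (deterministic, no randomized components).
    """
    if model.kind != "voxels":
        raise ConfigurationError("solve_voxel_potential requires a voxel model")
    if montage.footprints is None:
        raise ConfigurationError("montage has no rasterized footprints")

    sigma = model.conductivity_grid()
    mask = sigma > 0

    # keep only the connected component holding the electrodes
    struct = ndimage.generate_binary_structure(3, 1)
    comp, _ = ndimage.label(mask, structure=struct)
    foot_all = np.concatenate([idx for idx, _ in montage.footprints.values()])
    comp_ids = np.unique(comp.ravel()[foot_all])
    if len(comp_ids) != 1 or comp_ids[0] == 0:
        raise SolverError("electrode patches are not connected by a conducting path")
    maskc = comp == comp_ids[0]

    idx = -np.ones(model.labels.shape, dtype=np.int64)
    n_nodes = int(maskc.sum())
    idx[maskc] = np.arange(n_nodes)

    h_m = model.voxel_size_mm * 1e-3
    rows, cols, vals = [], [], []
    diag = np.zeros(n_nodes)
    for axis in range(3):
        g, both, sl1, sl2 = _face_conductance(sigma, axis, h_m, model)
        m = both & maskc[sl1] & maskc[sl2]
        i = idx[sl1][m]
        j = idx[sl2][m]
        gg = g[m]
        rows.append(i)
        cols.append(j)
        vals.append(-gg)
        rows.append(j)
        cols.append(i)
        vals.append(-gg)
        np.add.at(diag, i, gg)
        np.add.at(diag, j, gg)
    rows.append(np.arange(n_nodes))
    cols.append(np.arange(n_nodes))
    vals.append(diag)
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_nodes, n_nodes),
    ).tocsr()

    b = np.zeros(n_nodes)
    for pi, (vox, cur) in montage.footprints.items():
        node = idx.ravel()[vox]
        keep = node >= 0
        if not np.all(keep):
            raise SolverError("part of a patch footprint is outside the conductor")
        np.add.at(b, node, cur)

    # cells whose faces all sampled as non-conducting are isolated; they can
    # carry no current and are dropped from the system
    isolated = diag == 0.0
    if np.any(isolated & (b != 0.0)):
        raise SolverError("a patch footprint voxel is electrically isolated")

    # Gauge: pin a current-free conducting node.  For balanced sources the
    # reduced system is then exactly equivalent to the singular one; pinning
    # a node that carries source current would let part of that current
    # escape through the ground and introduce a spurious monopole.
    free = np.flatnonzero((b == 0.0) & ~isolated)
    if free.size == 0:
        raise SolverError("no current-free node available for the gauge pin")
    xs, ys, zs = model.voxel_centers()
    cand = np.argwhere(maskc)
    pts = np.stack([xs[cand[:, 0]], ys[cand[:, 1]], zs[cand[:, 2]]], axis=1)
    center = pts.mean(axis=0)
    d2 = np.einsum("ij,ij->i", pts - center, pts - center)
    order = idx[maskc]  # node index per cand row (arange by construction)
    freemask = np.zeros(n_nodes, dtype=bool)
    freemask[free] = True
    sel = freemask[order]
    pin = order[sel][np.argmin(d2[sel])]

    keep = ~isolated
    keep[pin] = False
    Ar = A[keep][:, keep].tocsr()
    br = b[keep]

    # symmetric Jacobi scaling: absorbs the tissue-conductivity contrast into
    # the diagonal, after which plain CG converges rapidly
    dscale = 1.0 / np.sqrt(Ar.diagonal())
    D = sparse.diags(dscale)
    As = (D @ Ar @ D).tocsr()
    bs = dscale * br
    it = [0]

    def _count(_):
        it[0] += 1

    y, info = cg(As, bs, rtol=tolerance, atol=0.0, maxiter=max_iterations,
                 callback=_count)
    x = dscale * y
    res = float(np.linalg.norm(Ar @ x - br) / np.linalg.norm(br))
    if info != 0:
        raise SolverError(
            f"conjugate gradients did not converge in {max_iterations} iterations "
            f"(relative residual {res:.3e})",
            residual=res,
        )

    Vnodes = np.zeros(n_nodes)
    Vnodes[keep] = x
    Vnodes[isolated] = np.nan
    # report potentials relative to the reference patch centroid
    ref_pi = next(
        (i for i, p in enumerate(montage.patches) if p.role == "reference"), 0
    )
    ref_center = np.asarray(montage.patches[ref_pi].center_mm, dtype=float)
    dref = np.linalg.norm(pts - ref_center, axis=1)
    dref[isolated[order]] = np.inf
    Vnodes -= Vnodes[order[np.argmin(dref)]]
    V = np.full(model.labels.shape, np.nan)
    V[maskc] = Vnodes
    return VoxelSolution(model, montage, V, residual=res, iterations=it[0])


def plane_current(solution: VoxelSolution, axis: int, index: int) -> float:
    """Total current (A) crossing the grid plane between slices ``index`` and
    ``index + 1`` along ``axis`` (positive towards increasing index)."""
    model = solution.model
    sigma = model.conductivity_grid()
    h_m = model.voxel_size_mm * 1e-3
    g, both, sl1, sl2 = _face_conductance(sigma, axis, h_m, model)
    V1 = solution.potential[sl1]
    V2 = solution.potential[sl2]
    take = [slice(None)] * 3
    take[axis] = index
    take = tuple(take)
    gg = g[take]
    dv = V1[take] - V2[take]
    ok = both[take] & np.isfinite(dv)
    return float(np.sum(gg[ok] * dv[ok]))


# ---------------------------------------------------------------------------
# Dispatch, strip sampling and depth profiles
# ---------------------------------------------------------------------------

def solve_potential(model: TissueModel, montage: Montage,
                    tolerance: float = 1e-8, max_iterations: int = 5000):
    """Solve the volume-conduction problem on any supported geometry."""
    if model.kind == "voxels":
        return solve_voxel_potential(model, montage, tolerance, max_iterations)
    if model.kind == "shells":
        return solve_shell_montage(model, montage)
    if model.kind == "slab":
        area_m2 = sum(p.area_cm2 for p in montage.patches if p.current_mA > 0) * 1e-4
        I_A = montage.total_active_current_mA * 1e-3
        return solve_slab(model, I_A / area_m2)
    raise ConfigurationError(f"unknown model kind {model.kind!r}")


def _trilinear(values: np.ndarray, model: TissueModel, points_mm) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    h = model.voxel_size_mm
    o = np.asarray(model.origin_mm)
    f = (pts - o) / h - 0.5  # fractional voxel-centre coordinates
    out = np.empty(len(pts))
    shape = values.shape
    for pi, fc in enumerate(f):
        i0 = np.floor(fc).astype(int)
        if np.any(i0 < 0) or np.any(i0 + 1 >= shape):
            raise ConfigurationError("interpolation point outside the grid")
        w = fc - i0
        acc = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    v = values[i0[0] + dx, i0[1] + dy, i0[2] + dz]
                    if not np.isfinite(v):
                        raise ConfigurationError(
                            "interpolation stencil touches non-conducting voxels"
                        )
                    wx = w[0] if dx else 1 - w[0]
                    wy = w[1] if dy else 1 - w[1]
                    wz = w[2] if dz else 1 - w[2]
                    acc += v * wx * wy * wz
        out[pi] = acc
    return out


def sample_potential(solution, points_mm) -> np.ndarray:
    """Potential (V) at arbitrary interior points: trilinear interpolation on
    voxel solutions, direct series evaluation on shell solutions."""
    if isinstance(solution, VoxelSolution):
        return _trilinear(solution.potential, solution.model, points_mm)
    if isinstance(solution, ShellSolution):
        return solution.potential_at(points_mm)
    raise ConfigurationError("point sampling needs a voxel or shell solution")


def sample_field_magnitude(solution, points_mm) -> np.ndarray:
    """|E| (mV/mm) at arbitrary interior points."""
    if isinstance(solution, VoxelSolution):
        return _trilinear(solution.field_magnitude, solution.model, points_mm)
    if isinstance(solution, ShellSolution):
        return solution.field_magnitude_at(points_mm)
    raise ConfigurationError("point sampling needs a voxel or shell solution")


def field_along_strip(solution, strip: StripSpec) -> np.ndarray:
    """Potentials (V) at the strip contact centres, by trilinear interpolation
    on voxel solutions or direct series evaluation on shell solutions."""
    pts = strip.contact_centers()
    if isinstance(solution, VoxelSolution):
        return _trilinear(solution.potential, solution.model, pts)
    if isinstance(solution, ShellSolution):
        return solution.potential_at(pts)
    raise ConfigurationError("strip sampling needs a voxel or shell solution")


def strip_pair_fields(contact_potentials_V: np.ndarray,
                      spacing_mm: float = 5.0) -> np.ndarray:
    """Adjacent-pair field magnitudes in mV/mm from contact potentials in V."""
    v_mV = np.asarray(contact_potentials_V, dtype=float) * 1e3
    return np.abs(np.diff(v_mV)) / spacing_mm


@dataclass(frozen=True)
class DepthProfile:
    """Field magnitude sampled along a line into the brain."""

    depths_mm: np.ndarray
    values_mV_per_mm: np.ndarray
    truncated: bool = False

    def __post_init__(self):
        if np.any(np.diff(self.depths_mm) <= 0):
            raise ConfigurationError("depths must be strictly increasing")
        if len(self.depths_mm) != len(self.values_mV_per_mm):
            raise ConfigurationError("depths and values must have the same length")


def depth_profile(solution, surface_point_mm, direction, max_depth_mm: float,
                  step_mm: float = 1.0) -> DepthProfile:
    """Sample |E| from ``surface_point`` along ``direction`` (into the head)."""
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    depths = np.arange(0.0, max_depth_mm + step_mm / 2, step_mm)
    pts = np.asarray(surface_point_mm, dtype=float) + np.outer(depths, u)
    if isinstance(solution, ShellSolution):
        vals = solution.field_magnitude_at(pts)
        return DepthProfile(depths, vals, truncated=False)
    if isinstance(solution, VoxelSolution):
        vals = []
        truncated = False
        for p in pts:
            try:
                vals.append(_trilinear(solution.field_magnitude, solution.model, p)[0])
            except ConfigurationError:
                truncated = True
                break
        if not vals:
            raise ConfigurationError("profile start point is outside the conductor")
        return DepthProfile(depths[: len(vals)], np.asarray(vals), truncated=truncated)
    raise ConfigurationError("depth profiles need a voxel or shell solution")
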