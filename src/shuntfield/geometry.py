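"""Parameterized head phantoms, conductivity sets, electrode montages and strips.

Three phantom representations are supported:

* a 1-D layered slab (series-resistor oracle geometry),
* N concentric spherical shells (analytic-oracle geometry), and
* a voxelized layered ellipsoid (finite-difference geometry).

All coordinates are right-handed, in millimetres, with the model centre at the
origin.  Voxel indices are 0-based and voxel ``(i, j, k)`` spans a half-open
cube starting at ``origin_mm + (i, j, k) * voxel_size_mm``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ConductivitySet",
    "TissueModel",
    "ElectrodePatch",
    "StripSpec",
    "Montage",
    "DEFAULT_CONDUCTIVITIES",
    "OPTIMIZED_CONDUCTIVITIES",
    "default_conductivities",
    "optimized_conductivities",
    "build_slab",
    "build_shell_model",
    "build_voxel_head",
    "place_montage",
    "footprint_area_cm2",
]


class ConfigurationError(ValueError):
    """Raised when a phantom/montage configuration violates a precondition."""


# Literature conductivities in S/m.  Air is exactly zero (non-conducting);
# "brain" is an alias used by shell/slab phantoms that do not separate gray
# and white matter, and carries the gray-matter value.
DEFAULT_CONDUCTIVITIES: Mapping[str, float] = {
    "gray_matter": 0.0988,
    "white_matter": 0.0626,
    "brain": 0.0988,
    "csf": 2.0,
    "skull": 0.00227,
    "scalp": 0.0002,
    "blood": 0.659,
    "muscle": 0.321,
    "air": 0.0,
}

# Conductivities after calibrating scalp and skull against strip recordings:
# roughly twice the literature defaults for both tissues.
OPTIMIZED_CONDUCTIVITIES: Mapping[str, float] = {
    **DEFAULT_CONDUCTIVITIES,
    "skull": 0.004,
    "scalp": 0.0004,
}

_REQUIRED_TISSUES = {"scalp", "skull", "csf", "gray_matter", "white_matter"}


@dataclass(frozen=True)
class ConductivitySet:
    """Map tissue name -> conductivity (S/m) with a provenance tag.

    Invariants: every value is strictly positive except ``air`` which must be
    exactly zero; the set contains at least scalp, skull, CSF, gray matter and
    white matter.
    """

    values: Mapping[str, float]
    provenance: str = "custom"

    def __post_init__(self):
        values = dict(self.values)
        missing = _REQUIRED_TISSUES - values.keys()
        if missing:
            raise ConfigurationError(f"conductivity set missing tissues: {sorted(missing)}")
        for name, sigma in values.items():
            if name == "air":
                if sigma != 0.0:
                    raise ConfigurationError("air conductivity must be exactly 0")
            elif not sigma > 0:
                raise ConfigurationError(f"conductivity of {name!r} must be > 0, got {sigma}")
        object.__setattr__(self, "values", values)

    def __getitem__(self, tissue: str) -> float:
        try:
            return self.values[tissue]
        except KeyError:
            raise ConfigurationError(f"unknown tissue name {tissue!r}") from None

    def __contains__(self, tissue: str) -> bool:
        return tissue in self.values

    def with_updates(self, provenance: str = "custom", **sigma: float) -> "ConductivitySet":
        return ConductivitySet({**self.values, **sigma}, provenance=provenance)

    def to_json(self) -> str:
        return json.dumps(
            {"units": "S/m", "provenance": self.provenance, "conductivities": self.values},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ConductivitySet":
        obj = json.loads(text)
        return cls(obj["conductivities"], provenance=obj.get("provenance", "custom"))


def default_conductivities() -> ConductivitySet:
    """Literature (uncalibrated) conductivity set."""
    return ConductivitySet(DEFAULT_CONDUCTIVITIES, provenance="default")


def optimized_conductivities() -> ConductivitySet:
    """Conductivity set with calibrated scalp (0.0004) and skull (0.004) values."""
    return ConductivitySet(OPTIMIZED_CONDUCTIVITIES, provenance="optimized")


@dataclass(frozen=True)
class TissueModel:
    """A labelled head phantom plus its conductivity set.

    ``kind`` selects the representation:

    * ``"slab"`` — ``layers`` lists (tissue, thickness_mm) outermost first.
    * ``"shells"`` — ``shells`` lists (tissue, outer_radius_mm) innermost first.
    * ``"voxels"`` — ``labels`` is an integer grid (0 = air), ``label_map``
      maps label -> tissue, with ``voxel_size_mm`` and ``origin_mm``.
      ``fractions`` optionally maps tissue -> per-voxel volume-fraction grid
      (partial-volume antialiasing of thin curved layers); when present the
      conductivity grid is the volume-weighted mixture instead of the pure
      centre label.
    """

    kind: str
    conductivities: ConductivitySet
    layers: tuple = ()                      # slab
    shells: tuple = ()                      # shells
    labels: np.ndarray | None = None        # voxels
    label_map: Mapping[int, str] | None = None
    voxel_size_mm: float | None = None
    origin_mm: tuple | None = None
    layer_order: tuple = ()                 # voxels: tissue names outermost->innermost
    fractions: Mapping[str, np.ndarray] | None = None
    face_fractions: tuple | None = None     # per axis: tissue -> face-plane area fractions

    # -- common helpers ---------------------------------------------------
    def sigma(self, tissue: str) -> float:
        return self.conductivities[tissue]

    @property
    def total_thickness_mm(self) -> float:
        if self.kind != "slab":
            raise ConfigurationError("total_thickness_mm is defined for slab models only")
        return float(sum(t for _, t in self.layers))

    @property
    def outer_radius_mm(self) -> float:
        if self.kind != "shells":
            raise ConfigurationError("outer_radius_mm is defined for shell models only")
        return float(self.shells[-1][1])

    def shell_radii(self) -> np.ndarray:
        return np.array([r for _, r in self.shells], dtype=float)

    def shell_sigmas(self) -> np.ndarray:
        return np.array([self.sigma(t) for t, _ in self.shells], dtype=float)

    def conductivity_grid(self) -> np.ndarray:
        """Per-voxel conductivity in S/m (voxel models only).

        With ``fractions`` present this is the volume-weighted arithmetic
        mixture sum_t f_t sigma_t (air contributes zero); otherwise the pure
        centre-label conductivity.
        """
        if self.kind != "voxels":
            raise ConfigurationError("conductivity_grid is defined for voxel models only")
        if self.fractions is not None:
            sig = np.zeros(self.labels.shape, dtype=float)
            for tissue, frac in self.fractions.items():
                sig += self.sigma(tissue) * frac
            return sig
        lut = np.zeros(max(self.label_map) + 1, dtype=float)
        for lab, tissue in self.label_map.items():
            lut[lab] = self.sigma(tissue)
        return lut[self.labels]

    def face_conductivity_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis conductivity sampled on the face planes between voxels
        (S/m), from the stored face area fractions and the current
        conductivity set.  Axis ``a`` has shape reduced by one along ``a``."""
        if self.kind != "voxels" or self.face_fractions is None:
            raise ConfigurationError("model carries no face fractions")
        out = []
        for per_axis in self.face_fractions:
            sig = None
            for tissue, frac in per_axis.items():
                term = self.sigma(tissue) * frac.astype(float)
                sig = term if sig is None else sig + term
            out.append(sig)
        return tuple(out)

    def has_tissue(self, tissue: str) -> bool:
        if self.kind == "slab":
            return any(t == tissue for t, _ in self.layers)
        if self.kind == "shells":
            return any(t == tissue for t, _ in self.shells)
        present = {self.label_map[l] for l in np.unique(self.labels)}
        return tissue in present

    def scalp_removed(self) -> "TissueModel":
        """Variant with the scalp layer stripped (surgically opened condition)."""
        if self.kind == "slab":
            layers = tuple((t, th) for t, th in self.layers if t != "scalp")
            return replace(self, layers=layers)
        if self.kind == "shells":
            shells = tuple((t, r) for t, r in self.shells if t != "scalp")
            return replace(self, shells=shells)
        labels = self.labels.copy()
        scalp_labels = [l for l, t in self.label_map.items() if t == "scalp"]
        for l in scalp_labels:
            labels[labels == l] = 0
        order = tuple(t for t in self.layer_order if t != "scalp")
        fractions = self.fractions
        if fractions is not None:
            fractions = {t: f for t, f in fractions.items() if t != "scalp"}
        face_fractions = self.face_fractions
        if face_fractions is not None:
            face_fractions = tuple(
                {t: f for t, f in per_axis.items() if t != "scalp"}
                for per_axis in face_fractions
            )
        return replace(self, labels=labels, layer_order=order,
                       fractions=fractions, face_fractions=face_fractions)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.labels.shape
        h = self.voxel_size_mm
        ox, oy, oz = self.origin_mm
        x = ox + (np.arange(nx) + 0.5) * h
        y = oy + (np.arange(ny) + 0.5) * h
        z = oz + (np.arange(nz) + 0.5) * h
        return x, y, z


@dataclass(frozen=True)
class ElectrodePatch:
    """An ideal current-source patch on the scalp or skull surface.

    The physical gel + steel electrode is reduced to a uniform current density
    over the rasterized footprint; positive ``current_mA`` injects current into
    the head, and the reference patch carries the (negative) return.
    """

    center_mm: tuple
    area_cm2: float
    attachment: str  # "scalp-surface" | "skull-surface"
    role: str = "active"  # "active" | "reference"
    current_mA: float = 0.0

    def __post_init__(self):
        if self.area_cm2 <= 0:
            raise ConfigurationError("patch area must be > 0")
        if self.attachment not in ("scalp-surface", "skull-surface"):
            raise ConfigurationError(f"unknown attachment {self.attachment!r}")
        if self.role not in ("active", "reference"):
            raise ConfigurationError(f"unknown role {self.role!r}")

    @property
    def radius_mm(self) -> float:
        return float(np.sqrt(self.area_cm2 * 100.0 / np.pi))

    @property
    def direction(self) -> np.ndarray:
        c = np.asarray(self.center_mm, dtype=float)
        n = np.linalg.norm(c)
        if n == 0:
            raise ConfigurationError("patch center must not be the model origin")
        return c / n


@dataclass(frozen=True)
class StripSpec:
    """An 8-contact subdural strip: 3 mm discs at 5 mm pitch on a line.

    ``first_contact_mm`` is the centre of contact 1; ``orientation`` the unit
    vector from contact 1 towards contact 8.
    """

    first_contact_mm: tuple
    orientation: tuple
    n_contacts: int = 8
    contact_diameter_mm: float = 3.0
    spacing_mm: float = 5.0

    def __post_init__(self):
        if self.n_contacts < 2:
            raise ConfigurationError("strip needs at least 2 contacts")
        if self.spacing_mm <= 0:
            raise ConfigurationError("contact spacing must be > 0")
        u = np.asarray(self.orientation, dtype=float)
        if not np.linalg.norm(u) > 0:
            raise ConfigurationError("orientation must be a non-zero vector")

    def contact_centers(self) -> np.ndarray:
        u = np.asarray(self.orientation, dtype=float)
        u = u / np.linalg.norm(u)
        p0 = np.asarray(self.first_contact_mm, dtype=float)
        return p0 + np.outer(np.arange(self.n_contacts) * self.spacing_mm, u)


@dataclass(frozen=True)
class Montage:
    """Electrode patches bound to a model, with rasterized injection footprints.

    For voxel models ``footprints`` maps each patch index to
    ``(flat_voxel_indices, per_voxel_current_A)``; for slab/shell models the
    patches remain symbolic (point/uniform sources used by the solvers).
    """

    model: TissueModel
    patches: tuple
    footprints: Mapping[int, tuple] | None = None

    @property
    def total_active_current_mA(self) -> float:
        return float(sum(p.current_mA for p in self.patches if p.current_mA > 0))

    def scaled(self, factor: float) -> "Montage":
        patches = tuple(replace(p, current_mA=p.current_mA * factor) for p in self.patches)
        foot = None
        if self.footprints is not None:
            foot = {i: (idx, cur * factor) for i, (idx, cur) in self.footprints.items()}
        return Montage(self.model, patches, foot)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_slab(layers: Sequence[tuple], conductivities: ConductivitySet) -> TissueModel:
    """1-D layered slab, layers ordered outermost -> innermost.

    ``layers`` is a sequence of ``(tissue_name, thickness_mm)``.
    """
    if len(layers) < 2:
        raise ConfigurationError("slab needs at least 2 layers")
    for tissue, th in layers:
        if tissue not in conductivities:
            raise ConfigurationError(f"unknown tissue name {tissue!r}")
        if not th > 0:
            raise ConfigurationError(f"layer thickness of {tissue!r} must be > 0, got {th}")
    return TissueModel(kind="slab", conductivities=conductivities, layers=tuple(layers))


def build_shell_model(
    radii_mm: Sequence[float],
    conductivities: ConductivitySet,
    tissues: Sequence[str] | None = None,
) -> TissueModel:
    """Concentric spherical shells; radii are outer radii, innermost first.

    The 4-shell default maps radii to brain / CSF / skull / scalp.
    """
    radii = np.asarray(radii_mm, dtype=float)
    if radii.ndim != 1 or len(radii) < 1:
        raise ConfigurationError("radii must be a non-empty 1-D sequence")
    if np.any(np.diff(radii) <= 0) or radii[0] <= 0:
        raise ConfigurationError("radii must be positive and strictly increasing")
    if tissues is None:
        if len(radii) == 4:
            tissues = ("brain", "csf", "skull", "scalp")
        elif len(radii) == 1:
            tissues = ("brain",)
        else:
            raise ConfigurationError("tissues must be given for a non-4-shell model")
    if len(tissues) != len(radii):
        raise ConfigurationError("tissues and radii must have the same length")
    for t in tissues:
        if t not in conductivities:
            raise ConfigurationError(f"unknown tissue name {t!r}")
    shells = tuple(zip(tissues, radii.tolist()))
    return TissueModel(kind="shells", conductivities=conductivities, shells=shells)


def _paint_labels(X, Y, Z, semi, cumulative, label_of) -> np.ndarray:
    """Label each point by the innermost layer ellipsoid containing it."""
    labels = np.zeros(X.shape, dtype=np.int8)
    for t, off in cumulative:
        a = semi - off
        inside = (X / a[0]) ** 2 + (Y / a[1]) ** 2 + (Z / a[2]) ** 2 <= 1.0
        labels[inside] = label_of[t]
    return labels


def build_voxel_head(
    semi_axes_mm: Sequence[float],
    layer_thicknesses_mm: Mapping[str, float],
    voxel_size_mm: float,
    conductivities: ConductivitySet,
    gray_thickness_mm: float | None = 8.0,
    include_scalp: bool = True,
    partial_volume: int = 4,
) -> TissueModel:
    """Voxelized layered ellipsoid head phantom.

    ``semi_axes_mm`` are the outer ellipsoid semi-axes; ``layer_thicknesses_mm``
    gives uniform shell thicknesses for (by default) scalp, skull and csf from
    the outside in.  The interior is split into a gray-matter rind of
    ``gray_thickness_mm`` and a white-matter core; ``gray_thickness_mm=None``
    fills the whole interior with gray matter (a pure shell phantom).
    Everything outside the outer ellipsoid is air (label 0).

    ``partial_volume`` > 1 supersamples each voxel on a cubic subgrid and
    stores per-tissue volume fractions; the solver then uses volume-mixed
    conductivities, which removes most of the staircase bias of thin curved
    layers (the highly conductive csf sheet is otherwise under-connected
    tangentially and the interior field is overestimated by O(voxel/thickness)).
    ``partial_volume=1`` keeps pure centre labels.
    """
    semi = np.asarray(semi_axes_mm, dtype=float)
    if semi.shape != (3,) or np.any(semi <= 0):
        raise ConfigurationError("semi_axes_mm must be 3 positive values")
    order = ["scalp", "skull", "csf"] if include_scalp else ["skull", "csf"]
    for t in order:
        if t not in layer_thicknesses_mm:
            raise ConfigurationError(f"missing thickness for layer {t!r}")
        if not layer_thicknesses_mm[t] > 0:
            raise ConfigurationError(f"layer thickness of {t!r} must be > 0")
    thin = min(layer_thicknesses_mm[t] for t in order)
    if gray_thickness_mm is not None:
        thin = min(thin, gray_thickness_mm)
    if voxel_size_mm > thin / 2:
        raise ConfigurationError(
            f"voxel size {voxel_size_mm} mm too coarse to resolve the thinnest "
            f"layer ({thin} mm); need voxel size <= thickness / 2"
        )

    tissues = order + ["gray_matter"]
    if gray_thickness_mm is not None:
        tissues = tissues + ["white_matter"]
    label_map = {0: "air"}
    label_of = {}
    for i, t in enumerate(tissues, start=1):
        label_map[i] = t
        label_of[t] = i

    h = float(voxel_size_mm)
    half = semi + 2 * h  # pad with a rim of air
    n = np.ceil(2 * half / h).astype(int)
    origin = -n * h / 2.0
    x = origin[0] + (np.arange(n[0]) + 0.5) * h
    y = origin[1] + (np.arange(n[1]) + 0.5) * h
    z = origin[2] + (np.arange(n[2]) + 0.5) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    offset = 0.0
    # paint from the outside in; later (inner) layers overwrite earlier ones
    cumulative = []
    for t in order:
        cumulative.append((t, offset))
        offset += layer_thicknesses_mm[t]
    cumulative.append(("gray_matter", offset))
    if gray_thickness_mm is not None:
        cumulative.append(("white_matter", offset + gray_thickness_mm))

    for t, off in cumulative:
        if np.any(semi - off <= 0):
            raise ConfigurationError(
                f"layer {t!r} not resolvable: cumulative thickness exceeds semi-axes"
            )
    labels = _paint_labels(X, Y, Z, semi, cumulative, label_of)

    fractions = None
    if int(partial_volume) > 1:
        ss = int(partial_volume)
        counts = {t: np.zeros(labels.shape, dtype=np.float32) for t in tissues}
        offs = ((np.arange(ss) + 0.5) / ss - 0.5) * h
        for dx in offs:
            for dy in offs:
                for dz in offs:
                    sub = _paint_labels(X + dx, Y + dy, Z + dz,
                                        semi, cumulative, label_of)
                    for t in tissues:
                        counts[t] += sub == label_of[t]
        inv = np.float32(1.0 / ss ** 3)
        fractions = {t: c * inv for t, c in counts.items()}

    face_fractions = None
    if int(partial_volume) > 1:
        ss = int(partial_volume)
        offs = ((np.arange(ss) + 0.5) / ss - 0.5) * h
        centers = [x, y, z]
        per_axis = []
        for axis in range(3):
            coords = list(centers)
            coords[axis] = centers[axis][:-1] + h / 2.0  # face planes
            taxes = [a for a in range(3) if a != axis]
            shape = tuple(len(c) for c in coords)
            counts = {t: np.zeros(shape, dtype=np.float32) for t in tissues}
            for t1 in offs:
                for t2 in offs:
                    sc = list(coords)
                    sc[taxes[0]] = coords[taxes[0]] + t1
                    sc[taxes[1]] = coords[taxes[1]] + t2
                    FX, FY, FZ = np.meshgrid(*sc, indexing="ij")
                    sub = _paint_labels(FX, FY, FZ, semi, cumulative, label_of)
                    for t in tissues:
                        counts[t] += sub == label_of[t]
            inv2 = np.float32(1.0 / ss ** 2)
            per_axis.append({t: c * inv2 for t, c in counts.items()})
        face_fractions = tuple(per_axis)

    present = set(np.unique(labels))
    for t in tissues:
        if label_of[t] not in present:
            raise ConfigurationError(f"grid too coarse to resolve layer {t!r}")

    return TissueModel(
        kind="voxels",
        conductivities=conductivities,
        labels=labels,
        label_map=label_map,
        voxel_size_mm=h,
        origin_mm=tuple(origin.tolist()),
        layer_order=tuple(tissues),
        fractions=fractions,
        face_fractions=face_fractions,
    )


# ---------------------------------------------------------------------------
# Montage placement
# ---------------------------------------------------------------------------

_CURRENT_BALANCE_TOL_mA = 1e-9


def _attachment_tissue(attachment: str) -> str:
    return "scalp" if attachment == "scalp-surface" else "skull"


def _surface_voxels(model: TissueModel, tissue: str) -> np.ndarray:
    """Flat indices of ``tissue`` voxels with a neighbour outside that tissue
    on the side facing out of the head (air or a more superficial layer)."""
    labels = model.labels
    label_of = {t: l for l, t in model.label_map.items()}
    if tissue not in label_of:
        raise ConfigurationError(f"model has no {tissue!r} layer")
    target = label_of[tissue]
    outside_tissues = {"air"}
    for t in model.layer_order:
        if t == tissue:
            break
        outside_tissues.add(t)
    outside_labels = {label_of.get(t, 0) for t in outside_tissues}

    is_target = labels == target
    touches_out = np.zeros_like(is_target)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(labels, shift, axis=axis)
            # roll wraps; the padding rim of air makes wrapped faces harmless
            touches_out |= is_target & np.isin(rolled, list(outside_labels))
    return np.flatnonzero(touches_out)


def place_montage(model: TissueModel, patches: Sequence[ElectrodePatch]) -> Montage:
    """Bind electrode patches to a model, rasterizing footprints on voxel grids.

    Signed patch currents must balance; after rasterization any floating-point
    residual is folded into the reference footprint so the discrete source
    vector sums to zero to machine precision.
    """
    patches = tuple(patches)
    total = sum(p.current_mA for p in patches)
    if abs(total) > _CURRENT_BALANCE_TOL_mA:
        raise ConfigurationError(f"montage currents do not balance: net {total} mA")
    for p in patches:
        tissue = _attachment_tissue(p.attachment)
        if not model.has_tissue(tissue):
            raise ConfigurationError(
                f"patch attachment {p.attachment!r} needs a {tissue!r} layer in the model"
            )

    if model.kind != "voxels":
        return Montage(model=model, patches=patches, footprints=None)

    xs, ys, zs = model.voxel_centers()
    centers = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    footprints: dict[int, tuple] = {}
    claimed: dict[int, int] = {}
    for i, p in enumerate(patches):
        tissue = _attachment_tissue(p.attachment)
        surf = _surface_voxels(model, tissue)
        d = np.linalg.norm(centers[surf] - np.asarray(p.center_mm, dtype=float), axis=1)
        sel = surf[d <= max(p.radius_mm, model.voxel_size_mm * 0.75)]
        if len(sel) == 0:
            # point-like patch smaller than the grid: use the nearest surface voxel
            sel = surf[[int(np.argmin(d))]]
        for v in sel:
            if v in claimed:
                raise ConfigurationError(f"patches {claimed[v]} and {i} overlap at voxel {v}")
            claimed[v] = i
        cur = np.full(len(sel), p.current_mA * 1e-3 / len(sel))  # A per voxel
        footprints[i] = (sel, cur)

    # fold the floating-point residual into the reference (largest-|I|) patch
    residual = sum(c.sum() for _, c in footprints.values())
    ref = next(
        (i for i, p in enumerate(patches) if p.role == "reference"),
        int(np.argmax([abs(p.current_mA) for p in patches])),
    )
    idx, cur = footprints[ref]
    footprints[ref] = (idx, cur - residual / len(cur))
    return Montage(model=model, patches=patches, footprints=footprints)


def footprint_area_cm2(montage: Montage, patch_index: int) -> float:
    """Effective area of a rasterized footprint, in cm².

    The staircase surface overestimates curved areas, so each exposed outward
    face is projected onto the patch axis; the projected faces tile the flat
    disc the patch approximates.
    """
    if montage.footprints is None:
        raise ConfigurationError("footprint areas are defined for voxel montages only")
    model = montage.model
    patch = montage.patches[patch_index]
    sel, _ = montage.footprints[patch_index]
    labels = model.labels
    label_of = {t: l for l, t in model.label_map.items()}
    tissue = _attachment_tissue(patch.attachment)
    outside_tissues = {"air"}
    for t in model.layer_order:
        if t == tissue:
            break
        outside_tissues.add(t)
    outside_labels = np.array([label_of.get(t, 0) for t in outside_tissues])

    axis_dir = patch.direction
    in_sel = np.zeros(labels.size, dtype=bool)
    in_sel[sel] = True
    in_sel = in_sel.reshape(labels.shape)
    h = model.voxel_size_mm
    area_mm2 = 0.0
    for axis in range(3):
        for shift in (1, -1):
            neighbour = np.roll(labels, shift, axis=axis)
            exposed = in_sel & np.isin(neighbour, outside_labels)
            area_mm2 += exposed.sum() * h * h * abs(axis_dir[axis])
    return float(area_mm2 / 100.0)
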