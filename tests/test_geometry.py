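import numpy as np
import pytest

from shuntfield import geometry as g
from shuntfield.geometry import ConfigurationError

from conftest import axial_pair_montage, build_benchmark_phantom


def test_conductivity_set_invariants():
    cs = g.default_conductivities()
    assert cs["scalp"] == 0.0002
    assert cs["air"] == 0.0
    with pytest.raises(ConfigurationError):
        g.ConductivitySet({"scalp": 0.1})  # missing required tissues
    with pytest.raises(ConfigurationError):
        cs.with_updates(skull=-1.0)
    with pytest.raises(ConfigurationError):
        g.ConductivitySet({**g.DEFAULT_CONDUCTIVITIES, "air": 0.1})
    with pytest.raises(ConfigurationError):
        cs["unobtainium"]


def test_conductivity_set_json_round_trip():
    cs = g.optimized_conductivities()
    back = g.ConductivitySet.from_json(cs.to_json())
    assert back.values == cs.values
    assert back.provenance == cs.provenance
    assert back["skull"] == 0.004 and back["scalp"] == 0.0004


def test_build_slab():
    cs = g.optimized_conductivities()
    slab = g.build_slab([("scalp", 4.0), ("skull", 4.0), ("brain", 40.0)], cs)
    assert slab.total_thickness_mm == 48.0
    assert slab.scalp_removed().layers == (("skull", 4.0), ("brain", 40.0))
    with pytest.raises(ConfigurationError):
        g.build_slab([("scalp", 4.0)], cs)
    with pytest.raises(ConfigurationError):
        g.build_slab([("scalp", -1.0), ("skull", 4.0)], cs)


def test_build_shell_model():
    cs = g.default_conductivities()
    model = g.build_shell_model([33, 37, 41, 45], cs)
    assert [t for t, _ in model.shells] == ["brain", "csf", "skull", "scalp"]
    assert model.outer_radius_mm == 45.0
    removed = model.scalp_removed()
    assert [t for t, _ in removed.shells] == ["brain", "csf", "skull"]
    with pytest.raises(ConfigurationError):
        g.build_shell_model([41, 37], cs)  # not increasing
    with pytest.raises(ConfigurationError):
        g.build_shell_model([33, 37], cs)  # tissues required for non-4-shell


def test_build_voxel_head_labels_and_fractions():
    model = build_benchmark_phantom(2.0)
    tissues = {model.label_map[l] for l in np.unique(model.labels)}
    assert tissues == {"air", "scalp", "skull", "csf", "gray_matter"}
    # volume fractions sum to <= 1 (remainder is air) and match labels broadly
    total = sum(model.fractions[t] for t in model.layer_order)
    assert np.all(total <= 1.0 + 1e-6)
    inside = model.labels > 0
    assert total[inside].mean() > 0.95
    # face fractions exist for all three axes with reduced shape
    assert len(model.face_fractions) == 3
    nx = model.labels.shape[0]
    assert model.face_fractions[0]["scalp"].shape[0] == nx - 1


def test_build_voxel_head_rejects_unresolvable_layers():
    cs = g.default_conductivities()
    with pytest.raises(ConfigurationError):
        g.build_voxel_head((45, 45, 45), {"scalp": 4, "skull": 4, "csf": 4},
                           3.0, cs)  # voxel too coarse for 4 mm layers
    with pytest.raises(ConfigurationError):
        g.build_voxel_head((10, 10, 10), {"scalp": 4, "skull": 4, "csf": 4},
                           1.0, cs)  # cumulative thickness exceeds semi-axes


def test_scalp_removed_voxel_variant():
    model = build_benchmark_phantom(2.0)
    removed = model.scalp_removed()
    tissues = {removed.label_map[l] for l in np.unique(removed.labels)}
    assert "scalp" not in tissues
    assert "scalp" not in removed.fractions
    assert all("scalp" not in per_axis for per_axis in removed.face_fractions)


def test_electrode_patch_validation():
    patch = g.ElectrodePatch((0, 0, 45.0), 0.5, "scalp-surface", "active", 1.0)
    assert patch.radius_mm == pytest.approx(np.sqrt(50.0 / np.pi))
    with pytest.raises(ConfigurationError):
        g.ElectrodePatch((0, 0, 45.0), 0.0, "scalp-surface")
    with pytest.raises(ConfigurationError):
        g.ElectrodePatch((0, 0, 45.0), 0.5, "dura-surface")
    with pytest.raises(ConfigurationError):
        g.ElectrodePatch((0, 0, 45.0), 0.5, "scalp-surface", role="ground")


def test_strip_spec_contacts():
    strip = g.StripSpec((0.0, 0.0, 0.0), (2.0, 0.0, 0.0))
    centers = strip.contact_centers()
    assert centers.shape == (8, 3)
    assert np.allclose(np.diff(centers[:, 0]), 5.0)
    with pytest.raises(ConfigurationError):
        g.StripSpec((0, 0, 0), (0, 0, 0))


def test_place_montage_balance_and_footprints():
    model = build_benchmark_phantom(2.0)
    with pytest.raises(ConfigurationError):
        g.place_montage(model, [
            g.ElectrodePatch((0, 0, 45.0), 0.5, "scalp-surface", "active", 1.0),
            g.ElectrodePatch((0, 0, -45.0), 0.5, "scalp-surface", "reference", -0.5),
        ])
    montage = axial_pair_montage(model, "scalp-surface", 45.0)
    # discrete source currents balance to machine precision
    total = sum(cur.sum() for _, cur in montage.footprints.values())
    assert abs(total) < 1e-18
    area = g.footprint_area_cm2(montage, 0)
    assert 0.1 <= area <= 2.0  # same order as the nominal 0.5 cm^2


def test_place_montage_requires_layer():
    model = build_benchmark_phantom(2.0).scalp_removed()
    with pytest.raises(ConfigurationError):
        axial_pair_montage(model, "scalp-surface", 45.0)
    # skull-surface placement still works on the opened model
    montage = axial_pair_montage(model, "skull-surface", 41.0)
    assert montage.footprints is not None


def test_montage_scaled():
    model = build_benchmark_phantom(2.0)
    montage = axial_pair_montage(model, "scalp-surface", 45.0)
    doubled = montage.scaled(2.0)
    assert doubled.total_active_current_mA == 2 * montage.total_active_current_mA
    idx0, cur0 = montage.footprints[0]
    idx2, cur2 = doubled.footprints[0]
    assert np.array_equal(idx0, idx2)
    assert np.allclose(cur2, 2 * cur0)
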