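"""HDF5 / JSON / CSV persistence for phantoms, solutions and recordings.

Voxel grids are stored in HDF5 under the dataset names ``labels``,
``voxel_size_mm`` and ``origin_mm``; recording epochs and iEEG sessions as
``channels x samples`` datasets with their metadata as attributes.  Units
are stated in-file.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .geometry import ConductivitySet, TissueModel
from .recording import RecordingEpoch
from .ieeg import Session

__all__ = [
    "save_voxel_model",
    "load_voxel_model",
    "save_epoch",
    "load_epoch",
    "save_session",
    "load_session",
    "save_solution",
    "measurements_to_frame",
]


def save_voxel_model(path: str, model: TissueModel) -> None:
    if model.kind != "voxels":
        raise ValueError("only voxel models are stored in HDF5")
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=model.labels, compression="gzip")
        f.create_dataset("voxel_size_mm", data=model.voxel_size_mm)
        f.create_dataset("origin_mm", data=np.asarray(model.origin_mm))
        f.attrs["label_map"] = json.dumps({str(k): v for k, v in model.label_map.items()})
        f.attrs["layer_order"] = json.dumps(list(model.layer_order))
        f.attrs["conductivities"] = model.conductivities.to_json()
        if model.fractions is not None:
            grp = f.create_group("fractions")
            for tissue, frac in model.fractions.items():
                grp.create_dataset(tissue, data=frac, compression="gzip")
        if model.face_fractions is not None:
            grp = f.create_group("face_fractions")
            for axis, per_axis in enumerate(model.face_fractions):
                sub = grp.create_group(str(axis))
                for tissue, frac in per_axis.items():
                    sub.create_dataset(tissue, data=frac, compression="gzip")


def load_voxel_model(path: str) -> TissueModel:
    with h5py.File(path, "r") as f:
        labels = f["labels"][()]
        voxel_size = float(f["voxel_size_mm"][()])
        origin = tuple(f["origin_mm"][()].tolist())
        label_map = {int(k): v for k, v in json.loads(f.attrs["label_map"]).items()}
        layer_order = tuple(json.loads(f.attrs["layer_order"]))
        cs = ConductivitySet.from_json(f.attrs["conductivities"])
        fractions = None
        if "fractions" in f:
            fractions = {t: f["fractions"][t][()] for t in f["fractions"]}
        face_fractions = None
        if "face_fractions" in f:
            face_fractions = tuple(
                {t: f["face_fractions"][str(axis)][t][()]
                 for t in f["face_fractions"][str(axis)]}
                for axis in range(3)
            )
    return TissueModel(kind="voxels", conductivities=cs, labels=labels,
                       label_map=label_map, voxel_size_mm=voxel_size,
                       origin_mm=origin, layer_order=layer_order,
                       fractions=fractions, face_fractions=face_fractions)


def save_epoch(path: str, epoch: RecordingEpoch) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data_mV", data=epoch.data, compression="gzip")
        d.attrs["fs_hz"] = epoch.fs_hz
        d.attrs["intensity_mA"] = epoch.intensity_mA
        d.attrs["frequency_hz"] = epoch.frequency_hz
        d.attrs["condition"] = epoch.condition
        d.attrs["montage_id"] = epoch.montage_id


def load_epoch(path: str) -> RecordingEpoch:
    with h5py.File(path, "r") as f:
        d = f["data_mV"]
        return RecordingEpoch(
            data=d[()], fs_hz=float(d.attrs["fs_hz"]),
            intensity_mA=float(d.attrs["intensity_mA"]),
            frequency_hz=float(d.attrs["frequency_hz"]),
            condition=str(d.attrs["condition"]),
            montage_id=str(d.attrs["montage_id"]),
        )


def save_session(path: str, session: Session) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("trace_uV", data=session.trace, compression="gzip")
        d.attrs["fs_hz"] = session.fs_hz
        d.attrs["condition"] = session.condition
        d.attrs["intensity_mA"] = session.intensity_mA
        d.attrs["phases"] = json.dumps({k: list(v) for k, v in session.phases.items()})


def load_session(path: str) -> Session:
    with h5py.File(path, "r") as f:
        d = f["trace_uV"]
        phases = {k: tuple(v) for k, v in json.loads(d.attrs["phases"]).items()}
        return Session(trace=d[()], fs_hz=float(d.attrs["fs_hz"]),
                       phases=phases, condition=str(d.attrs["condition"]),
                       intensity_mA=float(d.attrs["intensity_mA"]))


def save_solution(path: str, solution) -> None:
    """Store a voxel field solution (potential in V, field in mV/mm)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("potential_V", data=solution.potential, compression="gzip")
        ex, ey, ez = solution.field
        f.create_dataset("field_mV_per_mm", data=np.stack([ex, ey, ez]),
                         compression="gzip")
        f.attrs["residual"] = solution.residual
        f.attrs["iterations"] = solution.iterations
        f.attrs["voxel_size_mm"] = solution.model.voxel_size_mm


def measurements_to_frame(measurements) -> pd.DataFrame:
    """Tidy per-pair table: condition, intensity_mA, frequency_hz, pair_index,
    field_mV_per_mm."""
    rows = []
    for m in measurements:
        for i, v in enumerate(m.pair_fields_mV_per_mm):
            rows.append({
                "condition": m.condition,
                "intensity_mA": m.intensity_mA,
                "frequency_hz": m.frequency_hz,
                "pair_index": i,
                "field_mV_per_mm": v,
            })
    return pd.DataFrame(rows)
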