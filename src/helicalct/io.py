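"""File formats: sinogram HDF5/NPZ, NIfTI volumes and masks, PNG previews.

HDF5 layout: ``/source_<i>/values``, shared ``/beta``, ``/gamma``,
``/row_z_offset`` datasets, a ``geometry_hash`` attribute tying the data to
the geometry that produced it, and interpolated planes under
``/plane_<Z_R>/``.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional, Sequence

import h5py
import nibabel as nib
import numpy as np

from .errors import ValidationError
from .geometry import FanDetector, HelixGeometry, TableSpeed
from .phantom import BinaryMask, VoxelVolume
from .zinterp import PlanarFan

__all__ = [
    "geometry_hash",
    "geometry_to_dict",
    "geometry_from_dict",
    "save_sinograms",
    "load_sinograms",
    "save_planar_fan",
    "load_planar_fan",
    "save_volume_nifti",
    "load_volume_nifti",
    "save_mask_nifti",
    "load_mask_nifti",
    "save_volume_npz",
    "save_png_preview",
]


def geometry_to_dict(geom: HelixGeometry) -> dict:
    d = {
        "rho": geom.rho,
        "omega": geom.omega,
        "phases": list(geom.phases),
        "detector": {
            "gamma_grid": geom.detector.gamma_grid.tolist(),
            "n_rows": geom.detector.n_rows,
            "row_pitch": geom.detector.row_pitch,
            "source_detector_distance": geom.detector.source_detector_distance,
        },
    }
    if geom.is_variable:
        d["table_speed"] = {
            "beta_grid": geom.pitch.beta_grid.tolist(),
            "h_values": geom.pitch.h_values.tolist(),
        }
    else:
        d["pitch"] = float(geom.pitch)
    return d


def geometry_from_dict(d: dict) -> HelixGeometry:
    det = d["detector"]
    detector = FanDetector(
        gamma_grid=np.asarray(det["gamma_grid"], dtype=float),
        n_rows=int(det["n_rows"]),
        row_pitch=float(det["row_pitch"]),
        source_detector_distance=float(det.get("source_detector_distance", 1000.0)),
    )
    if "table_speed" in d:
        ts = d["table_speed"]
        pitch = TableSpeed(np.asarray(ts["beta_grid"], dtype=float), np.asarray(ts["h_values"], dtype=float))
    else:
        pitch = float(d["pitch"])
    return HelixGeometry(
        rho=float(d["rho"]),
        omega=float(d["omega"]),
        phases=tuple(d["phases"]),
        pitch=pitch,
        detector=detector,
    )


def geometry_hash(geom: HelixGeometry) -> str:
    payload = json.dumps(geometry_to_dict(geom), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def save_sinograms(path, sinograms: Sequence, geom: HelixGeometry) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["geometry_hash"] = geometry_hash(geom)
        fh.attrs["geometry_json"] = json.dumps(geometry_to_dict(geom), sort_keys=True)
        fh.create_dataset("beta", data=sinograms[0].beta_grid)
        fh.create_dataset("gamma", data=sinograms[0].gamma_grid)
        fh.create_dataset("row_z_offset", data=geom.detector.row_offsets)
        for s in sinograms:
            fh.create_dataset(f"source_{s.source_index}/values", data=s.values)


def load_sinograms(path):
    from .projector import SourceSinogram

    with h5py.File(path, "r") as fh:
        geom = geometry_from_dict(json.loads(fh.attrs["geometry_json"]))
        beta = fh["beta"][:]
        gamma = fh["gamma"][:]
        out = []
        keys = sorted(
            (k for k in fh.keys() if k.startswith("source_")),
            key=lambda k: int(k.split("_")[1]),
        )
        for k in keys:
            idx = int(k.split("_")[1])
            out.append(
                SourceSinogram(
                    values=fh[f"{k}/values"][:],
                    beta_grid=beta,
                    gamma_grid=gamma,
                    source_index=idx,
                    geometry=geom,
                )
            )
    return out, geom


def save_planar_fan(path, fan: PlanarFan) -> None:
    with h5py.File(path, "a") as fh:
        grp_name = f"plane_{fan.z_plane:g}"
        if grp_name in fh:
            del fh[grp_name]
        g = fh.create_group(grp_name)
        g.create_dataset("values", data=fan.values)
        g.create_dataset("beta", data=fan.beta_grid)
        g.create_dataset("gamma", data=fan.gamma_grid)
        g.attrs.update({"z_plane": fan.z_plane, "beta_R": fan.beta_R, "rho": fan.rho, "mode": fan.mode})
        if fan.provenance is not None:
            pg = g.create_group("provenance")
            pg.create_dataset("weight_above", data=fan.provenance["weight_above"])
            for side in ("above", "below"):
                sg = pg.create_group(side)
                for key, arr in fan.provenance[side].items():
                    sg.create_dataset(key, data=np.asarray(arr))


def load_planar_fan(path, z_plane: float) -> PlanarFan:
    with h5py.File(path, "r") as fh:
        g = fh[f"plane_{z_plane:g}"]
        provenance = None
        if "provenance" in g:
            provenance = {"weight_above": g["provenance/weight_above"][:]}
            for side in ("above", "below"):
                provenance[side] = {k: g[f"provenance/{side}/{k}"][:] for k in g[f"provenance/{side}"]}
        return PlanarFan(
            values=g["values"][:],
            z_plane=float(g.attrs["z_plane"]),
            beta_R=float(g.attrs["beta_R"]),
            beta_grid=g["beta"][:],
            gamma_grid=g["gamma"][:],
            rho=float(g.attrs["rho"]),
            mode=str(g.attrs["mode"]),
            provenance=provenance,
        )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def save_volume_nifti(path, volume: VoxelVolume) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_volume_nifti(path) -> VoxelVolume:
    img = nib.load(str(path))
    aff = img.affine
    return VoxelVolume(
        values=np.asarray(img.dataobj, dtype=float),
        spacing=tuple(float(aff[a, a]) for a in range(3)),
        origin=tuple(float(aff[a, 3]) for a in range(3)),
    )


def save_mask_nifti(path, mask: BinaryMask) -> None:
    if len(mask.shape) != 3:
        raise ValidationError("only 3-D masks are written as NIfTI")
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing, mask.origin))
    nib.save(img, str(path))


def load_mask_nifti(path) -> BinaryMask:
    img = nib.load(str(path))
    aff = img.affine
    return BinaryMask(
        values=np.asarray(img.dataobj) > 0,
        spacing=tuple(float(aff[a, a]) for a in range(3)),
        origin=tuple(float(aff[a, 3]) for a in range(3)),
    )


def save_volume_npz(path, volume: VoxelVolume) -> None:
    np.savez(path, values=volume.values, spacing=np.asarray(volume.spacing), origin=np.asarray(volume.origin))


def save_png_preview(path, values: np.ndarray) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    arr = np.asarray(values, dtype=float)
    plt.imsave(str(path), arr.T[::-1], cmap="gray")
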