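"""Slice stacking into volumes and multiplanar (MPR) resampling."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ValidationError
from .fbp import fan_fbp
from .geometry import HelixGeometry
from .phantom import VoxelVolume
from .zinterp import build_planar_fan

__all__ = ["reconstruct_volume", "mpr_view"]


def reconstruct_volume(
    sinograms: Sequence,
    geom: HelixGeometry,
    z_start: float,
    z_stop: float,
    slice_interval: float = 0.5,
    mode: str = "fixed",
    shape: Sequence[int] = (128, 128),
    spacing: Sequence[float] = (1.0, 1.0),
    filter_name: str = "ramp",
    slice_thickness: Optional[float] = None,
    n_beta: Optional[int] = None,
    k_range: int = 2,
) -> VoxelVolume:
    """Reconstruct planes z_start..z_stop at ``slice_interval`` (mm) spacing
    and stack them into a volume.

    Each plane runs the full interpolation + fan-FBP pipeline
    independently, so the result does not depend on evaluation order.  If
    ``slice_thickness`` exceeds the interval, each output slice is the
    average of round(thickness/interval) finely spaced sub-planes centered
    on it (the thick-slice reading of thinning reconstruction); default is
    no averaging (thickness = interval).
    """
    if slice_interval <= 0:
        raise ValidationError("slice_interval must be positive")
    if z_stop < z_start:
        raise ValidationError("z_stop must be >= z_start")
    z_planes = np.arange(z_start, z_stop + slice_interval / 2.0, slice_interval)
    n_avg = 1
    if slice_thickness is not None and slice_thickness > slice_interval:
        n_avg = int(round(slice_thickness / slice_interval))

    nx, ny = (int(s) for s in shape)
    dx, dy = (float(s) for s in spacing)
    origin_xy = (-(nx - 1) / 2.0 * dx, -(ny - 1) / 2.0 * dy)
    out = np.empty((nx, ny, z_planes.size))
    for zi, zc in enumerate(z_planes):
        subs = (
            [zc]
            if n_avg == 1
            else zc + (np.arange(n_avg) - (n_avg - 1) / 2.0) * (slice_thickness / n_avg)
        )
        acc = np.zeros((nx, ny))
        for zs in subs:
            fan = build_planar_fan(
                zs, sinograms, geom, mode=mode, n_beta=n_beta,
                k_range=k_range, with_provenance=False,
            )
            acc += fan_fbp(fan, (nx, ny), (dx, dy), origin_xy, filter_name).values
        out[:, :, zi] = acc / len(subs)
    return VoxelVolume(
        values=out,
        spacing=(dx, dy, float(slice_interval)),
        origin=(origin_xy[0], origin_xy[1], float(z_start)),
    )


def mpr_view(volume: VoxelVolume, plane: str, position: float) -> np.ndarray:
    """Trilinear resampling of an axial/sagittal/coronal plane at a world
    position (mm along the plane's normal axis)."""
    axis = {"sagittal": 0, "coronal": 1, "axial": 2}.get(plane)
    if axis is None:
        raise ValidationError("plane must be 'axial', 'sagittal' or 'coronal'")
    lo = volume.origin[axis]
    hi = volume.origin[axis] + volume.spacing[axis] * (volume.shape[axis] - 1)
    if not lo - 1e-9 <= position <= hi + 1e-9:
        raise ValidationError(f"position {position} outside volume extent [{lo}, {hi}] on axis {axis}")
    idx_pos = (position - volume.origin[axis]) / volume.spacing[axis]
    keep = [a for a in range(3) if a != axis]
    n0, n1 = volume.shape[keep[0]], volume.shape[keep[1]]
    I0, I1 = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    coords = [None, None, None]
    coords[axis] = np.full(I0.shape, idx_pos)
    coords[keep[0]] = I0.astype(float)
    coords[keep[1]] = I1.astype(float)
    return map_coordinates(volume.values, np.stack(coords), order=1, mode="nearest")
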