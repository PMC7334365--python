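"""Tensor-field phantoms for exercising deterministic tractography.

A phantom is a voxel grid carrying an FA value, a unit principal direction,
a brain mask and an integer parcel label per voxel. Geometry is axis-aligned:
0-based voxel indices, isotropic ``voxel_size`` mm, voxel centers at
``(index + 0.5) * voxel_size``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["TensorFieldPhantom", "make_bundle_phantom",
           "save_phantom", "load_phantom"]


@dataclass
class TensorFieldPhantom:
    fa: np.ndarray              # 3-D, values in [0, 1]
    directions: np.ndarray      # shape (*grid, 3), unit vectors where masked
    mask: np.ndarray            # 3-D bool
    labels: np.ndarray          # 3-D int, 0 = background
    voxel_size: float = 2.5     # mm, isotropic
    phantom_id: str = "phantom"

    def __post_init__(self) -> None:
        self.fa = np.asarray(self.fa, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.fa.min() < 0 or self.fa.max() > 1:
            raise ValueError("FA values must lie in [0, 1]")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        norms = np.linalg.norm(self.directions[self.mask], axis=-1)
        if norms.size and not np.allclose(norms[norms > 0], 1.0, atol=1e-6):
            raise ValueError("masked directions must be unit vectors")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.fa.shape

    def voxel_center(self, idx) -> np.ndarray:
        return (np.asarray(idx, dtype=float) + 0.5) * self.voxel_size

    def voxel_of(self, point_mm) -> tuple[int, int, int] | None:
        """Voxel index containing a world point, or None if off-grid."""
        idx = np.floor(np.asarray(point_mm, dtype=float) /
                       self.voxel_size).astype(int)
        if (idx < 0).any() or (idx >= np.array(self.shape)).any():
            return None
        return tuple(int(v) for v in idx)


def make_bundle_phantom(shape=(20, 10, 10), bundle_axis: int = 0,
                        bend_angle: float = 0.0, fa_inside: float = 0.5,
                        fa_outside: float = 0.0, radius: float = 1.0,
                        voxel_size: float = 2.5,
                        cap_thickness: int = 1) -> TensorFieldPhantom:
    """Straight or bent tubular fiber bundle with labelled end caps.

    The bundle runs along ``bundle_axis`` from one face toward the grid
    center; with ``bend_angle > 0`` a second straight segment leaves the
    elbow rotated by that angle (in the plane of ``bundle_axis`` and the
    next axis). Voxels within ``radius`` (voxel units) of the centerline get
    ``fa_inside`` and the local segment direction; all other voxels get
    ``fa_outside``. The first and last bundle slabs are labelled parcels
    1 and 2. The mask covers the whole grid (the "brain"), so tracking
    terminates on the FA rule, not on mask exit, inside the grid.
    """
    shape = tuple(int(s) for s in shape)
    if shape[bundle_axis] < 5:
        raise ValueError("grid must span at least 5 voxels along the bundle")
    if not fa_inside > 0.2 > fa_outside:
        raise ValueError("need fa_inside > 0.2 > fa_outside to exercise "
                         "the tracking threshold")

    fa = np.full(shape, float(fa_outside))
    directions = np.zeros(shape + (3,))
    labels = np.zeros(shape, dtype=int)
    mask = np.ones(shape, dtype=bool)

    ax = bundle_axis
    ax2 = (bundle_axis + 1) % 3
    d1 = np.zeros(3)
    d1[ax] = 1.0
    theta = np.deg2rad(bend_angle)
    d2 = np.zeros(3)
    d2[ax] = np.cos(theta)
    d2[ax2] = np.sin(theta)
    d2 /= np.linalg.norm(d2)

    # centerline: start on the low face midline, run to the grid center,
    # then continue along d2 until leaving the grid
    start = np.array([(s - 1) / 2.0 for s in shape])
    start[ax] = 1.0
    elbow = np.array(start)
    elbow[ax] = (shape[ax] - 1) / 2.0 if bend_angle else shape[ax] - 2.0
    seg1_len = elbow[ax] - start[ax]

    centerline: list[tuple[np.ndarray, np.ndarray]] = []
    step = 0.25
    for s in np.arange(0.0, seg1_len + step / 2, step):
        centerline.append((start + s * d1, d1))
    if bend_angle:
        max_len = max(shape) * 2
        for s in np.arange(step, max_len, step):
            p = elbow + s * d2
            if ((p < 0.5).any() or
                    (p > np.array(shape) - 1.5).any()):
                break
            centerline.append((p, d2))

    bundle_voxels = {}
    for p, d in centerline:
        lo = np.maximum(np.floor(p - radius), 0).astype(int)
        hi = np.minimum(np.ceil(p + radius), np.array(shape) - 1).astype(int)
        for i in range(lo[0], hi[0] + 1):
            for j in range(lo[1], hi[1] + 1):
                for k in range(lo[2], hi[2] + 1):
                    if np.linalg.norm(np.array([i, j, k]) - p) <= radius:
                        bundle_voxels[(i, j, k)] = d
    for vox, d in bundle_voxels.items():
        fa[vox] = fa_inside
        directions[vox] = d

    # end caps: slabs at the two extremes of the centerline
    first_pt = centerline[0][0]
    last_pt = centerline[-1][0]
    for vox in bundle_voxels:
        v = np.array(vox)
        if abs(v[ax] - first_pt[ax]) < cap_thickness - 0.5 + 1e-9 \
                and np.dot(v - first_pt, d1) <= 0:
            labels[vox] = 1
        seg_axis = d2 if bend_angle else d1
        if np.dot(v - last_pt, seg_axis) >= -(cap_thickness - 0.5 + 1e-9):
            labels[vox] = 2
    return TensorFieldPhantom(fa=fa, directions=directions, mask=mask,
                              labels=labels, voxel_size=voxel_size,
                              phantom_id=f"bundle_ax{ax}_bend{bend_angle:g}")


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size] * 3 + [1.0])
    aff[:3, 3] = voxel_size / 2.0  # voxel centers at (i + 0.5) * voxel_size
    return aff


def save_phantom(phantom: TensorFieldPhantom, out_dir) -> dict[str, str]:
    """Write one NIfTI per component (fa, dx, dy, dz, mask, labels)."""
    os.makedirs(out_dir, exist_ok=True)
    aff = _affine(phantom.voxel_size)
    paths = {}
    comps = {
        "fa": phantom.fa.astype(np.float32),
        "dx": phantom.directions[..., 0].astype(np.float32),
        "dy": phantom.directions[..., 1].astype(np.float32),
        "dz": phantom.directions[..., 2].astype(np.float32),
        "mask": phantom.mask.astype(np.uint8),
        "labels": phantom.labels.astype(np.int16),
    }
    for name, arr in comps.items():
        p = os.path.join(out_dir, f"{name}.nii")
        nib.save(nib.Nifti1Image(arr, aff), p)
        paths[name] = p
    return paths


def load_phantom(in_dir, phantom_id: str | None = None) -> TensorFieldPhantom:
    def read(name):
        return np.asarray(
            nib.load(os.path.join(in_dir, f"{name}.nii")).dataobj)

    fa = read("fa").astype(float)
    directions = np.stack([read("dx"), read("dy"), read("dz")],
                          axis=-1).astype(float)
    mask = read("mask").astype(bool)
    labels = read("labels").astype(int)
    img = nib.load(os.path.join(in_dir, "fa.nii"))
    voxel_size = float(img.affine[0, 0])
    return TensorFieldPhantom(fa=fa, directions=directions, mask=mask,
                              labels=labels, voxel_size=voxel_size,
                              phantom_id=phantom_id or str(in_dir))
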