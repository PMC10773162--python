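"""Time-resolved voxel velocity fields (the stand-in for 4D-flow MRI).

A :class:`VelocityField4D` holds three velocity components per voxel per
cardiac frame, a lumen label mask (0 background, 1 true lumen, 2 false
lumen), an affine mapping voxel indices to world coordinates in mm, and
the frame times of one cardiac cycle.

Internal array layout is ``(t, x, y, z, 3)`` with velocity in m/s; the
HDF5 on-disk layout stores ``/velocity`` as ``(t, z, y, x, 3)`` together
with ``/mask``, ``/affine`` and ``/time`` datasets.  Label volumes can
also be written as NIfTI (one file per velocity component, x,y,z,t).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["VelocityField4D", "LABEL_BACKGROUND", "LABEL_TL", "LABEL_FL"]

LABEL_BACKGROUND = 0
LABEL_TL = 1
LABEL_FL = 2


@dataclass
class VelocityField4D:
    """Velocity field on a regular voxel grid over one cardiac cycle.

    Attributes
    ----------
    velocity : np.ndarray
        Shape ``(n_frames, nx, ny, nz, 3)``, m/s, world-axis components.
    mask : np.ndarray
        Shape ``(nx, ny, nz)`` integer lumen labels {0, 1, 2}.
    affine : np.ndarray
        4x4 voxel-index -> world-mm affine.
    time_s : np.ndarray
        Frame times (s), strictly increasing, covering ``[0, T)``.
    period_s : float
        Cardiac cycle period ``T``.
    """

    velocity: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    time_s: np.ndarray
    period_s: float

    def __post_init__(self) -> None:
        v = np.asarray(self.velocity, dtype=float)
        m = np.asarray(self.mask)
        if v.ndim != 5 or v.shape[-1] != 3:
            raise ValueError("velocity must have shape (t, nx, ny, nz, 3)")
        if m.shape != v.shape[1:4]:
            raise ValueError("mask shape must match the spatial grid")
        if v.shape[0] != np.asarray(self.time_s).size:
            raise ValueError("number of frames must match time samples")
        self.velocity = v
        self.mask = m
        self.affine = np.asarray(self.affine, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.velocity.shape[1:4]

    # ---- coordinate transforms ----

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-mm points (N, 3) to fractional voxel indices (N, 3)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        homo = np.hstack([pts, np.ones((pts.shape[0], 1))])
        return (homo @ inv.T)[:, :3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(ijk, dtype=float))
        homo = np.hstack([pts, np.ones((pts.shape[0], 1))])
        return (homo @ self.affine.T)[:, :3]

    # ---- sampling ----

    def sample_velocity(self, points_mm: np.ndarray, frame: int,
                        order: int = 1) -> np.ndarray:
        """Interpolate the velocity (m/s) at world points for one frame.

        ``order=1`` is trilinear; ``order=3`` cubic B-spline (prefiltered).
        Points outside the grid return zero velocity.
        """
        vox = self.world_to_voxel(points_mm).T  # (3, N)
        out = np.empty((vox.shape[1], 3))
        for c in range(3):
            out[:, c] = map_coordinates(
                self.velocity[frame, ..., c], vox, order=order,
                mode="constant", cval=0.0)
        return out

    def sample_mask(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest-neighbour lumen label at world points."""
        vox = self.world_to_voxel(points_mm).T
        return map_coordinates(self.mask.astype(float), vox, order=0,
                               mode="constant", cval=0.0).astype(int)

    # ---- persistence ----

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            # on-disk layout (t, z, y, x, 3); axis order documented here
            f.create_dataset("velocity",
                             data=np.transpose(self.velocity, (0, 3, 2, 1, 4)))
            f.create_dataset("mask", data=np.transpose(self.mask, (2, 1, 0)))
            f.create_dataset("affine", data=self.affine)
            f.create_dataset("time", data=self.time_s)
            f.attrs["period_s"] = self.period_s
            f.attrs["velocity_units"] = "m/s"
            f.attrs["layout"] = "velocity: (t, z, y, x, component)"

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "VelocityField4D":
        with h5py.File(path, "r") as f:
            v = np.transpose(f["velocity"][()], (0, 3, 2, 1, 4))
            m = np.transpose(f["mask"][()], (2, 1, 0))
            aff = f["affine"][()]
            t = f["time"][()]
            period = float(f.attrs["period_s"])
        return cls(v, m, aff, t, period)

    def to_nifti(self, prefix: str | Path) -> list[Path]:
        """Write one 4-D NIfTI per velocity component plus the mask."""
        import nibabel as nib

        prefix = Path(prefix)
        paths = []
        for c, name in enumerate("xyz"):
            img = nib.Nifti1Image(
                np.transpose(self.velocity[..., c], (1, 2, 3, 0)), self.affine)
            p = prefix.with_name(prefix.name + f"_v{name}.nii")
            nib.save(img, p)
            paths.append(p)
        mimg = nib.Nifti1Image(self.mask.astype(np.uint8), self.affine)
        mp = prefix.with_name(prefix.name + "_mask.nii")
        nib.save(mimg, mp)
        paths.append(mp)
        return paths
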