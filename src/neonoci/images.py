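"""Volumetric containers and NIfTI I/O.

Two containers cover every image in the analysis: :class:`VoxelMap` for 3D
scalar maps (beta maps, t-maps, network templates, tract probability maps,
ROI masks) and :class:`Bold4D` for 4D functional runs with their repetition
time and optional event/motion tables.  Voxel vectorization everywhere uses
the ascending linear (C-order) index of the on-disk array so spatial
statistics are order-stable across modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd


@dataclass
class VoxelMap:
    """A 3D scalar image with an analysis mask.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values; values outside ``mask`` are ignored by all statistics.
    mask : ndarray of bool, same shape
        Analysis mask. Defaults to all-true.
    voxel_size_mm : tuple of float
        Voxel edge lengths in mm (used by smoothing kernels).
    affine : ndarray (4, 4), optional
        World affine; defaults to a diagonal affine from ``voxel_size_mm``.
    """

    data: np.ndarray
    mask: Optional[np.ndarray] = None
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelMap requires 3D data, got ndim={self.data.ndim}")
        if self.mask is None:
            self.mask = np.ones(self.data.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape does not match data shape")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def shape(self):
        return self.data.shape

    def values(self) -> np.ndarray:
        """In-mask values as a 1D vector (C-order linear index)."""
        return self.data[self.mask]

    def with_data(self, data: np.ndarray) -> "VoxelMap":
        return VoxelMap(data, self.mask.copy(), self.voxel_size_mm, self.affine.copy())

    def embed(self, values: np.ndarray, fill: float = 0.0) -> "VoxelMap":
        """Scatter a vector of in-mask values back into the 3D grid."""
        out = np.full(self.data.shape, fill, dtype=float)
        out[self.mask] = values
        return self.with_data(out)


@dataclass
class Bold4D:
    """A 4D BOLD timeseries with acquisition and nuisance metadata."""

    data: np.ndarray
    tr: float
    mask: Optional[np.ndarray] = None
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    affine: Optional[np.ndarray] = None
    events: Optional[pd.DataFrame] = None   # columns: onset, duration (s)
    motion: Optional[pd.DataFrame] = None   # T x 6 rigid parameters

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"Bold4D requires 4D data, got ndim={self.data.ndim}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match spatial dimensions")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def n_vols(self) -> int:
        return self.data.shape[3]

    def timeseries(self) -> np.ndarray:
        """In-mask data as a (T, V) matrix."""
        return self.data[self.mask].T

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_vols) * self.tr


def read_volume(path: Union[str, Path]) -> Union[VoxelMap, Bold4D]:
    """Read a NIfTI file, dispatching on header dimensionality.

    3D files become :class:`VoxelMap`, 4D files :class:`Bold4D` (with the
    repetition time taken from the header zooms).  Higher-dimensional files
    raise ``ValueError``.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    data = np.squeeze(data) if data.ndim > 4 else data
    zooms = img.header.get_zooms()
    vox = tuple(float(z) for z in zooms[:3])
    if data.ndim == 3:
        return VoxelMap(data, voxel_size_mm=vox, affine=np.asarray(img.affine))
    if data.ndim == 4:
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return Bold4D(data, tr=tr, voxel_size_mm=vox, affine=np.asarray(img.affine))
    raise ValueError(f"unsupported NIfTI dimensionality {data.ndim} for {path}")


def write_volume(obj: Union[VoxelMap, Bold4D], path: Union[str, Path]) -> Path:
    """Write a VoxelMap or Bold4D to NIfTI, preserving affine and voxel sizes."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(obj.data, dtype=np.float32), obj.affine)
    zooms = list(obj.voxel_size_mm)
    if isinstance(obj, Bold4D):
        zooms.append(obj.tr)
    img.header.set_zooms(tuple(zooms))
    nib.save(img, str(path))
    return path


def read_mask(path: Union[str, Path]) -> np.ndarray:
    vol = read_volume(path)
    if not isinstance(vol, VoxelMap):
        raise ValueError("mask file must be 3D")
    return vol.data > 0.5
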