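"""Volumetric containers and file IO.

All analysis objects live on a shared axis-aligned :class:`VolumeGrid`
(2 mm isotropic by convention).  Oblique orientations are not supported:
once every input shares a grid the analysis is purely grid-local, so the
voxel-to-mm mapping is a diagonal affine plus an offset.

Missing values inside analysis masks are represented as NaN and are
propagated as missing, never silently zero-filled; voxels whose log-FCD
is undefined must stay distinguishable from genuine zeros.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

GRID_ATOL_MM = 1e-6


class GridError(ValueError):
    """Raised when gridded inputs are mutually incompatible."""


@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned voxel grid: shape, voxel size (mm) and mm offset of voxel (0,0,0)."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "origin_offset_mm", tuple(float(v) for v in self.origin_offset_mm))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_offset_mm
        return aff

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk * np.asarray(self.voxel_size_mm) + np.asarray(self.origin_offset_mm)

    def compatible_with(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm, atol=GRID_ATOL_MM, rtol=0)
            and np.allclose(self.origin_offset_mm, other.origin_offset_mm, atol=GRID_ATOL_MM, rtol=0)
        )


def _check_values_shape(grid: VolumeGrid, values: np.ndarray, ndim: int):
    if values.shape[:3] != grid.shape or values.ndim != ndim:
        raise ValueError(f"value array shape {values.shape} does not match grid {grid.shape}")


@dataclass
class Volume3D:
    """A scalar per voxel; NaN marks missing values."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_values_shape(self.grid, self.values, 3)

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class BoldSeries:
    """4D BOLD-like data, time as the last axis, with its sampling interval."""

    grid: VolumeGrid
    data: np.ndarray
    sampling_interval_s: float = 2.5

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        _check_values_shape(self.grid, self.data, 4)
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class Mask:
    grid: VolumeGrid
    membership: np.ndarray

    def __post_init__(self):
        self.membership = np.asarray(self.membership, dtype=bool)
        _check_values_shape(self.grid, self.membership, 3)

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())

    def require_nonempty(self, what: str = "mask") -> "Mask":
        if self.n_voxels == 0:
            raise ValueError(f"{what} is empty")
        return self


@dataclass
class RoiInfo:
    name: str
    group: str
    spinnable: bool = True


@dataclass
class Parcellation:
    """Integer label volume (0 = background) plus a label table.

    ``group`` assigns each ROI to a functional network; ``spinnable``
    marks whether the spherical permutation test covers the region
    (subcortex and cerebellum analogues are flagged False).
    """

    grid: VolumeGrid
    labels: np.ndarray
    label_table: Mapping[int, RoiInfo]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            as_int = lab.astype(np.int64)
            if not np.array_equal(as_int, lab):
                raise ValueError("parcellation labels must be integer-valued")
            self.labels = as_int
        _check_values_shape(self.grid, self.labels, 3)
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(int(k) for k in self.label_table)
        if missing:
            raise ValueError(f"labels present in volume but absent from table: {sorted(missing)}")

    @property
    def roi_labels(self) -> list[int]:
        return sorted(int(k) for k in self.label_table)

    def roi_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def networks(self) -> dict[str, list[int]]:
        nets: dict[str, list[int]] = {}
        for lab in self.roi_labels:
            nets.setdefault(self.label_table[lab].group, []).append(lab)
        return nets

    def network_mask(self, group: str) -> np.ndarray:
        labs = self.networks.get(group, [])
        return np.isin(self.labels, labs)


def check_grid_compatibility(items: Sequence) -> None:
    """Raise :class:`GridError` on the first incompatible pair of gridded objects."""
    if len(items) == 0:
        raise ValueError("no gridded objects given")
    ref = items[0].grid
    for k, item in enumerate(items[1:], start=1):
        if not ref.compatible_with(item.grid):
            raise GridError(
                f"grid of item {k} incompatible with item 0: {item.grid} vs {ref}"
            )


def _grid_from_header(img) -> VolumeGrid:
    aff = img.affine
    lin = aff[:3, :3]
    if not np.allclose(lin - np.diag(np.diag(lin)), 0.0, atol=1e-6):
        raise ValueError("oblique/rotated affines are not supported; resample upstream")
    voxel = np.diag(lin)
    if np.any(voxel <= 0):
        raise ValueError("negative or zero voxel sizes in affine are not supported")
    return VolumeGrid(
        shape=tuple(int(s) for s in img.shape[:3]),
        voxel_size_mm=tuple(float(v) for v in voxel),
        origin_offset_mm=tuple(float(v) for v in aff[:3, 3]),
    )


def read_volume(path, sampling_interval_s: float | None = None):
    """Read a NIfTI file; 3D becomes :class:`Volume3D`, 4D a :class:`BoldSeries`.

    For 4D inputs the sampling interval is taken from the header TR unless
    overridden.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    ndim = len(img.shape)
    if ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D image, got {ndim}D: {path}")
    grid = _grid_from_header(img)
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if ndim == 3:
        return Volume3D(grid, data)
    if sampling_interval_s is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        sampling_interval_s = tr if tr > 0 else 2.5
    return BoldSeries(grid, data, sampling_interval_s=sampling_interval_s)


def write_volume(vol, path) -> None:
    """Write a Volume3D/BoldSeries (or anything with .grid/.values) as NIfTI."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    if hasattr(vol, "data"):
        data, grid = vol.data, vol.grid
    elif hasattr(vol, "values"):
        data, grid = vol.values, vol.grid
    elif hasattr(vol, "membership"):
        data, grid = vol.membership.astype(np.uint8), vol.grid
    elif hasattr(vol, "labels"):
        data, grid = vol.labels.astype(np.int32), vol.grid
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot write object of type {type(vol)}")
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    if hasattr(vol, "sampling_interval_s"):
        zooms = list(grid.voxel_size_mm) + [vol.sampling_interval_s]
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_parcellation(volume_path, table_path) -> Parcellation:
    """Read a label volume plus a TSV label table (columns: label, name, group, spinnable)."""
    vol = read_volume(volume_path)
    if isinstance(vol, BoldSeries):
        raise ValueError("parcellation volume must be 3D")
    labels = vol.values
    as_int = np.rint(labels).astype(np.int64)
    if not np.allclose(labels, as_int, atol=1e-6):
        raise ValueError("parcellation volume is not integer-valued")
    table = read_label_table(table_path)
    return Parcellation(vol.grid, as_int, table)


def read_label_table(table_path) -> dict[int, RoiInfo]:
    df = pd.read_csv(table_path, sep="\t")
    required = {"label", "name", "group", "spinnable"}
    if not required.issubset(df.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    table = {}
    for _, row in df.iterrows():
        spin = row["spinnable"]
        if isinstance(spin, str):
            spin = spin.strip().lower() in ("1", "true", "yes")
        table[int(row["label"])] = RoiInfo(str(row["name"]), str(row["group"]), bool(spin))
    return table


def write_label_table(table: Mapping[int, RoiInfo], path) -> None:
    rows = [
        {"label": lab, "name": info.name, "group": info.group, "spinnable": info.spinnable}
        for lab, info in sorted(table.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path) -> None:
    """All tabular results are tab-separated UTF-8 with a header row."""
    df.to_csv(path, sep="\t", index=False)


def read_mesh_text(path):
    """Plain-text sphere mesh: one vertex per line, ``x y z hemisphere``."""
    xs, hemis = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"expected 'x y z hemisphere' per line, got: {line!r}")
            xs.append([float(parts[0]), float(parts[1]), float(parts[2])])
            hemis.append(parts[3])
    return np.asarray(xs, dtype=float), np.asarray(hemis)


def write_mesh_text(vertices: np.ndarray, hemispheres: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for v, h in zip(vertices, hemispheres):
            fh.write(f"{v[0]:.12f} {v[1]:.12f} {v[2]:.12f} {h}\n")


def read_mesh_gifti(path):
    """Read vertex coordinates from a GIFTI surface; caller assigns the hemisphere tag."""
    img = nib.load(str(path))
    for arr in img.darrays:
        if arr.data.ndim == 2 and arr.data.shape[1] == 3:
            v = np.asarray(arr.data, dtype=float)
            norm = np.linalg.norm(v, axis=1, keepdims=True)
            return v / np.where(norm == 0, 1.0, norm)
    raise ValueError(f"no 3-column coordinate array found in {path}")
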