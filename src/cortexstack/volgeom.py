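"""Core volume / mesh / point geometry carriers and coordinate conventions.

All world coordinates are in micrometers (μm).  Volumes use a fixed axis
order ``(x, y, z)`` = left→right, posterior→anterior, inferior→superior.
Voxel indices are 0-based and refer to voxel *centers*: the world position
of voxel ``(i, j, k)`` is ``origin + index * spacing``.  Only axis-aligned
grids are supported; oblique affines are rejected on NIfTI import.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "VoxelGrid",
    "Mask",
    "SurfaceMesh",
    "PointSet",
    "resample_with_map",
    "mirror_x",
]

InterpMode = Literal["linear", "nearest"]


@dataclass
class VoxelGrid:
    """A 3D (or 4D channel-last) array with voxel spacing and world origin.

    Parameters
    ----------
    data:
        Numeric array, shape ``(nx, ny, nz)`` or ``(nx, ny, nz, c)``.
    spacing:
        Per-axis voxel size in μm, strictly positive.
    origin:
        World coordinate (μm) of the *center* of voxel ``(0, 0, 0)``.
    kind:
        ``"intensity"`` for continuous data, ``"label"`` for categorical
        volumes (labels may only be resampled with nearest-neighbor
        interpolation).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    kind: Literal["intensity", "label"] = "intensity"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"data must be 3D or 4D, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise ValueError("spacing must be strictly positive on all axes")

    # -- geometry -----------------------------------------------------------
    @property
    def shape3(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing) * 1e-9)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices ``(..., 3)`` to world μm."""
        idx = np.asarray(idx, dtype=float)
        return self.origin + idx * self.spacing

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world μm coordinates ``(..., 3)`` to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - self.origin) / self.spacing

    def world_center(self) -> np.ndarray:
        return self.origin + (np.array(self.shape3) - 1) * self.spacing / 2.0

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``shape3 + (3,)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape3], indexing="ij"), axis=-1
        )
        return self.voxel_to_world(idx)

    def like(self, data: np.ndarray, kind: str | None = None) -> "VoxelGrid":
        """A new grid with the same geometry carrying ``data``."""
        return VoxelGrid(data, self.spacing.copy(), self.origin.copy(),
                         kind or self.kind)

    def same_grid(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape3 == other.shape3
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    # -- I/O ----------------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.spacing)
        affine[:3, 3] = self.origin
        data = np.asarray(self.data)
        if data.dtype == bool:
            data = data.astype(np.uint8)
        elif data.dtype in (np.int64, np.uint64):
            data = data.astype(np.int32)  # NIfTI-1 has no 64-bit int
        img = nib.Nifti1Image(data, affine)
        img.header.set_xyzt_units(xyz="micron")
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, kind: str = "intensity") -> "VoxelGrid":
        img = nib.load(str(path))
        aff = np.asarray(img.affine, dtype=float)
        rot = aff[:3, :3]
        off_diag = rot - np.diag(np.diag(rot))
        if np.any(np.abs(off_diag) > 1e-6 * max(1.0, np.abs(rot).max())):
            raise ValueError("only axis-aligned NIfTI affines are supported")
        spacing = np.diag(rot)
        if np.any(spacing <= 0):
            raise ValueError("negative/zero affine scales are not supported")
        return cls(np.asanyarray(img.dataobj), spacing, aff[:3, 3], kind)


class Mask(VoxelGrid):
    """A binary :class:`VoxelGrid`; values are stored as uint8 in {0, 1}."""

    def __init__(self, data, spacing, origin, kind="label"):
        data = np.asarray(data)
        if data.ndim != 3:
            raise ValueError("Mask must be 3D")
        binary = (data != 0).astype(np.uint8)
        super().__init__(binary, spacing, origin, "label")

    @property
    def count(self) -> int:
        """Number of foreground voxels |mask|."""
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * self.voxel_volume_mm3

    @classmethod
    def from_grid(cls, grid: VoxelGrid) -> "Mask":
        return cls(grid.data, grid.spacing, grid.origin)


@dataclass
class SurfaceMesh:
    """Triangulated surface with per-vertex 2D flatmap coordinates.

    ``vertices`` are N×3 world μm, ``triangles`` M×3 vertex indices and
    ``flat_uv`` N×2 dimensionless flatmap coordinates in [0, 1]².
    """

    vertices: np.ndarray
    triangles: np.ndarray
    flat_uv: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.flat_uv = np.asarray(self.flat_uv, dtype=float)
        n = len(self.vertices)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be N×3")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be M×3")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise ValueError("triangle indices out of range")
        if self.flat_uv.shape != (n, 2):
            raise ValueError("flat_uv must be present for every vertex (N×2)")

    def n_connected_components(self) -> int:
        n = len(self.vertices)
        if n == 0:
            return 0
        i = np.concatenate([self.triangles[:, 0], self.triangles[:, 1],
                            self.triangles[:, 2]])
        j = np.concatenate([self.triangles[:, 1], self.triangles[:, 2],
                            self.triangles[:, 0]])
        adj = coo_matrix((np.ones_like(i), (i, j)), shape=(n, n))
        ncomp, _ = connected_components(adj, directed=False)
        return int(ncomp)

    def validate_connected(self) -> None:
        if self.n_connected_components() != 1:
            raise ValueError("mesh is not a single connected component")

    # -- I/O ----------------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        obj = {
            "vertices": self.vertices.tolist(),
            "triangles": self.triangles.tolist(),
            "flat_uv": self.flat_uv.tolist(),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "SurfaceMesh":
        obj = json.loads(Path(path).read_text())
        return cls(np.array(obj["vertices"]), np.array(obj["triangles"]),
                   np.array(obj["flat_uv"]))


@dataclass
class PointSet:
    """K×3 world-coordinate points with optional scalar values and labels."""

    points: np.ndarray
    values: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float).reshape(-1)
            if len(self.values) != len(self.points):
                raise ValueError("values length mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object).reshape(-1)
            if len(self.labels) != len(self.points):
                raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.points)

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.points, columns=["x", "y", "z"])
        if self.values is not None:
            df["value"] = self.values
        if self.labels is not None:
            df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PointSet":
        df = pd.read_csv(path)
        values = df["value"].to_numpy() if "value" in df else None
        labels = df["label"].to_numpy() if "label" in df else None
        return cls(df[["x", "y", "z"]].to_numpy(), values, labels)

    def to_json(self, path: str | Path) -> None:
        obj = {"points": self.points.tolist()}
        if self.values is not None:
            obj["values"] = self.values.tolist()
        if self.labels is not None:
            obj["labels"] = list(self.labels)
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "PointSet":
        obj = json.loads(Path(path).read_text())
        return cls(np.array(obj["points"]).reshape(-1, 3),
                   np.array(obj["values"]) if "values" in obj else None,
                   np.array(obj["labels"], dtype=object) if "labels" in obj else None)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _map_channel(channel: np.ndarray, vox_coords: np.ndarray, order: int,
                 cval: float) -> np.ndarray:
    return ndi.map_coordinates(
        channel, vox_coords, order=order, mode="constant", cval=cval,
        prefilter=False,
    )


def resample_with_map(
    volume: VoxelGrid,
    coordmap: np.ndarray,
    mode: InterpMode = "linear",
    fill: float = 0.0,
) -> VoxelGrid:
    """Resample ``volume`` at per-target-voxel source world coordinates.

    ``coordmap`` has shape ``target_shape + (3,)``; entry ``coordmap[v]`` is
    the world coordinate (μm) in the *source* volume whose (interpolated)
    value the output voxel ``v`` receives.  Entries may be NaN to mark
    undefined targets, which receive ``fill``; any other non-finite entry is
    an error.  Out-of-bounds coordinates receive ``fill``.

    Label volumes must use ``mode="nearest"``.
    """
    coordmap = np.asarray(coordmap, dtype=float)
    if coordmap.shape[-1] != 3:
        raise ValueError("coordmap must have a trailing axis of size 3")
    if np.any(np.isinf(coordmap)):
        raise ValueError("coordmap contains non-finite (inf) entries")
    if mode == "linear" and volume.kind == "label":
        raise ValueError("linear interpolation is invalid for label volumes")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    order = 1 if mode == "linear" else 0

    target_shape = coordmap.shape[:-1]
    undefined = np.any(np.isnan(coordmap), axis=-1)
    flat = coordmap.reshape(-1, 3)
    safe = np.where(np.isnan(flat), -1e9, flat)  # far outside -> fill value
    vox = volume.world_to_voxel(safe).T  # (3, K)

    if volume.data.ndim == 3:
        out = _map_channel(volume.data.astype(float, copy=False), vox, order, fill)
        out = out.reshape(target_shape)
        if volume.kind == "label":
            out = out.astype(volume.data.dtype)
    else:
        chans = [
            _map_channel(volume.data[..., c].astype(float, copy=False), vox,
                         order, fill).reshape(target_shape)
            for c in range(volume.data.shape[3])
        ]
        out = np.stack(chans, axis=-1)
    out[undefined] = fill
    # output inherits the source geometry by default; callers supply
    # target-grid geometry when they hold it (see flatstack.map_to_stack)
    return VoxelGrid(out, volume.spacing.copy(), volume.origin.copy(), volume.kind)


# ---------------------------------------------------------------------------
# mirroring
# ---------------------------------------------------------------------------

def _mirror_points(points: np.ndarray, x_mid: float) -> np.ndarray:
    out = np.array(points, dtype=float, copy=True)
    out[..., 0] = 2.0 * x_mid - out[..., 0]
    return out


def mirror_x(obj, x_mid: float | None = None):
    """Reflect an object through the mid-sagittal plane ``x = x_mid``.

    For a :class:`VoxelGrid` the default plane is the grid's world-center x,
    in which case mirroring is an exact axis flip (an involution).  For any
    other plane the volume is resampled back onto its own grid.  PointSets
    and tractograms (lists of polylines) reflect coordinates directly.
    """
    if isinstance(obj, VoxelGrid):
        center_x = obj.world_center()[0]
        if x_mid is None or abs(x_mid - center_x) < 1e-9:
            out = obj.like(np.flip(obj.data, axis=0).copy())
            if isinstance(obj, Mask):
                return Mask(out.data, out.spacing, out.origin)
            return out
        coordmap = obj.voxel_centers()
        coordmap = _mirror_points(coordmap, x_mid)
        mode = "nearest" if obj.kind == "label" else "linear"
        out = resample_with_map(obj, coordmap, mode=mode)
        if isinstance(obj, Mask):
            return Mask(out.data, out.spacing, out.origin)
        return out
    if isinstance(obj, PointSet):
        if x_mid is None:
            raise ValueError("x_mid is required to mirror a PointSet")
        return PointSet(_mirror_points(obj.points, x_mid),
                        None if obj.values is None else obj.values.copy(),
                        None if obj.labels is None else obj.labels.copy())
    if isinstance(obj, (list, tuple)):  # bare polyline list
        if x_mid is None:
            raise ValueError("x_mid is required to mirror polylines")
        return [np.ascontiguousarray(_mirror_points(np.asarray(p, dtype=float), x_mid))
                for p in obj]
    # duck-typed Tractogram (streamlines module) handles itself via this hook
    if hasattr(obj, "_mirror_x"):
        return obj._mirror_x(x_mid)
    raise TypeError(f"cannot mirror object of type {type(obj).__name__}")
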