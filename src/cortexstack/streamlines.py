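"""Tractogram symmetrization, mask-based selection, and track-density imaging.

Streamlines are polylines in world μm.  "Touching" a mask and visiting a
voxel are decided on the polyline densified to at most half-voxel steps
along every segment, which prevents segments from tunneling through thin
masks; the original geometry is never modified by selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .volgeom import Mask, VoxelGrid, _mirror_points

__all__ = [
    "Tractogram",
    "mirror_tractogram",
    "select_by_mask",
    "streamline_density",
    "densify_polyline",
]


@dataclass
class Tractogram:
    """A set of streamlines (ordered world-coordinate polylines, μm)."""

    streamlines: list
    metadata: list | None = None

    def __post_init__(self) -> None:
        sl = []
        for p in self.streamlines:
            arr = np.asarray(p, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or len(arr) < 2:
                raise ValueError("each streamline must be an L×3 polyline, L >= 2")
            if not np.all(np.isfinite(arr)):
                raise ValueError("streamline coordinates must be finite")
            sl.append(arr)
        self.streamlines = sl
        if self.metadata is not None and len(self.metadata) != len(sl):
            raise ValueError("one metadata entry per streamline required")

    def __len__(self) -> int:
        return len(self.streamlines)

    def _mirror_x(self, x_mid: float) -> "Tractogram":
        return Tractogram([_mirror_points(p, x_mid) for p in self.streamlines],
                          None if self.metadata is None else list(self.metadata))

    # -- TCK I/O (coordinates stored in μm) --------------------------------
    def to_tck(self, path: str | Path) -> None:
        tracto = nib.streamlines.Tractogram(
            [s.astype(np.float32) for s in self.streamlines],
            affine_to_rasmm=np.eye(4))
        nib.streamlines.save(tracto, str(path))

    @classmethod
    def from_tck(cls, path: str | Path) -> "Tractogram":
        tck = nib.streamlines.load(str(path))
        return cls([np.asarray(s, dtype=float) for s in tck.streamlines])


def densify_polyline(points: np.ndarray, max_step: float) -> np.ndarray:
    """Insert points so consecutive samples are at most ``max_step`` apart.

    Each segment is subdivided into a power-of-two number of pieces, so the
    sample set equals the original vertices plus recursively inserted
    segment midpoints (matching a vertex+midpoint touch oracle exactly).
    """
    points = np.asarray(points, dtype=float)
    seg = np.diff(points, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    out = [points[:1]]
    for p0, d, length in zip(points[:-1], seg, lens):
        n = 1 if length <= max_step else int(
            2 ** np.ceil(np.log2(length / max_step)))
        t = np.arange(1, n + 1)[:, None] / n
        out.append(p0 + t * d)
    return np.concatenate(out, axis=0)


def mirror_tractogram(t: Tractogram, x_mid: float) -> Tractogram:
    """Originals followed by their x-mirrored copies; count exactly doubles."""
    mirrored = t._mirror_x(x_mid)
    meta = None
    if t.metadata is not None:
        meta = list(t.metadata) + list(mirrored.metadata)
    return Tractogram(t.streamlines + mirrored.streamlines, meta)


def _visited_voxels(points: np.ndarray, grid: VoxelGrid, max_step: float
                    ) -> np.ndarray:
    """Unique voxel indices visited by the densified polyline (K×3 int)."""
    dense = densify_polyline(points, max_step)
    idx = np.round(grid.world_to_voxel(dense)).astype(np.int64)
    shape = np.asarray(grid.shape3)
    inb = np.all((idx >= 0) & (idx < shape), axis=1)
    idx = idx[inb]
    if len(idx) == 0:
        return idx
    return np.unique(idx, axis=0)


def select_by_mask(t: Tractogram, mask: Mask, sampling: float | None = None
                   ) -> Tractogram:
    """Streamlines whose densified path enters any foreground mask voxel.

    ``sampling`` is the densification step (μm); it defaults to half the
    smallest mask voxel size and may not exceed it.
    """
    max_step = float(mask.spacing.min()) / 2.0
    if sampling is not None:
        if sampling > max_step + 1e-9:
            raise ValueError("sampling must be <= half the mask voxel size")
        max_step = float(sampling)
    keep, meta = [], []
    data = mask.data
    for i, sl in enumerate(t.streamlines):
        vox = _visited_voxels(sl, mask, max_step)
        if len(vox) and np.any(data[vox[:, 0], vox[:, 1], vox[:, 2]] > 0):
            keep.append(sl)
            if t.metadata is not None:
                meta.append(t.metadata[i])
    return Tractogram(keep, meta if t.metadata is not None else None)


def streamline_density(t: Tractogram, grid: VoxelGrid,
                       sampling: float | None = None) -> VoxelGrid:
    """Track-density image: per voxel, the number of *distinct* streamlines
    whose densified path visits it (each streamline counts once per voxel).

    ``grid`` supplies the output geometry (its data values are ignored).
    """
    max_step = float(grid.spacing.min()) / 2.0
    if sampling is not None:
        max_step = min(max_step, float(sampling))
    density = np.zeros(grid.shape3, dtype=np.int64)
    for sl in t.streamlines:
        vox = _visited_voxels(sl, grid, max_step)
        if len(vox):
            density[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    return VoxelGrid(density, grid.spacing.copy(), grid.origin.copy())
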