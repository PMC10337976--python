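"""Tile vignetting correction and section stitching.

A tomography microscope emits overlapping image tiles (default 720×720 px,
~80 px overlap) together with plain-text world-coordinate offsets that are
precise enough to place tiles without cross-correlation refinement.
Vignetting is corrected by dividing each tile by a shading field estimated
as the (mean-normalized) average over many tiles; stitching crops the
unreliable tile borders and fuses the remainder with a linear-ramp blend
that forms a partition of unity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "TileSet",
    "estimate_shading",
    "correct_tiles",
    "stitch_tiles",
    "read_tileset",
    "write_tileset",
]

log = logging.getLogger(__name__)

#: paper-protocol defaults: 720×720 px tiles, ~80 px overlap, 50 px crop
TILE_SIZE = 720
TILE_OVERLAP = 80
CROP_PX = 50
#: in-plane pixel pitch, μm/px (row, column)
PIXEL_PITCH = (1.385, 1.339)


@dataclass
class TileSet:
    """Image tiles of one section with world-coordinate offsets.

    ``offsets[i]`` is the world position (μm, ``(row_axis, col_axis, z)``)
    of pixel (0, 0) of tile ``i``; ``pixel_pitch`` is μm/px per in-plane
    axis.
    """

    tiles: list
    offsets: np.ndarray
    pixel_pitch: np.ndarray

    def __post_init__(self) -> None:
        self.tiles = [np.asarray(t) for t in self.tiles]
        if not self.tiles:
            raise ValueError("TileSet needs at least one tile")
        shapes = {t.shape for t in self.tiles}
        if len(shapes) != 1:
            raise ValueError("all tiles must have the same shape")
        if self.tiles[0].ndim != 2:
            raise ValueError("tiles must be 2D arrays")
        self.offsets = np.asarray(self.offsets, dtype=float).reshape(-1, 3)
        if len(self.offsets) != len(self.tiles):
            raise ValueError("one offset per tile required")
        if not np.all(np.isfinite(self.offsets)):
            raise ValueError("offsets must be finite")
        self.pixel_pitch = np.asarray(self.pixel_pitch, dtype=float).reshape(2)
        if not np.all(self.pixel_pitch > 0):
            raise ValueError("pixel pitch must be positive")

    @property
    def tile_shape(self) -> tuple[int, int]:
        return self.tiles[0].shape

    def pixel_starts(self) -> np.ndarray:
        """Integer pixel placement of each tile on the section canvas."""
        return np.round(self.offsets[:, :2] / self.pixel_pitch).astype(np.int64)


# ---------------------------------------------------------------------------
# shading
# ---------------------------------------------------------------------------

def estimate_shading(tiles: Sequence[np.ndarray],
                     robust: Literal["mean", "median"] = "mean") -> np.ndarray:
    """Estimate the multiplicative shading (vignetting) field from tiles.

    The field is the per-pixel mean (or median) over the tile sample,
    normalized to mean 1; correcting a tile is ``tile / field``.
    """
    if len(tiles) == 0:
        raise ValueError("cannot estimate shading from an empty tile list")
    stack = np.stack([np.asarray(t, dtype=float) for t in tiles])
    if robust == "mean":
        field = stack.mean(axis=0)
    elif robust == "median":
        field = np.median(stack, axis=0)
    else:
        raise ValueError(f"unknown robust mode {robust!r}")
    if np.any(field <= 0):
        raise ValueError("shading field has non-positive pixels "
                         "(all-zero average at some pixel)")
    if len(tiles) == 1:
        log.warning("estimate_shading: single tile — the field is that tile "
                    "itself (degenerate estimate)")
    return field / field.mean()


def correct_tiles(tiles: Sequence[np.ndarray], field: np.ndarray) -> list:
    """Divide each tile by the shading field."""
    return [np.asarray(t, dtype=float) / field for t in tiles]


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------

def _axis_weight(n: int, crop_lead: int, crop_trail: int, ramp: int
                 ) -> np.ndarray:
    """1D blending weight across one tile axis after cropping.

    Rises linearly from 0 at a cropped border over ``ramp`` pixels; stays 1
    at uncropped (canvas-hull) borders.  The cropped span itself is excluded
    by giving it weight < 0 (meaning: no contribution).
    """
    w = np.full(n, -1.0)
    lo, hi = crop_lead, n - crop_trail
    span = np.ones(hi - lo)
    if crop_lead > 0 and ramp > 0:
        r = np.minimum(np.arange(hi - lo) / ramp, 1.0)
        span = np.minimum(span, r)
    if crop_trail > 0 and ramp > 0:
        r = np.minimum(np.arange(hi - lo)[::-1] / ramp, 1.0)
        span = np.minimum(span, r)
    w[lo:hi] = span
    return w


def stitch_tiles(tileset: TileSet, crop: int = CROP_PX,
                 blend: Literal["linear"] = "linear") -> np.ndarray:
    """Fuse tiles into one section image by linear blending.

    Each tile is cropped ``crop`` pixels on every border that faces another
    tile (borders on the section hull are kept so the canvas stays fully
    covered).  Within overlap zones the blending weight of a tile falls
    linearly to 0 at its cropped border over a ramp of
    ``max(overlap − 2·crop, 1)`` pixels, and the weights are normalized to
    a partition of unity.  Uncovered *interior* pixels raise an error that
    lists the gap bounding boxes.
    """
    if blend != "linear":
        raise ValueError("only linear blending is supported")
    starts = tileset.pixel_starts()
    th, tw = tileset.tile_shape
    origin = starts.min(axis=0)
    starts = starts - origin
    canvas_shape = tuple(starts.max(axis=0) + (th, tw))

    # implied overlap: smallest positive overlap between tile placements
    def _axis_overlap(axis: int, extent: int) -> int:
        pos = np.unique(starts[:, axis])
        if len(pos) < 2:
            return 0
        gaps = np.diff(pos)
        return int(max(extent - gaps.min(), 0))

    ov = max(_axis_overlap(0, th), _axis_overlap(1, tw))
    if ov and crop >= ov:
        # cropping more than half the overlap opens gaps between tiles
        log.warning("stitch_tiles: crop=%d >= implied overlap=%d", crop, ov)
    ramp = max(ov - 2 * crop, 1)

    acc = np.zeros(canvas_shape)
    wsum = np.zeros(canvas_shape)
    flat_acc = np.zeros(canvas_shape)
    cover = np.zeros(canvas_shape, dtype=np.int32)
    max_r, max_c = starts.max(axis=0)
    for tile, (r0, c0) in zip(tileset.tiles, starts):
        crop_r = (crop if r0 > 0 else 0, crop if r0 < max_r else 0)
        crop_c = (crop if c0 > 0 else 0, crop if c0 < max_c else 0)
        wr = _axis_weight(th, crop_r[0], crop_r[1], ramp)
        wc = _axis_weight(tw, crop_c[0], crop_c[1], ramp)
        w2 = np.minimum(wr[:, None], wc[None, :])
        inside = w2 >= 0.0
        w2 = np.where(inside, w2, 0.0)
        sl = (slice(r0, r0 + th), slice(c0, c0 + tw))
        t = np.asarray(tile, dtype=float)
        acc[sl] += t * w2
        wsum[sl] += w2
        flat_acc[sl] += np.where(inside, t, 0.0)
        cover[sl] += inside

    gaps = cover == 0
    if gaps.any():
        lab, n = ndi.label(gaps)
        boxes = ndi.find_objects(lab)
        desc = "; ".join(
            f"rows {b[0].start}:{b[0].stop} cols {b[1].start}:{b[1].stop}"
            for b in boxes[:10])
        raise ValueError(f"stitched section has {n} uncovered gap(s): {desc}")

    out = np.where(wsum > 0, acc / np.where(wsum > 0, wsum, 1.0),
                   flat_acc / cover)
    return out


# ---------------------------------------------------------------------------
# 16-bit tile I/O with plain-text offset tables
# ---------------------------------------------------------------------------

def write_tileset(tileset: TileSet, out_dir: str | Path,
                  prefix: str = "tile") -> Path:
    """Write tiles as 16-bit PNG plus an offset table ``offsets.txt``
    (one line per tile: ``path x y z``, coordinates in μm)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = [f"# pixel_pitch {tileset.pixel_pitch[0]} {tileset.pixel_pitch[1]}"]
    for i, (tile, off) in enumerate(zip(tileset.tiles, tileset.offsets)):
        name = f"{prefix}_{i:04d}.png"
        arr = np.clip(np.asarray(tile), 0, 65535).astype(np.uint16)
        iio.imwrite(out_dir / name, arr)
        lines.append(f"{name} {off[0]:.3f} {off[1]:.3f} {off[2]:.3f}")
    table = out_dir / "offsets.txt"
    table.write_text("\n".join(lines) + "\n")
    return table


def read_tileset(offsets_path: str | Path,
                 pixel_pitch: Sequence[float] | None = None) -> TileSet:
    """Read a tile set from an ``offsets.txt`` table written by
    :func:`write_tileset` (or by a microscope export in the same dialect)."""
    offsets_path = Path(offsets_path)
    base = offsets_path.parent
    tiles, offsets = [], []
    pitch = None if pixel_pitch is None else np.asarray(pixel_pitch, float)
    for line in offsets_path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts and parts[0] == "pixel_pitch":
                pitch = np.array([float(parts[1]), float(parts[2])])
            continue
        name, x, y, z = line.split()
        tiles.append(np.asarray(iio.imread(base / name)))
        offsets.append((float(x), float(y), float(z)))
    if pitch is None:
        pitch = np.asarray(PIXEL_PITCH)
    return TileSet(tiles, np.asarray(offsets), pitch)
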