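"""Synthetic phantoms with analytic ground truth for every pipeline stage.

Every generator is a pure function of its parameters and seed, and each
phantom is returned together with its ground-truth companions (masks, cell
centers, analytic coordinate functions, oracle voxel lists) so downstream
operations can be scored without external data.

The geometric workhorse is a spherical-shell cortex restricted to an
angular patch: relative depth and the equirectangular (longitude, latitude)
flatmap are then available in closed form, the patch keeps the flatmap
injective and distortion-bounded, and excluding the poles avoids the
coordinate singularities of the full sphere.  A flat-slab cortex covers the
degenerate limit where the direction field must be exactly constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import ndimage as ndi

from .flatstack import CortexModel
from .mosaic import PIXEL_PITCH, TILE_OVERLAP, TILE_SIZE, TileSet
from .sphere import DirectionSet, HardiImage
from .streamlines import Tractogram, densify_polyline
from .volgeom import Mask, PointSet, SurfaceMesh, VoxelGrid

__all__ = [
    "CortexTruth",
    "ShellCortexTruth",
    "SlabCortexTruth",
    "StptTruth",
    "make_shell_cortex",
    "make_slab_cortex",
    "make_stpt_phantom",
    "make_tileset",
    "make_hardi_phantom",
    "make_tractogram_phantom",
]


# ---------------------------------------------------------------------------
# cortex geometries with analytic coordinates
# ---------------------------------------------------------------------------

@dataclass
class CortexTruth:
    """A cortex model plus analytic depth and flatmap coordinate functions.

    ``depth_fn(points)`` returns relative depth in [0, 1] (0 = inner/white
    matter, 1 = outer/pia); ``flat_fn(points)`` returns (u, v) in [0, 1]².
    """

    cortex: CortexModel
    depth_fn: Callable[[np.ndarray], np.ndarray]
    flat_fn: Callable[[np.ndarray], np.ndarray]


@dataclass
class ShellCortexTruth(CortexTruth):
    r_inner: float = 0.0
    r_outer: float = 0.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    patch: tuple[float, float] = (0.0, 0.0)   # (Δlongitude, Δlatitude), rad


@dataclass
class SlabCortexTruth(CortexTruth):
    thickness: float = 0.0
    z_inner: float = 0.0


def _grid_for_extent(half_extent: np.ndarray, spacing: float):
    half_n = np.ceil(half_extent / spacing).astype(int) + 2
    shape = 2 * half_n + 1
    origin = -half_n * spacing
    return tuple(shape), origin


def make_shell_cortex(
    r_inner: float = 1000.0,
    r_outer: float = 2000.0,
    spacing: float = 50.0,
    patch: tuple[float, float] = (2 * np.pi / 3, 2 * np.pi / 3),
    mesh_density: float | None = None,
    seed: int = 0,
) -> ShellCortexTruth:
    """Spherical-shell cortex on an angular patch, with analytic truth.

    The patch is centered on the +x axis: longitude φ = atan2(y, x) and
    latitude λ = asin(z/r) each span the given extent symmetrically around
    zero, and must stay ≥ 10° away from the poles.  The mid-surface mesh
    is a regular (φ, λ) grid at radius (r_inner + r_outer)/2 whose flatmap
    coordinate is the patch-rescaled equirectangular map
    ``u = (φ − φ₀)/Δφ, v = (λ − λ₀)/Δλ``.

    ``mesh_density`` is in vertices per steradian (default: matched to the
    voxel size at the mid-surface radius).  ``seed`` is accepted for
    interface uniformity; the construction is deterministic.
    """
    del seed  # deterministic construction
    if not 0 < r_inner < r_outer:
        raise ValueError("need 0 < r_inner < r_outer")
    if spacing > (r_outer - r_inner) / 4:
        raise ValueError("spacing too coarse: shell thinner than 4 voxels")
    dphi, dlam = patch
    if dlam / 2 > np.radians(80.0):
        raise ValueError("patch must exclude the poles by at least 10°")

    shape, origin_val = _grid_for_extent(np.full(3, r_outer), spacing)
    origin = np.full(3, origin_val)
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape],
                               indexing="ij"), axis=-1)
    world = origin + idx * spacing
    r = np.linalg.norm(world, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.arcsin(np.clip(world[..., 2] / np.maximum(r, 1e-12), -1, 1))
        phi = np.arctan2(world[..., 1], world[..., 0])
    in_patch = (np.abs(phi) <= dphi / 2) & (np.abs(lam) <= dlam / 2)
    interior = (r > r_inner) & (r < r_outer) & in_patch

    dil = ndi.binary_dilation(interior, ndi.generate_binary_structure(3, 1))
    cand = dil & ~interior
    inner = cand & (r <= r_inner) & in_patch
    outer = cand & (r >= r_outer) & in_patch

    r_mid = 0.5 * (r_inner + r_outer)
    if mesh_density is None:
        # vertex pitch well below the voxel size so that flatmap coordinates
        # inherited from intersected vertices are not visibly quantized
        ang_step = spacing / (4.0 * r_mid)
    else:
        solid_angle = dphi * 2 * np.sin(dlam / 2)
        ang_step = float(np.sqrt(solid_angle / max(mesh_density * solid_angle,
                                                   16.0)))
    n_phi = max(int(np.ceil(dphi / ang_step)) + 1, 4)
    n_lam = max(int(np.ceil(dlam / ang_step)) + 1, 4)
    phis = np.linspace(-dphi / 2, dphi / 2, n_phi)
    lams = np.linspace(-dlam / 2, dlam / 2, n_lam)
    pp, ll = np.meshgrid(phis, lams, indexing="ij")
    verts = r_mid * np.stack([np.cos(ll) * np.cos(pp),
                              np.cos(ll) * np.sin(pp),
                              np.sin(ll)], axis=-1).reshape(-1, 3)
    uv = np.stack([(pp + dphi / 2) / dphi,
                   (ll + dlam / 2) / dlam], axis=-1).reshape(-1, 2)
    tris = []
    for i in range(n_phi - 1):
        for j in range(n_lam - 1):
            a = i * n_lam + j
            b = (i + 1) * n_lam + j
            tris.append((a, b, a + 1))
            tris.append((b, b + 1, a + 1))
    mesh = SurfaceMesh(verts, np.asarray(tris), uv)

    cortex = CortexModel(
        interior=Mask(interior, np.full(3, spacing), origin),
        inner_boundary=Mask(inner, np.full(3, spacing), origin),
        outer_boundary=Mask(outer, np.full(3, spacing), origin),
        mid_surface=mesh,
    )

    def depth_fn(points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        return (np.linalg.norm(pts, axis=1) - r_inner) / (r_outer - r_inner)

    def flat_fn(points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        rr = np.linalg.norm(pts, axis=1)
        lam_p = np.arcsin(np.clip(pts[:, 2] / np.maximum(rr, 1e-12), -1, 1))
        phi_p = np.arctan2(pts[:, 1], pts[:, 0])
        return np.stack([(phi_p + dphi / 2) / dphi,
                         (lam_p + dlam / 2) / dlam], axis=-1)

    return ShellCortexTruth(cortex, depth_fn, flat_fn, r_inner=r_inner,
                            r_outer=r_outer, center=np.zeros(3),
                            patch=(dphi, dlam))


def make_slab_cortex(
    thickness: float = 1000.0,
    lateral: float = 3000.0,
    spacing: float = 50.0,
) -> SlabCortexTruth:
    """Flat-slab cortex between two parallel planes (normal along +z).

    The analytic direction field is exactly the slab normal; depth is
    linear in z and the flatmap is the normalized (x, y) chart.
    """
    if spacing > thickness / 4:
        raise ValueError("spacing too coarse: slab thinner than 4 voxels")
    half = np.array([lateral / 2, lateral / 2, thickness / 2 + 2 * spacing])
    shape, _ = _grid_for_extent(half, spacing)
    origin = -(np.array(shape) - 1) * spacing / 2
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape],
                               indexing="ij"), axis=-1)
    world = origin + idx * spacing
    z0, z1 = -thickness / 2, thickness / 2
    lat = (np.abs(world[..., 0]) <= lateral / 2) & \
          (np.abs(world[..., 1]) <= lateral / 2)
    interior = (world[..., 2] > z0) & (world[..., 2] < z1) & lat
    dil = ndi.binary_dilation(interior, ndi.generate_binary_structure(3, 1))
    cand = dil & ~interior
    inner = cand & (world[..., 2] <= z0) & lat
    outer = cand & (world[..., 2] >= z1) & lat

    n_side = max(int(lateral / spacing) + 1, 4)
    ax = np.linspace(-lateral / 2, lateral / 2, n_side)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    verts = np.stack([xx, yy, np.zeros_like(xx)], axis=-1).reshape(-1, 3)
    uv = np.stack([(xx + lateral / 2) / lateral,
                   (yy + lateral / 2) / lateral], axis=-1).reshape(-1, 2)
    tris = []
    for i in range(n_side - 1):
        for j in range(n_side - 1):
            a = i * n_side + j
            b = (i + 1) * n_side + j
            tris.append((a, b, a + 1))
            tris.append((b, b + 1, a + 1))
    mesh = SurfaceMesh(verts, np.asarray(tris), uv)
    sp = np.full(3, spacing)
    cortex = CortexModel(Mask(interior, sp, origin), Mask(inner, sp, origin),
                         Mask(outer, sp, origin), mesh)

    def depth_fn(points):
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        return (pts[:, 2] - z0) / thickness

    def flat_fn(points):
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        return np.stack([(pts[:, 0] + lateral / 2) / lateral,
                         (pts[:, 1] + lateral / 2) / lateral], axis=-1)

    return SlabCortexTruth(cortex, depth_fn, flat_fn, thickness=thickness,
                           z_inner=z0)


# ---------------------------------------------------------------------------
# 3-channel tomography phantom
# ---------------------------------------------------------------------------

@dataclass
class StptTruth:
    """Ground truth companions of the 3-channel tomography phantom."""

    injection: Mask
    tracer: Mask
    cells: PointSet
    fiber_polylines: list


def _random_fiber(rng: np.random.Generator, start: np.ndarray,
                  length: float, step: float) -> np.ndarray:
    """A meandering polyline: unit steps with small random curvature."""
    n = max(int(length / step), 2)
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pts = [start]
    for _ in range(n):
        d = d + 0.35 * rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + step * d)
    return np.asarray(pts)


def make_stpt_phantom(
    truth: CortexTruth,
    injection_center: np.ndarray | None = None,
    injection_radius: float = 250.0,
    n_fibers: int = 12,
    n_cells: int = 30,
    noise_sd: float = 0.02,
    seed: int = 0,
):
    """Three-channel tomography-like volume with planted structures.

    Channel 0 carries the auto-fluorescent background (plus a faint tracer
    echo), channel 1 the same background plus bright tracer fibers
    emanating from a saturated injection blob, and channel 2 is near zero
    outside the injection with bright Gaussian spots at the planted cell
    centers inside it.  Returns ``(VoxelGrid 4D, StptTruth)``.
    """
    if n_fibers < 0:
        raise ValueError("n_fibers must be >= 0")
    rng = np.random.default_rng(seed)
    grid = truth.cortex.grid
    shape = grid.shape3
    spacing = float(grid.spacing.min())
    world = grid.voxel_centers()

    if injection_center is None:
        # a mid-depth point: centroid of the interior mask
        idx = np.argwhere(truth.cortex.interior.data > 0)
        injection_center = grid.voxel_to_world(idx.mean(axis=0))
    injection_center = np.asarray(injection_center, dtype=float)
    dist = np.linalg.norm(world - injection_center, axis=-1)
    inj = dist <= injection_radius
    if not inj.any():
        raise ValueError("injection sphere does not cover any voxel")

    rough = ndi.gaussian_filter(rng.normal(size=shape), 4.0)
    background = np.clip(1000.0 + 50.0 * rough / max(rough.std(), 1e-9),
                         0, None)

    fiber_mask = np.zeros(shape, dtype=bool)
    polylines = []
    for _ in range(n_fibers):
        poly = _random_fiber(rng, injection_center,
                             length=12 * injection_radius, step=spacing)
        polylines.append(poly)
        dense = densify_polyline(poly, spacing / 2)
        vox = np.round(grid.world_to_voxel(dense)).astype(int)
        ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
        vox = vox[ok]
        fiber_mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    fiber_mask = ndi.binary_dilation(fiber_mask, ndi.generate_binary_structure(3, 1))
    tracer_only = fiber_mask & ~inj

    fiber_amp = 3000.0
    ch1 = background + 0.1 * fiber_amp * tracer_only
    ch2 = background + fiber_amp * tracer_only
    ch2[inj] = 60000.0

    # channel 2 (index): cell-body spots inside the injection sphere
    cells = []
    cand_idx = np.argwhere(dist <= injection_radius * 0.8)
    rng.shuffle(cand_idx)
    min_sep = 3.0 * spacing
    for ci in cand_idx:
        p = grid.voxel_to_world(ci)
        if all(np.linalg.norm(p - q) >= min_sep for q in cells):
            cells.append(p)
        if len(cells) >= n_cells:
            break
    spots = np.zeros(shape)
    for p in cells:
        ci = tuple(np.round(grid.world_to_voxel(p)).astype(int))
        spots[ci] = 3000.0 * (0.9 + 0.2 * rng.random())
    ch3 = ndi.gaussian_filter(spots, 1.0) * (2 * np.pi) ** 1.5  # peak ≈ amp
    ch3 += np.abs(rng.normal(0.0, 5.0, size=shape))

    def noisy(c):
        return np.clip(c * (1.0 + noise_sd * rng.normal(size=shape)), 0, None)

    data = np.stack([noisy(ch1), noisy(ch2), noisy(ch3)], axis=-1)
    vol = VoxelGrid(data, grid.spacing, grid.origin)
    truth_out = StptTruth(
        injection=Mask(inj, grid.spacing, grid.origin),
        tracer=Mask(tracer_only, grid.spacing, grid.origin),
        cells=PointSet(np.asarray(cells).reshape(-1, 3),
                       values=np.ones(len(cells))),
        fiber_polylines=polylines,
    )
    return vol, truth_out


# ---------------------------------------------------------------------------
# tile mosaics
# ---------------------------------------------------------------------------

def make_tileset(
    image: np.ndarray,
    tile_size: int = TILE_SIZE,
    overlap: int = TILE_OVERLAP,
    vignette: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    pixel_pitch: Sequence[float] = PIXEL_PITCH,
) -> TileSet:
    """Cut an image into overlapping tiles with vignetting and noise.

    Tile count per axis is ``ceil((size − overlap)/(tile_size − overlap))``;
    the last tile is shifted back so every tile has the full size.  Images
    smaller than one tile yield a single (smaller) tile.  Each tile is
    ``crop × vignette × (1 + noise)`` with multiplicative Gaussian noise.
    """
    image = np.asarray(image, dtype=float)
    if overlap >= tile_size / 2:
        raise ValueError("overlap must be < tile_size/2")
    if vignette is not None:
        vignette = np.asarray(vignette, dtype=float)
        if np.any(vignette <= 0):
            raise ValueError("vignette must be strictly positive")
    rng = np.random.default_rng(seed)
    pitch = np.asarray(pixel_pitch, dtype=float)

    def _starts(size: int) -> list[int]:
        if size <= tile_size:
            return [0]
        stride = tile_size - overlap
        count = int(np.ceil((size - overlap) / stride))
        return [min(i * stride, size - tile_size) for i in range(count)]

    tiles, offsets = [], []
    for r0 in _starts(image.shape[0]):
        for c0 in _starts(image.shape[1]):
            t = image[r0:r0 + tile_size, c0:c0 + tile_size].copy()
            if vignette is not None:
                t = t * vignette[: t.shape[0], : t.shape[1]]
            if noise_sd > 0:
                t = np.clip(t * (1 + noise_sd * rng.normal(size=t.shape)),
                            0, None)
            tiles.append(t)
            offsets.append((r0 * pitch[0], c0 * pitch[1], 0.0))
    return TileSet(tiles, np.asarray(offsets), pitch)


# ---------------------------------------------------------------------------
# HARDI phantom (single-tensor signal)
# ---------------------------------------------------------------------------

def make_hardi_phantom(
    shape: tuple[int, int, int],
    dirs: DirectionSet,
    bvals: np.ndarray,
    tensor_field: np.ndarray,
    s0: float = 1000.0,
    spacing: float = 200.0,
) -> HardiImage:
    """Analytic single-tensor diffusion signal ``S = S0·exp(−b·nᵀDn)``.

    ``tensor_field`` is one 3×3 SPD tensor (mm²/s) applied everywhere or a
    per-voxel ``shape + (3, 3)`` array; ``bvals`` (s/mm²) has one entry per
    direction.  Antipodal symmetry holds exactly by construction.
    """
    tensors = np.asarray(tensor_field, dtype=float)
    if tensors.shape == (3, 3):
        tensors = np.broadcast_to(tensors, tuple(shape) + (3, 3))
    elif tensors.shape != tuple(shape) + (3, 3):
        raise ValueError("tensor_field must be 3×3 or shape+(3,3)")
    eig = np.linalg.eigvalsh(tensors.reshape(-1, 3, 3))
    sym = np.abs(tensors - np.swapaxes(tensors, -1, -2)).max()
    if sym > 1e-12 or np.any(eig <= 0):
        raise ValueError("tensors must be symmetric positive definite")
    bvals = np.asarray(bvals, dtype=float).reshape(-1)
    n = dirs.vectors
    if len(bvals) != len(n):
        raise ValueError("one b-value per direction required")
    # nᵀ D n per voxel and direction
    ndn = np.einsum("di,...ij,dj->...d", n, tensors, n)
    signal = s0 * np.exp(-bvals * ndn)
    return HardiImage(signal, dirs, bvals, np.full(3, float(spacing)),
                      np.zeros(3))


# ---------------------------------------------------------------------------
# tractogram phantom
# ---------------------------------------------------------------------------

def make_tractogram_phantom(
    n: int,
    geometry: Literal["straight", "arc", "helix"] = "straight",
    bbox: tuple[np.ndarray, np.ndarray] = ((0.0, 0.0, 0.0),
                                           (2000.0, 2000.0, 2000.0)),
    seed: int = 0,
    ref_grid: VoxelGrid | None = None,
    n_points: int = 32,
) -> Tractogram:
    """Synthetic streamlines with known geometry.

    ``straight`` lines run along +x through randomly chosen (y, z)
    positions; when ``ref_grid`` is given these positions snap to voxel
    centers and each streamline's metadata records the exact voxel row it
    traverses (the oracle for selection/density tests).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    lo = np.asarray(bbox[0], dtype=float)
    hi = np.asarray(bbox[1], dtype=float)
    rng = np.random.default_rng(seed)
    streamlines, metadata = [], []
    for _ in range(n):
        if geometry == "straight":
            if ref_grid is not None:
                shape = np.asarray(ref_grid.shape3)
                j = int(rng.integers(0, shape[1]))
                k = int(rng.integers(0, shape[2]))
                y, z = ref_grid.voxel_to_world((0.0, j, k))[1:]
                x0 = ref_grid.voxel_to_world((0.0, 0, 0))[0]
                x1 = ref_grid.voxel_to_world((shape[0] - 1.0, 0, 0))[0]
                xs = np.linspace(x0, x1, n_points)
                voxels = np.stack([np.arange(shape[0]),
                                   np.full(shape[0], j),
                                   np.full(shape[0], k)], axis=-1)
                metadata.append({"voxels": voxels})
            else:
                y, z = rng.uniform(lo[1:], hi[1:])
                xs = np.linspace(lo[0], hi[0], n_points)
                metadata.append({})
            pts = np.stack([xs, np.full_like(xs, y), np.full_like(xs, z)],
                           axis=-1)
        elif geometry == "arc":
            c = rng.uniform(lo, hi)
            r = 0.25 * float(np.min(hi - lo)) * (0.5 + rng.random())
            t = np.linspace(0, np.pi, n_points)
            pts = c + r * np.stack([np.cos(t), np.sin(t),
                                    np.zeros_like(t)], axis=-1)
            metadata.append({})
        elif geometry == "helix":
            c = rng.uniform(lo, hi)
            r = 0.15 * float(np.min(hi - lo))
            t = np.linspace(0, 4 * np.pi, n_points)
            pts = c + np.stack([r * np.cos(t), r * np.sin(t),
                                t / (4 * np.pi) * (hi[2] - lo[2]) * 0.5],
                               axis=-1)
            metadata.append({})
        else:
            raise ValueError(f"unknown geometry {geometry!r}")
        streamlines.append(pts)
    return Tractogram(streamlines, metadata)
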