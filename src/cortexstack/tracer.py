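"""Injection-site localization, cell peak extraction, and tracer maps.

The injection site is found as the brightest connected structure of the
third acquisition channel: Gaussian smoothing, a threshold at half the
image maximum, and the largest 26-connected component.  Cell bodies are
strict local maxima of a probability map above 0.5.  Anterograde tracer
signal is summarized two ways: a *density* stack counting tracer-positive
pixels per 50×50 μm in-plane bin of each section, and a *normalized
intensity* (channel 2 − channel 1, normalized by its strongest value
outside the injection site, where the signal saturates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi

from .volgeom import Mask, PointSet, VoxelGrid

__all__ = [
    "InjectionSite",
    "CellSet",
    "TracerMaps",
    "locate_injection_site",
    "extract_peaks",
    "segment_tracer_by_intensity",
    "tracer_density",
    "normalized_intensity",
    "combine_max",
    "rasterize_points",
    "classify_laminar",
]

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class InjectionSite:
    """Largest bright connected component of the injection channel."""

    mask: Mask
    centroid: np.ndarray        # world μm
    volume_mm3: float
    peak: float                 # maximum smoothed intensity used to threshold

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(3)


class CellSet(PointSet):
    """Detected cell locations with probabilities and laminar labels."""

    @property
    def probabilities(self) -> np.ndarray | None:
        return self.values


@dataclass
class TracerMaps:
    """Tracer density (counts) and normalized intensity on a common grid."""

    density: VoxelGrid
    intensity: VoxelGrid
    norm_constant: float


# ---------------------------------------------------------------------------
# injection site
# ---------------------------------------------------------------------------

def locate_injection_site(
    ch3: VoxelGrid,
    sigma: float = 100.0,
    threshold_frac: float = 0.5,
) -> InjectionSite:
    """Rough injection-site localization in the cell-body channel.

    Gaussian smoothing (``sigma`` in μm), a threshold at
    ``threshold_frac`` × the smoothed maximum (default: half max), and
    26-connected component analysis; the largest component is the site.
    """
    data = np.asarray(ch3.data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected a single-channel 3D volume")
    if data.max() <= 0:
        raise ValueError("no injection signal (all-zero volume)")
    sigma_vox = sigma / ch3.spacing
    smoothed = ndi.gaussian_filter(data, sigma_vox)
    peak = float(smoothed.max())
    above = smoothed >= threshold_frac * peak
    if above.all():
        log.warning("locate_injection_site: threshold keeps the entire "
                    "volume (degenerate uniform input)")
    lab, n = ndi.label(above, structure=_CONN26)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    best = int(sizes.argmax())
    comp = lab == best
    mask = Mask(comp, ch3.spacing, ch3.origin)
    centroid_vox = np.array(ndi.center_of_mass(comp))
    return InjectionSite(mask=mask,
                         centroid=ch3.voxel_to_world(centroid_vox),
                         volume_mm3=mask.volume_mm3, peak=peak)


# ---------------------------------------------------------------------------
# peak extraction
# ---------------------------------------------------------------------------

def extract_peaks(
    prob_map: VoxelGrid | np.ndarray,
    p_min: float = 0.5,
    min_separation: float = 0.0,
) -> CellSet:
    """Cell locations as local probability maxima above ``p_min``.

    Maxima are strict with respect to their full (8/26) neighborhood;
    plateaus of equal probability collapse to their centroid.  Peaks closer
    than ``min_separation`` (μm) are non-maximum-suppressed in descending
    probability order.  Output is invariant under monotone intensity
    transforms that preserve the ``p_min`` crossing.
    """
    if isinstance(prob_map, VoxelGrid):
        data = np.asarray(prob_map.data, dtype=float)
        spacing = prob_map.spacing
        origin = prob_map.origin
    else:
        data = np.asarray(prob_map, dtype=float)
        spacing = np.ones(3)
        origin = np.zeros(3)
    if data.ndim not in (2, 3):
        raise ValueError("probability map must be 2D or 3D")
    if data.min() < -1e-6 or data.max() > 1 + 1e-6:
        raise ValueError("probabilities must lie in [0, 1]")

    footprint = np.ones((3,) * data.ndim, dtype=bool)
    maxf = ndi.maximum_filter(data, footprint=footprint, mode="constant",
                              cval=-np.inf)
    cand = (data >= maxf) & (data >= p_min)
    if not cand.any():
        return CellSet(np.empty((0, 3)), values=np.empty(0))
    lab, n = ndi.label(cand, structure=footprint)
    centroids = np.asarray(ndi.center_of_mass(cand, lab, np.arange(1, n + 1)))
    probs = np.asarray(ndi.maximum(data, lab, np.arange(1, n + 1)), dtype=float)

    if data.ndim == 2:
        centroids = np.column_stack([centroids, np.zeros(len(centroids))])
        sp3 = np.array([spacing[0], spacing[1], 1.0])
        world = centroids * sp3 + np.array([origin[0], origin[1], 0.0])
    else:
        world = centroids * spacing + origin

    # deterministic NMS: descending probability, then lexicographic position
    order = np.lexsort((world[:, 2], world[:, 1], world[:, 0], -probs))
    kept: list[int] = []
    for i in order:
        p = world[i]
        if all(np.linalg.norm(p - world[j]) >= min_separation for j in kept):
            kept.append(i)
    kept_arr = np.array(kept, dtype=int)
    return CellSet(world[kept_arr], values=probs[kept_arr])


# ---------------------------------------------------------------------------
# tracer segmentation stand-in
# ---------------------------------------------------------------------------

def segment_tracer_by_intensity(
    ch1: VoxelGrid | np.ndarray,
    ch2: VoxelGrid | np.ndarray,
    k_sd: float = 3.0,
    injection: Mask | None = None,
    dilation: int = 2,
) -> Mask:
    """Threshold-based tracer segmentation (probability-map stand-in).

    Keeps voxels where ``ch2 − ch1`` exceeds the background mean plus
    ``k_sd`` standard deviations; background statistics are estimated
    outside the injection mask dilated by ``dilation`` voxels.  A single
    morphological opening removes isolated voxels.  Any probability-map
    producer (e.g. a trained network) can replace this by supplying its own
    mask; downstream maps only consume masks.
    """
    a = ch1.data if isinstance(ch1, VoxelGrid) else np.asarray(ch1)
    b = ch2.data if isinstance(ch2, VoxelGrid) else np.asarray(ch2)
    if a.shape != b.shape:
        raise ValueError("channels must be co-registered with equal shape")
    diff = b.astype(float) - a.astype(float)
    bg = np.ones(a.shape, dtype=bool)
    if injection is not None:
        excl = ndi.binary_dilation(injection.data.astype(bool),
                                   iterations=dilation)
        bg &= ~excl
    mu = float(diff[bg].mean())
    sd = float(diff[bg].std())
    raw = diff > mu + k_sd * sd
    opened = ndi.binary_opening(
        raw, structure=ndi.generate_binary_structure(a.ndim, 1))
    if isinstance(ch2, VoxelGrid):
        return Mask(opened, ch2.spacing, ch2.origin)
    return Mask(opened, np.ones(3), np.zeros(3))


# ---------------------------------------------------------------------------
# density / intensity maps
# ---------------------------------------------------------------------------

def tracer_density(
    section_masks: Sequence[np.ndarray],
    pixel_pitch: Sequence[float],
    out_spacing: float = 50.0,
    section_pitch: float = 50.0,
) -> VoxelGrid:
    """Tracer density stack from per-section binary segmentations.

    Each output voxel counts the tracer-positive pixels whose centers fall
    in its ``out_spacing`` × ``out_spacing`` μm in-plane bin; the z index is
    the section index.  The total positive-pixel count is conserved.
    """
    pitch = np.asarray(pixel_pitch, dtype=float).reshape(2)
    if np.any(pitch <= 0) or out_spacing <= 0:
        raise ValueError("pitches must be positive")
    n_sections = len(section_masks)
    if n_sections == 0:
        raise ValueError("need at least one section")
    shapes = np.array([np.asarray(m).shape for m in section_masks])
    h, w = shapes.max(axis=0)
    nx = int(np.ceil(h * pitch[0] / out_spacing))
    ny = int(np.ceil(w * pitch[1] / out_spacing))
    density = np.zeros((max(nx, 1), max(ny, 1), n_sections), dtype=np.int64)
    for z, m in enumerate(section_masks):
        pos = np.argwhere(np.asarray(m) != 0)
        if len(pos) == 0:
            continue
        bins = np.floor(pos * pitch / out_spacing).astype(np.int64)
        np.add.at(density, (bins[:, 0], bins[:, 1], np.full(len(bins), z)), 1)
    origin = np.array([out_spacing / 2, out_spacing / 2, 0.0])
    return VoxelGrid(density, (out_spacing, out_spacing, section_pitch),
                     origin)


def normalized_intensity(
    ch1: VoxelGrid,
    ch2: VoxelGrid,
    injection: Mask,
    dilation: int = 2,
) -> tuple[VoxelGrid, float]:
    """Tracer signal intensity normalized outside the injection site.

    The signal is ``max(ch2 − ch1, 0)`` divided by its maximum over voxels
    outside the injection mask dilated by ``dilation`` voxels (the site
    itself saturates, so values inside it may exceed 1 and are not
    clamped).  Returns ``(intensity, norm_constant)``.
    """
    if not (ch1.same_grid(ch2) and ch1.same_grid(injection)):
        raise ValueError("channels and injection mask must share one grid")
    diff = np.clip(ch2.data.astype(float) - ch1.data.astype(float), 0, None)
    excl = ndi.binary_dilation(injection.data.astype(bool),
                               iterations=dilation)
    outside = diff[~excl]
    norm = float(outside.max()) if outside.size else 0.0
    if norm <= 0:
        raise ValueError("no tracer signal to normalize outside the "
                         "injection site")
    return ch1.like(diff / norm), norm


def combine_max(maps: Sequence[VoxelGrid]) -> VoxelGrid:
    """Voxelwise maximum of co-registered (normalized) tracer maps."""
    if len(maps) == 0:
        raise ValueError("need at least one map")
    ref = maps[0]
    out = np.asarray(ref.data, dtype=float).copy()
    for m in maps[1:]:
        if not ref.same_grid(m):
            raise ValueError("maps must share one grid")
        out = np.maximum(out, m.data)
    return ref.like(out)


def rasterize_points(
    points: PointSet,
    spacing: float,
    extent: tuple[np.ndarray, np.ndarray] | None = None,
) -> VoxelGrid:
    """Point (cell) density image: per-voxel counts at ``spacing`` μm.

    ``extent`` is ``(lower, upper)`` world corners; by default it snaps to
    the point bounding box.  Points outside the extent are counted and
    logged, never silently dropped into edge bins.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pts = points.points
    if extent is None:
        if len(pts) == 0:
            return VoxelGrid(np.zeros((1, 1, 1), dtype=np.int64),
                             np.full(3, spacing), np.full(3, spacing / 2))
        lo = np.floor(pts.min(axis=0) / spacing) * spacing
        hi = pts.max(axis=0)
    else:
        lo = np.asarray(extent[0], dtype=float)
        hi = np.asarray(extent[1], dtype=float)
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    bins = np.floor((pts - lo) / spacing).astype(np.int64)
    inb = np.all((bins >= 0) & (bins < shape), axis=1)
    n_out = int(np.sum(~inb))
    if n_out:
        log.info("rasterize_points: %d points outside the extent", n_out)
    data = np.zeros(tuple(shape), dtype=np.int64)
    b = bins[inb]
    np.add.at(data, (b[:, 0], b[:, 1], b[:, 2]), 1)
    return VoxelGrid(data, np.full(3, spacing), lo + spacing / 2)


def classify_laminar(
    cells: PointSet,
    depth_of: Callable[[np.ndarray], np.ndarray],
    boundary: float = 0.5,
) -> CellSet:
    """Label cells supra-/infragranular by relative cortical depth.

    ``depth_of`` maps world points to relative depth (0 = white-matter
    side, 1 = pial side); depth below ``boundary`` is infragranular, at or
    above is supragranular.  The default boundary 0.5 is a documented
    surrogate for cortical layer IV.  Points without a valid depth (outside
    the cortex) are labeled ``"unassigned"`` and logged.
    """
    if not 0 <= boundary <= 1:
        raise ValueError("boundary must lie in [0, 1]")
    depth = np.asarray(depth_of(cells.points), dtype=float).reshape(-1)
    labels = np.where(depth < boundary, "infragranular", "supragranular")
    labels = labels.astype(object)
    bad = ~np.isfinite(depth)
    if bad.any():
        labels[bad] = "unassigned"
        log.info("classify_laminar: %d cells outside the cortex", int(bad.sum()))
    return CellSet(cells.points.copy(),
                   values=None if cells.values is None else cells.values.copy(),
                   labels=labels)
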