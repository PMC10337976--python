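"""Similarity and validation statistics.

Normalized cross-correlation (NCC) matrices between tracer maps,
nearest-injection pairing, permutation tests on (upper-triangle) matrix
correlations, Dice overlap of masks, and landmark-displacement reports
comparing automated registration against human experts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .volgeom import Mask, VoxelGrid

__all__ = [
    "SimilarityMatrix",
    "PermutationResult",
    "DisplacementReport",
    "ncc",
    "pair_by_injection_distance",
    "similarity_matrix",
    "corr_perm_test",
    "dice",
    "landmark_report",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Pairwise NCC values with row/column identifiers."""

    values: np.ndarray
    row_ids: list
    col_ids: list
    symmetric: bool = False
    missing: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids,
                            columns=self.col_ids)


@dataclass
class PermutationResult:
    """Observed correlation and permutation p-value (+1 corrected)."""

    observed: float
    n_reps: int
    p_value: float
    seed: int
    method: str


@dataclass
class DisplacementReport:
    """Landmark displacement comparison: experts vs automated mapping."""

    table: pd.DataFrame           # per (subject, landmark) medians per group
    per_landmark: pd.DataFrame    # medians aggregated over subjects
    fraction_auto_closer: float
    n_excluded: int


# ---------------------------------------------------------------------------
# image similarity
# ---------------------------------------------------------------------------

def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, VoxelGrid) else np.asarray(x)


def ncc(a, b, mask=None) -> float:
    """Normalized cross-correlation over a mask (Pearson on voxels).

    Default mask: union of the nonzero supports of both inputs.  Raises on
    degenerate inputs (fewer than 2 masked voxels or zero variance).
    """
    av, bv = _as_array(a).astype(float), _as_array(b).astype(float)
    if av.shape != bv.shape:
        raise ValueError("inputs must be co-registered with equal shape")
    if mask is None:
        m = (av != 0) | (bv != 0)
    else:
        m = _as_array(mask).astype(bool)
        if m.shape != av.shape:
            raise ValueError("mask shape mismatch")
    x, y = av[m], bv[m]
    if x.size < 2:
        raise ValueError("degenerate NCC: fewer than 2 masked voxels")
    x = x - x.mean()
    y = y - y.mean()
    sx, sy = np.sqrt(np.sum(x * x)), np.sqrt(np.sum(y * y))
    if sx == 0 or sy == 0:
        raise ValueError("degenerate NCC: zero variance under the mask")
    return float(np.clip(np.sum(x * y) / (sx * sy), -1.0, 1.0))


def similarity_matrix(items: Sequence, mask=None, ids: Sequence | None = None,
                      items_b: Sequence | None = None,
                      ids_b: Sequence | None = None) -> SimilarityMatrix:
    """Pairwise NCC matrix over a list of volumes (or two lists).

    With a single list the result is symmetric with unit diagonal.
    Degenerate entries are recorded in ``missing`` and set to NaN, never
    silently zeroed.
    """
    if ids is None:
        ids = list(range(len(items)))
    sym = items_b is None
    b_items = items if sym else items_b
    b_ids = ids if sym else (ids_b if ids_b is not None
                             else list(range(len(b_items))))
    n, m = len(items), len(b_items)
    vals = np.full((n, m), np.nan)
    missing = []
    for i in range(n):
        for j in range(m):
            if sym and j < i:
                vals[i, j] = vals[j, i]
                continue
            if sym and i == j:
                vals[i, j] = 1.0
                continue
            try:
                vals[i, j] = ncc(items[i], b_items[j], mask=mask)
            except ValueError as err:
                missing.append((ids[i], b_ids[j], str(err)))
    if missing:
        log.warning("similarity_matrix: %d degenerate entries", len(missing))
    return SimilarityMatrix(vals, list(ids), list(b_ids), symmetric=sym,
                            missing=missing)


def pair_by_injection_distance(sites_a, sites_b,
                               ids_a: Sequence | None = None,
                               ids_b: Sequence | None = None) -> pd.DataFrame:
    """Pair each site in ``a`` with its nearest-centroid site in ``b``.

    Accepts :class:`~cortexstack.tracer.InjectionSite` lists or (K, 3)
    centroid arrays.  Ties break toward the lower identifier index (and are
    logged).  Returns a table with columns ``a, b, distance_um``.
    """
    def _centroids(sites):
        if hasattr(sites[0], "centroid"):
            return np.stack([s.centroid for s in sites])
        return np.asarray(sites, dtype=float).reshape(-1, 3)

    if len(sites_a) == 0 or len(sites_b) == 0:
        raise ValueError("both site lists must be non-empty")
    ca, cb = _centroids(sites_a), _centroids(sites_b)
    ids_a = list(ids_a) if ids_a is not None else list(range(len(ca)))
    ids_b = list(ids_b) if ids_b is not None else list(range(len(cb)))
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    j = d.argmin(axis=1)
    best = d[np.arange(len(ca)), j]
    for i in range(len(ca)):
        if np.sum(np.isclose(d[i], best[i])) > 1:
            log.info("pair_by_injection_distance: tie for site %s resolved "
                     "toward the first candidate", ids_a[i])
    return pd.DataFrame({"a": ids_a, "b": [ids_b[k] for k in j],
                         "distance_um": best})


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _upper_triangle(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _pearson_many(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Pearson r of x against each row of ys (vectorized)."""
    xc = x - x.mean()
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = yc @ xc
    den = np.sqrt(np.sum(xc * xc) * np.sum(yc * yc, axis=1))
    return num / den


def corr_perm_test(
    x: np.ndarray,
    y: np.ndarray | None = None,
    method: Literal["pearson", "spearman"] = "pearson",
    n_reps: int = 10_000,
    seed: int = 0,
    upper_triangle_of: tuple[np.ndarray, np.ndarray] | None = None,
) -> PermutationResult:
    """Two-sided permutation test of a correlation coefficient.

    With ``upper_triangle_of=(A, B)`` the inputs are the strict upper
    triangles of two symmetric matrices (e.g. two similarity matrices).
    The null is built by permuting ``y``; the p-value uses the add-one
    correction ``(1 + #{|r_perm| ≥ |r_obs|}) / (1 + n_reps)``, so it is
    never exactly zero.  Deterministic given ``seed``.
    """
    if upper_triangle_of is not None:
        a, b = upper_triangle_of
        x = _upper_triangle(a)
        y = _upper_triangle(b)
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    if method == "spearman":
        x = pd.Series(x).rank().to_numpy()
        y = pd.Series(y).rank().to_numpy()
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    observed = float(_pearson_many(x, y[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(y, (n_reps, 1)), axis=1)
    r_perm = _pearson_many(x, perms)
    n_extreme = int(np.sum(np.abs(r_perm) >= abs(observed) - 1e-12))
    p = (1 + n_extreme) / (1 + n_reps)
    return PermutationResult(observed=observed, n_reps=n_reps, p_value=p,
                             seed=seed, method=method)


# ---------------------------------------------------------------------------
# overlap and landmarks
# ---------------------------------------------------------------------------

def dice(m1: Mask, m2: Mask) -> float:
    """Dice overlap ``2|A∩B| / (|A| + |B|)`` of two masks on one grid.

    Two empty masks overlap perfectly by convention (logged).
    """
    if not m1.same_grid(m2):
        raise ValueError("masks must share one grid")
    a = m1.data.astype(bool)
    b = m2.data.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        log.info("dice: both masks empty, returning 1.0 by convention")
        return 1.0
    return 2.0 * int(np.sum(a & b)) / denom


def landmark_report(
    manual: Sequence[Sequence[Mapping[str, np.ndarray]]],
    auto: Sequence[Mapping[str, np.ndarray]],
) -> DisplacementReport:
    """Compare automated landmark mapping against human experts.

    ``manual[s][e]`` maps landmark id → world coordinate for subject ``s``
    and expert ``e`` (≥ 2 experts); ``auto[s]`` holds the automatically
    mapped landmarks.  Group 1 collects displacements between the same
    landmark placed by different experts, group 2 between each expert and
    the automation; per (subject, landmark) cell the median of each group
    is kept.  ``fraction_auto_closer`` counts cells where the automation
    median is strictly smaller (ties count for the manual group).
    Landmarks missing from any set of a subject are excluded and counted.
    """
    if len(manual) != len(auto):
        raise ValueError("one expert list and one auto set per subject")
    if any(len(experts) < 2 for experts in manual):
        raise ValueError("need at least 2 experts per subject")
    rows = []
    n_excluded = 0
    for s, (experts, auto_set) in enumerate(zip(manual, auto)):
        common = set(auto_set)
        for e in experts:
            common &= set(e)
        all_ids = set(auto_set)
        for e in experts:
            all_ids |= set(e)
        n_excluded += len(all_ids - common)
        for lid in sorted(common):
            pts = [np.asarray(e[lid], dtype=float) for e in experts]
            ap = np.asarray(auto_set[lid], dtype=float)
            mm = [np.linalg.norm(pts[i] - pts[j])
                  for i in range(len(pts)) for j in range(i + 1, len(pts))]
            am = [np.linalg.norm(p - ap) for p in pts]
            rows.append({"subject": s, "landmark": lid,
                         "median_manual_manual": float(np.median(mm)),
                         "median_auto_manual": float(np.median(am))})
    table = pd.DataFrame(rows)
    if len(table) == 0:
        raise ValueError("no landmark present in every set")
    closer = table["median_auto_manual"] < table["median_manual_manual"]
    per_landmark = (table.groupby("landmark")[
        ["median_manual_manual", "median_auto_manual"]].median())
    return DisplacementReport(
        table=table, per_landmark=per_landmark,
        fraction_auto_closer=float(closer.mean()),
        n_excluded=n_excluded)
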