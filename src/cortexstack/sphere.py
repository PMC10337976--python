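"""Symmetric gradient-direction design and spherical signal operations.

A diffusion gradient scheme that is pooled with its left-right mirrored
counterpart must satisfy two symmetries: antipodal equivalence
``S(x, n) = S(x, -n)`` and x-mirror closure
``S(x, y, z, nx, ny, nz) = S(-x, y, z, -nx, ny, nz)``.  Directions are
therefore *lines* (one representative per antipodal pair), and the set of
lines must map onto itself under ``M = diag(-1, 1, 1)``.

The direction optimizer places mutually repelling unit charges on the
sphere (Coulomb ``1/d`` potential on the antipodally symmetrized chordal
distance) and descends the total energy with a projected gradient and a
backtracking step, which makes the energy trace non-increasing.  Mirror
closure is enforced by construction: ``n = 2k`` lines are parametrized as
``k`` free representatives together with their exact mirror images; for odd
``n`` one additional line is confined to the mirror plane (a line on the
plane is its own mirror image up to antipode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .volgeom import VoxelGrid, mirror_x

__all__ = [
    "DirectionSet",
    "HardiImage",
    "optimize_symmetric_directions",
    "random_symmetric_directions",
    "coulomb_energy",
    "min_pairwise_angle",
    "spherical_interpolate",
    "symmetrize_population",
    "mirror_hardi",
]

log = logging.getLogger(__name__)

_MIRROR = np.diag([-1.0, 1.0, 1.0])


# ---------------------------------------------------------------------------
# DirectionSet
# ---------------------------------------------------------------------------

@dataclass
class DirectionSet:
    """Unit vectors on the sphere, one representative per antipodal pair."""

    vectors: np.ndarray
    mirror_symmetric: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float).reshape(-1, 3)
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero direction vector")
        self.vectors = v / norms[:, None]

    def __len__(self) -> int:
        return len(self.vectors)

    def pairwise_line_angles(self) -> np.ndarray:
        """Angles (radians, in [0, π/2]) between all distinct line pairs."""
        d = np.abs(self.vectors @ self.vectors.T)
        iu = np.triu_indices(len(self), k=1)
        return np.arccos(np.clip(d[iu], -1.0, 1.0))

    def min_angle(self) -> float:
        """Smallest pairwise line angle of the scheme, radians."""
        ang = self.pairwise_line_angles()
        return float(ang.min()) if ang.size else float(np.pi / 2)

    def is_antipodal_distinct(self, tol: float = 1e-8) -> bool:
        d = np.abs(self.vectors @ self.vectors.T)
        np.fill_diagonal(d, 0.0)
        return bool(np.all(d < 1.0 - tol))

    def is_mirror_closed(self, tol: float = 1e-9) -> bool:
        """Closure of the line set under x-mirroring, up to antipodes."""
        mirrored = self.vectors @ _MIRROR.T
        d = np.abs(mirrored @ self.vectors.T)  # |cos| between mirror image and set
        return bool(np.all(d.max(axis=1) >= 1.0 - tol))

    # -- FSL-style bvec/bval text I/O --------------------------------------
    def to_bvec(self, path: str | Path) -> None:
        np.savetxt(path, self.vectors.T, fmt="%.10f")

    @classmethod
    def from_bvec(cls, path: str | Path, mirror_symmetric: bool = False
                  ) -> "DirectionSet":
        arr = np.loadtxt(path)
        if arr.shape[0] == 3:
            arr = arr.T
        return cls(arr, mirror_symmetric=mirror_symmetric)


# ---------------------------------------------------------------------------
# electrostatic-repulsion design
# ---------------------------------------------------------------------------

def _pair_terms(u: np.ndarray):
    """Signed differences and distances for the antipodal-min chordal metric.

    Returns ``(diff, dist, sign)`` with ``diff[i, j] = u_i - sign[i, j] u_j``
    where the sign minimizes the chordal distance between lines i and j.
    """
    dots = u @ u.T
    sign = np.where(dots >= 0.0, 1.0, -1.0)
    diff = u[:, None, :] - sign[..., None] * u[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    return diff, dist, sign


def coulomb_energy(vectors: np.ndarray, eps: float = 1e-12) -> float:
    """Total ``1/d`` Coulomb energy over all distinct line pairs.

    ``d`` is the antipodally symmetrized chordal distance
    ``min(|u_i - u_j|, |u_i + u_j|)``; near-coincident lines contribute
    ``1/eps`` so collapse is never energetically favorable.
    """
    u = np.asarray(vectors, dtype=float).reshape(-1, 3)
    n = len(u)
    if n < 2:
        return 0.0
    _, dist, _ = _pair_terms(u)
    iu = np.triu_indices(n, k=1)
    d = np.maximum(dist[iu], eps)
    return float(np.sum(1.0 / d))


def _energy_gradient(u: np.ndarray, eps: float = 1e-12):
    """Energy and per-line gradient of :func:`coulomb_energy`."""
    n = len(u)
    diff, dist, sign = _pair_terms(u)
    np.fill_diagonal(dist, np.inf)
    d = np.maximum(dist, eps)
    iu = np.triu_indices(n, k=1)
    energy = float(np.sum(1.0 / d[iu]))
    # dE/du_i = sum_{j != i} -(u_i - s_ij u_j)/d_ij^3 ; row i of the full
    # distance matrix enumerates every pair containing i exactly once
    inv3 = 1.0 / d**3
    grad = -np.einsum("ij,ijk->ik", inv3, diff)
    return energy, grad


def _assemble(q: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Full line set: free representatives, their mirrors, plane lines."""
    parts = [q, q @ _MIRROR.T] if len(q) else []
    if len(s):
        parts.append(s)
    return np.concatenate(parts, axis=0) if parts else np.zeros((0, 3))


def _normalize_rows(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def optimize_symmetric_directions(
    n: int,
    seed: int = 0,
    lr: float = 0.05,
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> DirectionSet:
    """Electrostatic-repulsion design of ``n`` symmetric gradient directions.

    Returns ``n`` unit representatives (one per antipodal pair) whose line
    set is *exactly* closed under x-mirroring.  The accepted-iterate energy
    sequence is non-increasing.  On hitting ``max_iter`` without meeting
    ``tol`` the best iterate found is returned with a warning.

    Parameters
    ----------
    n:
        Number of direction representatives (e.g. 64 for the template
        HARDI scheme).
    seed:
        Seed of the random initial configuration.
    lr:
        Initial gradient step; adapted by backtracking.
    tol:
        Relative energy decrease below which the descent stops.
    max_iter:
        Maximum number of accepted descent steps.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    k, odd = divmod(n, 2)
    q = _normalize_rows(rng.normal(size=(k, 3))) if k else np.zeros((0, 3))
    if k:  # keep free representatives off the mirror plane initially
        q[np.abs(q[:, 0]) < 1e-3, 0] += 2e-3
        q = _normalize_rows(q)
    if odd:
        s = rng.normal(size=(1, 3))
        s[:, 0] = 0.0
        s = _normalize_rows(s)
    else:
        s = np.zeros((0, 3))

    energy = coulomb_energy(_assemble(q, s))
    step = lr
    n_iter = 0
    for n_iter in range(max_iter):
        u = _assemble(q, s)
        e, grad_u = _energy_gradient(u)
        # chain rule back to free parameters
        gq = grad_u[:k] + grad_u[k:2 * k] @ _MIRROR.T if k else np.zeros((0, 3))
        gs = grad_u[2 * k:].copy() if odd else np.zeros((0, 3))
        if odd:
            gs[:, 0] = 0.0  # plane constraint
        # tangent projection on the sphere
        if k:
            gq -= (np.sum(gq * q, axis=1, keepdims=True)) * q
        if odd:
            gs -= (np.sum(gs * s, axis=1, keepdims=True)) * s
        gnorm = np.sqrt(np.sum(gq**2) + np.sum(gs**2))
        if gnorm < 1e-14:
            break
        accepted = False
        for _ in range(60):
            q_new = _normalize_rows(q - step * gq) if k else q
            if odd:
                s_new = s - step * gs
                s_new[:, 0] = 0.0
                s_new = _normalize_rows(s_new)
            else:
                s_new = s
            e_new = coulomb_energy(_assemble(q_new, s_new))
            if e_new <= energy:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel = (energy - e_new) / max(abs(energy), 1e-30)
        q, s, energy = q_new, s_new, e_new
        step = min(step * 1.3, 1.0)
        if rel < tol:
            break
    else:
        log.warning(
            "direction optimizer hit max_iter=%d (final gradient norm %.3e); "
            "returning best iterate", max_iter, float(gnorm))

    vectors = _assemble(q, s)
    ds = DirectionSet(
        vectors,
        mirror_symmetric=True,
        provenance={
            "n": n, "seed": seed, "iterations": n_iter + 1,
            "energy": energy, "lr0": lr, "tol": tol,
        },
    )
    assert ds.is_mirror_closed(tol=1e-12)
    return ds


def random_symmetric_directions(n: int, seed: int = 0) -> DirectionSet:
    """A random (unoptimized) mirror-closed scheme; baseline for comparison."""
    rng = np.random.default_rng(seed)
    k, odd = divmod(n, 2)
    q = _normalize_rows(rng.normal(size=(k, 3))) if k else np.zeros((0, 3))
    if odd:
        s = rng.normal(size=(1, 3))
        s[:, 0] = 0.0
        s = _normalize_rows(s)
    else:
        s = np.zeros((0, 3))
    return DirectionSet(_assemble(q, s), mirror_symmetric=True,
                        provenance={"n": n, "seed": seed, "random": True})


def min_pairwise_angle(vectors: np.ndarray) -> float:
    """Minimum line angle (radians) over all pairs of a direction set."""
    return DirectionSet(vectors).min_angle()


# ---------------------------------------------------------------------------
# HARDI container and spherical interpolation
# ---------------------------------------------------------------------------

@dataclass
class HardiImage:
    """Multi-direction diffusion signal on a voxel grid.

    ``signal`` has shape ``(nx, ny, nz, n_dirs)``; ``bvals`` (s/mm²) has one
    entry per direction.
    """

    signal: np.ndarray
    directions: DirectionSet
    bvals: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (space × direction)")
        self.bvals = np.asarray(self.bvals, dtype=float).reshape(-1)
        if len(self.bvals) != self.signal.shape[3]:
            raise ValueError("bvals length must match signal's 4th axis")
        if np.any(self.bvals < 0):
            raise ValueError("bvals must be >= 0")
        if len(self.directions) != self.signal.shape[3]:
            raise ValueError("direction count must match signal's 4th axis")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    def grid(self, channel_data: np.ndarray | None = None) -> VoxelGrid:
        return VoxelGrid(self.signal if channel_data is None else channel_data,
                         self.spacing, self.origin)


def _line_angles(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Antipodally symmetrized angles between direction rows of a and b."""
    return np.arccos(np.clip(np.abs(a @ b.T), -1.0, 1.0))


def _idw_weights(src: np.ndarray, dst: np.ndarray, k: int, max_gap: float
                 ) -> np.ndarray:
    """(n_src, n_dst) normalized inverse-angle k-NN weights."""
    theta = _line_angles(src, dst)  # (n_src, n_dst)
    w = np.zeros_like(theta)
    k_eff = min(k, len(src))
    for j in range(theta.shape[1]):
        t = theta[:, j]
        if t.min() > max_gap:
            raise ValueError(
                f"target direction {j} is {np.degrees(t.min()):.1f}° from the "
                f"nearest source direction (allowed {np.degrees(max_gap):.1f}°)")
        if t.min() < 1e-9:  # exact hit: pass through
            w[np.argmin(t), j] = 1.0
            continue
        nn = np.argsort(t)[:k_eff]
        w[nn, j] = 1.0 / t[nn]
    return w / w.sum(axis=0, keepdims=True)


def _rbf_weights(src: np.ndarray, dst: np.ndarray, max_gap: float,
                 sigma: float | None = None) -> np.ndarray:
    theta_ss = _line_angles(src, src)
    theta_sd = _line_angles(src, dst)
    if np.any(theta_sd.min(axis=0) > max_gap):
        j = int(np.argmax(theta_sd.min(axis=0)))
        raise ValueError(
            f"target direction {j} is {np.degrees(theta_sd[:, j].min()):.1f}° "
            "from the nearest source direction")
    if sigma is None:
        # ~2 mean inter-direction spacings of the (antipodal) source scheme
        sigma = 2.0 * float(np.sqrt(4 * np.pi / (2 * len(src))))
    a = np.exp(-((theta_ss / sigma) ** 2))
    a += 1e-8 * np.eye(len(src))
    b = np.exp(-((theta_sd / sigma) ** 2))
    t = np.linalg.solve(a, b)  # (n_src, n_dst); A symmetric
    # normalize to a partition of unity so constants are reproduced exactly
    # even where the source scheme leaves angular gaps
    return t / t.sum(axis=0, keepdims=True)


def spherical_interpolate(
    img: HardiImage,
    new_dirs: DirectionSet,
    kernel: Literal["idw", "rbf"] = "idw",
    k: int = 8,
    max_gap: float = np.radians(45.0),
    bval_tol: float = 1.0,
) -> HardiImage:
    """Resample a HARDI image onto a new direction scheme, shell by shell.

    Interpolation operates strictly within each b-value shell on the
    antipodally symmetrized angular distance; b=0 volumes pass through
    unchanged.  The default kernel is normalized inverse-angular-distance
    over the ``k`` nearest source directions; ``"rbf"`` uses an exact
    Gaussian radial-basis fit in angle (higher order, dense solve).
    """
    src = img.directions.vectors
    dst = new_dirs.vectors
    shells = sorted(set(np.round(img.bvals / bval_tol).astype(int) * int(bval_tol)))
    out_sig, out_dirs, out_bvals = [], [], []
    flat = img.signal.reshape(-1, img.signal.shape[3])
    for shell in shells:
        sel = np.abs(img.bvals - shell) < bval_tol / 2 + 1e-9
        if shell == 0:
            out_sig.append(flat[:, sel])
            out_dirs.append(src[sel])
            out_bvals.append(img.bvals[sel])
            continue
        if kernel == "idw":
            w = _idw_weights(src[sel], dst, k=k, max_gap=max_gap)
        elif kernel == "rbf":
            w = _rbf_weights(src[sel], dst, max_gap=max_gap)
        else:
            raise ValueError(f"unknown kernel {kernel!r}")
        out_sig.append(flat[:, sel] @ w)
        out_dirs.append(dst)
        out_bvals.append(np.full(len(dst), float(shell)))
    signal = np.concatenate(out_sig, axis=1).reshape(
        img.signal.shape[:3] + (-1,))
    dirs = DirectionSet(np.concatenate(out_dirs, axis=0),
                        mirror_symmetric=new_dirs.mirror_symmetric,
                        provenance={"interpolated": True, "kernel": kernel})
    return HardiImage(signal, dirs, np.concatenate(out_bvals),
                      img.spacing, img.origin)


# ---------------------------------------------------------------------------
# symmetric weighted population averaging
# ---------------------------------------------------------------------------

def _mirror_direction_permutation(dirs: DirectionSet, tol: float = 1e-9
                                  ) -> np.ndarray:
    """Permutation π with ``M d_i ≡ ± d_π(i)`` for a mirror-closed scheme."""
    mirrored = dirs.vectors @ _MIRROR.T
    sim = np.abs(mirrored @ dirs.vectors.T)
    perm = np.argmax(sim, axis=1)
    if np.any(sim[np.arange(len(perm)), perm] < 1.0 - tol):
        raise ValueError("direction scheme is not mirror-closed")
    return perm


def mirror_hardi(img: HardiImage, x_mid: float | None = None) -> HardiImage:
    """Spatially mirror a HARDI image, consistently permuting directions."""
    perm = _mirror_direction_permutation(img.directions)
    flipped = np.flip(img.signal, axis=0) if x_mid is None else None
    if flipped is None:
        raise NotImplementedError("off-center mirror planes are not supported "
                                  "for HARDI images")
    # channel i of the mirrored image holds the signal measured along M d_i,
    # which is the original channel perm[i]
    signal = flipped[..., perm]
    return HardiImage(signal, img.directions, img.bvals[perm],
                      img.spacing, img.origin)


def symmetrize_population(
    images: Sequence[VoxelGrid] | Sequence[HardiImage],
    weights: Sequence[np.ndarray | float] | None = None,
    mirror: bool = False,
):
    """Voxelwise weighted population average, optionally mirror-symmetrized.

    ``out = Σ w_i I_i / Σ w_i`` per voxel; voxels where the total weight is
    zero (e.g. missing tissue everywhere) fall back to the unweighted mean
    and their count is logged.  With ``mirror=True`` every input (and its
    weight map) is pooled together with its x-mirrored copy, so the output
    is exactly invariant under :func:`~cortexstack.volgeom.mirror_x`.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    is_hardi = isinstance(images[0], HardiImage)
    if weights is None:
        weights = [1.0] * len(images)
    if len(weights) != len(images):
        raise ValueError("one weight per image required")

    def _as_weight(w, shape3):
        arr = np.asarray(w, dtype=float)
        if arr.ndim == 0:
            arr = np.full(shape3, float(arr))
        if np.any(arr < 0):
            raise ValueError("weights must be >= 0")
        return arr

    if is_hardi:
        ref = images[0]
        datas = [im.signal for im in images]
        shape3 = ref.signal.shape[:3]
        ws = [_as_weight(w, shape3) for w in weights]
        if mirror:
            datas += [mirror_hardi(im).signal for im in images]
            ws += [np.flip(w, axis=0) for w in ws[:len(images)]]
        acc = np.zeros_like(datas[0], dtype=float)
        tw = np.zeros(shape3, dtype=float)
        for d, w in zip(datas, ws):
            acc += d * w[..., None]
            tw += w
        bad = tw == 0
        out = np.where(bad[..., None], np.mean(datas, axis=0),
                       acc / np.where(bad, 1.0, tw)[..., None])
        if bad.any():
            log.info("symmetrize_population: %d voxels had zero total weight",
                     int(bad.sum()))
        return HardiImage(out, ref.directions, ref.bvals, ref.spacing,
                          ref.origin)

    ref = images[0]
    for im in images[1:]:
        if not ref.same_grid(im):
            raise ValueError("population images must share one grid")
    datas = [im.data.astype(float) for im in images]
    ws = [_as_weight(w, ref.shape3) for w in weights]
    if mirror:
        datas += [np.flip(d, axis=0) for d in datas[:len(images)]]
        ws += [np.flip(w, axis=0) for w in ws[:len(images)]]
    acc = np.zeros_like(datas[0])
    tw = np.zeros(ref.shape3, dtype=float)
    for d, w in zip(datas, ws):
        acc += d * w
        tw += w
    bad = tw == 0
    out = np.where(bad, np.mean(datas, axis=0), acc / np.where(bad, 1.0, tw))
    if bad.any():
        log.info("symmetrize_population: %d voxels had zero total weight",
                 int(bad.sum()))
    return ref.like(out)
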