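"""Closed-boundary extraction and complex Fourier shape descriptors.

A patch or polygon boundary is an ordered closed loop of M points
(x_m, y_m).  Treating it as the complex signal z_m = x_m + i*y_m, the
discrete Fourier coefficients

    a_n + i*b_n = (1/M) * sum_m z_m * exp(-2*pi*i*n*m / M)

describe the shape at decreasing length scales as n grows: n = 0 is the
centroid (translation), n = 1 the gross size/ellipticity, higher n the finer
features.  The descriptor magnitudes f_n = sqrt(a_n^2 + b_n^2) for
n = 1..N, divided by f_1, form a translation-, rotation-, scale- and
starting-point-invariant shape signature; Euclidean distances between such
signatures quantify shape dissimilarity.  Magnitudes discard phase, so
mirror images are indistinguishable — acceptable here, where only the
degree of shape irregularity matters.

Raster patch boundaries are traced with the Moore-neighbour contour-following
algorithm (ordered pixel loop, 8-connectivity); polygon boundaries (e.g.
Voronoi zones) are resampled to M equally spaced perimeter points.  Loops
are forced counterclockwise and padded to even M by duplicating the last
point, as the transform convention expects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import pdist, squareform
from shapely.geometry.polygon import Polygon

from .zones import PatchRecord, VoronoiZone

#: descriptor orders used by default: n = 1..20 (capped at M/2 - 1)
DEFAULT_N_DESCRIPTORS = 20

# Moore neighbourhood in clockwise order starting due west
_CLOCKWISE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


class DegenerateBoundaryError(ValueError):
    pass


@dataclass
class BoundaryLoop:
    """Ordered closed boundary: coords[m] = (x_m, y_m), first follows last."""

    coords: np.ndarray  # (M, 2) float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (M, 2)")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def signed_area(self) -> float:
        x, y = self.coords[:, 0], self.coords[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class FDSpectrum:
    """Fourier-descriptor magnitudes f_n for n = 1..N (n = 0 excluded)."""

    magnitudes: np.ndarray  # f_n, n = 1..N
    coefficients: Optional[np.ndarray] = None  # complex a_n + i b_n, same n
    normalized: bool = False

    @property
    def n_descriptors(self) -> int:
        return len(self.magnitudes)


def _even(coords: np.ndarray) -> np.ndarray:
    """Duplicate the final point if the loop length is odd."""
    if len(coords) % 2:
        coords = np.vstack([coords, coords[-1]])
    return coords


def _force_ccw(coords: np.ndarray) -> np.ndarray:
    x, y = coords[:, 0], coords[:, 1]
    if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
        coords = coords[::-1].copy()
    return coords


def _trace_moore(mask: np.ndarray) -> np.ndarray:
    """Ordered outer-boundary pixels of a connected mask (Moore tracing)."""
    padded = np.pad(mask, 1)
    rs, cs = np.nonzero(padded)
    start = (int(rs[0]), int(cs[0]))  # topmost-leftmost: its W and N sides are empty
    if mask.sum() == 1:
        return np.array([start])
    # walk clockwise; a (position, backtrack) state determines the rest of the
    # walk, so the first repeated state closes the boundary cycle exactly
    cur = start
    backtrack = (start[0], start[1] - 1)
    seen: dict[tuple, int] = {}
    seq: list[tuple[int, int]] = []
    while (cur, backtrack) not in seen:
        seen[(cur, backtrack)] = len(seq)
        seq.append(cur)
        k = _CLOCKWISE.index((backtrack[0] - cur[0], backtrack[1] - cur[1]))
        nxt = None
        for i in range(1, 9):
            dr, dc = _CLOCKWISE[(k + i) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if padded[cand]:
                nxt = cand
                break
            backtrack = cand
        if nxt is None:  # pragma: no cover - isolated pixel handled above
            break
        cur = nxt
    return np.array(seq[seen[(cur, backtrack)] :])


def trace_boundary(
    patch: Union[PatchRecord, VoronoiZone, Polygon, np.ndarray],
    n_samples: int = 256,
) -> BoundaryLoop:
    """Extract a closed, counterclockwise, even-length boundary loop.

    Raster patches yield their ordered boundary pixels (x = col, y = row);
    polygons (or (k, 2) vertex arrays) are resampled to ``n_samples``
    equally spaced perimeter points.  The last point is duplicated when the
    loop length comes out odd.
    """
    if isinstance(patch, PatchRecord):
        mask, (r0, c0) = patch.mask()
        from skimage import measure as _measure

        if _measure.label(mask, connectivity=2).max() > 1:
            raise ValueError("patch must be a single connected component")
        pix = _trace_moore(mask)
        if len(pix) < 4:
            raise DegenerateBoundaryError(
                f"patch boundary has only {len(pix)} points; need >= 4"
            )
        xy = np.column_stack([pix[:, 1] - 1 + c0, pix[:, 0] - 1 + r0]).astype(float)
        return BoundaryLoop(_even(_force_ccw(xy)))
    if isinstance(patch, VoronoiZone):
        poly = patch.polygon
    elif isinstance(patch, Polygon):
        poly = patch
    else:
        poly = Polygon(np.asarray(patch, dtype=float))
    if n_samples % 2:
        n_samples += 1
    ring = poly.exterior
    if ring is None or ring.length == 0:
        raise DegenerateBoundaryError("degenerate polygon boundary")
    verts = np.asarray(ring.coords)  # closed: last == first
    seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    dists = np.arange(n_samples) * cum[-1] / n_samples
    pts = np.column_stack(
        [np.interp(dists, cum, verts[:, 0]), np.interp(dists, cum, verts[:, 1])]
    )
    return BoundaryLoop(_even(_force_ccw(pts)))


def resample_loop(loop: BoundaryLoop, n_samples: int = 256) -> BoundaryLoop:
    """Resample a closed loop to ``n_samples`` points equally spaced in arc length.

    Pixel-index parameterization weights diagonal boundary runs differently
    from straight ones, which makes raw pixel-loop descriptors sensitive to
    raster resolution; uniform arc-length resampling removes that, so use it
    whenever spectra of different shapes (or resolutions) are compared.
    """
    if n_samples % 2:
        n_samples += 1
    closed = np.vstack([loop.coords, loop.coords[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 0])  # drop duplicated points
    closed = closed[keep]
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] == 0:
        raise DegenerateBoundaryError("zero-length boundary")
    dists = np.arange(n_samples) * cum[-1] / n_samples
    pts = np.column_stack(
        [np.interp(dists, cum, closed[:, 0]), np.interp(dists, cum, closed[:, 1])]
    )
    return BoundaryLoop(pts)


def boundary_dft(loop: BoundaryLoop) -> np.ndarray:
    """All M complex coefficients c_n = (1/M) sum_m z_m exp(-2 pi i n m / M)."""
    z = loop.coords[:, 0] + 1j * loop.coords[:, 1]
    return np.fft.fft(z) / len(z)


def fourier_descriptors(
    loop: BoundaryLoop, n_descriptors: int = DEFAULT_N_DESCRIPTORS
) -> FDSpectrum:
    """Descriptor magnitudes f_n, n = 1..n_descriptors, of a closed loop.

    The translation term n = 0 is excluded.  Requires even M and
    M >= 2 * n_descriptors so every requested order is resolved.
    """
    m = len(loop)
    if m % 2:
        raise ValueError("loop length must be even (duplicate the last point)")
    if n_descriptors < 1:
        raise ValueError("n_descriptors must be >= 1")
    if m < 2 * n_descriptors:
        raise ValueError(
            f"loop of {m} points resolves at most {m // 2} descriptors; "
            f"{n_descriptors} requested"
        )
    c = boundary_dft(loop)[1 : n_descriptors + 1]
    return FDSpectrum(magnitudes=np.abs(c), coefficients=c, normalized=False)


def normalize_spectrum(spec: FDSpectrum) -> FDSpectrum:
    """Scale-normalize: divide all magnitudes by f_1; phases are discarded.

    Magnitudes are already rotation- and starting-point-invariant; dividing
    by f_1 adds scale invariance, giving a pure shape signature with
    f_1 = 1.
    """
    f1 = spec.magnitudes[0]
    if f1 <= 0:
        raise ValueError("f_1 = 0: degenerate loop cannot be normalized")
    return FDSpectrum(magnitudes=spec.magnitudes / f1, coefficients=None, normalized=True)


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative pairwise-distance matrix with item ids."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if (v < 0).any() or not np.allclose(np.diag(v), 0):
            raise ValueError("matrix must be nonnegative with zero diagonal")
        self.values = v

    def __len__(self) -> int:
        return len(self.ids)


def pairwise_fd_distances(
    spectra: Sequence[FDSpectrum], ids: Optional[Sequence] = None
) -> DissimilarityMatrix:
    """Euclidean distances between normalized descriptor-magnitude vectors."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    n = spectra[0].n_descriptors
    for s in spectra:
        if s.n_descriptors != n:
            raise ValueError("all spectra must have the same descriptor count")
        if not s.normalized:
            raise ValueError("spectra must be normalized before comparison")
    mat = np.vstack([s.magnitudes for s in spectra])
    d = squareform(pdist(mat, metric="euclidean"))
    ids = list(ids) if ids is not None else list(range(len(spectra)))
    return DissimilarityMatrix(ids=ids, values=d)


def eccentricity(patch: PatchRecord, return_degenerate: bool = False):
    """Best-fit-ellipse eccentricity of a patch from second central moments.

    0 for isotropic shapes (disk, square), approaching 1 for elongated ones.
    Collinear pixel sets are degenerate: e = 1 with the flag set.
    """
    if patch.area < 3:
        raise ValueError("patch must have at least 3 pixels")
    pix = patch.pixels.astype(float)
    cov = np.cov(pix.T, bias=True)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    degenerate = evals[0] <= 0 or evals[1] / evals[0] < 1e-12
    e = 1.0 if degenerate else float(np.sqrt(1.0 - evals[1] / evals[0]))
    return (e, degenerate) if return_degenerate else e


def shape_correspondence(
    patch: PatchRecord,
    zone: VoronoiZone,
    n_descriptors: int = DEFAULT_N_DESCRIPTORS,
    n_samples: int = 256,
) -> float:
    """Shape distance between a patch and its founder's Voronoi zone.

    Both boundaries are reduced to normalized FD signatures over the same
    descriptor orders — the patch's traced pixel loop and the zone polygon
    are both resampled to ``n_samples`` points equally spaced in arc length
    — and compared by Euclidean distance; 0 means identical shape up to
    similarity transforms.
    """
    patch_loop = resample_loop(trace_boundary(patch), n_samples)
    zone_loop = trace_boundary(zone, n_samples=n_samples)
    n = min(n_descriptors, n_samples // 2 - 1)
    if n < 1:
        raise DegenerateBoundaryError("boundary too short for any descriptor")
    a = normalize_spectrum(fourier_descriptors(patch_loop, n))
    b = normalize_spectrum(fourier_descriptors(zone_loop, n))
    return float(np.linalg.norm(a.magnitudes - b.magnitudes))
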