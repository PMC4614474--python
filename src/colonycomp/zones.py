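"""Voronoi territories, colonized patches, and the winner index.

Each founder cell is assigned the region of the domain closer to it than to
any other founder (its Voronoi zone, area ``A_V``).  After colonization its
clonal lineage occupies a contiguous patch of area ``A_P``.  The winner
index

    WI = A_P / A_V

measures competitive success: WI = 1 means the lineage claimed exactly the
space nearest its founder, WI > 1 a winner, WI < 1 a loser.

This module computes the tessellation (clipped to the observation
rectangle), extracts per-lineage patches from integer label maps, pairs
patches with zones by maximal pixel overlap (discarding edge-touching,
fragmented, or merged cases, mirroring the experimental analysis), and
summarizes WI distributions with the lognormal coefficient of variation and
the median absolute deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point, box
from shapely.geometry.polygon import Polygon, orient
from skimage import measure


class DuplicatePointsError(ValueError):
    pass


@dataclass
class VoronoiZone:
    """A founder's territory: convex polygon clipped to the domain rectangle."""

    founder_id: int
    polygon: Polygon
    founder_xy: tuple[float, float]
    clipped: bool  # touches the domain rectangle's boundary

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def vertices(self) -> np.ndarray:
        """Exterior vertices, counterclockwise, closing point dropped."""
        xy = np.asarray(orient(self.polygon, 1.0).exterior.coords)
        return xy[:-1]


@dataclass
class PatchRecord:
    """One 8-connected component of one lineage in a label map."""

    lineage_id: int
    pixels: np.ndarray  # (n, 2) array of (row, col)
    touches_edge: bool
    component: int = 0  # component index within the lineage (0-based)

    @property
    def area(self) -> int:
        return len(self.pixels)

    def mask(self) -> tuple[np.ndarray, tuple[int, int]]:
        """Cropped boolean mask and its (row, col) offset in the map frame."""
        rmin, cmin = self.pixels.min(axis=0)
        rmax, cmax = self.pixels.max(axis=0)
        m = np.zeros((rmax - rmin + 1, cmax - cmin + 1), dtype=bool)
        m[self.pixels[:, 0] - rmin, self.pixels[:, 1] - cmin] = True
        return m, (int(rmin), int(cmin))


@dataclass
class WIDistributionSummary:
    n: int
    c_v: float  # lognormal coefficient of variation sqrt(exp(s^2) - 1)
    mad: float  # raw median absolute deviation
    median: float


def default_domain(shape: tuple[int, int]) -> tuple[float, float, float, float]:
    """Domain rectangle for a label map whose pixel centres sit at integers.

    Pixel (r, c) owns the unit cell centred on (x=c, y=r), so an H x W map
    covers the rectangle [-0.5, W-0.5] x [-0.5, H-0.5] with area W*H.
    """
    h, w = shape
    return (-0.5, -0.5, w - 0.5, h - 0.5)


def voronoi_tessellate(
    points: np.ndarray,
    domain: tuple[float, float, float, float],
    founder_ids: Optional[Sequence[int]] = None,
) -> list[VoronoiZone]:
    """Voronoi tessellation of founder positions, clipped to a rectangle.

    ``points`` is (n, 2) of (x, y); all must lie inside ``domain``
    (xmin, ymin, xmax, ymax) and be pairwise distinct.  The returned zones
    tile the rectangle: their areas sum to its area.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("points must be a nonempty (n, 2) array")
    ids = np.asarray(founder_ids) if founder_ids is not None else np.arange(1, len(pts) + 1)
    _check_duplicates(pts, ids)
    xmin, ymin, xmax, ymax = domain
    rect = box(xmin, ymin, xmax, ymax)
    for (x, y), fid in zip(pts, ids):
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise ValueError(f"founder {fid} at ({x}, {y}) lies outside the domain")
    if len(pts) == 1:
        return [VoronoiZone(int(ids[0]), orient(rect, 1.0), tuple(pts[0]), True)]
    cells = shapely.voronoi_polygons(MultiPoint(pts), extend_to=rect)
    tree = shapely.STRtree(list(cells.geoms))
    zones = []
    for (x, y), fid in zip(pts, ids):
        p = Point(x, y)
        hits = [i for i in tree.query(p, predicate="intersects")]
        cell = None
        for i in hits:
            if cells.geoms[i].intersects(p):
                cell = cells.geoms[i]
                break
        if cell is None:  # pragma: no cover - GEOS guarantees coverage
            raise RuntimeError(f"no Voronoi cell found for founder {fid}")
        clipped_poly = cell.intersection(rect)
        zones.append(
            VoronoiZone(
                founder_id=int(fid),
                polygon=orient(clipped_poly, 1.0),
                founder_xy=(float(x), float(y)),
                clipped=clipped_poly.exterior.intersects(rect.exterior),
            )
        )
    return zones


def _check_duplicates(pts: np.ndarray, ids: np.ndarray) -> None:
    _, inverse, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    if (counts > 1).any():
        dup_ids = sorted(int(i) for i in ids[np.isin(inverse, np.where(counts > 1)[0])])
        raise DuplicatePointsError(f"duplicate founder positions for ids {dup_ids}")


def extract_patches(label_map: np.ndarray, background: int = 0) -> list[PatchRecord]:
    """Split a label map into 8-connected components per lineage id."""
    label_map = np.asarray(label_map)
    records = []
    for lineage in np.unique(label_map):
        if lineage == background:
            continue
        comp = measure.label(label_map == lineage, connectivity=2)
        for k in range(1, comp.max() + 1):
            pix = np.argwhere(comp == k)
            touches = (
                (pix[:, 0] == 0).any()
                or (pix[:, 0] == label_map.shape[0] - 1).any()
                or (pix[:, 1] == 0).any()
                or (pix[:, 1] == label_map.shape[1] - 1).any()
            )
            records.append(
                PatchRecord(
                    lineage_id=int(lineage),
                    pixels=pix,
                    touches_edge=bool(touches),
                    component=k - 1,
                )
            )
    return records


def rasterize_zones(zones: Iterable[VoronoiZone], shape: tuple[int, int]) -> np.ndarray:
    """Nearest-founder id at each pixel centre: the zones sampled on the grid."""
    zones = list(zones)
    pts = np.array([z.founder_xy for z in zones])
    ids = np.array([z.founder_id for z in zones])
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    _, nearest = cKDTree(pts).query(np.column_stack([cols.ravel(), rows.ravel()]))
    return ids[nearest].reshape(h, w).astype(np.int32)


@dataclass
class MatchedPair:
    patch: PatchRecord
    zone: VoronoiZone
    overlap_fraction: float  # patch pixels inside the zone raster / patch area


def match_patches_to_zones(
    patches: Sequence[PatchRecord],
    zones: Sequence[VoronoiZone],
    shape: tuple[int, int],
) -> tuple[list[MatchedPair], pd.DataFrame]:
    """Pair each patch with the zone of maximal pixel overlap.

    Discards (with a logged reason): patches touching the raster edge
    ("edge"), lineages fragmented into several components
    ("multi_component"), patches with no overlap with any zone
    ("no_overlap"), and groups of patches claiming the same zone
    ("shared_zone") — the raster analogue of two founders' progeny merging
    into one patch.
    """
    zone_raster = rasterize_zones(zones, shape)
    by_id = {z.founder_id: z for z in zones}
    n_components: dict[int, int] = {}
    for p in patches:
        n_components[p.lineage_id] = n_components.get(p.lineage_id, 0) + 1
    discards: list[dict] = []
    candidates: list[tuple[PatchRecord, int, float]] = []
    for p in patches:
        if n_components[p.lineage_id] > 1:
            discards.append({"lineage_id": p.lineage_id, "reason": "multi_component"})
            continue
        if p.touches_edge:
            discards.append({"lineage_id": p.lineage_id, "reason": "edge"})
            continue
        under = zone_raster[p.pixels[:, 0], p.pixels[:, 1]]
        vals, counts = np.unique(under, return_counts=True)
        best = int(vals[np.argmax(counts)])
        frac = counts.max() / p.area
        if best not in by_id or frac == 0:
            discards.append({"lineage_id": p.lineage_id, "reason": "no_overlap"})
            continue
        candidates.append((p, best, float(frac)))
    claimed: dict[int, int] = {}
    for _, zid, _ in candidates:
        claimed[zid] = claimed.get(zid, 0) + 1
    pairs = []
    for p, zid, frac in candidates:
        if claimed[zid] > 1:
            discards.append({"lineage_id": p.lineage_id, "reason": "shared_zone"})
        else:
            pairs.append(MatchedPair(p, by_id[zid], frac))
    log = pd.DataFrame(discards, columns=["lineage_id", "reason"])
    return pairs, log


def match_patches_to_zones_by_id(
    patches: Sequence[PatchRecord],
    zones: Sequence[VoronoiZone],
) -> tuple[list[MatchedPair], pd.DataFrame]:
    """Pair patches with zones by shared founder/lineage id.

    For simulated or ground-truth label maps the pixel labels are the
    founder ids, so the pairing is known exactly and only the quality
    filters apply: edge-touching patches and fragmented lineages are
    discarded, as is any patch without a same-id zone ("no_zone").
    """
    by_id = {z.founder_id: z for z in zones}
    n_components: dict[int, int] = {}
    for p in patches:
        n_components[p.lineage_id] = n_components.get(p.lineage_id, 0) + 1
    pairs, discards = [], []
    for p in patches:
        if n_components[p.lineage_id] > 1:
            discards.append({"lineage_id": p.lineage_id, "reason": "multi_component"})
        elif p.touches_edge:
            discards.append({"lineage_id": p.lineage_id, "reason": "edge"})
        elif p.lineage_id not in by_id:
            discards.append({"lineage_id": p.lineage_id, "reason": "no_zone"})
        else:
            pairs.append(MatchedPair(p, by_id[p.lineage_id], float("nan")))
    log = pd.DataFrame(discards, columns=["lineage_id", "reason"])
    return pairs, log


def winner_index(a_p: float, a_v: float) -> float:
    """WI = A_P / A_V, the patch area over the founder's Voronoi-zone area."""
    if a_v <= 0:
        raise ValueError("Voronoi zone area must be positive")
    if a_p < 0:
        raise ValueError("patch area must be nonnegative")
    return a_p / a_v


def wi_table(pairs: Sequence[MatchedPair]) -> pd.DataFrame:
    """WI per matched founder: columns founder_id, A_P, A_V, WI."""
    rows = [
        {
            "founder_id": m.zone.founder_id,
            "A_P": float(m.patch.area),
            "A_V": float(m.zone.area),
            "WI": winner_index(m.patch.area, m.zone.area),
        }
        for m in pairs
    ]
    return pd.DataFrame(rows, columns=["founder_id", "A_P", "A_V", "WI"])


def summarize_wi(wi: Iterable[float]) -> WIDistributionSummary:
    """Distribution-width summary of a set of WI values.

    ``c_v = sqrt(exp(s^2) - 1)`` with ``s`` the sample standard deviation of
    ln(WI) — the coefficient of variation of the lognormal fitted to the WI
    distribution.  ``mad`` is the raw median absolute deviation (no
    normal-consistency factor).
    """
    wi = np.asarray(list(wi), dtype=float)
    if len(wi) < 2:
        raise ValueError("need at least two WI records")
    if (wi <= 0).any():
        raise ValueError("all WI values must be positive")
    s = float(np.std(np.log(wi), ddof=1))
    med = float(np.median(wi))
    return WIDistributionSummary(
        n=len(wi),
        c_v=math.sqrt(math.expm1(s * s)),
        mad=float(np.median(np.abs(wi - med))),
        median=med,
    )


def median_wi_by_area_bin(table: pd.DataFrame, n_bins: int) -> pd.DataFrame:
    """Median WI per Voronoi-area bin (equal-count bins over A_V).

    Returns one row per nonempty bin: area_lo, area_hi, median_WI, count.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    t = table.sort_values("A_V", kind="stable").reset_index(drop=True)
    bins = pd.qcut(t["A_V"].rank(method="first"), q=min(n_bins, len(t)), labels=False)
    out = []
    for b in sorted(pd.unique(bins)):
        sub = t[bins == b]
        out.append(
            {
                "area_lo": sub["A_V"].min(),
                "area_hi": sub["A_V"].max(),
                "median_WI": sub["WI"].median(),
                "count": len(sub),
            }
        )
    return pd.DataFrame(out)


def select_winners_losers(table: pd.DataFrame, fraction: float = 0.10) -> pd.Series:
    """Label the top/bottom WI fraction of founders winner/loser.

    Winners are the ``floor(N * fraction)`` records with the highest WI,
    losers the same count with the lowest; everyone else is "neither".
    Ties are broken by stable (WI, founder_id) order.
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    n = len(table)
    if n < math.ceil(1.0 / fraction):
        raise ValueError(
            f"need at least {math.ceil(1.0 / fraction)} records for fraction {fraction}"
        )
    k = int(math.floor(n * fraction))
    order = table[["WI", "founder_id"]].sort_values(
        ["WI", "founder_id"], kind="stable"
    ).index
    labels = pd.Series("neither", index=table.index, name="status")
    labels.loc[order[:k]] = "loser"
    labels.loc[order[n - k :]] = "winner"
    return labels


def analyze_label_map(
    founders: pd.DataFrame,
    label_map: np.ndarray,
    domain: Optional[tuple[float, float, float, float]] = None,
    match: str = "id",
) -> tuple[pd.DataFrame, pd.DataFrame, list[VoronoiZone]]:
    """Full WI pipeline: tessellate, extract, match, compute WI.

    ``founders`` needs a ``lineage_id`` column plus either continuous
    ``x``/``y`` or lattice ``row``/``col`` coordinates.  ``match="id"``
    pairs patches with zones through the shared lineage id (simulated and
    ground-truth maps are labelled by founder); ``match="overlap"`` pairs by
    maximal pixel overlap, as when patches come from segmented micrographs
    with no id correspondence.  Returns the WI table, the discard log, and
    the zones (for downstream shape analysis).
    """
    if "x" in founders.columns and "y" in founders.columns:
        pts = founders[["x", "y"]].to_numpy(dtype=float)
    elif "row" in founders.columns and "col" in founders.columns:
        pts = founders[["col", "row"]].to_numpy(dtype=float)
    else:
        raise ValueError("founder table needs x/y or row/col columns")
    if domain is None:
        domain = default_domain(label_map.shape)
    zones = voronoi_tessellate(pts, domain, founder_ids=founders["lineage_id"])
    patches = extract_patches(label_map)
    if match == "id":
        pairs, log = match_patches_to_zones_by_id(patches, zones)
    elif match == "overlap":
        pairs, log = match_patches_to_zones(patches, zones, label_map.shape)
    else:
        raise ValueError(f"unknown match mode {match!r}")
    return wi_table(pairs), log, zones
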