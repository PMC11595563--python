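"""Spatiotemporal pattern: 100-km gridding of occurrences, per-cell mean
divergence time (MDT), Jenks levels, suitability grouping, and the
Kruskal-Wallis comparison with Dunn-Holm post hoc.

Synthetic data live on a planar km grid and need no projection; real
geographic data are projected with an Albers equal-area conic (standard
parallels 25N/47N, suited to China) before gridding, so that 100 km x
100 km cells have honest areas.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .occurrences import OccurrenceRecord
from .phylo import StemAgeTable, mean_divergence_time
from .rasters import RasterLayer
from .sdm import jenks_breaks

__all__ = [
    "GridSpec", "CellSummary", "KWResult", "albers_project", "build_grid",
    "cell_mdt", "classify_mdt", "attach_suitability", "kruskal_wallis",
    "pairwise_posthoc", "assign_region",
]


# -- equal-area projection (real-data mode) ---------------------------------

def albers_project(lat: np.ndarray, lon: np.ndarray, *,
                   lat1: float = 25.0, lat2: float = 47.0,
                   lat0: float = 0.0, lon0: float = 105.0,
                   radius_km: float = 6371.0088
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Albers equal-area conic forward transform (spherical form), km.

    Defaults place the standard parallels and central meridian over China.
    """
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    phi0, lam0 = math.radians(lat0), math.radians(lon0)
    n = (math.sin(phi1) + math.sin(phi2)) / 2.0
    C = math.cos(phi1) ** 2 + 2.0 * n * math.sin(phi1)
    rho = radius_km * np.sqrt(C - 2.0 * n * np.sin(phi)) / n
    rho0 = radius_km * math.sqrt(C - 2.0 * n * math.sin(phi0)) / n
    theta = n * (lam - lam0)
    return rho * np.sin(theta), rho0 - rho * np.cos(theta)


# -- gridding ---------------------------------------------------------------

@dataclass
class GridSpec:
    """A regular analysis grid in projected/planar km.

    Cells are half-open [x, x + s) x [y, y + s), lower-left inclusive, so
    every point maps into exactly one cell.
    """
    origin: tuple[float, float]
    cell_size_km: float
    n_rows: int
    n_cols: int
    projection: str = "planar"

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        ox, oy = self.origin
        col = int(np.floor((x - ox) / self.cell_size_km))
        row = int(np.floor((y - oy) / self.cell_size_km))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"point ({x}, {y}) outside grid")
        return row, col

    def cell_bounds(self, row: int, col: int
                    ) -> tuple[float, float, float, float]:
        ox, oy = self.origin
        s = self.cell_size_km
        return (ox + col * s, oy + row * s, ox + (col + 1) * s,
                oy + (row + 1) * s)


def build_grid(points: np.ndarray, cell_size_km: float = 100.0,
               projection: str = "planar") -> GridSpec:
    """Grid anchored at the floor (whole km) of the points' bounding box,
    just large enough that every point falls inside a half-open cell."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("no points to grid")
    ox, oy = np.floor(pts[:, 0].min()), np.floor(pts[:, 1].min())
    span_x = pts[:, 0].max() - ox
    span_y = pts[:, 1].max() - oy
    n_cols = max(1, int(np.floor(span_x / cell_size_km)) + 1)
    n_rows = max(1, int(np.floor(span_y / cell_size_km)) + 1)
    return GridSpec(origin=(float(ox), float(oy)), cell_size_km=cell_size_km,
                    n_rows=n_rows, n_cols=n_cols, projection=projection)


@dataclass
class CellSummary:
    """One occupied (or summarized) grid cell."""
    cell_id: tuple[int, int]
    species_present: set = field(default_factory=set)
    mdt: float | None = None
    mdt_class: int | None = None
    suitability_value: float | None = None
    suitability_class: int | None = None
    region: str | None = None


def cell_mdt(grid: GridSpec, records: Sequence[OccurrenceRecord],
             stem_ages: StemAgeTable) -> list[CellSummary]:
    """Per-cell species sets and mean divergence times.

    Each species counts once per cell regardless of how many records fall
    there; MDT is the arithmetic mean stem age of the cell's species set.
    Only occupied cells are returned.
    """
    missing = sorted({r.species for r in records} - set(stem_ages.ages))
    if missing:
        raise KeyError(f"species missing from stem-age table: {missing}")
    cells: dict[tuple[int, int], set] = {}
    for rec in records:
        cid = grid.cell_of(*rec.point)
        cells.setdefault(cid, set()).add(rec.species)
    return [CellSummary(cell_id=cid, species_present=sps,
                        mdt=mean_divergence_time(sps, stem_ages))
            for cid, sps in sorted(cells.items())]


def classify_mdt(cells: list[CellSummary], k: int = 4) -> list[float]:
    """Jenks-classify the occupied cells' MDTs into k levels (in place);
    returns the k-1 break values."""
    mdts = [c.mdt for c in cells if c.mdt is not None]
    breaks = jenks_breaks(mdts, k)
    for c in cells:
        if c.mdt is not None:
            c.mdt_class = int(1 + np.digitize(c.mdt, breaks, right=True))
    return breaks


def attach_suitability(cells: list[CellSummary], grid: GridSpec,
                       suitability: RasterLayer, breaks: Sequence[float]
                       ) -> list[CellSummary]:
    """Attach each cell's mean ensemble suitability and its class under
    the global habitat breaks.  Cells with no valid raster coverage are
    flagged (class None) and returned separately by the caller's filter."""
    cx, cy = suitability.centers()
    valid = ~suitability.nodata_mask
    vals = suitability.values
    for cell in cells:
        x0, y0, x1, y1 = grid.cell_bounds(*cell.cell_id)
        inside = (cx >= x0) & (cx < x1) & (cy >= y0) & (cy < y1) & valid
        if not inside.any():
            cell.suitability_value = None
            cell.suitability_class = None
            continue
        cell.suitability_value = float(vals[inside].mean())
        cell.suitability_class = int(
            1 + np.digitize(cell.suitability_value, np.asarray(breaks),
                            right=True))
    return cells


# -- Kruskal-Wallis and post hoc --------------------------------------------

@dataclass
class KWResult:
    H: float
    df: int
    p_value: float
    group_sizes: list[int]
    pairwise: list[tuple[int, int, float, float]] = field(
        default_factory=list)  # (group i, group j, z, adjusted p)


def _kw_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H (direct rank arithmetic)."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / tie if tie > 0 else 0.0


def kruskal_wallis(groups: Sequence[Sequence[float]],
                   permutation: bool = False,
                   max_permutations: int = 100_000,
                   seed: int = 0) -> KWResult:
    """Kruskal-Wallis H test across >= 2 groups.

    The default p-value is the chi-square approximation with
    df = groups - 1 (tie-corrected H, via scipy).  With
    ``permutation=True`` an exact permutation p is computed instead: all
    distinct assignments of the pooled values to the group sizes when
    their count is <= *max_permutations*, otherwise a seeded Monte Carlo
    sample of that size.  Identical observations across the board give
    H = 0, p = 1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 1 for a in arrs):
        raise ValueError("need >= 2 non-empty groups")
    n_total = sum(len(a) for a in arrs)
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    sizes = [len(a) for a in arrs]
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        return KWResult(H=0.0, df=len(arrs) - 1, p_value=1.0,
                        group_sizes=sizes)
    h, p_chi2 = stats.kruskal(*arrs)
    if not permutation:
        return KWResult(H=float(h), df=len(arrs) - 1, p_value=float(p_chi2),
                        group_sizes=sizes)
    p_perm = _permutation_p(arrs, float(h), max_permutations, seed)
    return KWResult(H=float(h), df=len(arrs) - 1, p_value=p_perm,
                    group_sizes=sizes)


def _partitions(indices: tuple, sizes: list[int]):
    """All distinct assignments of indices into ordered groups of given
    sizes (first group chosen by combination, recurse)."""
    if len(sizes) == 1:
        yield (indices,)
        return
    first, rest_sizes = sizes[0], sizes[1:]
    for combo in itertools.combinations(indices, first):
        chosen = set(combo)
        rest = tuple(i for i in indices if i not in chosen)
        for tail in _partitions(rest, rest_sizes):
            yield (combo,) + tail


def _permutation_p(arrs: list[np.ndarray], h_obs: float,
                   max_permutations: int, seed: int) -> float:
    sizes = [len(a) for a in arrs]
    pooled = np.concatenate(arrs)
    n = len(pooled)
    n_exact = math.factorial(n)
    for s in sizes:
        n_exact //= math.factorial(s)
    if n_exact <= max_permutations:
        count = 0
        total = 0
        for assignment in _partitions(tuple(range(n)), sizes):
            h = _kw_h([pooled[list(ix)] for ix in assignment])
            count += h >= h_obs - 1e-12
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(max_permutations):
        perm = rng.permutation(n)
        gs, start = [], 0
        for s in sizes:
            gs.append(pooled[perm[start:start + s]])
            start += s
        count += _kw_h(gs) >= h_obs - 1e-12
    return (count + 1) / (max_permutations + 1)


def pairwise_posthoc(groups: Sequence[Sequence[float]],
                     method: str = "dunn-holm",
                     alpha: float = 0.05
                     ) -> list[tuple[int, int, float, float, bool]]:
    """Dunn's pairwise z tests on the pooled ranks with Holm adjustment.

    Returns one (i, j, z, adjusted p, significant) tuple per pair of
    groups (0-based indices into the input order).
    """
    if method != "dunn-holm":
        raise ValueError(f"unsupported post hoc method {method!r}")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(arrs)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank, start = [], 0
    for a in arrs:
        mean_rank.append(ranks[start:start + len(a)].mean())
        start += len(a)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    zs, pairs = [], []
    for i, j in itertools.combinations(range(len(arrs)), 2):
        se = math.sqrt(base_var * (1.0 / len(arrs[i]) + 1.0 / len(arrs[j])))
        z = (mean_rank[i] - mean_rank[j]) / se if se > 0 else 0.0
        zs.append(z)
        pairs.append((i, j))
    raw_p = 2.0 * stats.norm.sf(np.abs(zs))
    from statsmodels.stats.multitest import multipletests
    reject, adj_p, *_ = multipletests(raw_p, alpha=alpha, method="holm")
    return [(i, j, float(z), float(ap), bool(rej))
            for (i, j), z, ap, rej in zip(pairs, zs, adj_p, reject)]


# -- region assignment ------------------------------------------------------

def assign_region(point: tuple[float, float], line_west_east,
                  line_north_south) -> str:
    """Classify a projected point into NE / NW / SE / SW.

    *line_west_east* separates west from east (e.g. the Heihe-Tengchong
    line), *line_north_south* separates north from south (the
    Qinling-Huaihe extension).  Lines are shapely LineStrings or
    coordinate sequences.  The side is the sign of the cross product
    against the nearest segment's direction; points exactly on a line go
    to the east/south side.
    """
    ew = _side_of(point, line_west_east)      # >0 left of the line
    ns = _side_of(point, line_north_south)
    east = _is_east(point, line_west_east, ew)
    north = _is_north(point, line_north_south, ns)
    return ("N" if north else "S") + ("E" if east else "W")


def _as_linestring(line):
    from shapely.geometry import LineString
    if isinstance(line, LineString):
        return line
    return LineString(line)


def _side_of(point, line) -> float:
    """Signed cross product of the nearest segment direction with the
    vector to the point (positive = left of travel direction)."""
    ls = _as_linestring(line)
    coords = np.asarray(ls.coords)
    d = ls.project(_point_geom(point))
    # locate the segment containing the projected arc length
    seg_len = np.hypot(*np.diff(coords, axis=0).T)
    cum = np.r_[0.0, np.cumsum(seg_len)]
    i = int(np.clip(np.searchsorted(cum, d, side="right") - 1, 0,
                    len(seg_len) - 1))
    a, b = coords[i], coords[i + 1]
    v = b - a
    w = np.asarray(point, dtype=float) - a
    return float(v[0] * w[1] - v[1] * w[0])


def _point_geom(point):
    from shapely.geometry import Point
    return Point(point)


def _is_east(point, line, side: float) -> bool:
    """East = right of a generally-northward line (ties -> east)."""
    coords = np.asarray(_as_linestring(line).coords)
    northward = coords[-1][1] >= coords[0][1]
    right = side < 0 if northward else side > 0
    return right or side == 0.0


def _is_north(point, line, side: float) -> bool:
    """North = left of a generally-eastward line (ties -> south)."""
    coords = np.asarray(_as_linestring(line).coords)
    eastward = coords[-1][0] >= coords[0][0]
    left = side > 0 if eastward else side < 0
    return left and side != 0.0
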