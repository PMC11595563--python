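"""Occurrence ingestion, spatial thinning and raster collinearity filtering.

Occurrence records carry (lat, lon).  Two distance modes exist: geographic
(WGS84 decimal degrees, haversine distance) and planar (synthetic grids,
where ``lon`` is x in km and ``lat`` is y in km, Euclidean distance).
Everything downstream is metric-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rasters import RasterLayer, RasterStack

__all__ = [
    "OccurrenceRecord", "great_circle_km", "planar_km", "thin_occurrences",
    "pearson_r", "collinearity_filter", "host_counts_to_raster",
    "read_occurrences", "write_occurrences",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class OccurrenceRecord:
    """A georeferenced species observation."""
    species: str
    lat: float
    lon: float
    record_id: str = ""

    def __post_init__(self):
        if not self.species:
            raise ValueError("species label must be non-empty")

    @property
    def point(self) -> tuple[float, float]:
        """(x, y) = (lon, lat): planar km in synthetic mode."""
        return (self.lon, self.lat)


def _check_geographic(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0):
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    if not (-180.0 <= lon <= 180.0):
        raise ValueError(f"longitude {lon} outside [-180, 180]")


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) points."""
    _check_geographic(*a)
    _check_geographic(*b)
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = (math.sin(dlat / 2) ** 2
         + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def planar_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Euclidean distance for planar (y km, x km) points."""
    return math.hypot(a[0] - b[0], a[1] - b[1])


_METRICS = {"haversine": great_circle_km, "planar": planar_km}


def thin_occurrences(records: list[OccurrenceRecord], radius_km: float = 10.0,
                     *, metric: str = "haversine",
                     seed: int | None = None
                     ) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord]]:
    """Collapse records closer than *radius_km* to a single representative.

    Greedy scan: a record is retained iff it lies farther than *radius_km*
    from every previously retained record; otherwise it is dropped as a
    replicate.  The default scan order is input order (deterministic); pass
    *seed* to shuffle the scan order and probe sensitivity of the rule.
    """
    if not records:
        raise ValueError("no occurrence records to thin")
    dist = _METRICS[metric]
    order = list(range(len(records)))
    if seed is not None:
        np.random.default_rng(seed).shuffle(order)
    retained: list[OccurrenceRecord] = []
    dropped: list[OccurrenceRecord] = []
    for i in order:
        rec = records[i]
        p = (rec.lat, rec.lon)
        if all(dist(p, (r.lat, r.lon)) > radius_km for r in retained):
            retained.append(rec)
        else:
            dropped.append(rec)
    return retained, dropped


def pearson_r(layer_a: RasterLayer, layer_b: RasterLayer) -> float:
    """Sample Pearson correlation over cells valid in both layers."""
    if layer_a.shape != layer_b.shape or layer_a.transform != layer_b.transform:
        raise ValueError("layers are not aligned")
    joint = ~(layer_a.nodata_mask | layer_b.nodata_mask)
    if joint.sum() < 3:
        raise ValueError("fewer than 3 jointly valid cells")
    va, vb = layer_a.values[joint], layer_b.values[joint]
    if np.ptp(va) == 0:
        raise ValueError(f"constant layer: {layer_a.name!r}")
    if np.ptp(vb) == 0:
        raise ValueError(f"constant layer: {layer_b.name!r}")
    return float(np.corrcoef(va, vb)[0, 1])


def collinearity_filter(stack: RasterStack, threshold: float = 0.8,
                        priority: list[str] | str = "input-order",
                        seed: int | None = None
                        ) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop one member of every layer pair with |r| > *threshold*.

    Layers are scanned in priority order (default: stack order; pass a name
    list, or a *seed* to randomize the order, mimicking a literal "randomly
    retained" choice).  A layer is kept iff its |r| with every already-kept
    layer is <= threshold; otherwise it is dropped and the offending kept
    partner and r are logged.  The kept set therefore never contains a pair
    above the threshold.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 layers")
    if priority == "input-order":
        order = stack.names
    else:
        if set(priority) != set(stack.names):
            raise ValueError("priority list must name every layer exactly once")
        order = list(priority)
    if seed is not None:
        np.random.default_rng(seed).shuffle(order)
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for name in order:
        conflict = None
        for other in kept:
            r = pearson_r(stack[name], stack[other])
            if abs(r) > threshold:
                conflict = (name, other, r)
                break
        if conflict is None:
            kept.append(name)
        else:
            dropped.append(conflict)
    return kept, dropped


def host_counts_to_raster(points: np.ndarray, template: RasterLayer,
                          name: str = "host") -> RasterLayer:
    """Rasterize host-plant occurrence points to per-cell counts.

    *points* is an (n, 2) array of (x, y); points outside the template grid
    are ignored.  Cells without points hold 0 (not nodata) wherever the
    template is valid.
    """
    counts = np.zeros(template.shape)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    for x, y in pts:
        try:
            r, c = template.cell_of(x, y)
        except IndexError:
            continue
        counts[r, c] += 1
    return RasterLayer(name, counts, template.transform,
                       template.nodata_mask.copy(), template.crs_tag)


# -- CSV I/O ----------------------------------------------------------------

def read_occurrences(path) -> list[OccurrenceRecord]:
    df = pd.read_csv(path)
    need = {"species", "lat", "lon"}
    if not need <= set(df.columns):
        raise ValueError(f"occurrence CSV must have columns {sorted(need)}")
    has_id = "record_id" in df.columns
    return [OccurrenceRecord(row.species, float(row.lat), float(row.lon),
                             str(row.record_id) if has_id else f"r{i}")
            for i, row in enumerate(df.itertuples())]


def write_occurrences(records: list[OccurrenceRecord], path) -> None:
    pd.DataFrame([(r.species, r.lat, r.lon, r.record_id) for r in records],
                 columns=["species", "lat", "lon", "record_id"]
                 ).to_csv(path, index=False)
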