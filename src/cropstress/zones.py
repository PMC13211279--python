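"""Field-scale stress zones: merge pixel predictions into georeferenced regions.

The support of a target class is morphologically closed (to bridge small
gaps), 8-connected components are labeled, components below a minimum
area are dropped, and the survivors become zones ordered by descending
area.  Zone area counts only the original predicted pixels of the
component (closing serves grouping, not area), and the centroid is the
geotransformed mean pixel coordinate.  Zone IDs follow the field
convention RR (rust), WL (water-low), WH (water-high) plus a 3-digit
ordinal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from cropstress.masks import LabelMask

ZONE_PREFIX = {4: "RR", 1: "WL", 2: "WH"}


@dataclass
class StressZone:
    zone_id: str
    class_id: int
    centroid_latlon: tuple[float, float]
    area_m2: float
    pixel_count: int
    bbox_px: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max) inclusive


def pixel_to_lonlat(rows, cols, geotransform) -> tuple:
    """Apply a GDAL-style geotransform at pixel centers -> (lon, lat)."""
    x0, dx, rx, y0, ry, dy = geotransform
    cols = np.asarray(cols, dtype=np.float64) + 0.5
    rows = np.asarray(rows, dtype=np.float64) + 0.5
    lon = x0 + cols * dx + rows * rx
    lat = y0 + cols * ry + rows * dy
    return lon, lat


def zone_geometry(component_pixels: tuple[np.ndarray, np.ndarray], geotransform,
                  gsd_m: float) -> tuple[tuple[float, float], float]:
    """Centroid (lat, lon) and metric area of one component's pixel set."""
    rows, cols = component_pixels
    if rows.size == 0:
        raise ValueError("empty pixel set")
    lon, lat = pixel_to_lonlat(rows.mean(), cols.mean(), geotransform)
    area = float(rows.size) * gsd_m**2
    return (float(lat), float(lon)), area


def merge_zones(
    mask: LabelMask,
    target_class: int,
    geotransform,
    gsd_m: float,
    close_radius_px: int = 5,
    min_area_m2: float = 1.0,
) -> list[StressZone]:
    """Group a class's pixels into zones; see module docstring for the rule."""
    if geotransform is None:
        raise ValueError("mask is not georeferenced (missing geotransform)")
    support = mask.labels == target_class
    if not support.any():
        return []
    merged = ndimage.binary_closing(support, structure=disk(close_radius_px)) if close_radius_px else support
    labeled, n = ndimage.label(merged, structure=np.ones((3, 3), dtype=bool))
    prefix = ZONE_PREFIX.get(target_class, f"Z{target_class}")
    zones = []
    for comp in range(1, n + 1):
        pix = np.nonzero((labeled == comp) & support)  # original pixels only
        if pix[0].size == 0:
            continue
        centroid, area = zone_geometry(pix, geotransform, gsd_m)
        if area < min_area_m2:
            continue
        bbox = (int(pix[0].min()), int(pix[1].min()), int(pix[0].max()), int(pix[1].max()))
        zones.append(StressZone("", target_class, centroid, area, int(pix[0].size), bbox))
    zones.sort(key=lambda z: -z.area_m2)
    for i, z in enumerate(zones, start=1):
        z.zone_id = f"{prefix}{i:03d}"
    return zones


def zone_table(zones: list[StressZone]) -> list[dict]:
    """Tabular records matching the field-report columns."""
    return [
        {
            "zone_id": z.zone_id,
            "class_id": z.class_id,
            "centroid_lat": z.centroid_latlon[0],
            "centroid_lon": z.centroid_latlon[1],
            "area_m2": round(z.area_m2, 1),
            "pixel_count": z.pixel_count,
        }
        for z in zones
    ]


def zones_to_geojson(zones: list[StressZone], geotransform) -> dict:
    """Zones as a GeoJSON FeatureCollection (bbox polygons + properties)."""
    features = []
    for z in zones:
        r0, c0, r1, c1 = z.bbox_px
        corners_rc = [(r0, c0), (r0, c1 + 1), (r1 + 1, c1 + 1), (r1 + 1, c0), (r0, c0)]
        ring = []
        for r, c in corners_rc:
            lon, lat = pixel_to_lonlat(np.array([r - 0.5]), np.array([c - 0.5]), geotransform)
            ring.append([float(lon[0]), float(lat[0])])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "zone_id": z.zone_id,
                    "class_id": z.class_id,
                    "centroid_lat": z.centroid_latlon[0],
                    "centroid_lon": z.centroid_latlon[1],
                    "area_m2": z.area_m2,
                    "pixel_count": z.pixel_count,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_zone_outputs(zones: list[StressZone], geotransform, csv_path=None, geojson_path=None):
    if csv_path is not None:
        rows = zone_table(zones)
        with open(csv_path, "w") as fh:
            fh.write("zone_id,class_id,centroid_lat,centroid_lon,area_m2,pixel_count\n")
            for r in rows:
                fh.write(
                    f"{r['zone_id']},{r['class_id']},{r['centroid_lat']:.9f},"
                    f"{r['centroid_lon']:.9f},{r['area_m2']},{r['pixel_count']}\n"
                )
    if geojson_path is not None:
        with open(geojson_path, "w") as fh:
            json.dump(zones_to_geojson(zones, geotransform), fh, indent=2)
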