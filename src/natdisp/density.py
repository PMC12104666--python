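"""Truncated Thiessen (Voronoi) local-density estimation around nests.

Local density at an active nest is the reciprocal (1/km^2) of the area of
its Thiessen polygon truncated at a maximum radius ``r_trunc`` (default
12.7 km, the historical mean nearest-neighbour distance of the study
population at low density). Nests are projected to a local equal-area
planar frame before tessellation; external nests (neighbouring countries)
shape their neighbours' cells but get no output row; cells touching a
user-supplied exclusion boundary are flagged and dropped from density
analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from .geo import LocalEqualAreaProjection

logger = logging.getLogger(__name__)

DEFAULT_R_TRUNC_KM = 12.7
#: Vertices of the polygonal approximation of the truncation disc.
DISC_VERTICES = 256


@dataclass
class TerritoryPolygon:
    """One nest's truncated Thiessen cell for one year."""

    territory_id: str
    year: int
    polygon: Polygon  # planar ring(s), km, in the tessellation's projection
    area: float  # km^2
    density: float  # km^-2 (= 1/area)
    truncated: bool  # clipped by the truncation disc
    excluded: bool  # touches the exclusion boundary


def _disc(x: float, y: float, r: float) -> Polygon:
    theta = np.linspace(0.0, 2.0 * math.pi, DISC_VERTICES, endpoint=False)
    return Polygon(np.column_stack([x + r * np.cos(theta), y + r * np.sin(theta)]))


def truncated_thiessen(nests: pd.DataFrame,
                       r_trunc: float = DEFAULT_R_TRUNC_KM,
                       external_nests: Optional[pd.DataFrame] = None,
                       exclusion_boundary: Optional[Polygon] = None,
                       projection: Optional[LocalEqualAreaProjection] = None,
                       ) -> list:
    """Build truncated Thiessen cells for one year's active nests.

    Parameters
    ----------
    nests
        Columns ``territory_id``, ``lon``, ``lat`` (one year's active
        nests inside the study country).
    r_trunc
        Truncation radius in km.
    external_nests
        Nests outside the study country (columns ``lon``, ``lat``): they
        constrain the tessellation but receive no output cell.
    exclusion_boundary
        Planar polygon *in the projected km frame* (or WGS84 lon/lat ring
        if ``projection`` is None it is projected with the same frame);
        cells intersecting it are flagged ``excluded``.
    projection
        Planar frame to use; defaults to an equal-area projection centred
        on the centroid of all supplied nests, so that polygon areas are
        true sphere areas in km^2.
    """
    if len(nests) == 0:
        raise ValueError("at least one nest is required")
    ext = external_nests if external_nests is not None else pd.DataFrame(columns=["lon", "lat"])
    all_lon = np.concatenate([nests["lon"].to_numpy(float), ext["lon"].to_numpy(float)])
    all_lat = np.concatenate([nests["lat"].to_numpy(float), ext["lat"].to_numpy(float)])
    if projection is None:
        projection = LocalEqualAreaProjection.for_points(all_lon, all_lat)
    x, y = projection.forward(all_lon, all_lat)
    pts = np.column_stack([x, y])

    dup = _duplicate_ids(pts, list(nests["territory_id"]) + ["<external>"] * len(ext))
    if dup:
        raise ValueError(f"duplicate nest coordinates: {sorted(dup)}")

    n_internal = len(nests)
    cells = _voronoi_cells(pts, pad=3.0 * r_trunc)

    excl = None
    if exclusion_boundary is not None:
        if isinstance(exclusion_boundary, shapely.geometry.base.BaseGeometry):
            excl = exclusion_boundary
        else:
            excl = shapely.geometry.shape(exclusion_boundary)

    out = []
    years = nests["year"].to_numpy() if "year" in nests.columns else [None] * n_internal
    for i in range(n_internal):
        disc = _disc(pts[i, 0], pts[i, 1], r_trunc)
        cell = cells[i].intersection(disc)
        truncated = cell.area < cells[i].area - 1e-9
        excluded = bool(excl is not None and cell.intersects(excl))
        area = cell.area
        out.append(TerritoryPolygon(
            territory_id=str(nests["territory_id"].iloc[i]),
            year=int(years[i]) if years[i] is not None and not pd.isna(years[i]) else -1,
            polygon=cell,
            area=float(area),
            density=float(1.0 / area),
            truncated=bool(truncated),
            excluded=excluded,
        ))
    return out


def _duplicate_ids(pts: np.ndarray, ids: Sequence[str], tol: float = 1e-9) -> set:
    """IDs of points sharing coordinates (within tol km)."""
    seen: dict = {}
    dup = set()
    for (px, py), tid in zip(np.round(pts / max(tol, 1e-12)).astype(np.int64), ids):
        key = (int(px), int(py))
        if key in seen:
            dup.add(seen[key])
            dup.add(tid)
        else:
            seen[key] = tid
    return dup


def _voronoi_cells(pts: np.ndarray, pad: float) -> list:
    """Bounded Voronoi cell per input point.

    The point cloud is mirrored across the four sides of its bounding
    box padded by ``pad`` km, which bounds every original cell exactly
    at the box edge — safely beyond any truncation disc. Computed with
    scipy/Qhull, which is robust to degenerate (cocircular) generators
    such as regular lattices.
    """
    if len(pts) == 1:
        return [box(pts[0, 0] - pad, pts[0, 1] - pad,
                    pts[0, 0] + pad, pts[0, 1] + pad)]
    minx, miny = pts.min(axis=0) - pad
    maxx, maxy = pts.max(axis=0) + pad
    mirrors = []
    for axis, bound in ((0, minx), (0, maxx), (1, miny), (1, maxy)):
        m = pts.copy()
        m[:, axis] = 2.0 * bound - m[:, axis]
        mirrors.append(m)
    vor = Voronoi(np.vstack([pts] + mirrors))
    out = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[[v for v in region if v >= 0]]
        ang = np.arctan2(verts[:, 1] - pts[i, 1], verts[:, 0] - pts[i, 0])
        out.append(Polygon(verts[np.argsort(ang)]))
    return out


def yearly_density_table(nests_all_years: pd.DataFrame,
                         r_trunc: float = DEFAULT_R_TRUNC_KM,
                         external_nests: Optional[pd.DataFrame] = None,
                         exclusion_boundary: Optional[Polygon] = None,
                         years: Optional[Sequence[int]] = None,
                         projection: Optional[LocalEqualAreaProjection] = None,
                         ) -> pd.DataFrame:
    """Per-year local densities for all active, non-excluded nests.

    Returns a long table (territory_id, year, area, density). The same
    projection (centred on the full nest cloud) is used for every year so
    densities are comparable across years.
    """
    nests = nests_all_years
    if "active" in nests.columns:
        nests = nests[nests["active"].astype(bool)]
    if years is None:
        years = sorted(nests["year"].unique())
    if projection is None:
        lons = nests["lon"].to_numpy(float)
        lats = nests["lat"].to_numpy(float)
        if external_nests is not None and len(external_nests):
            lons = np.concatenate([lons, external_nests["lon"].to_numpy(float)])
            lats = np.concatenate([lats, external_nests["lat"].to_numpy(float)])
        projection = LocalEqualAreaProjection.for_points(lons, lats)
    rows = []
    for year in years:
        sub = nests[nests["year"] == year]
        if len(sub) == 0:
            logger.warning("no active nests in year %s", year)
            continue
        ext = None
        if external_nests is not None:
            ext = external_nests
            if "year" in external_nests.columns:
                ext = external_nests[external_nests["year"] == year]
        for cell in truncated_thiessen(sub, r_trunc, ext, exclusion_boundary,
                                       projection=projection):
            if cell.excluded:
                continue
            rows.append({"territory_id": cell.territory_id, "year": int(year),
                         "area": cell.area, "density": cell.density})
    return pd.DataFrame(rows, columns=["territory_id", "year", "area", "density"])


def polygons_to_geojson(cells: Sequence[TerritoryPolygon],
                        projection: LocalEqualAreaProjection,
                        path=None) -> dict:
    """Export territory polygons as a WGS84 GeoJSON FeatureCollection.

    Ring coordinates are back-projected from the planar km frame; each
    feature carries territory_id, year, area (km^2), density (km^-2) and
    the truncated/excluded flags.
    """
    import json

    features = []
    for cell in cells:
        geoms = getattr(cell.polygon, "geoms", [cell.polygon])
        rings = []
        for g in geoms:
            xy = np.asarray(g.exterior.coords)
            lon, lat = projection.inverse(xy[:, 0], xy[:, 1])
            rings.append([np.column_stack([lon, lat]).tolist()])
        geom = ({"type": "Polygon", "coordinates": rings[0]} if len(rings) == 1
                else {"type": "MultiPolygon", "coordinates": rings})
        features.append({
            "type": "Feature", "geometry": geom,
            "properties": {"territory_id": cell.territory_id, "year": cell.year,
                           "area_km2": cell.area, "density_km2": cell.density,
                           "truncated": cell.truncated, "excluded": cell.excluded},
        })
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc
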