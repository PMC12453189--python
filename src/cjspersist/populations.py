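"""Population delineation and zonal covariate extraction.

A *population* is a connected blob of occurrence records: each cleaned target
record gets a disc of radius ``buffer_km`` (default 2.5 km) around it and
overlapping discs are dissolved into one polygon, so records less than
``2 * buffer_km`` apart share a population.  Populations then receive an
ecoregion label (centroid containment in a level-III ecoregion layer), a
protected-area category, and zonal means of the covariate rasters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape, mapping as shapely_mapping
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .projection import DEFAULT_PROJECTION, AlbersEqualArea
from .rasters import Raster
from .records import ConfigurationError, project_geometry

#: buffer polygonization resolution; a 4*quad_segs-gon underestimates disc
#: area by ~2pi^2/(3 n^2), < 0.05% at quad_segs=32
BUFFER_QUAD_SEGS = 32


@dataclass
class PopulationSet:
    """Dissolved-buffer population polygons with attributes.

    ``table`` has one row per population: ``pop_id``, ``geometry`` (shapely
    polygon, projected equal-area meters), ``centroid_x``/``centroid_y``,
    ``area_km2``, ``n_records``, and, once assigned, ``ecoregion``,
    ``ecoregion_flag``, ``protected_category``, ``protected_flag``, ``state``
    and covariates ``h``/``w``/``v``.  ``membership`` maps each record_id to
    its ``pop_id``.
    """

    table: pd.DataFrame
    membership: pd.Series  # index: record_id, value: pop_id
    buffer_km: float
    projection: AlbersEqualArea = field(default_factory=AlbersEqualArea)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def geometries(self) -> list[BaseGeometry]:
        return list(self.table["geometry"])

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        return self.table["centroid_x"].to_numpy(), self.table["centroid_y"].to_numpy()

    # ---------------------------------------------------------------- export
    def attributes_frame(self) -> pd.DataFrame:
        return self.table.drop(columns=["geometry"])

    def write(self, geojson_path: str | Path, csv_path: str | Path | None = None) -> None:
        """GeoJSON (geometry back in lon/lat) plus a CSV attribute mirror."""
        from .records import unproject_geometry

        feats = []
        for _, row in self.table.iterrows():
            props = {k: v for k, v in row.items() if k != "geometry"}
            geom = unproject_geometry(row["geometry"], self.projection)
            feats.append({"type": "Feature", "properties": _jsonable(props), "geometry": shapely_mapping(geom)})
        with open(geojson_path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
        if csv_path is not None:
            self.attributes_frame().to_csv(csv_path, index=False)


def _jsonable(d: Mapping) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        elif isinstance(v, (np.bool_,)):
            v = bool(v)
        out[k] = v
    return out


def delineate_populations(
    target_records: pd.DataFrame,
    buffer_km: float = 2.5,
    projection: AlbersEqualArea = DEFAULT_PROJECTION,
) -> PopulationSet:
    """Buffer-dissolve record points into population polygons.

    Each record contributes a disc of radius ``buffer_km``; the union is
    exploded into its connected polygons and every record is assigned the
    polygon containing it.  Zero records yield an empty set (with a warning
    left to the caller's logging).
    """
    if buffer_km <= 0:
        raise ConfigurationError("buffer_km must be > 0")
    n = len(target_records)
    if n == 0:
        empty = pd.DataFrame(
            columns=["pop_id", "geometry", "centroid_x", "centroid_y", "area_km2", "n_records"]
        )
        return PopulationSet(empty, pd.Series(dtype=object), buffer_km, projection)

    x, y = projection.forward(target_records["lon"].to_numpy(), target_records["lat"].to_numpy())
    pts = shapely.points(x, y)
    discs = shapely.buffer(pts, buffer_km * 1000.0, quad_segs=BUFFER_QUAD_SEGS)
    dissolved = shapely.union_all(discs)
    polys = list(dissolved.geoms) if dissolved.geom_type == "MultiPolygon" else [dissolved]

    tree = STRtree(polys)
    # assign each record point to the polygon containing it
    idx = tree.query(pts, predicate="intersects")
    poly_of_record = np.full(n, -1, dtype=int)
    poly_of_record[idx[0]] = idx[1]
    if (poly_of_record < 0).any():
        # numerically-on-boundary points: snap to nearest polygon
        for i in np.nonzero(poly_of_record < 0)[0]:
            poly_of_record[i] = int(tree.nearest(pts[i]))

    # stable ordering: west-to-east by centroid, then south-to-north
    cents = [p.centroid for p in polys]
    order = np.lexsort(([c.y for c in cents], [c.x for c in cents]))
    relabel = {old: new for new, old in enumerate(order)}
    rows = []
    for old, poly in enumerate(polys):
        new = relabel[old]
        c = cents[old]
        rows.append(
            {
                "pop_id": f"pop{new:04d}",
                "geometry": poly,
                "centroid_x": c.x,
                "centroid_y": c.y,
                "area_km2": poly.area / 1e6,
                "n_records": int((poly_of_record == old).sum()),
            }
        )
    table = pd.DataFrame(rows).sort_values("pop_id").reset_index(drop=True)
    membership = pd.Series(
        [f"pop{relabel[p]:04d}" for p in poly_of_record],
        index=target_records["record_id"].to_numpy(),
        name="pop_id",
    )
    return PopulationSet(table, membership, buffer_km, projection)


def _assign_by_centroid(
    pops: PopulationSet,
    layers: Sequence[tuple[str, BaseGeometry]],
    fallback_nearest: bool,
) -> tuple[list[str | None], list[bool]]:
    """Label each population by the first layer polygon containing its centroid.

    Layer order is the tie-break for overlapping/shared-boundary polygons.
    With ``fallback_nearest`` a centroid outside all polygons gets the nearest
    layer's label, flagged.
    """
    cx, cy = pops.centroids()
    labels: list[str | None] = []
    flags: list[bool] = []
    geoms = [g for _, g in layers]
    for i in range(len(pops)):
        pt = shapely.points(cx[i], cy[i])
        hit = [j for j, g in enumerate(geoms) if g.covers(pt)]
        if hit:
            labels.append(layers[hit[0]][0])
            flags.append(len(hit) > 1)
        elif fallback_nearest and geoms:
            d = [g.distance(pt) for g in geoms]
            labels.append(layers[int(np.argmin(d))][0])
            flags.append(True)
        else:
            labels.append(None)
            flags.append(False)
    return labels, flags


def assign_ecoregion(
    pops: PopulationSet,
    ecoregion_polygons: Sequence[tuple[str, BaseGeometry]],
    projected: bool = True,
) -> PopulationSet:
    """Label populations with the ecoregion containing their centroid.

    ``ecoregion_polygons`` is an ordered sequence of (name, polygon); a
    centroid on a shared boundary takes the first region in layer order
    (flagged), and a centroid outside every region takes the nearest one
    (flagged).  Polygons are expected in the projected plane unless
    ``projected=False`` (lon/lat, reprojected here).
    """
    if not ecoregion_polygons:
        raise ConfigurationError("ecoregion layer is empty")
    layers = [
        (name, g if projected else project_geometry(g, pops.projection))
        for name, g in ecoregion_polygons
    ]
    labels, flags = _assign_by_centroid(pops, layers, fallback_nearest=True)
    pops.table["ecoregion"] = labels
    pops.table["ecoregion_flag"] = flags
    return pops


def assign_protected(
    pops: PopulationSet,
    protected_polygons: Sequence[tuple[str, BaseGeometry]],
    category_map: Mapping[str, str] | None = None,
    category_priority: Sequence[str] = (),
    projected: bool = True,
) -> PopulationSet:
    """Assign a protected-area category by centroid containment, else "none".

    ``protected_polygons`` pairs a raw designation with its polygon;
    ``category_map`` collapses designations into analysis categories (an
    unmapped designation becomes ``"other"``).  When a centroid falls in
    several designations the earliest category in ``category_priority`` wins
    (flagged); otherwise layer order decides.
    """
    category_map = dict(category_map or {})
    layers = []
    for raw, g in protected_polygons:
        cat = category_map.get(raw, raw if not category_map else "other")
        layers.append((cat, g if projected else project_geometry(g, pops.projection)))
    if category_priority:
        rank = {c: i for i, c in enumerate(category_priority)}
        layers.sort(key=lambda kv: rank.get(kv[0], len(rank)))
    labels, flags = _assign_by_centroid(pops, layers, fallback_nearest=False)
    pops.table["protected_category"] = [l if l is not None else "none" for l in labels]
    pops.table["protected_flag"] = flags
    return pops


def zonal_mean(pops: PopulationSet, raster: Raster, column: str | None = None) -> np.ndarray:
    """Mean raster value over cells whose *centers* fall inside each polygon.

    Nodata (NaN) cells are ignored.  A polygon containing no cell center
    falls back to the nearest finite cell's value (flagged via
    ``<column>_flag`` when a column name is given).
    """
    xs, ys = raster.cell_centers()
    vals = raster.values
    out = np.empty(len(pops))
    flags = np.zeros(len(pops), dtype=bool)
    finite = np.isfinite(vals)
    fin_r, fin_c = np.nonzero(finite)
    for i, poly in enumerate(pops.table["geometry"]):
        xmin, ymin, xmax, ymax = poly.bounds
        jj = np.nonzero((xs >= xmin - raster.cell) & (xs <= xmax + raster.cell))[0]
        ii = np.nonzero((ys >= ymin - raster.cell) & (ys <= ymax + raster.cell))[0]
        if len(jj) and len(ii):
            gx, gy = np.meshgrid(xs[jj], ys[ii])
            inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
            sub = vals[np.ix_(ii, jj)]
            sel = inside & np.isfinite(sub)
        else:
            sel = np.zeros((0, 0), dtype=bool)
        if sel.any():
            out[i] = sub[sel].mean()
        else:
            # nearest finite cell center to the polygon centroid
            c = poly.centroid
            d2 = (xs[fin_c] - c.x) ** 2 + (ys[fin_r] - c.y) ** 2
            k = int(np.argmin(d2))
            out[i] = vals[fin_r[k], fin_c[k]]
            flags[i] = True
    if column is not None:
        pops.table[column] = out
        if flags.any():
            pops.table[f"{column}_flag"] = flags
    return out


def covariate_correlations(pops: PopulationSet, columns: Sequence[str] = ("h", "w", "v")) -> pd.DataFrame:
    """Pairwise Pearson correlations among population covariates.

    Requires at least three populations; a zero-variance covariate yields
    NaN entries (flagged by pandas' NaN, as documented).
    """
    if len(pops) < 3:
        raise ConfigurationError("need at least 3 populations for correlations")
    return pops.table[list(columns)].corr(method="pearson")


# -------------------------------------------------------------- GeoJSON I/O

def read_geojson_layers(path: str | Path, name_property: str = "name") -> list[tuple[str, BaseGeometry]]:
    """Read a GeoJSON FeatureCollection as ordered (name, lon/lat geometry) pairs."""
    with open(path) as fh:
        gj = json.load(fh)
    out = []
    for feat in gj.get("features", []):
        name = str(feat.get("properties", {}).get(name_property, len(out)))
        out.append((name, shapely_shape(feat["geometry"])))
    return out


def write_geojson_layers(path: str | Path, layers: Sequence[tuple[str, BaseGeometry]], name_property: str = "name") -> None:
    feats = [
        {"type": "Feature", "properties": {name_property: name}, "geometry": shapely_mapping(geom)}
        for name, geom in layers
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
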