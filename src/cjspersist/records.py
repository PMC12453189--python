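"""Occurrence-record ingestion and cleaning.

Raw occurrence tables (museum, community-science, survey) arrive as CSV with
one dated, georeferenced observation per row.  The cleaning rules implemented
here mirror the compilation protocol for a presence-only persistence analysis:

* target-species records: drop points falling more than a tolerance (default
  10 km) outside the species range polygon; drop location uncertainty above
  5 km but *retain* records whose uncertainty is unrecorded; collapse same-day
  records within 10 m of each other (database duplicates with rounded
  coordinates) to a single representative;
* effort (non-target) records: keep only the target's activity season (Nov 1 -
  Apr 30 by default), drop uncertainty above 2.5 km *or missing*, keep one
  event per (date, coordinates, observer), and restrict region-limited index
  species to their allowed states.

Every rule appends its drop count to a :class:`CleaningReport`, which must
reconcile exactly with the input/output row counts.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from .projection import DEFAULT_PROJECTION, AlbersEqualArea, haversine_m

#: canonical column order for a validated record table
COLUMNS = [
    "record_id",
    "species",
    "event_date",
    "lon",
    "lat",
    "coord_uncertainty_m",
    "observer",
    "source",
    "state",
]


class ConfigurationError(ValueError):
    """A problem with configuration or inputs, detected before any row work."""


@dataclass
class CleaningReport:
    """Per-rule drop counts; ``dropped + retained == input`` for every rule."""

    entries: list[dict] = field(default_factory=list)

    def add(self, rule: str, n_in: int, n_out: int, note: str = "") -> None:
        self.entries.append(
            {"rule": rule, "input": n_in, "dropped": n_in - n_out, "retained": n_out, "note": note}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["rule", "input", "dropped", "retained", "note"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_records(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    run_date: _dt.date | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate an occurrence CSV.

    ``column_map`` maps canonical names (see :data:`COLUMNS`) to the file's
    column names; identity is assumed for omitted keys.  Returns
    ``(records, errors)``: malformed rows land in ``errors`` with a reason,
    never silently vanish.  A missing *required* column (species, event_date,
    lon, lat) raises :class:`ConfigurationError`.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {column_map.get(k, k): k for k in COLUMNS if column_map.get(k, k) in raw.columns}
    df = raw.rename(columns=rename)
    required = ["species", "event_date", "lon", "lat"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"required column(s) missing from {path}: {missing}")
    for c in COLUMNS:
        if c not in df.columns:
            df[c] = ""
    df = df[COLUMNS].copy()
    if (df["record_id"] == "").all():
        df["record_id"] = [f"r{i:06d}" for i in range(len(df))]

    run_date = run_date or _dt.date.today()
    errors: list[dict] = []

    dates = pd.to_datetime(df["event_date"], errors="coerce", format="mixed")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    unc = pd.to_numeric(df["coord_uncertainty_m"].mask(df["coord_uncertainty_m"].eq("")), errors="coerce")

    bad_date = dates.isna() | (dates.dt.date > run_date)
    bad_coord = lon.isna() | lat.isna() | (lon.abs() > 180) | (lat.abs() > 90)
    bad_unc = df["coord_uncertainty_m"].ne("") & (unc.isna() | (unc < 0))
    bad = bad_date | bad_coord | bad_unc
    for idx in df.index[bad]:
        reasons = []
        if bad_date[idx]:
            reasons.append("unparseable or future event_date")
        if bad_coord[idx]:
            reasons.append("invalid coordinates")
        if bad_unc[idx]:
            reasons.append("negative or unparseable coord_uncertainty_m")
        errors.append({"record_id": df.at[idx, "record_id"], "row": int(idx), "reason": "; ".join(reasons)})

    out = df[~bad].copy()
    out["event_date"] = dates[~bad].dt.date
    out["lon"] = lon[~bad]
    out["lat"] = lat[~bad]
    out["coord_uncertainty_m"] = unc[~bad]
    for c in ("observer", "source", "state", "species"):
        out[c] = out[c].mask(out[c].eq(""))
    return out.reset_index(drop=True), pd.DataFrame(errors, columns=["record_id", "row", "reason"])


def filter_range(
    records: pd.DataFrame,
    range_polygon: BaseGeometry,
    tolerance_km: float = 10.0,
    projection: AlbersEqualArea = DEFAULT_PROJECTION,
    report: CleaningReport | None = None,
) -> pd.DataFrame:
    """Drop records farther than ``tolerance_km`` outside the range polygon.

    ``range_polygon`` is in lon/lat degrees; distances are measured in the
    package's equal-area projection.
    """
    if range_polygon is None or range_polygon.is_empty:
        raise ConfigurationError("range polygon is empty")
    if tolerance_km < 0:
        raise ConfigurationError("tolerance_km must be >= 0")
    poly_xy = project_geometry(range_polygon, projection)
    x, y = projection.forward(records["lon"].to_numpy(), records["lat"].to_numpy())
    prepared = prep(poly_xy)
    keep = np.empty(len(records), dtype=bool)
    import shapely

    pts = shapely.points(x, y)
    for i, pt in enumerate(np.atleast_1d(pts)):
        keep[i] = prepared.contains(pt) or poly_xy.distance(pt) <= tolerance_km * 1000.0
    out = records[keep].reset_index(drop=True)
    if report is not None:
        report.add("range", len(records), len(out), f"tolerance_km={tolerance_km}")
    return out


def filter_uncertainty(
    records: pd.DataFrame,
    max_m: float,
    drop_missing: bool,
    report: CleaningReport | None = None,
) -> pd.DataFrame:
    """Drop records with coordinate uncertainty above ``max_m``.

    Records with *missing* uncertainty are retained when ``drop_missing`` is
    False (target-species rule) and dropped when True (effort rule).
    """
    if max_m <= 0:
        raise ConfigurationError("max_m must be > 0")
    unc = records["coord_uncertainty_m"]
    keep = unc.le(max_m)
    if not drop_missing:
        keep = keep | unc.isna()
    out = records[keep].reset_index(drop=True)
    if report is not None:
        report.add("uncertainty", len(records), len(out), f"max_m={max_m} drop_missing={drop_missing}")
    return out


def _cluster_same_day(lon: np.ndarray, lat: np.ndarray, dist_m: float) -> np.ndarray:
    """Single-linkage clusters (union-find) of points within ``dist_m`` geodesic."""
    n = len(lon)
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        d = haversine_m(lon[i], lat[i], lon[i + 1:], lat[i + 1:])
        for j in np.nonzero(np.atleast_1d(d) <= dist_m)[0]:
            ra, rb = find(i), find(i + 1 + j)
            if ra != rb:
                parent[rb] = ra
    return np.array([find(i) for i in range(n)])


def dedup_target(
    records: pd.DataFrame,
    dist_m: float = 10.0,
    source_priority: Sequence[str] = (),
    report: CleaningReport | None = None,
) -> pd.DataFrame:
    """Collapse same-day records within ``dist_m`` (geodesic) to one per cluster.

    Clusters are single-linkage; the representative is the member with the
    highest-priority ``source`` (earlier in ``source_priority`` wins; unlisted
    sources rank last), ties broken by lexicographically smallest
    ``record_id`` so the result is independent of input row order.
    """
    if dist_m < 0:
        raise ConfigurationError("dist_m must be >= 0")
    rank = {s: i for i, s in enumerate(source_priority)}
    keep_ids: list = []
    for _, grp in records.groupby("event_date", sort=True):
        labels = _cluster_same_day(grp["lon"].to_numpy(), grp["lat"].to_numpy(), dist_m)
        grp = grp.assign(_cluster=labels)
        for _, cluster in grp.groupby("_cluster"):
            pri = cluster["source"].map(lambda s: rank.get(s, len(rank)))
            best = cluster.assign(_pri=pri).sort_values(["_pri", "record_id"]).iloc[0]
            keep_ids.append(best["record_id"])
    out = records[records["record_id"].isin(keep_ids)].reset_index(drop=True)
    if report is not None:
        report.add("duplicate", len(records), len(out), f"dist_m={dist_m}")
    return out


def dedup_effort(records: pd.DataFrame, report: CleaningReport | None = None) -> pd.DataFrame:
    """Keep exactly one event per (date, rounded coordinates, observer).

    Coordinates are rounded to 5 decimal places (~1 m) to define "exact same
    coordinates" across databases of mixed precision.  A missing observer is
    replaced in the key by the record's source, preserving the one-event-per-
    observer-day semantics for sources that do not report observers.
    """
    key_obs = records["observer"].fillna(records["source"]).fillna("")
    key = pd.DataFrame(
        {
            "d": records["event_date"],
            "lon": records["lon"].round(5),
            "lat": records["lat"].round(5),
            "o": key_obs,
        }
    )
    order = np.argsort(records["record_id"].to_numpy(), kind="stable")
    dup = key.iloc[order].duplicated(keep="first").to_numpy()
    mask = np.zeros(len(records), dtype=bool)
    mask[order[~dup]] = True
    out = records[mask].reset_index(drop=True)
    if report is not None:
        report.add("effort-duplicate", len(records), len(out))
    return out


def filter_season(
    records: pd.DataFrame,
    start_month_day: tuple[int, int] = (11, 1),
    end_month_day: tuple[int, int] = (4, 30),
    report: CleaningReport | None = None,
) -> pd.DataFrame:
    """Keep records whose month-day falls in the closed window.

    A window with start > end (e.g. Nov 1 - Apr 30) wraps across the year
    boundary; both endpoints are inclusive.
    """
    md = records["event_date"].map(lambda d: (d.month, d.day))
    s, e = tuple(start_month_day), tuple(end_month_day)
    if s <= e:
        keep = md.map(lambda x: s <= x <= e)
    else:
        keep = md.map(lambda x: x >= s or x <= e)
    out = records[keep].reset_index(drop=True)
    if report is not None:
        report.add("season", len(records), len(out), f"{s}..{e}")
    return out


def filter_nontarget_species(
    records: pd.DataFrame,
    species_region_map: Mapping[str, object],
    state_polygons: Mapping[str, BaseGeometry] | None = None,
    projection: AlbersEqualArea = DEFAULT_PROJECTION,
    report: CleaningReport | None = None,
) -> pd.DataFrame:
    """Keep effort-species records, honoring per-species state restrictions.

    ``species_region_map`` maps each effort species to ``"all"`` or a list of
    allowed 2-letter state codes.  Species absent from the map are dropped.
    For region-restricted species, the record's ``state`` field decides; when
    it is missing the point is located in ``state_polygons`` (lon/lat); a
    record with no state and no resolvable polygon is dropped and noted.
    """
    unresolved = 0
    keep = np.zeros(len(records), dtype=bool)
    prepared = {k: prep(v) for k, v in (state_polygons or {}).items()}
    import shapely

    for i, row in enumerate(records.itertuples(index=False)):
        allowed = species_region_map.get(row.species)
        if allowed is None:
            continue
        if allowed == "all":
            keep[i] = True
            continue
        state = row.state
        if not isinstance(state, str) or not state:
            state = None
            for code, geom in prepared.items():
                if geom.contains(shapely.points(row.lon, row.lat)):
                    state = code
                    break
            if state is None:
                unresolved += 1
                continue
        keep[i] = state in allowed
    out = records[keep].reset_index(drop=True)
    if report is not None:
        note = f"unresolved_state={unresolved}" if unresolved else ""
        report.add("species-region", len(records), len(out), note)
    return out


def project_geometry(geom: BaseGeometry, projection: AlbersEqualArea = DEFAULT_PROJECTION) -> BaseGeometry:
    """Reproject a lon/lat geometry into the equal-area plane, vertex-wise."""
    import shapely

    def _tx(coords: np.ndarray) -> np.ndarray:
        x, y = projection.forward(coords[:, 0], coords[:, 1])
        return np.column_stack([x, y])

    return shapely.transform(geom, _tx)


def unproject_geometry(geom: BaseGeometry, projection: AlbersEqualArea = DEFAULT_PROJECTION) -> BaseGeometry:
    """Inverse of :func:`project_geometry`."""
    import shapely

    def _tx(coords: np.ndarray) -> np.ndarray:
        lon, lat = projection.inverse(coords[:, 0], coords[:, 1])
        return np.column_stack([lon, lat])

    return shapely.transform(geom, _tx)
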