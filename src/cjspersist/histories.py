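"""Population x year detection and search-effort histories.

The persistence model consumes two aligned matrices over a fixed span of
calendar years (1950-2024 by default, 75 columns):

* ``y[i, t]`` — 1 iff at least one target record fell in population ``i``
  during year ``t``;
* ``e_raw[i, t]`` — the number of distinct observer-days (one observer
  reporting any indexing species, or the target itself, inside the population
  polygon on one date), plus a scaled version ``e`` used as the detection
  covariate.

Records dated before the first modeled year do not enter ``y``; they only
mark the population as known before the start (presence in the first year is
assumed for every population).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .populations import PopulationSet
from .records import ConfigurationError


@dataclass
class DetectionMatrix:
    y: np.ndarray  # (N, T) int8
    years: np.ndarray  # (T,) calendar years
    pop_ids: list[str]
    first_detection_year: np.ndarray  # (N,) year or -1 if never detected in-window
    last_detection_year: np.ndarray  # (N,) year or -1
    known_before_start: np.ndarray  # (N,) bool

    @property
    def n_populations(self) -> int:
        return self.y.shape[0]

    @property
    def n_years(self) -> int:
        return self.y.shape[1]

    def last_index(self) -> np.ndarray:
        """1-based index of the last detection year; 0 when never detected in-window."""
        idx = np.zeros(self.n_populations, dtype=np.int64)
        det = self.last_detection_year >= 0
        idx[det] = self.last_detection_year[det] - self.years[0] + 1
        return idx

    def write(self, wide_csv: str | Path, meta_json: str | Path | None = None) -> None:
        df = pd.DataFrame(self.y, index=self.pop_ids, columns=self.years)
        df.index.name = "pop_id"
        df.to_csv(wide_csv)
        if meta_json is not None:
            meta = {
                "years": [int(self.years[0]), int(self.years[-1])],
                "first_detection_year": self.first_detection_year.tolist(),
                "last_detection_year": self.last_detection_year.tolist(),
                "known_before_start": self.known_before_start.astype(bool).tolist(),
            }
            Path(meta_json).write_text(json.dumps(meta))


@dataclass
class EffortMatrix:
    e_raw: np.ndarray  # (N, T) int64 observer-days
    e: np.ndarray  # (N, T) float, scaled
    years: np.ndarray
    pop_ids: list[str]
    scaling: str
    scaling_constants: dict = field(default_factory=dict)

    def write(self, wide_csv: str | Path, meta_json: str | Path | None = None) -> None:
        df = pd.DataFrame(self.e_raw, index=self.pop_ids, columns=self.years)
        df.index.name = "pop_id"
        df.to_csv(wide_csv)
        if meta_json is not None:
            Path(meta_json).write_text(
                json.dumps(
                    {
                        "years": [int(self.years[0]), int(self.years[-1])],
                        "scaling": self.scaling,
                        "scaling_constants": self.scaling_constants,
                    }
                )
            )


def _year_of(dates: pd.Series, season_year: bool) -> np.ndarray:
    """Calendar year of each event; with ``season_year`` Nov/Dec shift forward

    so an observation belongs to the breeding season it opens."""
    years = np.array([d.year for d in dates])
    if season_year:
        months = np.array([d.month for d in dates])
        years = years + (months >= 11).astype(int)
    return years


def build_detection_matrix(
    target_records: pd.DataFrame,
    populations: PopulationSet,
    year_range: tuple[int, int] = (1950, 2024),
    season_year: bool = False,
) -> DetectionMatrix:
    """Binary detection history from cleaned, population-assigned records."""
    y0, y1 = year_range
    years = np.arange(y0, y1 + 1)
    pop_ids = list(populations.table["pop_id"])
    pos = {p: i for i, p in enumerate(pop_ids)}
    N, T = len(pop_ids), len(years)
    y = np.zeros((N, T), dtype=np.int8)
    known_before = np.zeros(N, dtype=bool)

    rec_pop = populations.membership
    ev_years = _year_of(target_records["event_date"], season_year)
    for rid, yr in zip(target_records["record_id"], ev_years):
        if rid not in rec_pop.index:
            raise ConfigurationError(f"record {rid} not assigned to any population")
        i = pos[rec_pop.loc[rid]]
        if yr < y0:
            known_before[i] = True
        elif yr <= y1:
            y[i, yr - y0] = 1

    det = y.any(axis=1)
    first = np.where(det, y0 + np.argmax(y, axis=1), -1)
    last = np.where(det, y0 + T - 1 - np.argmax(y[:, ::-1], axis=1), -1)
    return DetectionMatrix(y, years, pop_ids, first, last, known_before)


def build_effort_matrix(
    all_event_records: pd.DataFrame,
    populations: PopulationSet,
    year_range: tuple[int, int] = (1950, 2024),
    scaling: str = "zscore",
    season_year: bool = False,
) -> EffortMatrix:
    """Observer-day counts per population-year, raw and scaled.

    ``all_event_records`` should already be deduplicated to one row per
    (date, coordinates, observer) event and include the target's own records
    (a detection is itself a search event).  Events are assigned to the
    population polygon containing their point; events outside every polygon
    are discarded (they index effort nowhere).
    """
    if scaling not in {"zscore", "minmax", "none"}:
        raise ConfigurationError(f"unknown effort scaling {scaling!r}")
    y0, y1 = year_range
    years = np.arange(y0, y1 + 1)
    pop_ids = list(populations.table["pop_id"])
    N, T = len(pop_ids), len(years)
    e_raw = np.zeros((N, T), dtype=np.int64)

    if len(all_event_records):
        proj = populations.projection
        x, ycoord = proj.forward(
            all_event_records["lon"].to_numpy(), all_event_records["lat"].to_numpy()
        )
        pts = shapely.points(x, ycoord)
        tree = STRtree(populations.geometries)
        q = tree.query(pts, predicate="intersects")
        ev_years = _year_of(all_event_records["event_date"], season_year)
        for pt_i, poly_i in zip(q[0], q[1]):
            yr = ev_years[pt_i]
            if y0 <= yr <= y1:
                e_raw[poly_i, yr - y0] += 1

    if scaling == "zscore":
        mu, sd = float(e_raw.mean()), float(e_raw.std())
        e = (e_raw - mu) / sd if sd > 0 else np.zeros_like(e_raw, dtype=float)
        constants = {"mean": mu, "sd": sd}
    elif scaling == "minmax":
        lo, hi = float(e_raw.min()), float(e_raw.max())
        e = (e_raw - lo) / (hi - lo) if hi > lo else np.zeros_like(e_raw, dtype=float)
        constants = {"min": lo, "max": hi}
    else:
        e = e_raw.astype(float)
        constants = {}
    return EffortMatrix(e_raw, e, years, pop_ids, scaling, constants)


def cooccurrence_table(
    call_survey_records: pd.DataFrame,
    target_species: str,
    site_column: str | None = None,
    coord_decimals: int = 3,
) -> pd.DataFrame:
    """Fraction of target-present survey events at which each species co-occurs.

    Events are grouped by (site, date); the site key is ``site_column`` when
    provided, else coordinates rounded to ``coord_decimals`` places.  The
    returned table drives the (judgment) choice of effort-indexing species.
    Raises if the target was never present.
    """
    df = call_survey_records
    if site_column is not None:
        site = df[site_column]
    else:
        site = df["lon"].round(coord_decimals).astype(str) + "," + df["lat"].round(coord_decimals).astype(str)
    key = pd.DataFrame({"site": site, "date": df["event_date"], "species": df["species"]})
    events = key.groupby(["site", "date"])["species"].agg(set)
    with_target = events[events.map(lambda s: target_species in s)]
    if len(with_target) == 0:
        raise ConfigurationError("no survey events with the target species present")
    candidates = sorted(set(df["species"]) - {target_species})
    rows = [
        {
            "species": sp,
            "n_target_events": len(with_target),
            "n_cooccurrences": int(with_target.map(lambda s: sp in s).sum()),
        }
        for sp in candidates
    ]
    out = pd.DataFrame(rows)
    out["fraction"] = out["n_cooccurrences"] / out["n_target_events"]
    return out.sort_values("fraction", ascending=False).reset_index(drop=True)
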