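"""Synthetic landscapes, populations, and occurrence-record streams.

Every pipeline stage is testable without downloads: this module fabricates

* a landscape — smooth habitat-suitability field in [0,1], patchy
  imperviousness, monthly winter precipitation grids with a spatial gradient,
  banded level-III-style ecoregions, seven state bands, rectangular protected
  areas, and a range polygon;
* population ground truth — well-separated population centers with known
  covariates and known generating parameters of Table-2-like magnitude;
* record streams — observer-day events whose intensity rises log-linearly
  over calendar time (most effort after 2000, mirroring community-science
  growth), target detections drawn from the model's detection formula while
  the population is extant, non-target records of eight effort-indexing
  species in the Nov-Apr activity window, plus injected duplicates,
  out-of-range decoys, heterogeneous location uncertainty and a stated
  fraction of missing uncertainty, so the cleaning rules bite.

The generator is seed-deterministic end to end, and the model-level
``simulate_matrices`` path reproduces the fitted likelihood's generative
process exactly (every population anchored present in the first modeled
year), which is what parameter-recovery checks require.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Polygon, box

from .histories import DetectionMatrix, EffortMatrix
from .likelihood import ModelData, Params, invlogit, logit
from .projection import DEFAULT_PROJECTION, AlbersEqualArea
from .rasters import Raster, scale_01

ECOREGION_NAMES = ("Southern Coastal Plain", "Southeastern Plains", "Middle Atlantic Coastal Plain")
STATE_CODES = ("LA", "MS", "AL", "FL", "GA", "SC", "NC")
PROTECTED_CATEGORIES = (
    "state forest", "state park", "national forest", "national wildlife refuge",
    "wildlife management area", "military", "ngo/private", "other",
)
EFFORT_SPECIES = {
    "Pseudacris crucifer": "all",
    "Pseudacris nigrita": "all",
    "Pseudacris ocularis": "all",
    "Pseudacris brimleyi": ["SC"],
    "Pseudacris feriarum": ["SC"],
    "Lithobates sphenocephalus": "all",
    "Lithobates clamitans": ["MS"],
    "Dryophytes chrysoscelis": ["MS"],
}
TARGET_SPECIES = "Pseudacris ornata"


def default_params(n_ecoregions: int = 3) -> Params:
    """Generating parameters of the magnitudes the persistence model reports."""
    alpha = logit(np.array([0.815, 0.808, 0.834][:n_ecoregions]))
    return Params(
        alpha=alpha,
        beta_hs=2.856,
        beta_rain=4.007,
        beta_imp=-1.553,
        gamma0=float(logit(0.014)),
        beta_trend=0.019,
        beta_effort=0.279,
        ecoregion_names=ECOREGION_NAMES[:n_ecoregions],
    )


@dataclass
class Landscape:
    suitability: Raster
    imperviousness: Raster
    monthly_precip: dict[tuple[int, int], Raster]
    ecoregions: list[tuple[str, Polygon]]  # projected plane
    states: list[tuple[str, Polygon]]
    protected: list[tuple[str, Polygon]]
    range_polygon: Polygon
    projection: AlbersEqualArea
    bounds: tuple[float, float, float, float]  # projected xmin, ymin, xmax, ymax


def simulate_landscape(
    seed: int = 0,
    extent: tuple[float, float, float, float] = (-85.0, 29.5, -78.5, 34.5),
    n_ecoregions: int = 3,
    cell_km: float = 1.0,
    precip_years: tuple[int, int] = (1993, 2023),
) -> Landscape:
    """Fabricate rasters and polygon layers over a lon/lat extent.

    All rasters and polygons are produced in the package's projected plane so
    the pipeline's reprojection path is exercised by the record tables (which
    are lon/lat) rather than by the landscape itself.
    """
    rng = np.random.default_rng(seed)
    proj = DEFAULT_PROJECTION
    lons = [extent[0], extent[2], extent[0], extent[2]]
    lats = [extent[1], extent[1], extent[3], extent[3]]
    xs, ys = proj.forward(lons, lats)
    cell = cell_km * 1000.0
    x0 = float(np.floor(min(xs) / cell) * cell)
    y0 = float(np.floor(min(ys) / cell) * cell)
    x1 = float(np.ceil(max(xs) / cell) * cell)
    y1 = float(np.ceil(max(ys) / cell) * cell)
    nc = int(round((x1 - x0) / cell))
    nr = int(round((y1 - y0) / cell))

    def smooth(sigma: float) -> np.ndarray:
        return ndimage.gaussian_filter(rng.standard_normal((nr, nc)), sigma=sigma, mode="nearest")

    suit = Raster(scale_01(smooth(10.0)), x0, y0, cell, units="suitability")

    f = smooth(6.0)
    thr = np.quantile(f, 0.88)
    hi = np.quantile(f, 0.999)
    imp = np.clip((f - thr) / max(hi - thr, 1e-9), 0.0, 1.0) * 0.95
    imperv = Raster(imp, x0, y0, cell, units="fraction")

    # monthly precipitation: wetter toward the south-west, plus winter-to-winter
    # and within-grid noise
    col_grad = np.linspace(1.0, 0.0, nc)[None, :]
    row_grad = np.linspace(0.0, 1.0, nr)[:, None]  # row 0 = north
    base = 60.0 + 50.0 * (0.6 * col_grad + 0.4 * row_grad)
    monthly: dict[tuple[int, int], Raster] = {}
    for wy in range(precip_years[0], precip_years[1] + 1):
        for month in (12, 1, 2):
            key = (wy - 1, month) if month == 12 else (wy, month)
            vals = base + rng.normal(0.0, 12.0) + 8.0 * smooth(4.0)
            monthly[key] = Raster(np.clip(vals, 1.0, None), x0, y0, cell, units="mm")

    def bands(names, horizontal: bool) -> list[tuple[str, Polygon]]:
        k = len(names)
        out = []
        for i, name in enumerate(names):
            if horizontal:
                lo = y0 + (y1 - y0) * i / k
                hi_ = y0 + (y1 - y0) * (i + 1) / k
                out.append((name, box(x0, lo, x1, hi_)))
            else:
                lo = x0 + (x1 - x0) * i / k
                hi_ = x0 + (x1 - x0) * (i + 1) / k
                out.append((name, box(lo, y0, hi_, y1)))
        return out

    ecoregions = bands(list(ECOREGION_NAMES[:n_ecoregions]), horizontal=True)
    states = bands(list(STATE_CODES), horizontal=False)

    m = 40_000.0  # range margin so >10 km out-of-range decoys still fit in the extent
    rng_poly = Polygon(
        [
            (x0 + m, y0 + m),
            (x1 - m, y0 + m),
            (x1 - m, y1 - m - 60_000.0),
            (x1 - m - 60_000.0, y1 - m),
            (x0 + m, y1 - m),
        ]
    )

    # protected rectangles sized so roughly 35-40% of the range is protected,
    # matching the share of study populations with protected centroids
    protected: list[tuple[str, Polygon]] = []
    inner = rng_poly.buffer(-10_000.0)
    ixmin, iymin, ixmax, iymax = inner.bounds
    target_area = 0.4 * rng_poly.area
    covered = 0.0
    span = min(ixmax - ixmin, iymax - iymin)
    for i in range(200):
        if covered >= target_area:
            break
        cat = PROTECTED_CATEGORIES[i % len(PROTECTED_CATEGORIES)]
        w = rng.uniform(0.08, 0.25) * span
        h = rng.uniform(0.08, 0.25) * span
        cx = rng.uniform(ixmin, max(ixmax - w, ixmin + 1.0))
        cy = rng.uniform(iymin, max(iymax - h, iymin + 1.0))
        rect = box(cx, cy, cx + w, cy + h)
        if inner.contains(rect):
            protected.append((cat, rect))
            covered += rect.area

    return Landscape(suit, imperv, monthly, ecoregions, states, protected, rng_poly, proj, (x0, y0, x1, y1))


@dataclass
class TruthSpec:
    """Generating configuration for the record stream / detection histories."""

    params: Params = field(default_factory=default_params)
    n_populations: int = 400
    # centers >= 7.5 km apart: with <= 1 km record jitter, populations never
    # merge at the 2.5-km baseline buffer (record gaps stay > 5 km) but close
    # pairs can merge at 5 km and sparse ones can split at 1 km, so the
    # buffer-sensitivity rerun exercises real regrouping
    min_separation_km: float = 7.5
    # Poisson observer-days per population-year: lambda(t) = exp(a + b (t - start));
    # b = 0.08/yr puts ~87% of events on or after 2000 over 1950-2024, and the
    # defaults integrate to ~10.5 events per population over the span
    effort_log_rate: tuple[float, float] = (-6.05, 0.08)
    anchor_pre_start_frac: float = 1.0  # anchors dated before the first modeled year
    missing_uncertainty_frac: float = 0.36
    large_uncertainty_frac: float = 0.03
    duplicate_frac: float = 0.05
    decoy_frac: float = 0.02
    jitter_max_m: float = 1000.0


@dataclass
class SimulationTruth:
    """Everything needed to score a simulated dataset against its generator."""

    params: Params
    eco: np.ndarray
    hwv: np.ndarray
    centers_xy: np.ndarray  # (N, 2) projected, empty for matrix-level sims
    tau: np.ndarray  # latent extirpation year index (2..T+1); T+1 = survived
    e_raw: np.ndarray
    e_scaled: np.ndarray
    years: np.ndarray
    t_ref: float
    seed: int

    def extant_final(self) -> np.ndarray:
        return self.tau == len(self.years) + 1

    def to_json(self, path: str | Path) -> None:
        d = {
            "params": self.params.to_vector().tolist(),
            "ecoregion_names": list(self.params.ecoregion_names),
            "eco": self.eco.tolist(),
            "hwv": self.hwv.tolist(),
            "centers_xy": self.centers_xy.tolist(),
            "tau": self.tau.tolist(),
            "e_raw": self.e_raw.tolist(),
            "years": [int(self.years[0]), int(self.years[-1])],
            "t_ref": self.t_ref,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        params = Params.from_vector(np.array(d["params"]), tuple(d["ecoregion_names"]))
        e_raw = np.array(d["e_raw"], dtype=np.int64)
        sd = e_raw.std()
        e_scaled = (e_raw - e_raw.mean()) / sd if sd > 0 else e_raw.astype(float)
        return cls(
            params,
            np.array(d["eco"], dtype=np.int64),
            np.array(d["hwv"], dtype=float),
            np.array(d["centers_xy"], dtype=float),
            np.array(d["tau"], dtype=np.int64),
            e_raw,
            e_scaled,
            np.arange(d["years"][0], d["years"][1] + 1),
            float(d["t_ref"]),
            int(d["seed"]),
        )


def sample_extirpation_years(phi: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
    """Draw the first-dead-year index tau in {2..T+1} (T+1 = survived span).

    tau - 2 survival transitions succeed then one fails:
    P(tau=k) = phi^(k-2) (1-phi) for k <= T and P(tau=T+1) = phi^(T-1).
    """
    phi = np.asarray(phi, dtype=float)
    tau = np.full(phi.shape, T + 1, dtype=np.int64)
    ok = phi < 1.0
    g = rng.geometric(1.0 - phi[ok])  # trials to first death, >= 1
    tau[ok] = np.minimum(g + 1, T + 1)
    return tau


def _effort_rates(truth: TruthSpec, years: np.ndarray) -> np.ndarray:
    a, b = truth.effort_log_rate
    return np.exp(a + b * (years - years[0]))


def simulate_matrices(
    truth_spec: TruthSpec | None = None,
    seed: int = 0,
    year_range: tuple[int, int] = (1950, 2024),
    t_ref: float | None = None,
) -> tuple[ModelData, SimulationTruth]:
    """Model-level generator: detection/effort matrices straight from the model.

    Covariates are drawn as h, w ~ Beta(2,2) and imperviousness v ~ Beta(1.2, 8)
    (mostly-rural with a few heavily built polygons); ecoregions are uniform.
    Every population is treated as known present in the first modeled year, so
    the marginal likelihood fitted later is exactly the generating law.
    """
    truth_spec = truth_spec or TruthSpec()
    rng = np.random.default_rng(seed)
    years = np.arange(year_range[0], year_range[1] + 1)
    T = len(years)
    N = truth_spec.n_populations
    params = truth_spec.params
    R = params.n_ecoregions

    eco = rng.integers(0, R, size=N)
    hwv = np.column_stack(
        [rng.beta(2.0, 2.0, N), rng.beta(2.0, 2.0, N), rng.beta(1.2, 8.0, N)]
    )
    lam = _effort_rates(truth_spec, years)
    e_raw = rng.poisson(lam[None, :], size=(N, T))
    sd = e_raw.std()
    e = (e_raw - e_raw.mean()) / sd if sd > 0 else e_raw.astype(float)

    phi = invlogit(params.alpha[eco] + params.beta_hs * hwv[:, 0] + params.beta_rain * hwv[:, 1] + params.beta_imp * hwv[:, 2])
    tau = sample_extirpation_years(phi, T, rng)
    tref = float(t_ref if t_ref is not None else (years[0] + years[-1]) // 2)
    p = invlogit(params.gamma0 + params.beta_trend * (years[None, :] - tref) + params.beta_effort * e)
    alive = (np.arange(1, T + 1)[None, :] < tau[:, None])
    y = ((rng.random((N, T)) < p) & alive).astype(np.int8)

    last = np.zeros(N, dtype=np.int64)
    det = y.any(axis=1)
    last[det] = T - np.argmax(y[:, ::-1], axis=1)[det]
    L = np.maximum(last, 1)

    data = ModelData(y, e, L, eco, hwv, years, tref, params.ecoregion_names)
    truth = SimulationTruth(params, eco, hwv, np.empty((N, 0)), tau, e_raw, e, years, tref, seed)
    return data, truth


def _sample_centers(rng: np.random.Generator, landscape: Landscape, n: int, min_sep_m: float) -> np.ndarray:
    """Rejection-sample population centers inside the range, pairwise separated."""
    area = landscape.range_polygon.buffer(-5000.0)
    xmin, ymin, xmax, ymax = area.bounds
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n and tries < 200_000:
        tries += 1
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        if not shapely.contains_xy(area, x, y):
            continue
        ok = True
        for px, py in pts:
            if (px - x) ** 2 + (py - y) ** 2 < min_sep_m**2:
                ok = False
                break
        if ok:
            pts.append((x, y))
    if len(pts) < n:
        raise RuntimeError(f"could only place {len(pts)} of {n} separated population centers")
    return np.array(pts)


def _raster_at(raster: Raster, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xs, ys = raster.cell_centers()
    j = np.clip(((x - raster.x0) / raster.cell).astype(int), 0, raster.ncols - 1)
    i = np.clip((raster.nrows - 1 - (y - raster.y0) / raster.cell).astype(int), 0, raster.nrows - 1)
    return raster.values[i, j]


def _season_date(rng: np.random.Generator, year: int) -> _dt.date:
    """A date in the Nov-Apr activity window of calendar ``year``."""
    days = []
    for month, ndays in ((1, 31), (2, 28), (3, 31), (4, 30), (11, 30), (12, 31)):
        days += [(month, d) for d in range(1, ndays + 1)]
    month, day = days[rng.integers(0, len(days))]
    return _dt.date(year, month, day)


def simulate_records(
    truth_spec: TruthSpec,
    landscape: Landscape,
    year_range: tuple[int, int] = (1950, 2024),
    seed: int = 0,
    t_ref: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Full record-level generator: (target_records, nontarget_records, truth).

    Populations are seeded at separated centers, each anchored by a historical
    record (dated before the first modeled year for ``anchor_pre_start_frac``
    of them, else in the first modeled year), so delineation can recover the
    exact population count after cleaning.  Observer-day events drive both the
    effort stream and, while a population is extant, per-event target
    detections at the model's detection probability.
    """
    rng = np.random.default_rng(seed)
    proj = landscape.projection
    years = np.arange(year_range[0], year_range[1] + 1)
    T = len(years)
    params = truth_spec.params
    N = truth_spec.n_populations
    tref = float(t_ref if t_ref is not None else (years[0] + years[-1]) // 2)

    centers = _sample_centers(rng, landscape, N, truth_spec.min_separation_km * 1000.0)
    cx, cy = centers[:, 0], centers[:, 1]
    h = _raster_at(landscape.suitability, cx, cy)
    v = _raster_at(landscape.imperviousness, cx, cy)
    from .rasters import winter_precip_mean

    wyears = sorted({y for (y, m) in landscape.monthly_precip if m != 12})
    wmean = winter_precip_mean(landscape.monthly_precip, (min(wyears), max(wyears)))
    w = _raster_at(scale_01(wmean), cx, cy)
    hwv = np.column_stack([h, w, v])

    eco = np.zeros(N, dtype=np.int64)
    eco_names = tuple(name for name, _ in landscape.ecoregions)
    for i in range(N):
        for r, (_, poly) in enumerate(landscape.ecoregions):
            if shapely.contains_xy(poly, cx[i], cy[i]):
                eco[i] = r
                break
    state_of_pop = np.empty(N, dtype=object)
    for i in range(N):
        state_of_pop[i] = next(
            (code for code, poly in landscape.states if shapely.contains_xy(poly, cx[i], cy[i])), "FL"
        )

    phi = invlogit(params.alpha[eco % params.n_ecoregions] + params.beta_hs * h + params.beta_rain * w + params.beta_imp * v)
    tau = sample_extirpation_years(phi, T, rng)
    lam = _effort_rates(truth_spec, years)
    e_raw = rng.poisson(lam[None, :], size=(N, T))
    sd = e_raw.std()
    e_scaled = (e_raw - e_raw.mean()) / sd if sd > 0 else e_raw.astype(float)
    p_det = invlogit(params.gamma0 + params.beta_trend * (years[None, :] - tref) + params.beta_effort * e_scaled)

    observers = [f"obs{k:03d}" for k in range(40)]
    sources = ["gbif", "inat", "herpmapper", "museum", "survey"]
    species_names = list(EFFORT_SPECIES)

    def uncertainty(missing_frac: float, large_frac: float) -> float:
        u = rng.random()
        if u < missing_frac:
            return np.nan
        if u < missing_frac + large_frac:
            return float(rng.uniform(5_500.0, 20_000.0))
        return float(min(np.exp(rng.normal(np.log(150.0), 1.0)), 4_900.0))

    def jitter(i: int, unc: float) -> tuple[float, float]:
        r = rng.uniform(0.0, min(truth_spec.jitter_max_m, unc if np.isfinite(unc) else 300.0))
        th = rng.uniform(0.0, 2.0 * np.pi)
        lon, lat = proj.inverse(cx[i] + r * np.cos(th), cy[i] + r * np.sin(th))
        return float(lon), float(lat)

    target_rows: list[dict] = []
    nontarget_rows: list[dict] = []
    rid = 0

    def new_id() -> str:
        nonlocal rid
        rid += 1
        return f"s{rid:07d}"

    # anchors: every population known historically
    for i in range(N):
        if rng.random() < truth_spec.anchor_pre_start_frac:
            yr = int(rng.integers(1836, years[0]))
        else:
            yr = int(years[0])
        lon, lat = proj.inverse(cx[i], cy[i])
        target_rows.append(
            {
                "record_id": new_id(),
                "species": TARGET_SPECIES,
                "event_date": _dt.date(yr, int(rng.integers(1, 5)), int(rng.integers(1, 28))),
                "lon": float(lon),
                "lat": float(lat),
                "coord_uncertainty_m": 100.0,
                "observer": "museum",
                "source": "museum",
                "state": state_of_pop[i],
            }
        )

    for i in range(N):
        for tdx, yr in enumerate(years):
            for _ in range(int(e_raw[i, tdx])):
                obs = observers[rng.integers(0, len(observers))]
                src = sources[rng.integers(0, len(sources))]
                date = _season_date(rng, int(yr))
                alive = (tdx + 1) < tau[i]
                detected = alive and (rng.random() < p_det[i, tdx])
                if detected:
                    unc = uncertainty(truth_spec.missing_uncertainty_frac, truth_spec.large_uncertainty_frac)
                    lon, lat = jitter(i, unc)
                    target_rows.append(
                        {
                            "record_id": new_id(),
                            "species": TARGET_SPECIES,
                            "event_date": date,
                            "lon": lon,
                            "lat": lat,
                            "coord_uncertainty_m": unc,
                            "observer": obs,
                            "source": src,
                            "state": state_of_pop[i],
                        }
                    )
                # every event also reports 1-2 non-target species; the event's
                # records share one reported location (same checklist), which
                # is what the per-observer-day deduplication keys on
                unc = float(min(np.exp(rng.normal(np.log(150.0), 1.0)), 2_400.0))
                if rng.random() < 0.15:
                    unc = np.nan
                elif rng.random() < 0.05:
                    unc = float(rng.uniform(2_600.0, 10_000.0))
                lon, lat = jitter(i, unc)
                for _ in range(int(rng.integers(1, 3))):
                    sp = species_names[rng.integers(0, len(species_names))]
                    allowed = EFFORT_SPECIES[sp]
                    if allowed != "all" and state_of_pop[i] not in allowed and rng.random() > 0.05:
                        sp = "Pseudacris crucifer"
                    nontarget_rows.append(
                        {
                            "record_id": new_id(),
                            "species": sp,
                            "event_date": date,
                            "lon": lon,
                            "lat": lat,
                            "coord_uncertainty_m": unc,
                            "observer": obs,
                            "source": src,
                            "state": state_of_pop[i],
                        }
                    )

    target = pd.DataFrame(target_rows)
    # injected duplicates: same day, coordinates nudged < 10 m, another source
    n_dup = int(np.ceil(truth_spec.duplicate_frac * len(target)))
    for k in rng.choice(len(target), size=n_dup, replace=False):
        row = dict(target.iloc[int(k)])
        row["record_id"] = new_id()
        row["lon"] = row["lon"] + float(rng.uniform(-3e-5, 3e-5))
        row["source"] = "duplicate-db"
        target_rows.append(row)
    # out-of-range decoys: > 10 km outside the range polygon
    n_decoy = int(np.ceil(truth_spec.decoy_frac * len(target)))
    ring = box(*landscape.bounds).difference(landscape.range_polygon.buffer(12_000.0))
    bxmin, bymin, bxmax, bymax = ring.bounds
    made = 0
    while made < n_decoy:
        x = rng.uniform(bxmin, bxmax)
        yv = rng.uniform(bymin, bymax)
        if not shapely.contains_xy(ring, x, yv):
            continue
        lon, lat = proj.inverse(x, yv)
        target_rows.append(
            {
                "record_id": new_id(),
                "species": TARGET_SPECIES,
                "event_date": _season_date(rng, int(rng.integers(years[0], years[-1] + 1))),
                "lon": float(lon),
                "lat": float(lat),
                "coord_uncertainty_m": 200.0,
                "observer": "decoy",
                "source": "gbif",
                "state": np.nan,
            }
        )
        made += 1

    target = pd.DataFrame(target_rows).reset_index(drop=True)
    nontarget = pd.DataFrame(nontarget_rows).reset_index(drop=True)
    truth = SimulationTruth(
        Params(params.alpha, params.beta_hs, params.beta_rain, params.beta_imp,
               params.gamma0, params.beta_trend, params.beta_effort, eco_names),
        eco, hwv, centers, tau, e_raw, e_scaled, years, tref, seed,
    )
    return target, nontarget, truth


# ------------------------------------------------------------------ fixtures

FIXTURES = {
    "tiny": dict(n_populations=12, seed=101, cell_km=4.0, extent=(-83.5, 30.0, -80.5, 32.5), effort_log_rate=(-4.2, 0.06)),
    "full-scale": dict(n_populations=400, seed=202, cell_km=2.0, extent=(-85.0, 29.5, -78.5, 34.5), effort_log_rate=(-6.05, 0.08)),
}


def fixture_bundle(name: str, outdir: str | Path | None = None, seed: int | None = None):
    """Deterministic packaged dataset for tests and docs.

    ``"tiny"`` (12 populations) regenerates byte-identically from its seed;
    ``"full-scale"`` mirrors the study's size (~400 populations, 1950-2024).
    Returns ``(landscape, target_records, nontarget_records, truth)`` and, if
    ``outdir`` is given, writes the record CSVs, rasters, polygon layers and
    truth JSON there.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    cfg = dict(FIXTURES[name])
    default_seed = cfg.pop("seed")
    base_seed = default_seed if seed is None else seed
    n_pop = cfg.pop("n_populations")
    effort = cfg.pop("effort_log_rate")
    landscape = simulate_landscape(seed=base_seed, **cfg)
    spec = TruthSpec(n_populations=n_pop, effort_log_rate=effort)
    target, nontarget, truth = simulate_records(spec, landscape, seed=base_seed + 1)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for df, fname in ((target, "target_records.csv"), (nontarget, "nontarget_records.csv")):
            df.to_csv(out / fname, index=False)
        landscape.suitability.write_ascii(out / "suitability.asc")
        landscape.imperviousness.write_ascii(out / "imperviousness.asc")
        from .populations import write_geojson_layers
        from .records import unproject_geometry

        for layers, fname in (
            (landscape.ecoregions, "ecoregions.geojson"),
            (landscape.states, "states.geojson"),
            (landscape.protected, "protected.geojson"),
            ([("range", landscape.range_polygon)], "range.geojson"),
        ):
            write_geojson_layers(out / fname, [(n, unproject_geometry(g, landscape.projection)) for n, g in layers])
        truth.to_json(out / "truth.json")
    return landscape, target, nontarget, truth
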