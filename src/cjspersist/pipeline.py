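"""End-to-end pipeline driver: clean -> delineate -> covariates -> histories
-> model -> report, plus the buffer-size sensitivity rerun.

A run is configured by a plain dict (usually loaded from YAML), validated up
front, and fully determined by its seed: rerunning the same config writes
byte-identical tables.  Inputs come either from on-disk files (CSV records,
ASCII-grid rasters, GeoJSON layers) or from a named synthetic fixture.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import shapely

from . import histories as hist
from . import records as rec
from .likelihood import ModelData
from .mcmc import ModelSpec, PosteriorDraws, gelman_rubin, posterior_predictive_check, run_mcmc, summarize_posterior
from .populations import (
    PopulationSet,
    assign_ecoregion,
    assign_protected,
    covariate_correlations,
    delineate_populations,
    read_geojson_layers,
    zonal_mean,
)
from .rasters import Raster, scale_01, winter_precip_mean
from .records import ConfigurationError
from .reporting import categorize, persistence_vs_last_obs, summarize_groups, welch_t
from .simulate import EFFORT_SPECIES, TARGET_SPECIES, fixture_bundle

log = logging.getLogger("cjspersist")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "run",
    "fixture": None,  # name of a synthetic fixture, or None when inputs given
    "inputs": {},  # target_csv, nontarget_csv, suitability_asc, imperviousness_asc,
    #               range_geojson, ecoregions_geojson, states_geojson, protected_geojson
    "buffer_km": 2.5,
    "year_range": [1950, 2024],
    "t_ref": 1987,
    "range_tolerance_km": 10.0,
    "target_max_uncertainty_m": 5000.0,
    "effort_max_uncertainty_m": 2500.0,
    "season": [[11, 1], [4, 30]],
    "effort_scaling": "zscore",
    "target_species": TARGET_SPECIES,
    "effort_species": None,  # mapping species -> "all" | [states]; default set used if None
    "mcmc": {"chains": 3, "iterations": 100_000, "burn_in": 50_000, "thin": 3, "prior_sd": 10.0},
    "ppc_windows": [[1970, 1974], [2000, 2004], [2020, 2024]],
}


def resolve_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Merge with defaults and validate; fails before any compute."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in config.items():
        if k not in cfg:
            raise ConfigurationError(f"unknown config key {k!r}")
        if isinstance(cfg[k], dict) and isinstance(v, Mapping):
            cfg[k].update(v)
        else:
            cfg[k] = v
    if cfg["fixture"] is None:
        required = ["target_csv", "nontarget_csv", "suitability_asc", "imperviousness_asc", "range_geojson", "ecoregions_geojson"]
        missing = [k for k in required if k not in cfg["inputs"]]
        if missing:
            raise ConfigurationError(f"config.inputs missing {missing} (or set a fixture)")
    if cfg["buffer_km"] <= 0:
        raise ConfigurationError("buffer_km must be positive")
    y0, y1 = cfg["year_range"]
    if y1 <= y0:
        raise ConfigurationError("year_range end must exceed start")
    return cfg


@dataclass
class PipelineResult:
    outdir: Path
    populations: PopulationSet
    detection: hist.DetectionMatrix
    effort: hist.EffortMatrix
    draws: PosteriorDraws
    persistence: pd.DataFrame
    summaries: dict[str, pd.DataFrame] = field(default_factory=dict)


def _load_inputs(cfg: dict[str, Any]):
    """Return (target_df, nontarget_df, rasters+layers dict)."""
    if cfg["fixture"] is not None:
        landscape, target, nontarget, truth = fixture_bundle(cfg["fixture"], seed=cfg["seed"])
        wyears = sorted({y for (y, m) in landscape.monthly_precip if m != 12})
        from .records import unproject_geometry

        unproj = lambda g: unproject_geometry(g, landscape.projection)
        layers = {
            "suitability": landscape.suitability,
            "imperviousness": landscape.imperviousness,
            "monthly_precip": landscape.monthly_precip,
            "precip_years": (min(wyears), max(wyears)),
            "range": unproj(landscape.range_polygon),
            "ecoregions": [(n, g) for n, g in landscape.ecoregions],  # already projected
            "ecoregions_projected": True,
            "states": [(n, unproj(g)) for n, g in landscape.states],
            "protected": [(n, g) for n, g in landscape.protected],
            "protected_projected": True,
            "truth": truth,
        }
        return target, nontarget, layers

    inp = cfg["inputs"]
    target, terr = rec.read_records(inp["target_csv"])
    nontarget, nerr = rec.read_records(inp["nontarget_csv"])
    if len(terr) or len(nerr):
        log.warning("malformed rows: %d target, %d non-target", len(terr), len(nerr))
    layers = {
        "suitability": Raster.read_ascii(inp["suitability_asc"]),
        "imperviousness": Raster.read_ascii(inp["imperviousness_asc"]),
        "monthly_precip": None,
        "precip_asc": inp.get("winter_precip_asc"),
        "range": read_geojson_layers(inp["range_geojson"])[0][1],
        "ecoregions": read_geojson_layers(inp["ecoregions_geojson"]),
        "ecoregions_projected": False,
        "states": read_geojson_layers(inp["states_geojson"]) if "states_geojson" in inp else [],
        "protected": read_geojson_layers(inp["protected_geojson"]) if "protected_geojson" in inp else [],
        "protected_projected": False,
        "truth": None,
    }
    return target, nontarget, layers


def clean_target(target: pd.DataFrame, range_polygon, cfg: dict[str, Any], report: rec.CleaningReport) -> pd.DataFrame:
    """Range tolerance, uncertainty threshold (missing retained), duplicate collapse."""
    df = target[target["species"] == cfg["target_species"]].reset_index(drop=True)
    df = rec.filter_range(df, range_polygon, cfg["range_tolerance_km"], report=report)
    df = rec.filter_uncertainty(df, cfg["target_max_uncertainty_m"], drop_missing=False, report=report)
    df = rec.dedup_target(df, report=report)
    return df


def clean_effort(
    nontarget: pd.DataFrame,
    cleaned_target: pd.DataFrame,
    cfg: dict[str, Any],
    report: rec.CleaningReport,
    state_polygons=None,
) -> pd.DataFrame:
    """Season window, strict uncertainty, species-region rules, effort dedup.

    Target detections are appended (a detection is itself a search event)
    before the per-observer-day deduplication.
    """
    season = cfg["season"]
    df = rec.filter_season(nontarget, tuple(season[0]), tuple(season[1]), report=report)
    df = rec.filter_uncertainty(df, cfg["effort_max_uncertainty_m"], drop_missing=True, report=report)
    species_map = cfg["effort_species"] if cfg["effort_species"] is not None else EFFORT_SPECIES
    df = rec.filter_nontarget_species(df, species_map, state_polygons, report=report)
    combined = pd.concat([df, cleaned_target], ignore_index=True)
    return rec.dedup_effort(combined, report=report)


def build_populations(cleaned_target: pd.DataFrame, layers: dict, cfg: dict[str, Any]) -> PopulationSet:
    pops = delineate_populations(cleaned_target, cfg["buffer_km"])
    if len(pops) == 0:
        raise ConfigurationError("no populations after cleaning")
    assign_ecoregion(pops, layers["ecoregions"], projected=layers["ecoregions_projected"])
    if layers["protected"]:
        assign_protected(pops, layers["protected"], projected=layers["protected_projected"])
    else:
        pops.table["protected_category"] = "none"
    # state of a population = state polygon containing its centroid
    if layers["states"]:
        from .populations import _assign_by_centroid
        from .records import project_geometry

        st = [(n, project_geometry(g, pops.projection)) for n, g in layers["states"]]
        labels, _ = _assign_by_centroid(pops, st, fallback_nearest=True)
        pops.table["state"] = labels
    else:
        pops.table["state"] = "NA"

    zonal_mean(pops, layers["suitability"], column="h")
    if layers["monthly_precip"] is not None:
        wmean = winter_precip_mean(layers["monthly_precip"], layers["precip_years"])
        zonal_mean(pops, scale_01(wmean), column="w")
    elif layers.get("precip_asc"):
        zonal_mean(pops, scale_01(Raster.read_ascii(layers["precip_asc"])), column="w")
    else:
        raise ConfigurationError("no winter precipitation input available")
    zonal_mean(pops, layers["imperviousness"], column="v")
    for c in ("h", "w", "v"):
        pops.table[c] = pops.table[c].clip(0.0, 1.0)
    return pops


def fit_model(
    pops: PopulationSet,
    det: hist.DetectionMatrix,
    eff: hist.EffortMatrix,
    cfg: dict[str, Any],
) -> tuple[ModelData, PosteriorDraws]:
    data = ModelData.from_matrices(
        det, eff, list(pops.table["ecoregion"]), pops.table[["h", "w", "v"]].to_numpy(), t_ref=cfg["t_ref"]
    )
    m = cfg["mcmc"]
    spec = ModelSpec(
        year_range=tuple(cfg["year_range"]),
        t_ref=cfg["t_ref"],
        chains=m["chains"],
        iterations=m["iterations"],
        burn_in=m["burn_in"],
        thin=m["thin"],
        prior_sd=m["prior_sd"],
        seed=cfg["seed"],
    )
    draws = run_mcmc(spec, data, pop_ids=det.pop_ids)
    return data, draws


def run_pipeline(config: Mapping[str, Any]) -> PipelineResult:
    """Execute the full analysis; every artifact lands under config['outdir']."""
    cfg = resolve_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    try:
        (outdir / "config.json").write_text(json.dumps(cfg, indent=2, default=str))
        log.info("stage: load")
        target, nontarget, layers = _load_inputs(cfg)

        log.info("stage: clean")
        report = rec.CleaningReport()
        cleaned = clean_target(target, layers["range"], cfg, report)
        state_polys = {n: g for n, g in layers["states"]}
        effort_events = clean_effort(nontarget, cleaned, cfg, report, state_polys)
        report.write_csv(outdir / "cleaning_report.csv")
        cleaned.to_csv(outdir / "cleaned_target_records.csv", index=False)
        effort_events.to_csv(outdir / "effort_events.csv", index=False)

        log.info("stage: delineate (%d cleaned records)", len(cleaned))
        pops = build_populations(cleaned, layers, cfg)
        pops.write(outdir / "populations.geojson", outdir / "populations.csv")
        corr = covariate_correlations(pops)
        corr.to_csv(outdir / "covariate_correlations.csv")

        log.info("stage: histories (%d populations)", len(pops))
        year_range = tuple(cfg["year_range"])
        det = hist.build_detection_matrix(cleaned, pops, year_range)
        eff = hist.build_effort_matrix(effort_events, pops, year_range, scaling=cfg["effort_scaling"])
        det.write(outdir / "detection_matrix.csv", outdir / "detection_meta.json")
        eff.write(outdir / "effort_matrix.csv", outdir / "effort_meta.json")

        log.info("stage: fit")
        data, draws = fit_model(pops, det, eff, cfg)
        param_summary = summarize_posterior(draws)
        rhat, degenerate = gelman_rubin(draws.thetas)
        param_summary.loc[: len(draws.param_names) - 1, "rhat"] = rhat
        param_summary.to_csv(outdir / "parameter_summary.csv", index=False)
        ppc = posterior_predictive_check(draws, data, windows=tuple(tuple(w) for w in cfg["ppc_windows"]))
        ppc.to_csv(outdir / "posterior_predictive.csv", index=False)
        flat = draws.flat()
        pd.DataFrame(flat, columns=draws.param_names).to_csv(outdir / "posterior_draws.csv", index=False)

        log.info("stage: report")
        persistence = draws.persistence_table()
        attrs = pops.attributes_frame()[["pop_id", "state", "ecoregion", "protected_category", "h", "w", "v", "area_km2", "n_records"]]
        persistence = persistence.merge(attrs, on="pop_id")
        persistence.to_csv(outdir / "persistence.csv", index=False)

        summaries = {}
        for grouping in ("state", "ecoregion", "protected_category", "protected_binary"):
            s = summarize_groups(persistence, grouping)
            s.to_csv(outdir / f"summary_by_{grouping}.csv", index=False)
            summaries[grouping] = s
        counts = categorize(persistence["persistence_mean"].to_numpy())
        pd.DataFrame({"bin": ["[0,0.25)", "[0.25,0.5)", "[0.5,0.75)", "[0.75,0.9)", "[0.9,1]"], "count": counts}).to_csv(
            outdir / "persistence_categories.csv", index=False
        )
        prot = persistence[persistence["protected_category"].ne("none")]["persistence_mean"]
        unprot = persistence[persistence["protected_category"].eq("none")]["persistence_mean"]
        extras = {
            "n_populations": len(pops),
            "mean_persistence": float(persistence["persistence_mean"].mean()),
            "sd_persistence": float(persistence["persistence_mean"].std(ddof=1)),
            "pearson_r_last_obs": persistence_vs_last_obs(persistence, det),
            "max_rhat": float(np.nanmax(rhat)),
            "seed": cfg["seed"],
        }
        if len(prot) >= 2 and len(unprot) >= 2:
            t, df_, p = welch_t(prot, unprot)
            extras.update({"welch_t_protected": t, "welch_df_protected": df_, "welch_p_protected": p})
        (outdir / "run_summary.json").write_text(json.dumps(extras, indent=2))
        log.info("done: %s", json.dumps(extras))
        return PipelineResult(outdir, pops, det, eff, draws, persistence, summaries)
    finally:
        log.removeHandler(fh)
        fh.close()


def sensitivity_run(config: Mapping[str, Any], buffer_list=(1.0, 2.5, 5.0)) -> pd.DataFrame:
    """Re-run delineation -> histories -> model per buffer radius.

    Cleaning happens once; each buffer re-delineates and re-fits.  The
    comparison table reports population counts, coefficient posterior
    intervals per buffer, and the Spearman rank correlation of record-level
    persistence between consecutive buffers (records inherit their
    population's persistence mean, giving a common index across buffers).
    """
    cfg = resolve_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    target, nontarget, layers = _load_inputs(cfg)
    report = rec.CleaningReport()
    cleaned = clean_target(target, layers["range"], cfg, report)
    state_polys = {n: g for n, g in layers["states"]}
    effort_events = clean_effort(nontarget, cleaned, cfg, report, state_polys)

    rows = []
    record_persist: dict[float, pd.Series] = {}
    for buffer_km in buffer_list:
        sub = dict(cfg)
        sub["buffer_km"] = float(buffer_km)
        pops = build_populations(cleaned, layers, sub)
        det = hist.build_detection_matrix(cleaned, pops, tuple(cfg["year_range"]))
        eff = hist.build_effort_matrix(effort_events, pops, tuple(cfg["year_range"]), scaling=cfg["effort_scaling"])
        data, draws = fit_model(pops, det, eff, sub)
        summary = summarize_posterior(draws).set_index("parameter")
        persistence = draws.persistence_table().set_index("pop_id")["persistence_mean"]
        record_persist[buffer_km] = pops.membership.map(persistence)
        for name in ("beta_hs", "beta_rain", "beta_imp", "beta_trend", "beta_effort"):
            s = summary.loc[name]
            rows.append(
                {
                    "buffer_km": buffer_km,
                    "n_populations": len(pops),
                    "parameter": name,
                    "mean": s["mean"],
                    "q2.5": s["q2.5"],
                    "q97.5": s["q97.5"],
                    "sign": int(np.sign(s["mean"])),
                }
            )
    out = pd.DataFrame(rows)
    buffers = list(buffer_list)
    from scipy.stats import spearmanr

    for a, b in zip(buffers[:-1], buffers[1:]):
        common = record_persist[a].index.intersection(record_persist[b].index)
        rho = spearmanr(record_persist[a].loc[common], record_persist[b].loc[common]).statistic
        out.loc[out.index[-1] + 1] = {
            "buffer_km": f"{a}vs{b}",
            "n_populations": len(common),
            "parameter": "record_persistence_spearman",
            "mean": float(rho),
            "q2.5": np.nan,
            "q97.5": np.nan,
            "sign": int(np.sign(rho)) if np.isfinite(rho) else 0,
        }
    out.to_csv(outdir / "sensitivity.csv", index=False)
    return out
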