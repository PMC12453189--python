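"""Shared state for the numbered analysis scripts.

Each script re-derives (deterministically) what it needs from the full-scale
synthetic dataset; the expensive model fit is cached under scratch/analysis/ so
later scripts can reuse it.  All published tables land in results/.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis"
SEED = 202  # the full-scale fixture's default seed

MCMC = {"chains": 3, "iterations": 100_000, "burn_in": 50_000, "thin": 3, "prior_sd": 10.0}


def ensure_dirs() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)


def get_bundle():
    from cjspersist.simulate import fixture_bundle

    return fixture_bundle("full-scale")


def get_cleaned(bundle=None):
    import cjspersist as cp
    from cjspersist.pipeline import clean_effort, clean_target, resolve_config
    from cjspersist.records import CleaningReport, unproject_geometry

    landscape, target, nontarget, truth = bundle or get_bundle()
    cfg = resolve_config({"fixture": "full-scale", "seed": SEED})
    report = CleaningReport()
    cleaned = clean_target(target, unproject_geometry(landscape.range_polygon), cfg, report)
    states = {n: unproject_geometry(g, landscape.projection) for n, g in landscape.states}
    events = clean_effort(nontarget, cleaned, cfg, report, states)
    return cleaned, events, report, cfg


def get_run():
    """Full pipeline result, cached across scripts."""
    ensure_dirs()
    cache = SCRATCH / "full_run.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    from cjspersist.pipeline import run_pipeline

    res = run_pipeline({"seed": SEED, "outdir": str(SCRATCH / "full_run"), "fixture": "full-scale", "mcmc": MCMC})
    with open(cache, "wb") as fh:
        pickle.dump(res, fh)
    return res
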