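"""Post-model summaries: group tables, persistence categories, comparisons.

Persistence posteriors are summarized per state, ecoregion, and protected-area
category (mean, SD, n, and the proportion of populations below/above the
conventional thresholds), binned into the map-legend categories, compared
between protected and unprotected land with Welch's unequal-variance t-test,
and correlated with the year of last observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .histories import DetectionMatrix
from .records import ConfigurationError

#: persistence thresholds reported per group; "below" thresholds are strict
#: (< 0.25, < 0.5), "above" thresholds are strict too (> 0.75, > 0.9)
THRESHOLDS_BELOW = (0.25, 0.5)
THRESHOLDS_ABOVE = (0.75, 0.9)
DEFAULT_BIN_EDGES = (0.0, 0.25, 0.5, 0.75, 0.9, 1.0)


def summarize_groups(persistence_table: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Per-group persistence summary.

    ``persistence_table`` needs a ``persistence_mean`` column and the grouping
    column (``state``, ``ecoregion``, ``protected_category``, or
    ``protected_binary`` derived from ``protected_category != "none"``).
    Empty groups (all-NaN labels) are reported with n = 0.
    """
    df = persistence_table.copy()
    if grouping == "protected_binary":
        df["protected_binary"] = np.where(df["protected_category"].ne("none"), "protected", "unprotected")
    if grouping not in df.columns:
        raise ConfigurationError(f"grouping column {grouping!r} not present")
    rows = []
    for name, grp in df.groupby(grouping, dropna=False):
        x = grp["persistence_mean"].to_numpy()
        row = {
            grouping: name,
            "n": len(x),
            "mean": float(x.mean()) if len(x) else np.nan,
            "sd": float(x.std(ddof=1)) if len(x) > 1 else np.nan,
        }
        for thr in THRESHOLDS_BELOW:
            row[f"prop_lt_{thr}"] = float((x < thr).mean()) if len(x) else np.nan
        for thr in THRESHOLDS_ABOVE:
            row[f"prop_gt_{thr}"] = float((x > thr).mean()) if len(x) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).sort_values(grouping).reset_index(drop=True)


def categorize(values, bin_edges=DEFAULT_BIN_EDGES) -> np.ndarray:
    """Histogram counts of persistence values in the legend categories.

    Edges must strictly increase and cover [0, 1]; bins are left-closed with
    the final bin closed on both ends, so counts always sum to n.  Values
    outside [0, 1] raise.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0) or edges[0] > 0 or edges[-1] < 1:
        raise ConfigurationError("bin edges must strictly increase and cover [0, 1]")
    x = np.asarray(values, dtype=float)
    if x.size and (x.min() < 0 or x.max() > 1):
        raise ValueError("persistence values outside [0, 1]")
    counts, _ = np.histogram(x, bins=edges)
    return counts


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test: (t, df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ConfigurationError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def persistence_vs_last_obs(persistence_table: pd.DataFrame, det: DetectionMatrix) -> float:
    """Pearson correlation between persistence mean and last detection year.

    Populations never detected in-window use the year before the modeled span
    (their presence is anchored there).  Constant last-observation years make
    the correlation undefined (returns NaN).
    """
    last = pd.Series(det.last_detection_year, index=det.pop_ids).replace(-1, det.years[0] - 1)
    df = persistence_table.set_index("pop_id")
    aligned = last.loc[df.index]
    if aligned.nunique() < 2:
        return float("nan")
    r, _ = stats.pearsonr(df["persistence_mean"], aligned)
    return float(r)
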