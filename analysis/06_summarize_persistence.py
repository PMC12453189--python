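"""Summarize per-population persistence posteriors.

Range-wide mean/SD and category histogram, per-state / per-ecoregion /
per-protected-category tables, the protected-vs-unprotected Welch comparison,
and the correlation between persistence and the year of last observation.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, ensure_dirs, get_run

import cjspersist as cp


def main() -> None:
    ensure_dirs()
    res = get_run()
    pers = res.persistence
    pm = pers["persistence_mean"]

    print(f"{len(pers)} populations; mean persistence in 2024 = {pm.mean():.2f} (SD {pm.std(ddof=1):.2f})")
    counts = cp.categorize(pm.to_numpy())
    bins = ["<0.25", "0.25-0.5", "0.5-0.75", "0.75-0.9", ">0.9"]
    hist = pd.DataFrame({"category": bins, "n_populations": counts})
    hist.to_csv(RESULTS / "persistence_categories.csv", index=False)
    print(hist.to_string(index=False))
    print(f"possibly extirpated (<0.5): {(pm < 0.5).mean():.1%}; likely persisting (>0.9): {(pm > 0.9).mean():.1%}")

    for grouping in ("state", "ecoregion", "protected_category", "protected_binary"):
        tab = cp.summarize_groups(pers, grouping)
        tab.to_csv(RESULTS / f"summary_by_{grouping}.csv", index=False)
        print(f"\nby {grouping}:")
        print(tab.round(3).to_string(index=False))

    prot = pers.loc[pers["protected_category"].ne("none"), "persistence_mean"]
    unprot = pers.loc[pers["protected_category"].eq("none"), "persistence_mean"]
    t, df, p = cp.welch_t(prot, unprot)
    print(f"\nWelch t (protected vs unprotected): t = {t:.2f}, df = {df:.0f}, p = {p:.3g}")
    r = cp.persistence_vs_last_obs(pers, res.detection)
    print(f"Pearson r (persistence vs year of last observation): {r:.2f}")
    pd.DataFrame(
        [{"welch_t": t, "welch_df": df, "welch_p": p, "pearson_r_last_obs": r}]
    ).to_csv(RESULTS / "comparisons.csv", index=False)


if __name__ == "__main__":
    main()
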