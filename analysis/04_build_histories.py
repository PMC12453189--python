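"""Build the population x year detection and search-effort matrices.

Also reports the effort-species co-occurrence fractions (the statistic used
to justify which non-target species index search effort).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SCRATCH, ensure_dirs, get_bundle, get_cleaned

import cjspersist as cp
from cjspersist.simulate import TARGET_SPECIES


def main() -> None:
    ensure_dirs()
    bundle = get_bundle()
    cleaned, events, *_ = get_cleaned(bundle)
    pops = cp.delineate_populations(cleaned, 2.5)
    det = cp.build_detection_matrix(cleaned, pops, (1950, 2024))
    eff = cp.build_effort_matrix(events, pops, (1950, 2024))
    det.write(SCRATCH / "detection_matrix.csv", SCRATCH / "detection_meta.json")
    eff.write(SCRATCH / "effort_matrix.csv", SCRATCH / "effort_meta.json")

    detected = det.y.any(axis=1)
    rows = [
        ("populations", det.n_populations),
        ("years modeled", det.n_years),
        ("populations with >= 1 in-window detection", int(detected.sum())),
        ("populations known only before 1950", int((~detected & det.known_before_start).sum())),
        ("total effort events in polygons", int(eff.e_raw.sum())),
        ("population-years with any effort", int((eff.e_raw > 0).sum())),
        ("share of effort on/after 2000", round(float(eff.e_raw[:, 50:].sum() / eff.e_raw.sum()), 3)),
    ]
    summary = pd.DataFrame(rows, columns=["quantity", "value"])
    summary.to_csv(RESULTS / "history_summary.csv", index=False)
    print(summary.to_string(index=False))

    # co-occurrence of candidate effort species with the target at survey events
    nontarget = bundle[2]
    surveys = pd.concat([bundle[1], nontarget], ignore_index=True)
    cooc = cp.cooccurrence_table(surveys, TARGET_SPECIES, coord_decimals=2)
    cooc.to_csv(RESULTS / "cooccurrence.csv", index=False)
    print("\nco-occurrence with the target at survey events:")
    print(cooc.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
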