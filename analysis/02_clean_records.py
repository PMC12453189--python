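"""Apply the record-cleaning rules and report what each rule removed.

Target records: range-polygon tolerance (10 km), location uncertainty
(<= 5 km, missing retained), same-day 10-m duplicate collapse.  Effort
records: Nov-Apr window, uncertainty <= 2.5 km (missing dropped), per-species
state restrictions, one event per (date, coordinates, observer).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, ensure_dirs, get_cleaned


def main() -> None:
    ensure_dirs()
    cleaned, events, report, _ = get_cleaned()
    tab = report.to_frame()
    tab.to_csv(RESULTS / "cleaning_report.csv", index=False)
    print(tab.to_string(index=False))
    print(f"\ncleaned target records: {len(cleaned)}; effort events after dedup: {len(events)}")


if __name__ == "__main__":
    main()
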