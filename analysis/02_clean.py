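#!/usr/bin/env python
"""Clean the synthetic extract: deduplicate case versions, keep reports with
the target drug as primary suspect, strip handling-issue PTs.

Writes the stage-count cleaning report to results/cleaning_report.json.
"""

import json
from pathlib import Path

from pvsignal import load_case_set

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"


def main() -> None:
    if not DATA_DIR.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    target, background, report = load_case_set(DATA_DIR)
    RESULTS.mkdir(exist_ok=True)
    payload = report.as_dict()
    payload["n_background"] = len(background)
    (RESULTS / "cleaning_report.json").write_text(json.dumps(payload, indent=2) + "\n")

    print(f"{report.raw_rows} raw report versions -> {report.after_dedup} unique cases")
    print(f"{report.after_ps_filter} cases with the target drug as primary suspect")
    print(f"{report.after_pt_exclusion} remain after PT exclusions "
          f"({len(report.dropped_no_reaction_primaryids)} dropped with no reactions left)")
    print(f"background: {len(background)} non-target cases")


if __name__ == "__main__":
    main()
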