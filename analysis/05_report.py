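#!/usr/bin/env python
"""Descriptive and stratified reporting.

Tabulates the cleaned target case set (demographics, outcomes, indications,
reporting years, with unknowns kept in every denominator) and computes
sex-stratified disproportionality with a z-test on the log-ROR difference.
Writes demographics.csv and stratified_sex.csv under results/.
"""

from pathlib import Path

from pvsignal import load_case_set, stratify_by_sex, summarize_demographics
from pvsignal.report import stratified_to_frame

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"


def main() -> None:
    if not DATA_DIR.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    target, background, _ = load_case_set(DATA_DIR)
    RESULTS.mkdir(exist_ok=True)

    summary = summarize_demographics(target)
    summary.to_frame().to_csv(RESULTS / "demographics.csv", index=False)
    print(f"{summary.total} target cases")
    for var in ("sex", "age", "reporter"):
        parts = ", ".join(f"{r.category} {r.count} ({r.percent}%)"
                          for r in summary.tables[var].itertuples())
        print(f"  {var}: {parts}")

    # stratify the ten most-reported PTs
    from collections import Counter
    counts = Counter(pt for c in target for pt in set(c.reactions))
    top = [pt for pt, _ in counts.most_common(10)]
    strat = stratify_by_sex(target, background, top)
    frame = stratified_to_frame(strat)
    frame.to_csv(RESULTS / "stratified_sex.csv", index=False)
    print("sex-stratified ROR (top terms):")
    for row in frame.itertuples():
        print(f"  {row.term}: F N={row.female_N} ROR={row.female_ROR} | "
              f"M N={row.male_N} ROR={row.male_ROR} | p={row.p}")


if __name__ == "__main__":
    main()
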