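"""Descriptive reporting and end-to-end pipeline orchestration.

Covers the descriptive summary of a cleaned case set (demographics, serious
outcomes, indications, reporting years — unknowns are first-class categories
and stay in every denominator), sex-stratified disproportionality with a
z-test on the log-ROR difference, the algorithm-overlap tally (how many terms
meet 1/2/3/4 criteria), and ``run_pipeline`` which chains
clean -> contingency -> signals -> onset -> report over a data directory.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as _scipy_stats

from . import defaults
from .contingency import ContingencyTable, build_all, build_table, tables_to_frame
from .ingest import CaseReport, CleaningReport, load_case_set
from .onset import BinScheme, bin_counts, compute_ttos, fit_weibull, growth_rate, ks_test, kruskal_wallis, summarize
from .signals import (
    DegenerateTableError,
    SignalCriteria,
    SignalResult,
    compute_signal,
    compute_signals,
    results_to_frame,
)

Z95 = 1.959963984540054


@dataclass
class DemographicsSummary:
    """Per-variable category counts and percents of the total case count.

    Single-valued variables (sex, age, weight, reporter, country, year) sum
    to the total including the unknown category; outcomes and indications are
    multi-valued per report, so their counts may exceed the total.
    """

    total: int
    tables: dict[str, pd.DataFrame]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for var, df in self.tables.items():
            part = df.copy()
            part.insert(0, "variable", var)
            frames.append(part)
        if not frames:
            return pd.DataFrame(columns=["variable", "category", "count", "percent"])
        return pd.concat(frames, ignore_index=True)


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 1) if total else 0.0


def _table(counts: Mapping[str, int], total: int, order: Sequence[str] | None = None) -> pd.DataFrame:
    keys = list(order) if order is not None else sorted(counts, key=lambda k: (-counts[k], k))
    rows = [(k, counts.get(k, 0), _pct(counts.get(k, 0), total)) for k in keys]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def _age_bin(age: float | None) -> str:
    if age is None:
        return "unknown"
    if age < 18:
        return "<18"
    if age <= 64:
        return "18-64"
    if age <= 85:
        return "65-85"
    return ">=86"


def _weight_bin(wt: float | None) -> str:
    if wt is None:
        return "unknown"
    if wt < 50:
        return "<50"
    if wt <= 100:
        return "50-100"
    return ">100"


def summarize_demographics(cases: Sequence[CaseReport]) -> DemographicsSummary:
    """Tabulate the cleaned case set the way safety papers present Table 1.

    Percentages use the full case count as denominator, so the unknown
    category is included (e.g. 470 female of 1,177 -> 39.9%).
    """
    total = len(cases)
    if total == 0:
        return DemographicsSummary(total=0, tables={})
    counts: dict[str, dict[str, int]] = {
        "sex": {}, "age": {}, "weight": {}, "reporter": {}, "country": {},
        "outcome": {}, "indication": {}, "year": {},
    }

    def bump(var: str, key: str) -> None:
        counts[var][key] = counts[var].get(key, 0) + 1

    for c in cases:
        bump("sex", c.sex)
        bump("age", _age_bin(c.age))
        bump("weight", _weight_bin(c.weight))
        bump("reporter", c.reporter)
        bump("country", c.country)
        if c.outcomes:
            for o in sorted(c.outcomes):
                bump("outcome", o)
        else:
            bump("outcome", "unknown")
        for ind in sorted(set(c.indications)):
            bump("indication", ind)
        year = c.fda_dt[:4] if len(c.fda_dt) >= 4 and c.fda_dt[:4].isdigit() else "unknown"
        bump("year", year)

    tables = {
        "sex": _table(counts["sex"], total, order=[k for k in ("female", "male", "unknown") if k in counts["sex"]]),
        "age": _table(counts["age"], total, order=[k for k in ("<18", "18-64", "65-85", ">=86", "unknown") if k in counts["age"]]),
        "weight": _table(counts["weight"], total, order=[k for k in ("<50", "50-100", ">100", "unknown") if k in counts["weight"]]),
        "reporter": _table(counts["reporter"], total),
        "country": _table(counts["country"], total),
        "outcome": _table(counts["outcome"], total),
        "indication": _table(counts["indication"], total),
        "year": _table(counts["year"], total, order=sorted(counts["year"])),
    }
    return DemographicsSummary(total=total, tables=tables)


# ---------------------------------------------------------------------------
# sex-stratified signals
# ---------------------------------------------------------------------------

@dataclass
class StratifiedSignal:
    term: str
    female: SignalResult | None
    male: SignalResult | None
    z: float | None
    p: float | None
    note: str = ""


def _ln_ror_se(result: SignalResult) -> float:
    return (math.log(result.ror_high) - math.log(result.ror_low)) / (2 * Z95)


def stratify_by_sex(
    case_set: Sequence[CaseReport],
    background_set: Sequence[CaseReport],
    terms: Sequence[str],
    level: str = "PT",
    pt_soc_map: Mapping[str, str] | None = None,
    criteria: SignalCriteria | None = None,
    **signal_kwargs,
) -> list[StratifiedSignal]:
    """Disproportionality per sex stratum with a z-test on the ln-ROR
    difference (pooled standard error from the two log-normal CIs).

    Unknown-sex reports are dropped from both strata. A term with no exposed
    cases, or a degenerate table, in one stratum yields a one-sided record
    with a note.
    """
    out: list[StratifiedSignal] = []
    strata = {
        "female": ([c for c in case_set if c.sex == "female"],
                   [c for c in background_set if c.sex == "female"]),
        "male": ([c for c in case_set if c.sex == "male"],
                 [c for c in background_set if c.sex == "male"]),
    }
    for term in terms:
        results: dict[str, SignalResult | None] = {}
        notes = []
        for name, (tgt, bg) in strata.items():
            table = build_table(tgt, bg, term, level=level, pt_soc_map=pt_soc_map)
            if table.a == 0:
                results[name] = None
                notes.append(f"no {name} cases")
                continue
            try:
                results[name] = compute_signal(table, criteria, **signal_kwargs)
            except DegenerateTableError:
                results[name] = None
                notes.append(f"degenerate {name} table")
        z = p = None
        f, m = results["female"], results["male"]
        if f is not None and m is not None:
            se = math.sqrt(_ln_ror_se(f) ** 2 + _ln_ror_se(m) ** 2)
            z = (math.log(f.ror) - math.log(m.ror)) / se
            p = 2.0 * (1.0 - _scipy_stats.norm.cdf(abs(z)))
        out.append(StratifiedSignal(term=term, female=f, male=m, z=z, p=p,
                                    note="; ".join(notes)))
    return out


def stratified_to_frame(results: Iterable[StratifiedSignal]) -> pd.DataFrame:
    rows = []
    for r in results:
        row: dict = {"term": r.term, "z": None if r.z is None else round(r.z, 3),
                     "p": None if r.p is None else round(r.p, 4), "note": r.note}
        for name, res in (("female", r.female), ("male", r.male)):
            if res is None:
                row[f"{name}_N"] = 0
                row[f"{name}_ROR"] = row[f"{name}_ROR_low"] = row[f"{name}_ROR_high"] = None
                row[f"{name}_classification"] = ""
            else:
                row[f"{name}_N"] = res.n
                row[f"{name}_ROR"] = round(res.ror, 2)
                row[f"{name}_ROR_low"] = round(res.ror_low, 2)
                row[f"{name}_ROR_high"] = round(res.ror_high, 2)
                row[f"{name}_classification"] = res.classification
        rows.append(row)
    return pd.DataFrame(rows)


def criteria_overlap(results: Iterable[SignalResult]) -> dict[str, int]:
    """Venn-style tally: number of terms meeting exactly k criteria and the
    size of each criteria subset."""
    by_k = {k: 0 for k in range(5)}
    subsets: dict[str, int] = {}
    for r in results:
        by_k[len(r.flags)] += 1
        key = "+".join(sorted(r.flags)) or "(none)"
        subsets[key] = subsets.get(key, 0) + 1
    return {
        **{f"exactly_{k}": v for k, v in by_k.items()},
        "all_four": by_k[4],
        "at_least_2": sum(v for k, v in by_k.items() if k >= 2),
        "subsets": subsets,
    }


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def run_pipeline(
    data_dir: str | Path,
    out_dir: str | Path,
    synonyms: Sequence[str] = defaults.TILDRAKIZUMAB_SYNONYMS,
    pt_soc_map: Mapping[str, str] | None = None,
    pt_exclusions: Sequence[str] = defaults.PT_EXCLUSIONS,
    indication_exclusions: Sequence[str] = defaults.INDICATION_EXCLUSIONS,
    levels: Sequence[str] = ("PT", "SOC"),
    criteria: SignalCriteria | None = None,
    min_count: int = 3,
    ic025_mode: str = "noren",
    ebgm_mode: str = "simple",
    bin_scheme: BinScheme | None = None,
    stratify_terms: int = 20,
) -> dict:
    """Clean, count, score, and summarise one data directory.

    Writes delimited tables and a JSON run log under ``out_dir`` and returns
    the run log as a dict. Any stage failure aborts with the stage name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pt_soc_map = dict(pt_soc_map) if pt_soc_map is not None else dict(defaults.PT_SOC_MAP)
    criteria = criteria or SignalCriteria()
    log: dict = {"data_dir": str(data_dir), "outputs": [], "stages": {}}

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        df.to_csv(path, index=False, lineterminator="\n")
        log["outputs"].append(name)

    try:
        target, background, cleaning = load_case_set(
            data_dir, synonyms=synonyms, pt_exclusions=pt_exclusions,
            indication_exclusions=indication_exclusions,
        )
    except Exception as err:  # noqa: BLE001 - stage attribution
        raise PipelineError("ingest", err) from err
    log["stages"]["cleaning"] = cleaning.as_dict()
    log["stages"]["cleaning"]["n_background"] = len(background)

    results_by_level: dict[str, list[SignalResult]] = {}
    try:
        for level in levels:
            meets, below = build_all(target, background, level=level,
                                     pt_soc_map=pt_soc_map, min_count=min_count)
            frame = tables_to_frame(meets + below)
            frame["meets_min_count"] = [t.a >= min_count for t in meets + below]
            _write(frame, f"contingency_{level.lower()}.csv")
            results = compute_signals(meets, criteria, ebgm_mode=ebgm_mode,
                                      ic025_mode=ic025_mode)
            results_by_level[level] = results
            _write(results_to_frame(results), f"signals_{level.lower()}.csv")
            log["stages"][f"signals_{level.lower()}"] = {
                "n_terms_scored": len(results),
                "n_below_min_count": len(below),
                "overlap": criteria_overlap(results),
            }
    except Exception as err:
        raise PipelineError("signals", err) from err

    try:
        records, exclusions = compute_ttos(target, synonyms, pt_soc_map)
        ttos = [r.tto_days for r in records]
        tto_log: dict = {"n_included": len(records), "exclusions": exclusions}
        if ttos:
            tto_log["summary"] = summarize(ttos)
            bins = bin_counts(ttos, bin_scheme)
            bins_frame = pd.DataFrame({
                "bin": [f"month_{i+1}" for i in range(len(bins.monthly))]
                       + [f"quarter_{i+1}" for i in range(len(bins.quarterly))]
                       + ["over_year"],
                "count": bins.monthly + bins.quarterly + [bins.over_year],
            })
            _write(bins_frame, "tto_bins.csv")
            tto_log["quarterly_counts"] = bins.quarterly
            tto_log["quarterly_growth_pct"] = growth_rate(bins.quarterly)
            tto_log["monthly_growth_pct"] = growth_rate(bins.monthly)
            tto_log["over_year"] = bins.over_year
        if len(ttos) >= 10:
            fit = fit_weibull(ttos)
            stat, p = ks_test(ttos, fit)
            tto_log["weibull"] = {
                "shape": round(fit.shape, 4), "shape_ci": [round(x, 4) for x in fit.shape_ci],
                "scale": round(fit.scale, 2), "scale_ci": [round(x, 2) for x in fit.scale_ci],
                "log_likelihood": round(fit.log_likelihood, 2), "n": fit.n,
                "onset_type": fit.onset_type,
                "ks_statistic": round(stat, 4), "ks_p": round(p, 4),
            }
            # per-SOC onset comparison among SOCs with enough records
            by_soc: dict[str, list[int]] = {}
            for rec in records:
                for soc in rec.socs:
                    by_soc.setdefault(soc, []).append(rec.tto_days)
            soc_rows = []
            for soc, vals in sorted(by_soc.items()):
                s = summarize(vals)
                soc_rows.append((soc, s["n"], s["median"], s["q1"], s["q3"]))
            if soc_rows:
                _write(pd.DataFrame(soc_rows, columns=["soc", "n", "median", "q1", "q3"]),
                       "tto_by_soc.csv")
            groups = [v for v in by_soc.values() if len(v) >= 3]
            if len(groups) >= 2:
                h, kw_p = kruskal_wallis(groups)
                tto_log["kruskal_wallis_socs"] = {"H": round(h, 3), "p": round(kw_p, 4),
                                                  "n_groups": len(groups)}
        log["stages"]["tto"] = tto_log
    except Exception as err:
        raise PipelineError("onset", err) from err

    try:
        demo = summarize_demographics(target)
        _write(demo.to_frame(), "demographics.csv")
        log["stages"]["demographics"] = {"total": demo.total}
    except Exception as err:
        raise PipelineError("demographics", err) from err

    try:
        pt_results = results_by_level.get("PT", [])
        top_terms = [r.term for r in sorted(pt_results, key=lambda r: -r.n)[:stratify_terms]]
        strat = stratify_by_sex(target, background, top_terms, level="PT",
                                pt_soc_map=pt_soc_map, criteria=criteria,
                                ic025_mode=ic025_mode)
        _write(stratified_to_frame(strat), "stratified_sex.csv")
        log["stages"]["stratified"] = {"n_terms": len(strat)}
    except Exception as err:
        raise PipelineError("stratified", err) from err

    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, default=str) + "\n")
    log["outputs"].append("run_log.json")
    return log
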