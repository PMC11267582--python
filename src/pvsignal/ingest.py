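"""Reading and cleaning of FAERS-style quarterly extracts.

The cleaning pipeline follows standard spontaneous-report practice:

1. **Deduplication** — a case (CASEID) may be submitted repeatedly; all
   versions share the CASEID but carry distinct PRIMARYIDs and receipt dates
   (FDA_DT). We keep, per CASEID, the version with the latest FDA_DT, ties
   broken by the largest PRIMARYID (a pure max-PRIMARYID rule is available).
   Deduplication is applied across the whole loaded quarter range, since cases
   are resubmitted across quarters.
2. **Target-drug identification** — drug names are matched against a synonym
   list (brand + generic + trial-code variants) case-insensitively after
   whitespace normalisation; matching is exact by default, substring behind a
   flag.
3. **Primary-suspect filter** — only reports where a matching drug carries
   role code PS are retained as the target case set; everything else forms the
   background.
4. **PT / indication exclusions** — administration and handling-issue terms
   (e.g. "Product dose omission issue") are removed from reaction lists, and
   the uninformative indication term from indication lists; cases left with no
   reactions are dropped and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import defaults

#: minimal column contract per table area
MANDATORY_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": ("PRIMARYID", "CASEID", "FDA_DT"),
    "DRUG": ("PRIMARYID", "DRUGNAME", "ROLE_COD"),
    "REAC": ("PRIMARYID", "PT"),
    "THER": ("PRIMARYID", "START_DT"),
    "INDI": ("PRIMARYID", "INDI_PT"),
    "OUTC": ("PRIMARYID", "OUTC_COD"),
    "RPSR": ("PRIMARYID",),
}

_SEX_LABELS = {"F": "female", "M": "male"}
_REPORTER_LABELS = {
    "CN": "consumer", "HP": "health professional", "MD": "physician",
    "PH": "pharmacist", "OT": "other",
}
_OUTCOME_LABELS = {
    "DE": "death", "LT": "life-threatening", "HO": "hospitalization",
    "DS": "disability", "CA": "congenital anomaly", "OT": "other serious",
}
# age-unit conversion to years
_AGE_FACTORS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52, "DY": 1 / 365, "HR": 1 / 8760}


class FormatError(ValueError):
    """A quarterly table violates the expected dialect."""


@dataclass
class DrugEntry:
    name: str
    role: str  # PS / SS / C / I
    therapy_start: str = ""  # YYYYMMDD, partial (YYYYMM/YYYY) or "" missing
    therapy_end: str = ""


@dataclass
class CaseReport:
    """One deduplicated safety report."""

    primaryid: int
    caseid: int
    fda_dt: str
    event_dt: str = ""
    sex: str = "unknown"  # female / male / unknown
    age: float | None = None  # years
    weight: float | None = None  # kg
    reporter: str = "unknown"
    country: str = "unknown"
    outcomes: frozenset[str] = frozenset()
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    indications: list[str] = field(default_factory=list)


@dataclass
class CleaningReport:
    """Row/case counts at each cleaning stage plus dropped identifiers."""

    raw_rows: int = 0
    after_dedup: int = 0
    target_any_role: int = 0
    after_ps_filter: int = 0
    after_pt_exclusion: int = 0
    dropped_duplicate_primaryids: list[int] = field(default_factory=list)
    dropped_no_reaction_primaryids: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "raw_rows": self.raw_rows,
            "after_dedup": self.after_dedup,
            "target_any_role": self.target_any_role,
            "after_ps_filter": self.after_ps_filter,
            "after_pt_exclusion": self.after_pt_exclusion,
            "n_dropped_duplicates": len(self.dropped_duplicate_primaryids),
            "n_dropped_no_reaction": len(self.dropped_no_reaction_primaryids),
        }


def read_quarter(paths: Mapping[str, str | Path]) -> dict[str, pd.DataFrame]:
    """Read one quarter's "$"-delimited tables into string DataFrames.

    Unparseable or partial dates are preserved verbatim (never coerced);
    missing values are empty strings. Raises :class:`FormatError` if a
    mandatory column is absent.
    """
    out: dict[str, pd.DataFrame] = {}
    for area, path in paths.items():
        df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False, engine="python")
        for col in MANDATORY_COLUMNS.get(area, ()):
            if col not in df.columns:
                raise FormatError(f"{path}: missing mandatory column {col} in {area} table")
        out[area] = df
    return out


def discover_quarters(data_dir: str | Path) -> dict[str, dict[str, Path]]:
    """Locate ``AREA_<quarter>.txt`` files under a directory."""
    data_dir = Path(data_dir)
    found: dict[str, dict[str, Path]] = {}
    for path in sorted(data_dir.glob("*_*.txt")):
        stem = path.stem
        area, _, quarter = stem.partition("_")
        if area in MANDATORY_COLUMNS:
            found.setdefault(quarter, {})[area] = path
    if not found:
        raise FormatError(f"no quarterly tables found under {data_dir}")
    return found


def normalize_drug_name(name: str) -> str:
    """Case-fold and collapse internal/surrounding whitespace."""
    return " ".join(str(name).split()).upper()


def match_drug(
    drugname: str,
    synonyms: Sequence[str] = defaults.TILDRAKIZUMAB_SYNONYMS,
    substring: bool = False,
) -> bool:
    """Whether a DRUGNAME value refers to the target drug.

    Exact match against the normalised synonym list by default; with
    ``substring=True``, any synonym occurring inside the name counts.
    """
    if not synonyms:
        raise ValueError("synonym list must be non-empty")
    norm = normalize_drug_name(drugname)
    syn = [normalize_drug_name(s) for s in synonyms]
    if substring:
        return any(s in norm for s in syn)
    return norm in set(syn)


def deduplicate(demo: pd.DataFrame, rule: str = "latest_fda_dt") -> pd.DataFrame:
    """Collapse case versions: one DEMO row per CASEID.

    ``latest_fda_dt`` (default): keep the row with the latest FDA_DT, ties
    broken by largest PRIMARYID. ``max_primaryid``: keep the largest PRIMARYID
    outright. Idempotent and invariant to input row order.
    """
    if rule not in ("latest_fda_dt", "max_primaryid"):
        raise ValueError(f"unknown dedup rule {rule!r}")
    if demo.empty:
        return demo.copy()
    work = demo.copy()
    work["_pid"] = work["PRIMARYID"].astype(np.int64)
    work["_case"] = work["CASEID"].astype(np.int64)
    if rule == "latest_fda_dt":
        work["_fda"] = pd.to_numeric(work["FDA_DT"], errors="coerce").fillna(-1).astype(np.int64)
        keys = ["_case", "_fda", "_pid"]
    else:
        keys = ["_case", "_pid"]
    work = work.sort_values(keys, kind="mergesort")
    kept = work.groupby("_case", sort=True).tail(1)
    return kept.drop(columns=[c for c in ("_pid", "_case", "_fda") if c in kept.columns]).reset_index(drop=True)


def _parse_age_years(age: str, unit: str) -> float | None:
    try:
        value = float(age)
    except (TypeError, ValueError):
        return None
    factor = _AGE_FACTORS.get(unit.strip().upper() or "YR")
    if factor is None:
        return None
    return value * factor


def _parse_weight_kg(wt: str, unit: str) -> float | None:
    try:
        value = float(wt)
    except (TypeError, ValueError):
        return None
    unit = unit.strip().upper() or "KG"
    if unit == "KG":
        return value
    if unit in ("LBS", "LB"):
        return value * 0.453592
    return None


def assemble_cases(tables: Mapping[str, pd.DataFrame]) -> list[CaseReport]:
    """Build :class:`CaseReport` objects from (already deduplicated) tables."""
    demo = tables["DEMO"]
    if demo.empty:
        return []
    pid = demo["PRIMARYID"].astype(np.int64)
    keep = set(pid.tolist())

    def _grouped(area: str, cols: list[str]) -> dict[int, list]:
        df = tables.get(area)
        if df is None or df.empty:
            return {}
        sub = df[df["PRIMARYID"].astype(np.int64).isin(keep)]
        out: dict[int, list] = {}
        for row in sub[["PRIMARYID"] + cols].itertuples(index=False):
            out.setdefault(int(row[0]), []).append(tuple(row[1:]))
        return out

    drug_map = _grouped("DRUG", ["DRUGNAME", "ROLE_COD"])
    reac_map = _grouped("REAC", ["PT"])
    ther_map = _grouped("THER", ["START_DT", "END_DT"] if "END_DT" in tables.get("THER", pd.DataFrame()).columns else ["START_DT"])
    indi_map = _grouped("INDI", ["INDI_PT"])
    outc_map = _grouped("OUTC", ["OUTC_COD"])

    cases: list[CaseReport] = []
    for row in demo.itertuples(index=False):
        rec = dict(zip(demo.columns, row))
        p = int(rec["PRIMARYID"])
        start_end = ther_map.get(p, [])
        therapy_start = start_end[0][0] if start_end else ""
        therapy_end = start_end[0][1] if start_end and len(start_end[0]) > 1 else ""
        drugs = []
        for k, (name, role) in enumerate(drug_map.get(p, [])):
            drugs.append(DrugEntry(
                name=name,
                role=role,
                # therapy dates attach to the primary-suspect entry
                therapy_start=therapy_start if role == "PS" else "",
                therapy_end=therapy_end if role == "PS" else "",
            ))
        outcomes = frozenset(
            _OUTCOME_LABELS.get(c[0].strip().upper(), "unknown") for c in outc_map.get(p, [])
        )
        cases.append(CaseReport(
            primaryid=p,
            caseid=int(rec["CASEID"]),
            fda_dt=rec.get("FDA_DT", ""),
            event_dt=rec.get("EVENT_DT", ""),
            sex=_SEX_LABELS.get(rec.get("SEX", "").strip().upper(), "unknown"),
            age=_parse_age_years(rec.get("AGE", ""), rec.get("AGE_COD", "")),
            weight=_parse_weight_kg(rec.get("WT", ""), rec.get("WT_COD", "")),
            reporter=_REPORTER_LABELS.get(rec.get("OCCP_COD", "").strip().upper(), "unknown"),
            country=rec.get("REPORTER_COUNTRY", "").strip() or "unknown",
            outcomes=outcomes,
            drugs=drugs,
            reactions=[r[0] for r in reac_map.get(p, [])],
            indications=[i[0] for i in indi_map.get(p, [])],
        ))
    return cases


def filter_primary_suspect(
    cases: Iterable[CaseReport],
    synonyms: Sequence[str] = defaults.TILDRAKIZUMAB_SYNONYMS,
    substring: bool = False,
) -> list[CaseReport]:
    """Retain cases with >= 1 drug of role PS whose name matches the synonyms."""
    syn = set(normalize_drug_name(s) for s in synonyms)

    def _is_target_ps(c: CaseReport) -> bool:
        for d in c.drugs:
            if d.role.strip().upper() == "PS":
                norm = normalize_drug_name(d.name)
                if (any(s in norm for s in syn) if substring else norm in syn):
                    return True
        return False

    return [c for c in cases if _is_target_ps(c)]


def exclude_pts(
    cases: Iterable[CaseReport],
    exclusion_list: Sequence[str] = defaults.PT_EXCLUSIONS,
    indication_exclusions: Sequence[str] = defaults.INDICATION_EXCLUSIONS,
) -> tuple[list[CaseReport], list[int]]:
    """Strip excluded PTs from reactions and indication exclusions from
    indications; drop (and report) cases left without reactions.

    Returns ``(kept_cases, dropped_primaryids)``. Input objects are not
    mutated.
    """
    excl = {e.strip().casefold() for e in exclusion_list}
    ind_excl = {e.strip().casefold() for e in indication_exclusions}
    kept: list[CaseReport] = []
    dropped: list[int] = []
    for c in cases:
        reactions = [r for r in c.reactions if r.strip().casefold() not in excl]
        if not reactions:
            dropped.append(c.primaryid)
            continue
        indications = [i for i in c.indications if i.strip().casefold() not in ind_excl]
        if reactions == c.reactions and indications == c.indications:
            kept.append(c)
        else:
            kept.append(CaseReport(
                primaryid=c.primaryid, caseid=c.caseid, fda_dt=c.fda_dt,
                event_dt=c.event_dt, sex=c.sex, age=c.age, weight=c.weight,
                reporter=c.reporter, country=c.country, outcomes=c.outcomes,
                drugs=c.drugs, reactions=reactions, indications=indications,
            ))
    return kept, dropped


def load_case_set(
    data_dir: str | Path,
    synonyms: Sequence[str] = defaults.TILDRAKIZUMAB_SYNONYMS,
    pt_exclusions: Sequence[str] = defaults.PT_EXCLUSIONS,
    indication_exclusions: Sequence[str] = defaults.INDICATION_EXCLUSIONS,
    dedup_rule: str = "latest_fda_dt",
    substring_match: bool = False,
    drop_target_from_background: bool = False,
) -> tuple[list[CaseReport], list[CaseReport], CleaningReport]:
    """Run the full cleaning pipeline over every quarter under ``data_dir``.

    Returns ``(target_cases, background_cases, cleaning_report)``. The target
    set contains deduplicated reports with the target drug as primary suspect
    and >= 1 reaction after exclusions; the background set contains all other
    deduplicated reports (optionally excluding any report that mentions the
    target drug in any role).
    """
    quarters = discover_quarters(data_dir)
    area_frames: dict[str, list[pd.DataFrame]] = {}
    for q in sorted(quarters):
        tables = read_quarter(quarters[q])
        for area, df in tables.items():
            area_frames.setdefault(area, []).append(df)
    merged = {area: pd.concat(frames, ignore_index=True) for area, frames in area_frames.items()}
    if "DEMO" not in merged:
        raise FormatError(f"no DEMO tables found under {data_dir}")

    report = CleaningReport(raw_rows=len(merged["DEMO"]))
    demo = deduplicate(merged["DEMO"], rule=dedup_rule)
    report.after_dedup = len(demo)
    kept_pids = set(demo["PRIMARYID"].astype(np.int64).tolist())
    all_pids = set(merged["DEMO"]["PRIMARYID"].astype(np.int64).tolist())
    report.dropped_duplicate_primaryids = sorted(all_pids - kept_pids)

    merged["DEMO"] = demo
    cases = assemble_cases(merged)

    syn = set(normalize_drug_name(s) for s in synonyms)

    def _mentions_target(c: CaseReport) -> bool:
        return any(normalize_drug_name(d.name) in syn for d in c.drugs)

    report.target_any_role = sum(1 for c in cases if _mentions_target(c))
    target = filter_primary_suspect(cases, synonyms, substring=substring_match)
    report.after_ps_filter = len(target)
    target_pids = {c.primaryid for c in target}
    background = [c for c in cases if c.primaryid not in target_pids]
    if drop_target_from_background:
        background = [c for c in background if not _mentions_target(c)]

    target, dropped = exclude_pts(target, pt_exclusions, indication_exclusions)
    report.dropped_no_reaction_primaryids = dropped
    report.after_pt_exclusion = len(target)
    background, bg_dropped = exclude_pts(background, pt_exclusions, indication_exclusions)
    report.dropped_no_reaction_primaryids = dropped + bg_dropped
    return target, background, report
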