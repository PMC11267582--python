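"""Synthetic FAERS-style quarterly extract generator.

Emits "$"-delimited ASCII tables (DEMO, DRUG, REAC, THER, INDI, OUTC, RPSR)
that mimic the structure of real spontaneous-report quarterly extracts, with a
ground-truth ledger so every downstream cleaning and signal-detection stage can
be checked against known answers:

* configurable drug--event associations (per-PT relative risks applied when the
  target drug is the primary suspect),
* duplicate case versions (same CASEID, multiple PRIMARYIDs with strictly
  increasing FDA_DT) so deduplication has a unique correct answer,
* heavy, configurable missingness in demographics and dates, including partial
  dates (YYYYMM / YYYY) that time-to-onset analysis must exclude,
* therapy-start/event date pairs whose difference follows a Weibull law with
  known shape and scale.

Everything is driven by a single :class:`GeneratorConfig`; identical config and
seed produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import defaults

AREAS = ("DEMO", "DRUG", "REAC", "THER", "INDI", "OUTC", "RPSR")

DEMO_COLUMNS = (
    "PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "SEX", "AGE", "AGE_COD",
    "WT", "WT_COD", "OCCP_COD", "REPORTER_COUNTRY",
)

_AGE_BIN_RANGES = {"18-64": (18, 65), "65-85": (65, 86), ">=86": (86, 100)}
_WT_BIN_RANGES = {"<50": (35, 50), "50-100": (50, 101), ">100": (101, 141)}
_RPSR_FROM_OCCP = {"CN": "CSM", "HP": "HP", "MD": "HP", "PH": "HP", "OT": "OTH", "": ""}


class GeneratorConfigError(ValueError):
    """Raised when a generator configuration field is invalid."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


def _default_quarters() -> list[str]:
    return [f"{y}Q{q}" for y in (2022, 2023) for q in (1, 2, 3, 4)]


@dataclass
class GeneratorConfig:
    """All distributions, association strengths, missingness and duplication
    rates for the synthetic report emitter.

    Defaults emulate the marginal structure of a recent six-year slice of a
    spontaneous-report database around a single biologic of interest: heavy
    missingness of age/weight, mostly consumer reports, US-dominated, and a
    time-to-onset law with shape < 1 (early-failure type).
    """

    n_reports: int = 50_000
    target_drug_name: str = "TILDRAKIZUMAB"
    synonym_variants: Sequence[str] = ("TILDRAKIZUMAB", "ILUMYA", "ILUMYA TILDRAKIZUMAB")
    background_drugs: Sequence[tuple[str, float]] = defaults.BACKGROUND_DRUGS
    pt_vocabulary: Sequence[tuple[str, str, float]] = defaults.PT_VOCABULARY
    #: (PT name, relative risk multiplier applied when target drug is PS)
    injected_signals: Sequence[tuple[str, float]] = (
        ("Vulvovaginal candidiasis", 10.0),
        ("Psoriasis", 8.0),
        ("Therapy cessation", 5.0),
        ("Urinary tract infection", 4.0),
    )
    #: optional sex-specific relative risks, PT -> (RR in females, RR in males)
    injected_signals_by_sex: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    #: probability that a report's primary-suspect drug is the target drug
    target_prob: float = 0.02
    role_code_probs: Mapping[str, float] = field(
        default_factory=lambda: {"PS": 0.0, "SS": 0.3, "C": 0.5, "I": 0.2}
    )
    duplicate_rate: float = 0.10
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {
            "sex": 0.16, "age": 0.58, "weight": 0.789,
            "event_dt": 0.40, "start_dt": 0.40,
        }
    )
    #: fraction of present dates degraded to YYYYMM or YYYY
    partial_date_rate: float = 0.10
    #: rate at which a non-reaction handling-issue PT is injected into reports
    excluded_pt_rate: float = 0.05
    excluded_pt_name: str = "Product dose omission issue"
    tto_shape: float = 0.89
    tto_scale: float = 269.56
    demographic_distributions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in defaults.DEMOGRAPHIC_DISTRIBUTIONS.items()}
    )
    indication_table: Mapping[str, float] = field(
        default_factory=lambda: dict(defaults.INDICATION_TABLE)
    )
    drugs_per_report_geom_p: float = 0.45
    max_drugs_per_report: int = 5
    quarters: Sequence[str] = field(default_factory=_default_quarters)
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 0:
            raise GeneratorConfigError("n_reports", "must be >= 0")
        if not (0.0 <= self.target_prob <= 1.0):
            raise GeneratorConfigError("target_prob", "must be in [0, 1]")
        if not (0.0 <= self.duplicate_rate <= 1.0):
            raise GeneratorConfigError("duplicate_rate", "must be in [0, 1]")
        if not (0.0 <= self.partial_date_rate <= 1.0):
            raise GeneratorConfigError("partial_date_rate", "must be in [0, 1]")
        if not (0.0 <= self.excluded_pt_rate <= 1.0):
            raise GeneratorConfigError("excluded_pt_rate", "must be in [0, 1]")
        if self.tto_shape <= 0:
            raise GeneratorConfigError("tto_shape", "must be > 0")
        if self.tto_scale <= 0:
            raise GeneratorConfigError("tto_scale", "must be > 0")
        if not self.synonym_variants:
            raise GeneratorConfigError("synonym_variants", "must be non-empty")
        if not self.quarters:
            raise GeneratorConfigError("quarters", "must be non-empty")
        for key, frac in self.missingness.items():
            if not (0.0 <= frac <= 1.0):
                raise GeneratorConfigError(f"missingness[{key}]", "must be in [0, 1]")
        for pt, soc, p in self.pt_vocabulary:
            if not (0.0 < p < 1.0):
                raise GeneratorConfigError(
                    "pt_vocabulary", f"baseline probability for {pt!r} must be in (0, 1)"
                )
        vocab = {pt for pt, _, _ in self.pt_vocabulary}
        for pt, rr in self.injected_signals:
            if rr < 0:
                raise GeneratorConfigError("injected_signals", f"relative risk for {pt!r} must be >= 0")
            if pt not in vocab:
                raise GeneratorConfigError("injected_signals", f"{pt!r} not in pt_vocabulary")
        for name, dist in self.demographic_distributions.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise GeneratorConfigError(
                    f"demographic_distributions[{name}]", f"probabilities sum to {total!r}, not 1"
                )
            if any(p < 0 for p in dist.values()):
                raise GeneratorConfigError(
                    f"demographic_distributions[{name}]", "probabilities must be >= 0"
                )
        if abs(sum(self.indication_table.values()) - 1.0) > 1e-9:
            raise GeneratorConfigError("indication_table", "probabilities must sum to 1")
        role_total = sum(self.role_code_probs.get(r, 0.0) for r in ("PS", "SS", "C", "I"))
        if abs(role_total - 1.0) > 1e-9 and abs(role_total) > 1e-9:
            # PS is assigned structurally (exactly one per report); the rest is
            # renormalised over SS/C/I, so any non-degenerate total is usable,
            # but a distribution is still required to sum to 1 (or PS-less 1).
            raise GeneratorConfigError("role_code_probs", "must sum to 1 over {PS,SS,C,I}")
        if not (0.0 < self.drugs_per_report_geom_p <= 1.0):
            raise GeneratorConfigError("drugs_per_report_geom_p", "must be in (0, 1]")
        if self.max_drugs_per_report < 1:
            raise GeneratorConfigError("max_drugs_per_report", "must be >= 1")

    def with_(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class QuarterlyFileSet:
    """Paths of one generated multi-quarter extract plus its truth ledger."""

    out_dir: Path
    quarters: list[str]
    #: quarter label -> {area name -> file path}
    files: dict[str, dict[str, Path]]
    ledger_cases: Path
    ledger_pts: Path

    def load_ledger_cases(self) -> pd.DataFrame:
        return pd.read_csv(self.ledger_cases)

    def load_ledger_pts(self) -> pd.DataFrame:
        return pd.read_csv(self.ledger_pts)


def sample_tto(n: int, shape: float, scale: float, seed) -> np.ndarray:
    """Draw ``n`` Weibull(shape, scale) onset intervals, rounded to whole days.

    ``seed`` may be an integer or a :class:`numpy.random.Generator`.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = scale * rng.weibull(shape, size=int(n))
    return np.round(draws).astype(np.int64)


def _quarter_bounds(label: str) -> tuple[np.datetime64, np.datetime64]:
    """Return [start, end) day bounds for a quarter label like ``2023Q1``."""
    try:
        year, q = label.split("Q")
        year, q = int(year), int(q)
        if not 1 <= q <= 4:
            raise ValueError
    except ValueError:
        raise GeneratorConfigError("quarters", f"bad quarter label {label!r}")
    start = np.datetime64(f"{year}-{3 * (q - 1) + 1:02d}-01")
    end = (
        np.datetime64(f"{year + 1}-01-01")
        if q == 4
        else np.datetime64(f"{year}-{3 * q + 1:02d}-01")
    )
    return start, end


def _categorical(rng: np.random.Generator, dist: Mapping[str, float], n: int) -> np.ndarray:
    cats = list(dist.keys())
    probs = np.array([dist[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(cats), size=n, p=probs)
    return np.array(cats, dtype=object)[idx]


def _date_strings(
    dates: np.ndarray,  # datetime64[D]
    missing: np.ndarray,
    partial: np.ndarray,
    partial_kind: np.ndarray,  # 0 -> YYYYMM, 1 -> YYYY
) -> np.ndarray:
    """Format dates as FAERS-style integer strings with missing/partial."""
    full = pd.DatetimeIndex(dates).strftime("%Y%m%d").to_numpy(dtype=object)
    out = full.copy()
    ym = pd.DatetimeIndex(dates).strftime("%Y%m").to_numpy(dtype=object)
    yy = pd.DatetimeIndex(dates).strftime("%Y").to_numpy(dtype=object)
    out[partial & (partial_kind == 0)] = ym[partial & (partial_kind == 0)]
    out[partial & (partial_kind == 1)] = yy[partial & (partial_kind == 1)]
    out[missing] = ""
    return out


def generate_dataset(config: GeneratorConfig, out_dir: str | Path) -> QuarterlyFileSet:
    """Generate one multi-quarter synthetic extract under ``out_dir``.

    Deterministic given ``config.seed``: identical config and seed produce
    byte-identical files. Every report carries at least one drug (exactly one
    with role PS) and at least one reaction PT; for reports whose PS drug is
    the target, PT occurrence probabilities are multiplied by the configured
    relative risks, and the event date equals the therapy start date plus a
    rounded Weibull(shape, scale) draw.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    pts = [pt for pt, _, _ in config.pt_vocabulary]
    socs = {pt: soc for pt, soc, _ in config.pt_vocabulary}
    base_p = np.array([p for _, _, p in config.pt_vocabulary], dtype=float)
    pt_index = {pt: i for i, pt in enumerate(pts)}
    n_pts = len(pts)

    caseid = 100_000_001 + np.arange(n, dtype=np.int64)
    primaryid_v1 = caseid * 10 + 1

    # --- receipt dates: uniform within an assigned quarter -------------------
    q_starts = []
    q_ends = []
    for q in config.quarters:
        s, e = _quarter_bounds(q)
        q_starts.append(s)
        q_ends.append(e)
    q_starts_arr = np.array(q_starts, dtype="datetime64[D]")
    q_lens = (np.array(q_ends, dtype="datetime64[D]") - q_starts_arr).astype(int)
    qidx = rng.integers(0, len(config.quarters), size=n)
    fda_dt = q_starts_arr[qidx] + (rng.random(n) * q_lens[qidx]).astype(int)

    # --- demographics --------------------------------------------------------
    dd = config.demographic_distributions
    sex = _categorical(rng, dd["sex"], n)
    age_bin = _categorical(rng, dd["age"], n)
    age = np.zeros(n, dtype=np.int64)
    for b, (lo, hi) in _AGE_BIN_RANGES.items():
        m = age_bin == b
        age[m] = rng.integers(lo, hi, size=int(m.sum()))
    wt_bin = _categorical(rng, dd["weight"], n)
    wt = np.zeros(n, dtype=np.int64)
    for b, (lo, hi) in _WT_BIN_RANGES.items():
        m = wt_bin == b
        wt[m] = rng.integers(lo, hi, size=int(m.sum()))
    occp = _categorical(rng, dd["reporter"], n)
    country = _categorical(rng, dd["country"], n)
    outcome = _categorical(rng, dd["outcome"], n)
    indication = _categorical(rng, config.indication_table, n)

    # --- target assignment and reactions ------------------------------------
    is_target = rng.random(n) < config.target_prob
    probs = np.broadcast_to(base_p, (n, n_pts)).copy()
    rr_by_pt = {pt: 1.0 for pt in pts}
    for pt, rr in config.injected_signals:
        rr_by_pt[pt] = rr
        j = pt_index[pt]
        probs[is_target, j] = min(base_p[j] * rr, 0.95)
    for pt, (rr_f, rr_m) in config.injected_signals_by_sex.items():
        j = pt_index[pt]
        probs[is_target & (sex == "F"), j] = min(base_p[j] * rr_f, 0.95)
        probs[is_target & (sex == "M"), j] = min(base_p[j] * rr_m, 0.95)
    hits = rng.random((n, n_pts)) < probs
    # guarantee >= 1 PT: renormalised categorical draw for empty rows
    empty = ~hits.any(axis=1)
    if empty.any():
        sub = probs[empty]
        cum = np.cumsum(sub, axis=1)
        cum /= cum[:, -1:]
        u = rng.random(int(empty.sum()))
        choice = (u[:, None] > cum).sum(axis=1)
        hits[np.flatnonzero(empty), choice] = True
    has_excluded_pt = rng.random(n) < config.excluded_pt_rate

    # --- therapy / event dates ----------------------------------------------
    tto = sample_tto(n, config.tto_shape, config.tto_scale, rng)
    report_lag = rng.integers(0, 61, size=n)
    event_dt = fda_dt - report_lag
    start_dt = event_dt - tto
    end_dt = start_dt + rng.integers(28, 366, size=n)

    miss = config.missingness
    miss_sex = rng.random(n) < miss.get("sex", 0.0)
    miss_age = rng.random(n) < miss.get("age", 0.0)
    miss_wt = rng.random(n) < miss.get("weight", 0.0)
    miss_event = rng.random(n) < miss.get("event_dt", 0.0)
    miss_start = rng.random(n) < miss.get("start_dt", 0.0)
    part_event = (~miss_event) & (rng.random(n) < config.partial_date_rate)
    part_start = (~miss_start) & (rng.random(n) < config.partial_date_rate)
    part_kind_event = rng.integers(0, 2, size=n)
    part_kind_start = rng.integers(0, 2, size=n)
    miss_end = rng.random(n) < 0.5

    # --- drugs ----------------------------------------------------------------
    n_drugs = np.minimum(
        rng.geometric(config.drugs_per_report_geom_p, size=n), config.max_drugs_per_report
    )
    variants = np.array(list(config.synonym_variants), dtype=object)
    bg_names = np.array([d for d, _ in config.background_drugs], dtype=object)
    bg_w = np.array([w for _, w in config.background_drugs], dtype=float)
    bg_w = bg_w / bg_w.sum()
    ps_name = np.empty(n, dtype=object)
    n_target = int(is_target.sum())
    ps_name[is_target] = variants[rng.integers(0, len(variants), size=n_target)]
    ps_name[~is_target] = bg_names[rng.choice(len(bg_names), size=n - n_target, p=bg_w)]
    n_secondary = n_drugs - 1
    sec_report = np.repeat(np.arange(n), n_secondary)
    m_sec = len(sec_report)
    sec_name = bg_names[rng.choice(len(bg_names), size=m_sec, p=bg_w)]
    sec_roles_dist = {
        r: config.role_code_probs.get(r, 0.0) for r in ("SS", "C", "I")
    }
    tot = sum(sec_roles_dist.values()) or 1.0
    sec_roles_dist = {r: v / tot for r, v in sec_roles_dist.items()}
    sec_role = _categorical(rng, sec_roles_dist, m_sec)

    # --- duplicate versions ---------------------------------------------------
    is_dup = rng.random(n) < config.duplicate_rate
    dup_idx = np.flatnonzero(is_dup)
    dup_fda = fda_dt[dup_idx] + rng.integers(5, 91, size=len(dup_idx))
    # clamp into the generated range so the row lands in a real quarter file
    last_end = np.array(q_ends, dtype="datetime64[D]").max() - 1
    dup_fda = np.minimum(dup_fda, last_end)
    dup_primaryid = caseid[dup_idx] * 10 + 2

    # --- assemble long-format tables -----------------------------------------
    # one DEMO row per version; child rows duplicated per version
    ver_report = np.concatenate([np.arange(n), dup_idx])
    ver_primaryid = np.concatenate([primaryid_v1, dup_primaryid])
    ver_fda = np.concatenate([fda_dt, dup_fda])
    order = np.argsort(ver_primaryid, kind="stable")
    ver_report, ver_primaryid, ver_fda = (
        ver_report[order], ver_primaryid[order], ver_fda[order]
    )

    event_str_base = _date_strings(event_dt, miss_event, part_event, part_kind_event)
    start_str_base = _date_strings(start_dt, miss_start, part_start, part_kind_start)
    end_str_base = _date_strings(end_dt, miss_end, np.zeros(n, bool), part_kind_start)
    fda_str = pd.DatetimeIndex(ver_fda).strftime("%Y%m%d").to_numpy(dtype=object)

    sex_str = sex.copy(); sex_str[miss_sex] = ""
    age_str = age.astype(str).astype(object); age_str[miss_age] = ""
    age_cod = np.where(miss_age, "", "YR").astype(object)
    wt_str = wt.astype(str).astype(object); wt_str[miss_wt] = ""
    wt_cod = np.where(miss_wt, "", "KG").astype(object)

    demo = pd.DataFrame({
        "PRIMARYID": ver_primaryid,
        "CASEID": caseid[ver_report],
        "FDA_DT": fda_str,
        "EVENT_DT": event_str_base[ver_report],
        "SEX": sex_str[ver_report],
        "AGE": age_str[ver_report],
        "AGE_COD": age_cod[ver_report],
        "WT": wt_str[ver_report],
        "WT_COD": wt_cod[ver_report],
        "OCCP_COD": occp[ver_report],
        "REPORTER_COUNTRY": country[ver_report],
    })

    # drug rows per version: PS first, then secondaries
    nv = len(ver_report)
    ps_rows = pd.DataFrame({
        "PRIMARYID": ver_primaryid,
        "CASEID": caseid[ver_report],
        "DRUG_SEQ": np.ones(nv, dtype=int),
        "DRUGNAME": ps_name[ver_report],
        "ROLE_COD": np.full(nv, "PS", dtype=object),
    })
    # map secondary rows (per report) onto each version of that report
    sec_per_report: dict[int, list[int]] = {}
    for row_i, rep in enumerate(sec_report):
        sec_per_report.setdefault(int(rep), []).append(row_i)
    sec_rows_ver = []
    for v_i, rep in enumerate(ver_report):
        for k, row_i in enumerate(sec_per_report.get(int(rep), ())):
            sec_rows_ver.append((ver_primaryid[v_i], caseid[rep], k + 2,
                                 sec_name[row_i], sec_role[row_i]))
    sec_df = pd.DataFrame(
        sec_rows_ver, columns=["PRIMARYID", "CASEID", "DRUG_SEQ", "DRUGNAME", "ROLE_COD"]
    )
    drug = pd.concat([ps_rows, sec_df], ignore_index=True)
    drug = drug.sort_values(["PRIMARYID", "DRUG_SEQ"], kind="stable").reset_index(drop=True)

    # reaction rows per version
    rep_rows, pt_cols = np.nonzero(hits)
    reac_base = pd.DataFrame({
        "report": rep_rows,
        "PT": np.array(pts, dtype=object)[pt_cols],
    })
    if has_excluded_pt.any():
        extra = pd.DataFrame({
            "report": np.flatnonzero(has_excluded_pt),
            "PT": config.excluded_pt_name,
        })
        reac_base = pd.concat([reac_base, extra], ignore_index=True)
    ver_df = pd.DataFrame({
        "report": ver_report, "PRIMARYID": ver_primaryid, "CASEID": caseid[ver_report]
    })
    reac = ver_df.merge(reac_base, on="report")[["PRIMARYID", "CASEID", "PT"]]
    reac = reac.sort_values(["PRIMARYID", "PT"], kind="stable").reset_index(drop=True)

    ther = pd.DataFrame({
        "PRIMARYID": ver_primaryid,
        "CASEID": caseid[ver_report],
        "START_DT": start_str_base[ver_report],
        "END_DT": end_str_base[ver_report],
    })

    indi_mask = indication[ver_report] != ""
    indi = pd.DataFrame({
        "PRIMARYID": ver_primaryid[indi_mask],
        "CASEID": caseid[ver_report][indi_mask],
        "INDI_PT": indication[ver_report][indi_mask],
    })

    outc_mask = outcome[ver_report] != ""
    outc = pd.DataFrame({
        "PRIMARYID": ver_primaryid[outc_mask],
        "CASEID": caseid[ver_report][outc_mask],
        "OUTC_COD": outcome[ver_report][outc_mask],
    })

    rpsr_cod = np.array([_RPSR_FROM_OCCP.get(o, "OTH") for o in occp], dtype=object)
    rpsr_mask = rpsr_cod[ver_report] != ""
    rpsr = pd.DataFrame({
        "PRIMARYID": ver_primaryid[rpsr_mask],
        "CASEID": caseid[ver_report][rpsr_mask],
        "RPSR_COD": rpsr_cod[ver_report][rpsr_mask],
    })

    tables = {"DEMO": demo, "DRUG": drug, "REAC": reac, "THER": ther,
              "INDI": indi, "OUTC": outc, "RPSR": rpsr}

    # empty-input edge: emit headers only
    if n == 0:
        cols = {"DEMO": DEMO_COLUMNS,
                "DRUG": ("PRIMARYID", "CASEID", "DRUG_SEQ", "DRUGNAME", "ROLE_COD"),
                "REAC": ("PRIMARYID", "CASEID", "PT"),
                "THER": ("PRIMARYID", "CASEID", "START_DT", "END_DT"),
                "INDI": ("PRIMARYID", "CASEID", "INDI_PT"),
                "OUTC": ("PRIMARYID", "CASEID", "OUTC_COD"),
                "RPSR": ("PRIMARYID", "CASEID", "RPSR_COD")}
        tables = {a: pd.DataFrame(columns=list(c)) for a, c in cols.items()}

    # --- write per-quarter files ---------------------------------------------
    files: dict[str, dict[str, Path]] = {q: {} for q in config.quarters}
    q_of_version = np.searchsorted(q_starts_arr, ver_fda, side="right") - 1
    version_quarter = np.array(list(config.quarters), dtype=object)[
        np.clip(q_of_version, 0, len(config.quarters) - 1)
    ] if nv else np.array([], dtype=object)
    pid_quarter = dict(zip(ver_primaryid.tolist(), version_quarter.tolist())) if nv else {}
    for q in config.quarters:
        for area, df in tables.items():
            path = out_dir / f"{area}_{q}.txt"
            if len(df):
                sel = df["PRIMARYID"].map(pid_quarter) == q
                part = df[sel]
            else:
                part = df
            part.to_csv(path, sep="$", index=False, lineterminator="\n")
            files[q][area] = path

    # --- ground-truth ledger ---------------------------------------------------
    n_versions = np.ones(n, dtype=int)
    n_versions[dup_idx] += 1
    canonical_pid = primaryid_v1.copy()
    canonical_pid[dup_idx] = dup_primaryid
    tto_usable = is_target & ~miss_event & ~miss_start & ~part_event & ~part_start
    ledger_cases = pd.DataFrame({
        "caseid": caseid,
        "canonical_primaryid": canonical_pid,
        "n_versions": n_versions,
        "is_target_ps": is_target.astype(int),
        "sex": np.where(miss_sex, "", sex),
        "tto_days": tto,
        "tto_usable": tto_usable.astype(int),
        "has_excluded_pt": has_excluded_pt.astype(int),
        "n_pts": hits.sum(axis=1),
    })
    ledger_cases_path = out_dir / "ground_truth_cases.csv"
    ledger_cases.to_csv(ledger_cases_path, index=False, lineterminator="\n")

    target_counts = hits[is_target].sum(axis=0) if n else np.zeros(n_pts, dtype=int)
    bg_counts = hits[~is_target].sum(axis=0) if n else np.zeros(n_pts, dtype=int)
    ledger_pts = pd.DataFrame({
        "pt": pts,
        "soc": [socs[p] for p in pts],
        "baseline": base_p,
        "rr": [rr_by_pt[p] for p in pts],
        "target_cases": target_counts.astype(int),
        "background_cases": bg_counts.astype(int),
    })
    ledger_pts_path = out_dir / "ground_truth_pts.csv"
    ledger_pts.to_csv(ledger_pts_path, index=False, lineterminator="\n")

    return QuarterlyFileSet(
        out_dir=out_dir,
        quarters=list(config.quarters),
        files=files,
        ledger_cases=ledger_cases_path,
        ledger_pts=ledger_pts_path,
    )
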