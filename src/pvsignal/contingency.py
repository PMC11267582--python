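"""2x2 contingency tables for (target drug, term) pairs.

For a term t the table counts unique reports:

====  =========================================  =====================
cell  target-drug reports                        all other reports
====  =========================================  =====================
a     with t                                     --
b     without t                                  --
c     --                                         with t
d     --                                         without t
====  =========================================  =====================

Counting is at the report level: a report listing the same PT twice, or two
PTs mapping to the same SOC, contributes once. The background is every
deduplicated report whose primary-suspect drug is not the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ingest import CaseReport


class MappingError(KeyError):
    """A PT has no SOC assignment in the supplied map."""


@dataclass(frozen=True)
class ContingencyTable:
    term: str
    level: str  # "PT" or "SOC"
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def scaled(self, k: int) -> "ContingencyTable":
        return ContingencyTable(self.term, self.level, self.a * k, self.b * k,
                                self.c * k, self.d * k)


def load_pt_soc_map(path: str | Path) -> dict[str, str]:
    """Read a two-column delimited PT -> SOC file (TSV, header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns (PT, SOC)")
    cols = list(df.columns)
    # tolerate headerless files: first row is data if it is not a header word
    if cols[0].strip().lower() not in ("pt", "preferred_term", "term"):
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, header=None)
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


def write_pt_soc_map(mapping: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"pt": list(mapping.keys()), "soc": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _terms_of(case: CaseReport, level: str, pt_soc_map: Mapping[str, str] | None) -> set[str]:
    if level == "PT":
        return {r.strip() for r in case.reactions if r.strip()}
    if level == "SOC":
        if pt_soc_map is None:
            raise MappingError("SOC level requires a PT->SOC map")
        out = set()
        for r in case.reactions:
            r = r.strip()
            if not r:
                continue
            try:
                out.add(pt_soc_map[r])
            except KeyError:
                raise MappingError(f"PT {r!r} has no SOC mapping") from None
        return out
    raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")


def build_table(
    case_set: Sequence[CaseReport],
    background_set: Sequence[CaseReport],
    term: str,
    level: str = "PT",
    pt_soc_map: Mapping[str, str] | None = None,
) -> ContingencyTable:
    """Count the 2x2 table for one term at PT or SOC level."""
    a = sum(1 for c in case_set if term in _terms_of(c, level, pt_soc_map))
    b = len(case_set) - a
    c_ = sum(1 for c in background_set if term in _terms_of(c, level, pt_soc_map))
    d = len(background_set) - c_
    return ContingencyTable(term=term, level=level, a=a, b=b, c=c_, d=d)


def build_all(
    case_set: Sequence[CaseReport],
    background_set: Sequence[CaseReport],
    level: str = "PT",
    pt_soc_map: Mapping[str, str] | None = None,
    min_count: int = 3,
) -> tuple[list[ContingencyTable], list[ContingencyTable]]:
    """Build one table per distinct term observed in the target case set.

    Returns ``(tables, below_threshold)``: tables whose case count ``a`` meets
    ``min_count`` and, separately, those below it (still fully built — the
    threshold is a reporting gate, not a computation gate). Each list is
    sorted by descending ``a`` then term name.
    """
    target_terms: dict[str, int] = {}
    for case in case_set:
        for t in _terms_of(case, level, pt_soc_map):
            target_terms[t] = target_terms.get(t, 0) + 1
    bg_counts: dict[str, int] = {t: 0 for t in target_terms}
    for case in background_set:
        for t in _terms_of(case, level, pt_soc_map):
            if t in bg_counts:
                bg_counts[t] += 1
    n_target = len(case_set)
    n_bg = len(background_set)
    tables = [
        ContingencyTable(term=t, level=level, a=a, b=n_target - a,
                         c=bg_counts[t], d=n_bg - bg_counts[t])
        for t, a in target_terms.items()
    ]
    tables.sort(key=lambda t: (-t.a, t.term))
    meets = [t for t in tables if t.a >= min_count]
    below = [t for t in tables if t.a < min_count]
    return meets, below


def tables_to_frame(tables: Iterable[ContingencyTable]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.term, t.level, t.a, t.b, t.c, t.d) for t in tables],
        columns=["term", "level", "a", "b", "c", "d"],
    )
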