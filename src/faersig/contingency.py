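"""2x2 disproportionality tables for (drug, term) pairs.

Each table counts *reports* (not drug-event rows): ``a`` target-drug reports
mentioning the term, ``b`` background reports mentioning it, ``c`` target
reports without it, ``d`` background reports without it.  A report with
several PTs contributes to every term it mentions but to each cell at most
once; at SOC level two PTs of one report in the same SOC count that report
once.  Tables can be built overall or within a sex stratum, at PT or SOC
level.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .ingest import AdverseEventReport, ReportSet

#: The comparator universe (all non-target reports) is itself a ReportSet.
BackgroundSet = ReportSet

STRATA = ("overall", "F", "M")


@dataclass(frozen=True)
class ContingencyTable:
    drug: str
    term: str
    level: str  # "PT" | "SOC"
    stratum: str  # "overall" | "F" | "M"
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def _in_stratum(r: AdverseEventReport, stratum: str) -> bool:
    if stratum == "overall":
        return True
    if stratum in ("F", "M"):
        return r.sex == stratum
    raise ValueError(f"unknown stratum label {stratum!r}")


def _check_disjoint(target: ReportSet, background: BackgroundSet) -> None:
    overlap = target.primaryids() & background.primaryids()
    if overlap:
        raise ValueError(f"target and background overlap on {len(overlap)} primaryids")


def make_background(all_reports: ReportSet, target: ReportSet) -> BackgroundSet:
    """Comparator universe: every report not in the target set ("all other
    drugs")."""
    tids = target.primaryids()
    bg = all_reports.subset(lambda r: r.primaryid not in tids)
    return bg


def build_contingency(target: ReportSet, background: BackgroundSet, drug: str,
                      term: str, level: str = "PT",
                      stratum: str = "overall") -> ContingencyTable:
    """Build the 2x2 table for one (drug, term) pair.

    ``target`` must already be restricted to the drug's reports; ``drug`` is
    recorded as a label.  ``background`` and ``target`` must be disjoint.
    """
    if not term:
        raise ValueError("empty term")
    _check_disjoint(target, background)
    t = [r for r in target if _in_stratum(r, stratum)]
    g = [r for r in background if _in_stratum(r, stratum)]
    a = sum(1 for r in t if term in r.terms(level))
    b = sum(1 for r in g if term in r.terms(level))
    return ContingencyTable(drug=drug, term=term, level=level, stratum=stratum,
                            a=a, b=b, c=len(t) - a, d=len(g) - b)


def enumerate_tables(target: ReportSet, background: BackgroundSet, drug: str,
                     level: str = "PT", stratum: str = "overall",
                     min_a: int = 3) -> list[ContingencyTable]:
    """One table per distinct term with a >= min_a among target reports,
    sorted by descending a then term name."""
    _check_disjoint(target, background)
    t = [r for r in target if _in_stratum(r, stratum)]
    g = [r for r in background if _in_stratum(r, stratum)]
    a_counts: Counter[str] = Counter()
    for r in t:
        a_counts.update(r.terms(level))
    b_counts: Counter[str] = Counter()
    for r in g:
        b_counts.update(r.terms(level))
    out = []
    for term, a in sorted(a_counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if a < min_a:
            continue
        b = b_counts.get(term, 0)
        out.append(ContingencyTable(drug=drug, term=term, level=level,
                                    stratum=stratum, a=a, b=b,
                                    c=len(t) - a, d=len(g) - b))
    return out


def tables_to_frame(tables: Iterable[ContingencyTable]) -> pd.DataFrame:
    """Delimited-text-ready view: drug, level, stratum, term, a, b, c, d."""
    return pd.DataFrame([
        {"drug": t.drug, "level": t.level, "stratum": t.stratum, "term": t.term,
         "a": t.a, "b": t.b, "c": t.c, "d": t.d}
        for t in tables
    ], columns=["drug", "level", "stratum", "term", "a", "b", "c", "d"])
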