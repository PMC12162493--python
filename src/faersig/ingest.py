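"""Reading and filtering FAERS-dialect report tables.

The stages mirror the standard pharmacovigilance cleaning flow: parse the
quarterly ``$``-delimited tables into one record per primary id, collapse
multi-version cases to the latest version (largest primary id per case id),
restrict to reports whose primary-suspect (PS) drug matches the study
keywords, and attach a MedDRA system organ class (SOC) to every preferred
term (PT) via a two-column dictionary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

# Study keyword lists: generic names (with BLA suffixes) and product names.
DEFAULT_STUDY_KEYWORDS: dict[str, tuple[str, ...]] = {
    "lecanemab": ("lecanemab-irmb", "lecanemab", "leqembi"),
    "aducanumab": ("aducanumab-avwa", "aducanumab", "aduhelm"),
}

_REPORTER_BY_OCCP = {
    "CN": "consumer",
    "MD": "physician",
    "HP": "health-professional",
    "PH": "pharmacist",
}

AGE_BANDS = ("<18", "18-64.9", "65-85", ">85", "missing")


@dataclass
class AdverseEventReport:
    """One (deduplicated) safety report."""

    primaryid: str
    caseid: str
    drug_entries: list[tuple[str, str, str, int]] = field(default_factory=list)  # (drugname, prodname, role, seq)
    pts: set[str] = field(default_factory=set)
    socs: set[str] = field(default_factory=set)
    sex: str | None = None  # "F" / "M" / None
    age_years: float | None = None
    reporter_type: str | None = None
    country: str | None = None
    event_dt: str = ""  # raw YYYYMMDD / partial / ""
    start_dt: str = ""  # raw, for the PS drug
    target_drugs: tuple[str, ...] = ()

    @property
    def target_drug(self) -> str | None:
        return self.target_drugs[0] if self.target_drugs else None

    @property
    def ps_entries(self) -> list[tuple[str, str, str, int]]:
        return [e for e in self.drug_entries if e[2] == "PS"]

    def terms(self, level: str) -> set[str]:
        if level == "PT":
            return self.pts
        if level == "SOC":
            return self.socs
        raise ValueError(f"unknown level {level!r}")


@dataclass
class ReportSet:
    """A collection of reports plus provenance and processing flags."""

    reports: list[AdverseEventReport]
    provenance: list[str] = field(default_factory=list)
    dedup_applied: bool = False
    unmapped_pts: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[AdverseEventReport]:
        return iter(self.reports)

    def primaryids(self) -> set[str]:
        return {r.primaryid for r in self.reports}

    def subset(self, pred) -> "ReportSet":
        return ReportSet([r for r in self.reports if pred(r)],
                         provenance=list(self.provenance),
                         dedup_applied=self.dedup_applied,
                         unmapped_pts=set(self.unmapped_pts))


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="$", dtype=str, keep_default_na=False)


def parse_faers_tables(paths: Mapping[str, str | Path]) -> ReportSet:
    """Parse DEMO/DRUG/REAC (mandatory) and THER (optional) files.

    ``paths`` maps table name to file path.  Orphan DRUG/REAC/THER rows whose
    primary id is absent from DEMO are logged and dropped.
    """
    for name in ("DEMO", "DRUG", "REAC"):
        if name not in paths:
            raise FileNotFoundError(f"mandatory table {name} not provided")
    frames = {name: _read_table(p) for name, p in paths.items()}
    rs = reports_from_frames(frames)
    rs.provenance = [str(paths[k]) for k in paths]
    return rs


def _parse_age(age: str, cod: str) -> float | None:
    try:
        v = float(age)
    except (TypeError, ValueError):
        return None
    cod = (cod or "").strip().upper()
    if cod in ("", "YR"):
        return v
    if cod == "MON":
        return v / 12.0
    if cod == "DY":
        return v / 365.25
    if cod == "DEC":
        return v * 10.0
    return None  # unknown unit


def reports_from_frames(frames: Mapping[str, pd.DataFrame]) -> ReportSet:
    """Build one AdverseEventReport per DEMO primary id from in-memory tables."""
    demo = frames["DEMO"]
    drug = frames["DRUG"]
    reac = frames["REAC"]
    ther = frames.get("THER", pd.DataFrame(columns=["primaryid", "dsg_drug_seq", "start_dt"]))

    known = set(demo["primaryid"])
    for name, tab in (("DRUG", drug), ("REAC", reac), ("THER", ther)):
        orphans = (~tab["primaryid"].isin(known)).sum()
        if orphans:
            log.warning("%s: dropped %d orphan rows (primaryid not in DEMO)", name, orphans)
    drug = drug[drug["primaryid"].isin(known)]
    reac = reac[reac["primaryid"].isin(known)]
    ther = ther[ther["primaryid"].isin(known)]

    pts_by_pid = reac.groupby("primaryid")["pt"].agg(set).to_dict()
    for col in ("drugname", "prodname", "role_cod", "drug_seq"):
        if col not in drug.columns:
            drug = drug.assign(**{col: ""})
    drug_by_pid: dict[str, list[tuple[str, str, str, int]]] = {}
    for pid, name, prod, role, seq in zip(
        drug["primaryid"], drug["drugname"], drug["prodname"],
        drug["role_cod"], drug["drug_seq"],
    ):
        try:
            seq_i = int(seq)
        except (TypeError, ValueError):
            seq_i = 0
        drug_by_pid.setdefault(pid, []).append((str(name), str(prod), str(role), seq_i))

    # THER start dates keyed by (primaryid, drug sequence).
    ther_by_pid: dict[tuple[str, int], list[str]] = {}
    for pid, seq, sdt in zip(ther["primaryid"], ther["dsg_drug_seq"], ther["start_dt"]):
        try:
            seq_i = int(seq)
        except (TypeError, ValueError):
            continue
        ther_by_pid.setdefault((pid, seq_i), []).append(str(sdt))

    reports: list[AdverseEventReport] = []
    for row in demo.to_dict("records"):
        pid = str(row["primaryid"])
        entries = drug_by_pid.get(pid, [])
        # Therapy start for the PS drug: earliest full date among its THER rows.
        start = ""
        ps = [e for e in entries if e[2] == "PS"]
        if ps:
            cands = ther_by_pid.get((pid, ps[0][3]), [])
            full = sorted(s for s in cands if len(s) == 8 and s.isdigit())
            start = full[0] if full else (cands[0] if cands else "")
        raw_sex = str(row.get("sex", ""))
        reports.append(AdverseEventReport(
            primaryid=pid,
            caseid=str(row.get("caseid", pid)),
            drug_entries=entries,
            pts=set(pts_by_pid.get(pid, set())),
            sex=raw_sex if raw_sex in ("F", "M") else None,
            age_years=_parse_age(str(row.get("age", "")), str(row.get("age_cod", ""))),
            reporter_type=_REPORTER_BY_OCCP.get(str(row.get("occp_cod", ""))),
            country=str(row.get("occr_country", "")) or None,
            event_dt=str(row.get("event_dt", "")),
            start_dt=start,
        ))
    return ReportSet(reports)


def _pid_key(pid: str):
    return (0, int(pid)) if pid.isdigit() else (1, pid)


def deduplicate(rs: ReportSet) -> ReportSet:
    """Collapse exact duplicates and keep the latest version per case.

    Exact duplicate primary ids collapse to one record; among several primary
    ids sharing a case id, only the numerically largest (latest case version)
    is retained.
    """
    by_pid: dict[str, AdverseEventReport] = {}
    exact = 0
    for r in rs.reports:
        if r.primaryid in by_pid:
            exact += 1
            continue
        by_pid[r.primaryid] = r
    best: dict[str, AdverseEventReport] = {}
    for r in by_pid.values():
        cur = best.get(r.caseid)
        if cur is None or _pid_key(r.primaryid) > _pid_key(cur.primaryid):
            best[r.caseid] = r
    kept = sorted(best.values(), key=lambda r: _pid_key(r.primaryid))
    versions = len(by_pid) - len(kept)
    log.info("deduplicate: removed %d exact-duplicate and %d superseded-version records", exact, versions)
    return ReportSet(kept, provenance=list(rs.provenance), dedup_applied=True,
                     unmapped_pts=set(rs.unmapped_pts))


def _match_targets(report: AdverseEventReport,
                   keywords: Mapping[str, Sequence[str]]) -> tuple[str, ...]:
    names = [f"{n} {p}".lower() for n, p, role, _ in report.drug_entries if role == "PS"]
    hits = []
    for canonical, kws in keywords.items():
        if any(kw.lower() in nm for kw in kws for nm in names):
            hits.append(canonical)
    return tuple(hits)


def filter_primary_suspect(rs: ReportSet,
                           keywords: Mapping[str, Sequence[str]] | Sequence[str] = DEFAULT_STUDY_KEYWORDS,
                           ) -> ReportSet:
    """Retain reports whose PS drug matches a study keyword.

    Matching is case-insensitive substring on both drugname and prodname of
    PS-role entries only.  ``keywords`` maps a canonical drug name to its
    keyword list; a plain sequence of keywords is looked up against the
    default study map (unknown keywords become their own canonical name).
    Intended to run after :func:`deduplicate`.
    """
    if not keywords:
        raise ValueError("empty keyword list")
    if not isinstance(keywords, Mapping):
        kwmap: dict[str, list[str]] = {}
        for kw in keywords:
            canonical = next((c for c, kws in DEFAULT_STUDY_KEYWORDS.items()
                              if kw.lower() in [k.lower() for k in kws]), kw.lower())
            kwmap.setdefault(canonical, []).append(kw)
        keywords = kwmap
    kept = []
    ambiguous = 0
    for r in rs.reports:
        hits = _match_targets(r, keywords)
        if hits:
            if len(hits) > 1:
                ambiguous += 1
            r2 = replace(r, target_drugs=hits, pts=set(r.pts), socs=set(r.socs),
                         drug_entries=list(r.drug_entries))
            kept.append(r2)
    if ambiguous:
        log.warning("filter_primary_suspect: %d reports matched more than one study drug", ambiguous)
    return ReportSet(kept, provenance=list(rs.provenance), dedup_applied=rs.dedup_applied,
                     unmapped_pts=set(rs.unmapped_pts))


def read_meddra_dictionary(path: str | Path) -> dict[str, str]:
    """Read the two-column (PT, SOC) tab-delimited mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mapping: dict[str, str] = {}
    for pt, soc in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if pt in mapping and mapping[pt] != soc:
            raise ValueError(f"PT {pt!r} mapped to conflicting SOCs")
        mapping[pt] = soc
    return mapping


def map_meddra(rs: ReportSet, dictionary: Mapping[str, str]) -> ReportSet:
    """Attach SOCs to every report; unmapped PTs are logged and excluded from
    SOC-level counting (but kept for PT-level counting)."""
    if not dictionary:
        raise ValueError("empty MedDRA dictionary")
    unmapped: set[str] = set()
    out = []
    for r in rs.reports:
        socs = set()
        for pt in r.pts:
            soc = dictionary.get(pt)
            if soc is None:
                unmapped.add(pt)
            else:
                socs.add(soc)
        out.append(replace(r, socs=socs, pts=set(r.pts), drug_entries=list(r.drug_entries)))
    if unmapped:
        log.warning("map_meddra: %d PTs not in dictionary: %s", len(unmapped), sorted(unmapped)[:10])
    return ReportSet(out, provenance=list(rs.provenance), dedup_applied=rs.dedup_applied,
                     unmapped_pts=unmapped)


def share(count: float, total: float) -> float:
    """Percentage share rounded to two decimals (count / total * 100)."""
    if total == 0:
        return float("nan")
    return round(count / total * 100.0, 2)


def _age_band(age: float | None) -> str:
    if age is None:
        return "missing"
    if age < 18:
        return "<18"
    if age < 65:
        return "18-64.9"
    if age <= 85:
        return "65-85"
    return ">85"


def descriptive_summary(rs: ReportSet, drugs: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-drug and overall counts/percentages for sex, age band, reporter
    type and country (clinical-characteristics table).

    Returns a long-form frame with columns ``block, category`` and, per
    column group ``g`` in the drug list plus ``overall``: ``{g}_n, {g}_pct``.
    Percentages are count / column total * 100 rounded to 2 decimals.
    """
    if len(rs) == 0:
        log.warning("descriptive_summary: empty report set")
        return pd.DataFrame(columns=["block", "category"])
    if drugs is None:
        drugs = sorted({d for r in rs for d in r.target_drugs})
    groups: dict[str, list[AdverseEventReport]] = {
        d: [r for r in rs if d in r.target_drugs] for d in drugs
    }
    groups["overall"] = list(rs.reports)

    def categories(block: str) -> list[str]:
        if block == "sex":
            return ["F", "M", "missing"]
        if block == "age":
            return list(AGE_BANDS)
        if block == "reporter":
            cats = sorted({r.reporter_type for r in rs if r.reporter_type})
            return cats + ["missing"]
        if block == "country":
            cats = sorted({r.country for r in rs if r.country})
            return cats + ["missing"]
        raise ValueError(block)

    def value(r: AdverseEventReport, block: str) -> str:
        if block == "sex":
            return r.sex or "missing"
        if block == "age":
            return _age_band(r.age_years)
        if block == "reporter":
            return r.reporter_type or "missing"
        return r.country or "missing"

    rows = []
    # Leading block: report counts per drug as share of the overall total.
    total = len(groups["overall"])
    row: dict[str, object] = {"block": "reports", "category": "n"}
    for g, members in groups.items():
        row[f"{g}_n"] = len(members)
        row[f"{g}_pct"] = share(len(members), total)
    rows.append(row)
    for block in ("sex", "age", "reporter", "country"):
        for cat in categories(block):
            row = {"block": block, "category": cat}
            for g, members in groups.items():
                n = sum(1 for r in members if value(r, block) == cat)
                row[f"{g}_n"] = n
                row[f"{g}_pct"] = share(n, len(members)) if members else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
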