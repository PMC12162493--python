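"""Ground-truthed synthetic spontaneous-reporting database in FAERS dialect.

Spontaneous-reporting systems such as FAERS release quarterly ``$``-delimited
ASCII tables (DEMO, DRUG, REAC, THER, ...).  Real extracts cannot be bundled,
so this module generates a database with the same structural quirks —
multi-version cases keyed by case id / primary id, one primary-suspect (PS)
drug per report plus concomitants, multiple MedDRA preferred terms (PTs) per
report, demographic missingness, and YYYYMMDD dates that may be partial,
missing or inconsistent — on top of a background of exact drug–event
independence with *planted* associated pairs at known relative risk.

Every report draws each PT independently (Bernoulli) at a base probability
``background_pt_rate / n_PTs``; for a planted ``(drug, PT, RR)`` triple the
probability of that PT is multiplied by RR (clipped to 1) whenever the
report's PS drug is the planted drug.  The ground truth — planted pairs,
per-case assignments and the duplicate map — is returned as a manifest so
downstream deduplication, screening and time-to-onset stages can be checked
against it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "THER")
DELIM = "$"

# Canonical study drugs and their brand names (generic -> product).
DEFAULT_BRANDS: dict[str, str] = {
    "lecanemab": "LEQEMBI",
    "aducanumab": "ADUHELM",
}

DEFAULT_DRUGS: tuple[str, ...] = (
    "lecanemab",
    "aducanumab",
    "donepezil",
    "memantine",
    "rivastigmine",
    "galantamine",
    "metformin",
    "lisinopril",
    "atorvastatin",
    "omeprazole",
    "sertraline",
    "levothyroxine",
)

# A small PT catalogue spanning the organ classes most relevant to anti-Abeta
# antibody safety (ARIA events, infusion reactions, neuro-psychiatric terms)
# plus general background terms.
DEFAULT_PT_CATALOG: tuple[tuple[str, str], ...] = (
    ("Amyloid related imaging abnormality-oedema/effusion", "Nervous system disorders"),
    ("Amyloid related imaging abnormality-microhaemorrhages and haemosiderin deposits", "Nervous system disorders"),
    ("Cerebral microhaemorrhage", "Nervous system disorders"),
    ("Superficial siderosis of central nervous system", "Nervous system disorders"),
    ("Headache", "Nervous system disorders"),
    ("Dizziness", "Nervous system disorders"),
    ("Seizure", "Nervous system disorders"),
    ("Somnolence", "Nervous system disorders"),
    ("Tremor", "Nervous system disorders"),
    ("Aphasia", "Nervous system disorders"),
    ("Memory impairment", "Nervous system disorders"),
    ("Chills", "General disorders and administration site conditions"),
    ("Fatigue", "General disorders and administration site conditions"),
    ("Pyrexia", "General disorders and administration site conditions"),
    ("Infusion related reaction", "General disorders and administration site conditions"),
    ("Feeling cold", "General disorders and administration site conditions"),
    ("Influenza like illness", "General disorders and administration site conditions"),
    ("Confusional state", "Psychiatric disorders"),
    ("Disorientation", "Psychiatric disorders"),
    ("Anger", "Psychiatric disorders"),
    ("Abnormal dreams", "Psychiatric disorders"),
    ("Insomnia", "Psychiatric disorders"),
    ("Nausea", "Gastrointestinal disorders"),
    ("Diarrhoea", "Gastrointestinal disorders"),
    ("Vomiting", "Gastrointestinal disorders"),
    ("Atrial fibrillation", "Cardiac disorders"),
    ("Palpitations", "Cardiac disorders"),
    ("Blood pressure increased", "Investigations"),
    ("Weight decreased", "Investigations"),
    ("Fall", "Injury, poisoning and procedural complications"),
    ("Head injury", "Injury, poisoning and procedural complications"),
)

# Planted drug-event associations emulating the qualitative signal pattern of
# anti-Abeta antibodies (ARIA terms strongest, infusion-type and neuro terms
# moderate).  Relative risks are bounded by the Bernoulli mechanism
# (base_p * RR must stay below 1), so they are far smaller than the extreme
# real-world ARIA disproportionality.
DEFAULT_PLANTED: tuple[tuple[str, str, float], ...] = (
    ("lecanemab", "Amyloid related imaging abnormality-oedema/effusion", 12.0),
    ("lecanemab", "Amyloid related imaging abnormality-microhaemorrhages and haemosiderin deposits", 10.0),
    ("lecanemab", "Infusion related reaction", 8.0),
    ("lecanemab", "Chills", 6.0),
    ("lecanemab", "Headache", 3.0),
    ("aducanumab", "Amyloid related imaging abnormality-oedema/effusion", 14.0),
    ("aducanumab", "Amyloid related imaging abnormality-microhaemorrhages and haemosiderin deposits", 12.0),
    ("aducanumab", "Cerebral microhaemorrhage", 8.0),
    ("aducanumab", "Headache", 2.5),
)


class ConfigurationError(ValueError):
    """Invalid synthetic-database configuration."""


@dataclass(frozen=True)
class TTOSpec:
    """Per-drug time-to-onset distribution (days).

    ``lognormal`` draws ``median_days * exp(sigma * Z)``; the median of the
    drawn distribution is therefore exactly ``median_days``.
    """

    family: str = "lognormal"
    median_days: float = 60.0
    sigma: float = 0.6

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family != "lognormal":
            raise ConfigurationError(f"unknown TTO family {self.family!r}")
        return self.median_days * np.exp(self.sigma * rng.standard_normal(size))


# Median onset targets: fast for lecanemab (~33 d), slow for aducanumab
# (~146 d), generic background drugs in between.
DEFAULT_TTO: dict[str, TTOSpec] = {
    "lecanemab": TTOSpec(median_days=33.0),
    "aducanumab": TTOSpec(median_days=146.0),
}
_FALLBACK_TTO = TTOSpec(median_days=60.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic spontaneous-reporting database."""

    n_cases: int = 20_000
    drugs: tuple[str, ...] = DEFAULT_DRUGS
    target_drugs: tuple[str, ...] = ("lecanemab", "aducanumab")
    brand_names: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_BRANDS))
    pt_catalog: tuple[tuple[str, str], ...] = DEFAULT_PT_CATALOG
    planted_signals: tuple[tuple[str, str, float], ...] = ()
    background_pt_rate: float = 2.0
    duplicate_rate: float = 0.05
    missing_sex_rate: float = 0.07
    missing_age_rate: float = 0.26
    missing_date_rate: float = 0.10
    partial_date_rate: float = 0.05
    unreasonable_date_rate: float = 0.01
    tto_distributions: Mapping[str, TTOSpec] = field(default_factory=lambda: dict(DEFAULT_TTO))
    date_window: tuple[str, str] = ("20040101", "20240630")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ConfigurationError("n_cases must be positive")
        if not self.drugs:
            raise ConfigurationError("drug list is empty")
        if not self.pt_catalog:
            raise ConfigurationError("PT catalogue is empty")
        if not set(self.target_drugs) <= set(self.drugs):
            raise ConfigurationError("target_drugs must be a subset of drugs")
        pts = {p for p, _ in self.pt_catalog}
        for drug, pt, rr in self.planted_signals:
            if drug not in self.drugs or pt not in pts:
                raise ConfigurationError(f"planted pair ({drug!r}, {pt!r}) not in drugs x pt_catalog")
            if rr < 1:
                raise ConfigurationError("planted relative risk must be >= 1")
        for name in (
            "duplicate_rate", "missing_sex_rate", "missing_age_rate",
            "missing_date_rate", "partial_date_rate", "unreasonable_date_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.background_pt_rate <= 0:
            raise ConfigurationError("background_pt_rate must be positive")
        lo, hi = self.date_window
        if _parse_ymd(lo) > _parse_ymd(hi):
            raise ConfigurationError("date_window start must not exceed end")


@dataclass
class GroundTruthManifest:
    """Per-case ground truth emitted alongside the synthetic tables."""

    planted_signals: list[tuple[str, str, float]]
    caseids: list[str]
    ps_drug: list[str]
    pts: list[list[str]]
    sex: list[str]  # "F"/"M"/"" as emitted (before missingness the truth is F/M)
    tto_days: list[int]
    duplicate_map: dict[str, list[str]]  # caseid -> all primaryids (only >1 version)
    latest_primaryid: dict[str, str]  # caseid -> retained version

    @property
    def latest_primaryids(self) -> set[str]:
        return set(self.latest_primaryid.values())

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _parse_ymd(s: str) -> date:
    return date(int(s[:4]), int(s[4:6]), int(s[6:8]))


def _ordinal_to_ymd(ordinals: np.ndarray) -> list[str]:
    return [date.fromordinal(int(o)).strftime("%Y%m%d") for o in ordinals]


def generate_dataset(config: SyntheticConfig) -> tuple[dict[str, pd.DataFrame], GroundTruthManifest]:
    """Generate the four FAERS-dialect tables plus the ground-truth manifest.

    Identical ``config`` (including ``seed``) reproduces identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drugs = list(config.drugs)
    pt_names = [p for p, _ in config.pt_catalog]
    n_pt = len(pt_names)

    caseids = np.arange(10_000_001, 10_000_001 + n)
    ps_idx = rng.integers(0, len(drugs), size=n)

    # PT inclusion: independent Bernoulli per (report, PT); planted pairs
    # multiply the base probability by their relative risk (clipped to 1).
    base_p = config.background_pt_rate / n_pt
    prob = np.full((n, n_pt), base_p)
    for drug, pt, rr in config.planted_signals:
        di, pi = drugs.index(drug), pt_names.index(pt)
        prob[ps_idx == di, pi] = min(base_p * rr, 1.0)
    pt_mask = rng.random((n, n_pt)) < prob

    # Demographics.
    sex_true = np.where(rng.random(n) < 0.55, "F", "M")
    sex = np.where(rng.random(n) < config.missing_sex_rate, "", sex_true)
    age = np.clip(np.round(rng.normal(74.0, 10.0, size=n)), 18, 99).astype(int)
    age_str = np.where(rng.random(n) < config.missing_age_rate, "", age.astype(str))
    occp = rng.choice(np.array(["CN", "MD", "HP", "PH", ""]), size=n,
                      p=[0.47, 0.31, 0.19, 0.02, 0.01])
    country = rng.choice(np.array(["US", "JP", "FR", "CA", "GB", ""]), size=n,
                         p=[0.90, 0.03, 0.02, 0.02, 0.02, 0.01])

    # Dates: event uniform in the window; therapy start = event - TTO draw.
    lo_ord, hi_ord = _parse_ymd(config.date_window[0]).toordinal(), _parse_ymd(config.date_window[1]).toordinal()
    event_ord = rng.integers(lo_ord, hi_ord + 1, size=n)
    tto = np.empty(n)
    for di, drug in enumerate(drugs):
        m = ps_idx == di
        spec = config.tto_distributions.get(drug, _FALLBACK_TTO)
        tto[m] = spec.draw(rng, int(m.sum()))
    tto_days = np.maximum(np.round(tto), 0).astype(int)
    start_ord = event_ord - tto_days
    # "Unreasonable" dates: therapy start after the event (negative interval).
    bad = rng.random(n) < config.unreasonable_date_rate
    start_ord = np.where(bad, event_ord + np.maximum(tto_days, 1), start_ord)
    start_ord = np.maximum(start_ord, date(1900, 1, 2).toordinal())

    event_str = np.array(_ordinal_to_ymd(event_ord))
    start_str = np.array(_ordinal_to_ymd(start_ord))
    for arr in (event_str, start_str):
        miss = rng.random(n) < config.missing_date_rate
        part = (rng.random(n) < config.partial_date_rate) & ~miss
        trunc = np.where(rng.random(n) < 0.5, 6, 4)  # YYYYMM or YYYY
        arr[miss] = ""
        arr[part] = [s[:t] for s, t in zip(arr[part], trunc[part])]

    # Case versions: duplicated cases are re-emitted under a larger primaryid
    # with only reporter/country perturbed (drugs and PTs unchanged).
    dup = rng.random(n) < config.duplicate_rate
    pid_v1 = caseids * 10 + 1
    pid_v2 = caseids * 10 + 2
    occp_v2 = rng.choice(np.array(["CN", "MD", "HP", "PH", ""]), size=n,
                         p=[0.47, 0.31, 0.19, 0.02, 0.01])
    country_v2 = rng.choice(np.array(["US", "JP", "FR", "CA", "GB", ""]), size=n,
                            p=[0.90, 0.03, 0.02, 0.02, 0.02, 0.01])

    def _demo_frame(pids, idx, occp_arr, country_arr):
        return pd.DataFrame({
            "primaryid": pids.astype(str),
            "caseid": caseids[idx].astype(str),
            "event_dt": event_str[idx],
            "sex": sex[idx],
            "age": age_str[idx],
            "age_cod": np.where(age_str[idx] == "", "", "YR"),
            "occp_cod": occp_arr[idx],
            "occr_country": country_arr[idx],
        })

    all_idx = np.arange(n)
    demo = pd.concat(
        [_demo_frame(pid_v1, all_idx, occp, country),
         _demo_frame(pid_v2[dup], all_idx[dup], occp_v2, country_v2)],
        ignore_index=True,
    ).sort_values("primaryid", kind="stable").reset_index(drop=True)

    # DRUG: the PS row (seq 1) plus 0-2 concomitants per report.
    brands = dict(config.brand_names)
    drugname = np.array([d.upper() for d in drugs])[ps_idx]
    prodname = np.array([brands.get(d, d.upper()) for d in drugs])[ps_idx]
    n_conc = rng.integers(0, 3, size=n)
    conc_shift = rng.integers(1, max(len(drugs), 2), size=int(n_conc.sum()))
    conc_case = np.repeat(all_idx, n_conc)
    conc_idx = (ps_idx[conc_case] + conc_shift) % len(drugs)
    conc_seq = np.concatenate([np.arange(2, 2 + k) for k in n_conc]) if n_conc.sum() else np.array([], dtype=int)

    def _drug_rows(pids, idx):
        ps_rows = pd.DataFrame({
            "primaryid": pids[idx].astype(str),
            "drug_seq": "1",
            "role_cod": "PS",
            "drugname": drugname[idx],
            "prodname": prodname[idx],
        })
        sel = np.isin(conc_case, idx)
        cc = conc_case[sel]
        conc_rows = pd.DataFrame({
            "primaryid": pids[cc].astype(str),
            "drug_seq": conc_seq[sel].astype(str),
            "role_cod": "C",
            "drugname": np.array([d.upper() for d in drugs])[conc_idx[sel]],
            "prodname": np.array([brands.get(d, d.upper()) for d in drugs])[conc_idx[sel]],
        })
        return pd.concat([ps_rows, conc_rows], ignore_index=True)

    drug_tab = pd.concat(
        [_drug_rows(pid_v1, all_idx), _drug_rows(pid_v2, all_idx[dup])],
        ignore_index=True,
    ).sort_values(["primaryid", "drug_seq"], kind="stable").reset_index(drop=True)

    # REAC: one row per (report version, PT).
    rep_i, pt_i = np.nonzero(pt_mask)

    def _reac_rows(pids, keep_mask):
        sel = keep_mask[rep_i]
        return pd.DataFrame({
            "primaryid": pids[rep_i[sel]].astype(str),
            "pt": np.array(pt_names, dtype=object)[pt_i[sel]],
        })

    keep_all = np.ones(n, dtype=bool)
    reac = pd.concat([_reac_rows(pid_v1, keep_all), _reac_rows(pid_v2, dup)],
                     ignore_index=True).sort_values(["primaryid", "pt"], kind="stable").reset_index(drop=True)

    ther = pd.concat([
        pd.DataFrame({"primaryid": pid_v1.astype(str), "dsg_drug_seq": "1", "start_dt": start_str}),
        pd.DataFrame({"primaryid": pid_v2[dup].astype(str), "dsg_drug_seq": "1", "start_dt": start_str[dup]}),
    ], ignore_index=True).sort_values("primaryid", kind="stable").reset_index(drop=True)

    manifest = GroundTruthManifest(
        planted_signals=[tuple(s) for s in config.planted_signals],
        caseids=[str(c) for c in caseids],
        ps_drug=[drugs[i] for i in ps_idx],
        pts=[[pt_names[j] for j in np.nonzero(pt_mask[i])[0]] for i in range(n)],
        sex=list(sex),
        tto_days=[int(t) for t in tto_days],
        duplicate_map={str(c): [str(p1), str(p2)] for c, p1, p2 in zip(caseids[dup], pid_v1[dup], pid_v2[dup])},
        latest_primaryid={str(c): str(p2 if d else p1) for c, p1, p2, d in zip(caseids, pid_v1, pid_v2, dup)},
    )
    tables = {"DEMO": demo, "DRUG": drug_tab, "REAC": reac, "THER": ther}
    return tables, manifest


def generate_meddra_dictionary(config: SyntheticConfig) -> pd.DataFrame:
    """Two-column PT -> SOC mapping table for the configured catalogue.

    Stands in for the licensed MedDRA dictionary, which cannot be bundled.
    """
    if not config.pt_catalog:
        raise ConfigurationError("PT catalogue is empty")
    seen: dict[str, str] = {}
    for pt, soc in config.pt_catalog:
        if pt in seen and seen[pt] != soc:
            raise ConfigurationError(f"PT {pt!r} mapped to conflicting SOCs {seen[pt]!r} and {soc!r}")
        seen[pt] = soc
    return pd.DataFrame({"pt": list(seen), "soc": [seen[p] for p in seen]})


def write_dataset(tables: Mapping[str, pd.DataFrame], manifest: GroundTruthManifest,
                  outdir: str | Path) -> dict[str, Path]:
    """Write '$'-delimited tables and the JSON manifest; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in TABLE_NAMES:
        p = outdir / f"{name}.txt"
        tables[name].to_csv(p, sep=DELIM, index=False, lineterminator="\n")
        paths[name] = p
    mpath = outdir / "manifest.json"
    mpath.write_text(manifest.to_json())
    paths["manifest"] = mpath
    return paths


def write_meddra_dictionary(mapping: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mapping.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path
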