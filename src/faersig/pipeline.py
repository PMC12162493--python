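"""End-to-end orchestration: simulate -> ingest -> screen -> stratify -> TTO.

One :class:`RunConfig` drives a fully deterministic run: either a synthetic
database is generated (``synthetic`` mode) or existing FAERS-dialect files
are read (``input_tables`` mode), then the cleaning, screening, stratified
and time-to-onset stages execute in order, writing delimited-text artifacts,
optional figures, and a JSON run manifest (config hash, seed, per-stage row
counts).  Identical config + seed reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .contingency import enumerate_tables, make_background
from .disproportionality import DEFAULT_CRITERIA, SignalCriteria, screen_signals
from .ingest import (DEFAULT_STUDY_KEYWORDS, ReportSet, deduplicate,
                     descriptive_summary, filter_primary_suspect, map_meddra,
                     parse_faers_tables, read_meddra_dictionary,
                     reports_from_frames)
from .stratified import (StratumMatrix, cluster_order, log_ror_matrix,
                         matrix_to_frame, stratified_signals)
from .synthetic import (SyntheticConfig, generate_dataset,
                        generate_meddra_dictionary, write_dataset,
                        write_meddra_dictionary)
from .tto import compare_tto, compute_tto_records, tto_summary

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: Path
    synthetic: SyntheticConfig | None = None
    input_tables: Mapping[str, Path] | None = None
    meddra_path: Path | None = None
    keywords: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_STUDY_KEYWORDS))
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    min_a_pt: int = 3
    log_base: float = 10.0
    stratify: bool = True
    tto_test: str = "mannwhitney"
    make_figures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if (self.synthetic is None) == (self.input_tables is None):
            raise ValueError("exactly one of synthetic / input_tables must be set")
        if self.input_tables is not None and self.meddra_path is None:
            raise ValueError("input_tables mode requires meddra_path")

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def run_pipeline(cfg: RunConfig) -> dict[str, object]:
    """Execute all stages; returns artifact paths and in-memory results."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    artifacts: dict[str, object] = {"outdir": out}

    # --- stage: data ---------------------------------------------------
    if cfg.synthetic is not None:
        syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        tables, manifest = generate_dataset(syn)
        datadir = out / "data"
        write_dataset(tables, manifest, datadir)
        meddra = generate_meddra_dictionary(syn)
        meddra_path = write_meddra_dictionary(meddra, datadir / "meddra.tsv")
        rs = reports_from_frames(tables)
        dictionary = dict(zip(meddra["pt"], meddra["soc"]))
        artifacts["ground_truth"] = manifest
    else:
        rs = parse_faers_tables(cfg.input_tables)
        dictionary = read_meddra_dictionary(cfg.meddra_path)
    counts["parsed_reports"] = len(rs)

    # --- stage: clean --------------------------------------------------
    rs = deduplicate(rs)
    counts["after_dedup"] = len(rs)
    target = filter_primary_suspect(rs, cfg.keywords)
    counts["target_reports"] = len(target)
    rs = map_meddra(rs, dictionary)
    target = map_meddra(target, dictionary)
    drugs = sorted(cfg.keywords)
    # "all other drugs" comparator: per target drug, every deduplicated
    # report whose PS drug is not that drug (the other study drug included)
    backgrounds = {
        d: make_background(rs, target.subset(lambda r, d=d: d in r.target_drugs))
        for d in drugs
    }
    counts["background_reports"] = len(make_background(rs, target))

    # --- stage: descriptive --------------------------------------------
    desc = descriptive_summary(target, drugs=drugs)
    artifacts["descriptive"] = _write_csv(desc, out / "descriptive.csv")

    # --- stage: signals ------------------------------------------------
    soc_frames, pt_frames = [], []
    for drug in drugs:
        drug_rs = target.subset(lambda r, d=drug: d in r.target_drugs)
        soc_tables = enumerate_tables(drug_rs, backgrounds[drug], drug, level="SOC",
                                      stratum="overall", min_a=1)
        pt_tables = enumerate_tables(drug_rs, backgrounds[drug], drug, level="PT",
                                     stratum="overall", min_a=cfg.min_a_pt)
        soc_frames.append(screen_signals(soc_tables, cfg.criteria))
        pt_frames.append(screen_signals(pt_tables, cfg.criteria))
    soc_signals = pd.concat(soc_frames, ignore_index=True) if soc_frames else pd.DataFrame()
    pt_signals = pd.concat(pt_frames, ignore_index=True) if pt_frames else pd.DataFrame()
    artifacts["soc_signals"] = _write_csv(soc_signals, out / "soc_signals.csv")
    artifacts["pt_signals"] = _write_csv(pt_signals, out / "pt_signals.csv")
    artifacts["pt_signals_frame"] = pt_signals
    artifacts["soc_signals_frame"] = soc_signals
    counts["consensus_positive_pts"] = int(pt_signals["consensus"].sum()) if len(pt_signals) else 0

    # --- stage: stratified ----------------------------------------------
    if cfg.stratify:
        strata = stratified_signals(target, backgrounds, drugs, cfg.criteria)
        for label, frame in strata.items():
            _write_csv(frame, out / f"stratum_{label}.csv")
        try:
            matrix = cluster_order(log_ror_matrix(strata, log_base=cfg.log_base))
            ordered = matrix_to_frame(matrix)
            ordered.to_csv(out / "log_ror_matrix.csv", lineterminator="\n")
            (out / "matrix_orders.json").write_text(json.dumps(
                {"rows": matrix.rows, "columns": matrix.columns,
                 "row_order": matrix.row_order, "col_order": matrix.col_order},
                indent=1))
            artifacts["matrix"] = matrix
            if cfg.make_figures:
                artifacts["heatmap"] = render_heatmap(matrix, out / "heatmap.png")
        except ValueError as exc:
            log.warning("stratified matrix skipped: %s", exc)

    # --- stage: time-to-onset -------------------------------------------
    records = compute_tto_records(target)
    summary = tto_summary(records, group_by="drug")
    summary_sex = tto_summary(records, group_by="drug_sex")
    artifacts["tto_summary"] = _write_csv(summary, out / "tto_summary.csv")
    artifacts["tto_summary_sex"] = _write_csv(summary_sex, out / "tto_summary_by_sex.csv")
    artifacts["tto_records"] = records
    comparisons = {}
    by_drug = {d: [r.tto_days for r in records if r.included and r.drug == d] for d in drugs}
    if all(len(v) > 0 for v in by_drug.values()) and len(drugs) == 2:
        stat, p, name = compare_tto(by_drug[drugs[0]], by_drug[drugs[1]], test=cfg.tto_test)
        comparisons[f"{drugs[0]}_vs_{drugs[1]}"] = {"statistic": stat, "p": p, "test": name}
    for d in drugs:
        f = [r.tto_days for r in records if r.included and r.drug == d and r.sex == "F"]
        m = [r.tto_days for r in records if r.included and r.drug == d and r.sex == "M"]
        if f and m:
            stat, p, name = compare_tto(f, m, test=cfg.tto_test)
            comparisons[f"{d}_F_vs_M"] = {"statistic": stat, "p": p, "test": name}
    (out / "tto_comparisons.json").write_text(json.dumps(comparisons, indent=1))
    artifacts["tto_comparisons"] = comparisons
    if cfg.make_figures:
        artifacts["tto_figure"] = render_tto_figure(records, drugs, out / "tto_boxplot.png")

    # --- manifest --------------------------------------------------------
    manifest_doc = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "criteria": dataclasses.asdict(cfg.criteria),
        "min_a_pt": cfg.min_a_pt,
        "log_base": cfg.log_base,
        "stage_counts": counts,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest_doc, indent=1, sort_keys=True))
    artifacts["counts"] = counts
    return artifacts


def render_heatmap(matrix: StratumMatrix, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = matrix_to_frame(matrix)
    fig, ax = plt.subplots(figsize=(6, max(3, 0.3 * len(ordered))))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(ordered.columns)), ordered.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(ordered.index)), ordered.index, fontsize=6)
    fig.colorbar(im, ax=ax, label=f"log{matrix.log_base:g}(ROR)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def render_tto_figure(records, drugs: Sequence[str], path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups, labels = [], []
    for d in drugs:
        for sex in ("F", "M"):
            vals = [r.tto_days for r in records if r.included and r.drug == d and r.sex == sex]
            if vals:
                groups.append(vals)
                labels.append(f"{d}-{sex}")
    fig, ax = plt.subplots(figsize=(6, 4))
    if groups:
        ax.boxplot(groups, tick_labels=labels)
    ax.set_ylabel("time to onset (days)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _md_table(df: pd.DataFrame, max_rows: int = 40) -> str:
    df = df.head(max_rows)
    if df.empty:
        return "_(empty)_\n"
    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    sep = "|" + "---|" * len(df.columns)
    body = ["| " + " | ".join(str(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *body]) + "\n"


def render_report(outdir: str | Path) -> Path:
    """Render the run's artifacts as a single Markdown report."""
    out = Path(outdir)
    sections = ["# Disproportionality analysis report\n"]

    def add(title: str, fname: str, formatter=None):
        sections.append(f"## {title}\n")
        p = out / fname
        if not p.exists():
            sections.append("_(artifact absent)_\n")
            return
        if fname.endswith(".json"):
            sections.append("```json\n" + p.read_text() + "\n```\n")
        else:
            df = pd.read_csv(p)
            if formatter:
                df = formatter(df)
            sections.append(_md_table(df))

    def signal_view(df: pd.DataFrame) -> pd.DataFrame:
        keep = [c for c in ("drug", "stratum", "term", "a", "ROR (95% CI)",
                            "PRR (chi2)", "EBGM (EBGM05)", "IC (IC025)", "consensus")
                if c in df.columns]
        view = df[keep] if keep else df
        return view.rename(columns={"a": "Frequency"})

    add("Descriptive characteristics", "descriptive.csv")
    add("SOC-level signals", "soc_signals.csv", signal_view)
    add("PT-level signals", "pt_signals.csv", signal_view)
    pt_path = out / "pt_signals.csv"
    if pt_path.exists():
        pt = pd.read_csv(pt_path)
        n_pos = int(pt["consensus"].sum()) if len(pt) else 0
        sections.append(f"Consensus-positive PT signals: **{n_pos}**\n")
        if n_pos == 0:
            sections.append("No PT met all four algorithm criteria simultaneously.\n")
    add("Sex-stratified log-ROR matrix", "log_ror_matrix.csv")
    add("Time to onset", "tto_summary.csv")
    add("Time to onset by sex", "tto_summary_by_sex.csv")
    add("Group comparisons", "tto_comparisons.json")
    add("Run manifest", "run_manifest.json")
    path = out / "report.md"
    path.write_text("\n".join(sections))
    return path
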