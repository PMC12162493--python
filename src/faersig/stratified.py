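"""Sex-stratified PT-level screening and the clustered log-ROR matrix.

Signals are recomputed within each drug x sex stratum (both the target and
the comparator restricted to the stratum's sex; missing-sex reports excluded)
and the PT x stratum matrix of log-transformed RORs is assembled for the
cluster heatmap.  A stratum where a PT is never reported (a = 0, ROR of 0 /
undefined) receives the substitute value 0.01 before the log, so every cell
is finite: with base-10 logs such cells are exactly -2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .contingency import BackgroundSet, enumerate_tables
from .disproportionality import DEFAULT_CRITERIA, SignalCriteria, screen_signals
from .ingest import ReportSet

log = logging.getLogger(__name__)

SEXES = ("F", "M")
ZERO_SUBSTITUTE = 0.01


@dataclass
class StratumMatrix:
    """PT x stratum log-ROR values plus hierarchical-clustering leaf orders."""

    values: pd.DataFrame  # index: PT labels; columns: stratum labels
    log_base: float = 10.0
    row_order: list[int] = field(default_factory=list)
    col_order: list[int] = field(default_factory=list)

    @property
    def rows(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)


def stratified_signals(target: ReportSet,
                       background: BackgroundSet | Mapping[str, BackgroundSet],
                       drugs: Sequence[str],
                       criteria: SignalCriteria = DEFAULT_CRITERIA,
                       min_a: int = 1) -> dict[str, pd.DataFrame]:
    """PT-level screening within each drug x sex stratum.

    Returns ``{"<drug>-<sex>": signal frame}``.  ``background`` is either one
    comparator set shared by every drug or a per-drug mapping (the "all other
    drugs" universe differs per target drug).  ``min_a`` defaults to 1 so
    that sub-threshold RORs remain available to the matrix; positivity still
    applies the full criteria (including a >= 3).
    """
    out: dict[str, pd.DataFrame] = {}
    for drug in drugs:
        drug_reports = target.subset(lambda r, d=drug: d in r.target_drugs)
        bg = background[drug] if isinstance(background, Mapping) else background
        for sex in SEXES:
            label = f"{drug}-{sex}"
            tables = enumerate_tables(drug_reports, bg, drug,
                                      level="PT", stratum=sex, min_a=min_a)
            if not tables:
                log.warning("stratified_signals: empty stratum %s", label)
            out[label] = screen_signals(tables, criteria)
    return out


def _cell_value(frame: pd.DataFrame, pt: str, log_base: float) -> float:
    row = frame[frame["term"] == pt]
    if row.empty or int(row["a"].iloc[0]) == 0:
        val = ZERO_SUBSTITUTE  # PT never reported in this stratum
    else:
        r = float(row["ror"].iloc[0])
        if math.isnan(r):
            # a > 0 but a zero b/c cell: display with a Haldane 0.5 correction
            a, b, c, d = (float(row[k].iloc[0]) for k in "abcd")
            r = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        val = r if r > 0 else ZERO_SUBSTITUTE
    if log_base == 10.0:
        return math.log10(val)  # exact -2.0 for the 0.01 substitute
    if log_base == 2.0:
        return math.log2(val)
    return math.log(val, log_base)


def log_ror_matrix(stratum_tables: Mapping[str, pd.DataFrame],
                   log_base: float = 10.0) -> StratumMatrix:
    """Assemble the PT x stratum matrix of log RORs.

    Rows are the union of consensus-positive PTs over all strata; a PT
    positive in one stratum but present with a valid ROR in another uses that
    ROR as-is.
    """
    positive_pts = sorted({
        pt for frame in stratum_tables.values()
        for pt in frame.loc[frame["consensus"], "term"]
    })
    if not positive_pts:
        raise ValueError("no consensus-positive PT in any stratum")
    cols = list(stratum_tables)
    values = pd.DataFrame(
        [[_cell_value(stratum_tables[c], pt, log_base) for c in cols] for pt in positive_pts],
        index=positive_pts, columns=cols,
    )
    m = StratumMatrix(values=values, log_base=log_base)
    m.row_order = list(range(len(positive_pts)))
    m.col_order = list(range(len(cols)))
    return m


def _leaf_order(matrix: np.ndarray, labels: Sequence[str]) -> list[int]:
    """Average-linkage Euclidean leaf order, canonicalised by sorting labels
    first so the result is invariant to input row order."""
    k = len(labels)
    if k <= 1:
        return list(range(k))
    order = sorted(range(k), key=lambda i: labels[i])
    sorted_matrix = matrix[order]
    if k == 2:
        leaves = [0, 1]
    else:
        z = linkage(sorted_matrix, method="average", metric="euclidean")
        leaves = list(leaves_list(z))
    return [order[i] for i in leaves]


def cluster_order(m: StratumMatrix) -> StratumMatrix:
    """Set row/col leaf orders from hierarchical agglomerative clustering."""
    if m.values.empty:
        raise ValueError("empty matrix")
    vals = m.values.to_numpy(dtype=float)
    m.row_order = _leaf_order(vals, m.rows)
    m.col_order = _leaf_order(vals.T, m.columns)
    return m


def matrix_to_frame(m: StratumMatrix) -> pd.DataFrame:
    """Export view: labelled values in clustered order."""
    return m.values.iloc[m.row_order, m.col_order]
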