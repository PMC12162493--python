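"""The four signal-detection statistics and the consensus rule.

For a 2x2 report-count table (a, b, c, d) with N = a+b+c+d:

* ROR (reporting odds ratio) ``= ad/bc`` with Wald 95% CI
  ``exp(ln ROR ± z sqrt(1/a+1/b+1/c+1/d))``; positive when the CI lower
  bound exceeds 1 and a >= 3.
* PRR (proportional reporting ratio) ``= [a/(a+b)] / [c/(c+d)]`` with the
  uncorrected Pearson chi-square
  ``(ad-bc)^2 N / [(a+b)(c+d)(a+c)(b+d)]``; positive when PRR >= 2,
  chi2 >= 4 and a >= 3.
* BCPNN information component: shrinkage constant
  ``gamma = (N+2)^2 / [(a+b+1)(a+c+1)]``, posterior mean
  ``EIC = log2[(a+1)(N+2)^2 / ((N+gamma)(a+b+1)(a+c+1))]``, posterior
  variance ``VIC = (1/ln 2)^2 [ (b+c+d+gamma-1)/((a+1)(N+gamma+1))
  + (c+d+1)/((a+b+1)(N+3)) + (b+d+1)/((a+c+1)(N+3)) ]`` and lower bound
  ``IC025 = EIC - 2 sqrt(VIC)``; positive when IC025 > 0.
* MGPS closed-form empirical Bayes geometric mean
  ``EBGM = aN/((a+c)(a+b))`` with lower bound
  ``EBGM05 = exp(ln EBGM - z sqrt(1/a+1/b+1/c+1/d))``; positive when
  EBGM05 >= 2 and a > 0.

A (drug, term) pair is a *consensus-positive* signal only when all four
algorithms flag it simultaneously — the conjunction of one-sensitive
frequentist screens and more conservative Bayesian shrinkage keeps the
false-positive rate low.  No continuity correction is applied anywhere;
statistics whose formula divides by a zero cell are reported as undefined
(never positive) rather than corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .contingency import ContingencyTable

_LN2 = math.log(2.0)
NAN = float("nan")


@dataclass(frozen=True)
class SignalCriteria:
    """Positivity thresholds and z-values (defaults = the standard criteria)."""

    min_a: int = 3
    ror_ci_lower: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ebgm05_min: float = 2.0
    ic025_min: float = 0.0
    z: float = 1.96
    #: z for the EBGM lower bound; 1.96 as printed in the source criteria,
    #: 1.645 would be the conventional one-sided 95% value.
    z_ebgm: float = 1.96

    def __post_init__(self) -> None:
        if self.z <= 0 or self.z_ebgm <= 0:
            raise ValueError("z values must be positive")


DEFAULT_CRITERIA = SignalCriteria()


@dataclass(frozen=True)
class AlgorithmResult:
    algorithm: str  # ROR | PRR | BCPNN | MGPS
    point: float
    interval: tuple[float, float] | None
    auxiliary: Mapping[str, float]
    positive: bool
    defined: bool


@dataclass(frozen=True)
class SignalResult:
    table: ContingencyTable
    results: Mapping[str, AlgorithmResult]
    consensus_positive: bool


def _wald_se(a: float, b: float, c: float, d: float) -> float:
    return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def ror(t: ContingencyTable, criteria: SignalCriteria = DEFAULT_CRITERIA) -> AlgorithmResult:
    a, b, c, d = t.cells()
    if min(a, b, c, d) == 0:
        return AlgorithmResult("ROR", NAN, None, {}, positive=False, defined=False)
    point = (a * d) / (b * c)
    half = criteria.z * _wald_se(a, b, c, d)
    lo, hi = math.exp(math.log(point) - half), math.exp(math.log(point) + half)
    positive = lo > criteria.ror_ci_lower and a >= criteria.min_a
    return AlgorithmResult("ROR", point, (lo, hi), {}, positive=positive, defined=True)


def prr(t: ContingencyTable, criteria: SignalCriteria = DEFAULT_CRITERIA) -> AlgorithmResult:
    a, b, c, d = t.cells()
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = (a * d - b * c) ** 2 * n / denom if denom > 0 else NAN
    if c == 0 or a + b == 0 or c + d == 0:
        return AlgorithmResult("PRR", NAN, None, {"chi2": chi2}, positive=False, defined=False)
    point = (a / (a + b)) / (c / (c + d))
    interval = None
    if a > 0:
        se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        half = criteria.z * se
        interval = (math.exp(math.log(point) - half), math.exp(math.log(point) + half))
    positive = (point >= criteria.prr_min and not math.isnan(chi2)
                and chi2 >= criteria.chi2_min and a >= criteria.min_a)
    return AlgorithmResult("PRR", point, interval, {"chi2": chi2}, positive=positive, defined=True)


def bcpnn_ic(t: ContingencyTable, criteria: SignalCriteria = DEFAULT_CRITERIA) -> AlgorithmResult:
    a, b, c, d = t.cells()
    n = a + b + c + d
    gamma = (n + 2) ** 2 / ((a + b + 1) * (a + c + 1))
    eic = math.log2((a + 1) * (n + 2) ** 2 / ((n + gamma) * (a + b + 1) * (a + c + 1)))
    vic = (1 / _LN2) ** 2 * (
        (b + c + d + gamma - 1) / ((a + 1) * (n + gamma + 1))
        + (c + d + 1) / ((a + b + 1) * (n + 3))
        + (b + d + 1) / ((a + c + 1) * (n + 3))
    )
    ic025 = eic - 2 * math.sqrt(vic)
    positive = ic025 > criteria.ic025_min
    return AlgorithmResult("BCPNN", eic, (ic025, math.inf),
                           {"vic": vic, "gamma": gamma, "ic025": ic025},
                           positive=positive, defined=True)


def ebgm(t: ContingencyTable, criteria: SignalCriteria = DEFAULT_CRITERIA) -> AlgorithmResult:
    a, b, c, d = t.cells()
    n = a + b + c + d
    if (a + b) == 0 or (a + c) == 0:
        return AlgorithmResult("MGPS", NAN, None, {"ebgm05": NAN}, positive=False, defined=False)
    point = a * n / ((a + c) * (a + b))
    if min(a, b, c, d) == 0:
        return AlgorithmResult("MGPS", point, None, {"ebgm05": NAN}, positive=False, defined=False)
    half05 = criteria.z_ebgm * _wald_se(a, b, c, d)
    half = criteria.z * _wald_se(a, b, c, d)
    ebgm05 = math.exp(math.log(point) - half05)
    interval = (math.exp(math.log(point) - half), math.exp(math.log(point) + half))
    positive = ebgm05 >= criteria.ebgm05_min and a > 0
    return AlgorithmResult("MGPS", point, interval, {"ebgm05": ebgm05}, positive=positive, defined=True)


def evaluate_consensus(t: ContingencyTable,
                       criteria: SignalCriteria = DEFAULT_CRITERIA) -> SignalResult:
    """Run all four algorithms; the consensus flag is their conjunction."""
    results = {
        "ROR": ror(t, criteria),
        "PRR": prr(t, criteria),
        "BCPNN": bcpnn_ic(t, criteria),
        "MGPS": ebgm(t, criteria),
    }
    return SignalResult(table=t, results=results,
                        consensus_positive=all(r.positive for r in results.values()))


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and (math.isnan(x) or math.isinf(x))):
        return "NA"
    return f"{x:,.2f}"


def _fmt_pair(point: float, lo: float, hi: float | None = None) -> str:
    if hi is None:
        return f"{_fmt(point)} ({_fmt(lo)})"
    return f"{_fmt(point)} ({_fmt(lo)}–{_fmt(hi)})"


def screen_signals(tables: Iterable[ContingencyTable],
                   criteria: SignalCriteria = DEFAULT_CRITERIA) -> pd.DataFrame:
    """Evaluate every table; one row per table with raw statistics, formatted
    2-decimal rendering, per-algorithm flags and the consensus flag."""
    rows = []
    for t in tables:
        s = evaluate_consensus(t, criteria)
        r_ror, r_prr, r_ic, r_eb = (s.results[k] for k in ("ROR", "PRR", "BCPNN", "MGPS"))
        lo, hi = r_ror.interval if r_ror.interval else (NAN, NAN)
        rows.append({
            "drug": t.drug, "level": t.level, "stratum": t.stratum, "term": t.term,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": r_ror.point, "ror_lo": lo, "ror_hi": hi,
            "prr": r_prr.point, "chi2": r_prr.auxiliary["chi2"],
            "ebgm": r_eb.point, "ebgm05": r_eb.auxiliary["ebgm05"],
            "eic": r_ic.point, "ic025": r_ic.auxiliary["ic025"],
            "ror_positive": r_ror.positive, "prr_positive": r_prr.positive,
            "bcpnn_positive": r_ic.positive, "mgps_positive": r_eb.positive,
            "consensus": s.consensus_positive,
            "ROR (95% CI)": _fmt_pair(r_ror.point, lo, hi),
            "PRR (chi2)": _fmt_pair(r_prr.point, r_prr.auxiliary["chi2"]),
            "EBGM (EBGM05)": _fmt_pair(r_eb.point, r_eb.auxiliary["ebgm05"]),
            "IC (IC025)": _fmt_pair(r_ic.point, r_ic.auxiliary["ic025"]),
        })
    cols = ["drug", "level", "stratum", "term", "a", "b", "c", "d",
            "ror", "ror_lo", "ror_hi", "prr", "chi2", "ebgm", "ebgm05",
            "eic", "ic025", "ror_positive", "prr_positive", "bcpnn_positive",
            "mgps_positive", "consensus", "ROR (95% CI)", "PRR (chi2)",
            "EBGM (EBGM05)", "IC (IC025)"]
    return pd.DataFrame(rows, columns=cols)
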