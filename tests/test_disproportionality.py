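"""The four screening statistics against frozen values, an exact-arithmetic
oracle, and their structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from faersig.contingency import ContingencyTable
from faersig.disproportionality import (SignalCriteria, bcpnn_ic, ebgm,
                                        evaluate_consensus, prr, ror,
                                        screen_signals)

from _oracle import oracle_stats


def table(a, b, c, d):
    return ContingencyTable("drugX", "termY", "PT", "overall", a, b, c, d)


class TestWorkedExamples:
    """Hand-derived values for the reference table a=20, b=10, c=10, d=20."""

    T = table(20, 10, 10, 20)

    def test_ror(self):
        r = ror(self.T)
        assert r.point == pytest.approx(4.0, abs=1e-12)
        assert r.interval[0] == pytest.approx(1.3672, abs=5e-4)
        assert r.interval[1] == pytest.approx(11.703, abs=5e-3)
        assert r.positive

    def test_prr(self):
        r = prr(self.T)
        assert r.point == pytest.approx(2.0, abs=1e-12)
        assert r.auxiliary["chi2"] == pytest.approx(20 / 3, abs=1e-12)
        assert r.positive

    def test_bcpnn(self):
        r = bcpnn_ic(self.T)
        assert r.auxiliary["gamma"] == pytest.approx(4.0, abs=1e-12)
        assert r.point == pytest.approx(0.3923, abs=5e-5)
        assert r.auxiliary["vic"] == pytest.approx(0.13164, abs=5e-6)
        assert r.auxiliary["ic025"] == pytest.approx(-0.3333, abs=5e-5)
        assert not r.positive

    def test_mgps(self):
        r = ebgm(self.T)
        assert r.point == pytest.approx(4 / 3, abs=1e-12)
        assert r.auxiliary["ebgm05"] == pytest.approx(0.4557, abs=5e-5)
        assert not r.positive

    def test_consensus_is_conjunction(self):
        s = evaluate_consensus(self.T)
        assert s.results["ROR"].positive and s.results["PRR"].positive
        assert not s.results["BCPNN"].positive and not s.results["MGPS"].positive
        assert not s.consensus_positive


class TestEdgeCases:
    def test_balanced_table_not_positive(self):
        assert ror(table(10, 10, 10, 10)).point == 1.0
        assert not ror(table(10, 10, 10, 10)).positive

    def test_zero_cell_makes_ror_undefined(self):
        r = ror(table(5, 0, 3, 7))
        assert not r.defined and not r.positive and math.isnan(r.point)

    def test_small_a_gates_ror_and_prr(self):
        # strongly elevated but a=2: both frequency methods stay negative
        t = table(2, 1, 1, 1000)
        assert not ror(t).positive
        assert not prr(t).positive
        assert not evaluate_consensus(t).consensus_positive

    def test_prr_conjunction_requires_chi2(self):
        # PRR above 2 but chi-square below 4 -> not positive
        t = table(3, 3, 5, 25)
        r = prr(t)
        assert r.point > 2 and r.auxiliary["chi2"] < 4
        assert not r.positive

    def test_empty_table_ic_shrinks_to_zero(self):
        r = bcpnn_ic(table(0, 0, 0, 0))
        assert r.auxiliary["gamma"] == pytest.approx(4.0)
        assert r.point == pytest.approx(0.0, abs=1e-14)

    def test_large_n_independence_ic_vanishes(self):
        r = bcpnn_ic(table(1000, 1000, 1000, 1000))
        assert abs(r.point) < 0.01

    def test_ebgm_zero_a(self):
        r = ebgm(table(0, 5, 5, 50))
        assert r.point == 0.0 and not r.positive

    def test_strong_table_consensus(self):
        s = evaluate_consensus(table(100, 10, 100, 10_000))
        assert s.results["ROR"].point == pytest.approx(1000.0)
        assert s.results["PRR"].point == pytest.approx((100 / 110) / (100 / 10100))
        assert s.consensus_positive


def test_oracle_equivalence_random_tables(rng):
    """1,000 random tables: every statistic matches the exact-arithmetic
    oracle to relative error < 1e-12."""
    keymap = {
        "ror": lambda t: ror(t).point, "ror_lo": lambda t: ror(t).interval[0],
        "ror_hi": lambda t: ror(t).interval[1],
        "prr": lambda t: prr(t).point, "chi2": lambda t: prr(t).auxiliary["chi2"],
        "gamma": lambda t: bcpnn_ic(t).auxiliary["gamma"],
        "eic": lambda t: bcpnn_ic(t).point,
        "vic": lambda t: bcpnn_ic(t).auxiliary["vic"],
        "ic025": lambda t: bcpnn_ic(t).auxiliary["ic025"],
        "ebgm": lambda t: ebgm(t).point,
        "ebgm05": lambda t: ebgm(t).auxiliary["ebgm05"],
    }
    worst = 0.0
    for _ in range(1000):
        a, b, c, d = (int(x) for x in rng.integers(0, 501, size=4))
        t = table(a, b, c, d)
        expected = oracle_stats(a, b, c, d)
        for key, fn in keymap.items():
            if key not in expected:
                continue
            got = fn(t)
            ref = expected[key]
            # relative error, with an absolute floor where the statistic
            # itself is a near-cancelling difference (e.g. IC025 ~ 0)
            err = abs(got - ref) / max(abs(ref), 1.0)
            worst = max(worst, err)
            assert err < 1e-12, (key, a, b, c, d, got, ref)
    assert worst < 1e-12


@given(st.integers(1, 300), st.integers(1, 300), st.integers(1, 300), st.integers(1, 300))
def test_ror_prr_strictly_monotone_in_a(a, b, c, d):
    """Adding a co-occurrence report strictly increases the two frequency
    statistics whenever all cells are positive."""
    t1, t2 = table(a, b, c, d), table(a + 1, b, c, d)
    assert ror(t2).point > ror(t1).point
    assert prr(t2).point > prr(t1).point


@given(st.integers(1, 10), st.integers(50, 300), st.integers(50, 300), st.integers(50, 300))
def test_shrinkage_statistics_monotone_in_sparse_regime(a, b, c, d):
    """EBGM and EIC shrink toward 1 (resp. 0) as a grows to dominate the
    margins, so strict monotonicity in a only holds while the co-occurrence
    count is small relative to both margins."""
    t1, t2 = table(a, b, c, d), table(a + 1, b, c, d)
    assert ebgm(t2).point > ebgm(t1).point
    assert bcpnn_ic(t2).point > bcpnn_ic(t1).point


@given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 20))
def test_independence_calibration(r1, r2, k):
    """Tables with exact product margins give ROR = PRR = EBGM = 1, chi2 = 0."""
    a, b, c, d = r1 * r2, r1 * k, r2 * k, k * k  # a*d == b*c by construction
    t = table(a, b, c, d)
    assert ror(t).point == pytest.approx(1.0 * a * d / (b * c))
    assert prr(t).point == pytest.approx(1.0)
    assert prr(t).auxiliary["chi2"] == 0.0
    assert ebgm(t).point == pytest.approx(1.0)


def test_interval_brackets_point():
    rng = np.random.default_rng(5)
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(1, 400, size=4))
        t = table(a, b, c, d)
        for res in (ror(t), prr(t), ebgm(t)):
            lo, hi = res.interval
            assert lo <= res.point <= hi
        ic = bcpnn_ic(t)
        assert ic.auxiliary["ic025"] <= ic.point


def test_ror_ci_coverage_null(rng):
    """Wald 95% CI covers the true null odds ratio in 95% +- 2% of binomial
    draws with expected cells >= 10."""
    m = 2000
    a = rng.binomial(200, 0.3, size=m)
    b = rng.binomial(400, 0.3, size=m)
    covered = 0
    for ai, bi in zip(a, b):
        t = table(int(ai), int(bi), int(200 - ai), int(400 - bi))
        r = ror(t)
        if r.defined and r.interval[0] <= 1.0 <= r.interval[1]:
            covered += 1
    assert 0.93 <= covered / m <= 0.97


def test_screen_signals_formatting_and_flags():
    frame = screen_signals([table(20, 10, 10, 20), table(100, 10, 100, 10_000)])
    assert len(frame) == 2
    row = frame.iloc[1]
    assert row["consensus"]
    assert row["ROR (95% CI)"].count("–") == 1
    # rendering uses 2 decimals with thousands separators
    t = table(751, 123, 141, 1_000_000)
    f = screen_signals([t]).iloc[0]
    lo, hi = ror(t).interval
    assert f["ROR (95% CI)"] == f"{ror(t).point:,.2f} ({lo:,.2f}–{hi:,.2f})"


def test_screen_signals_empty():
    assert screen_signals([]).empty


def test_threshold_overrides():
    crit = SignalCriteria(ebgm05_min=1.0)
    t = table(20, 10, 10, 20)
    assert not ebgm(t).positive
    assert not ebgm(t, crit).positive  # ebgm05 ~ 0.456 still below 1
    crit2 = SignalCriteria(ebgm05_min=0.4)
    assert ebgm(t, crit2).positive
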