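"""ROR point estimates, Woolf intervals, signal criteria and ranking."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aadsignal.cleaning import DrugDictionary
from aadsignal.errors import ConfigurationError
from aadsignal.signal_stats import (ContingencyTable, SignalResult,
                                    build_contingency, classify_signal,
                                    compute_ror, rank_signals, signal_table)

cells = st.integers(min_value=1, max_value=100_000)


def woolf_oracle(a, b, c, d):
    """Independent textbook Woolf interval: statsmodels supplies the log
    odds ratio and its standard error; the published fixed 1.96 multiplier
    is applied (statsmodels' own confint uses the exact normal quantile
    1.95996..., which is not the interval under test)."""
    from statsmodels.stats.contingency_tables import Table2x2

    t = Table2x2(np.array([[a, b], [c, d]]))
    lor, se = t.log_oddsratio, t.log_oddsratio_se
    return t.oddsratio, np.exp(lor - 1.96 * se), np.exp(lor + 1.96 * se)


class TestComputeRor:
    def test_independence_table(self):
        r = compute_ror(ContingencyTable(10, 10, 10, 10))
        assert r.computable and r.ror == 1.0
        assert r.ci_lower == pytest.approx(0.2895, abs=5e-5)
        assert r.ci_upper == pytest.approx(3.4543, abs=5e-5)

    def test_strong_signal_table(self):
        r = compute_ror(ContingencyTable(20, 80, 100, 9800))
        assert r.ror == pytest.approx(24.5)
        assert r.ci_lower == pytest.approx(14.45, abs=5e-3)
        assert r.ci_upper == pytest.approx(41.55, abs=5e-3)
        assert r.is_signal

    def test_zero_cell_not_computable(self):
        for table in [(0, 5, 5, 5), (5, 0, 5, 5), (5, 5, 0, 5), (5, 5, 5, 0)]:
            r = compute_ror(ContingencyTable(*table))
            assert not r.computable and not r.is_signal
            assert r.ror is None and r.ci_lower is None

    def test_matches_independent_oracle_on_random_tables(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 10_000, size=4)
            r = compute_ror(ContingencyTable(int(a), int(b), int(c), int(d)))
            oror, olo, ohi = woolf_oracle(a, b, c, d)
            assert abs(r.ror - oror) <= 1e-9 * abs(oror)
            assert abs(r.ci_lower - olo) <= 1e-9 * abs(olo)
            assert abs(r.ci_upper - ohi) <= 1e-9 * abs(ohi)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=200, deadline=None)
    def test_symmetry_properties(self, a, b, c, d):
        base = compute_ror(ContingencyTable(a, b, c, d))
        swap_rows = compute_ror(ContingencyTable(c, d, a, b))
        swap_cols = compute_ror(ContingencyTable(b, a, d, c))
        assert swap_rows.ror == pytest.approx(1 / base.ror, rel=1e-12)
        assert swap_cols.ror == pytest.approx(1 / base.ror, rel=1e-12)
        # CI endpoints swap and invert along with the estimate
        assert swap_rows.ci_lower == pytest.approx(1 / base.ci_upper, rel=1e-9)

    @given(a=st.integers(1, 500), b=st.integers(1, 500),
           c=st.integers(1, 500), d=st.integers(1, 500),
           k=st.integers(2, 50))
    @settings(max_examples=200, deadline=None)
    def test_scaling_leaves_ror_and_narrows_ci(self, a, b, c, d, k):
        base = compute_ror(ContingencyTable(a, b, c, d))
        scaled = compute_ror(ContingencyTable(k * a, k * b, k * c, k * d))
        assert scaled.ror == pytest.approx(base.ror, rel=1e-12)
        width = np.log(base.ci_upper) - np.log(base.ci_lower)
        width_k = np.log(scaled.ci_upper) - np.log(scaled.ci_lower)
        assert width_k < width


class TestClassify:
    @pytest.mark.parametrize("ror, lo, hi, a, expected", [
        (0.98, 0.64, 1.51, 50, False),    # null CI spanning 1
        (29.19, 27.06, 31.50, 1000, True),
        (5.0, 1.2, 20.0, 2, False),       # fails the a >= 3 minimum
        (5.0, 1.001, 20.0, 3, True),
    ])
    def test_signal_rule(self, ror, lo, hi, a, expected):
        r = SignalResult(target="x", level="drug", a=a, ror=ror, ci_lower=lo,
                         ci_upper=hi, computable=True, is_signal=False)
        assert classify_signal(r) is expected

    def test_non_computable_never_signal(self):
        r = SignalResult(target="x", level="drug", a=10, ror=None,
                         ci_lower=None, ci_upper=None, computable=False,
                         is_signal=False)
        assert classify_signal(r) is False


class TestBuildContingency:
    dictionary = DrugDictionary(
        name_to_ingredient={},
        ingredient_to_class={"ceftriaxone": "third-generation cephalosporins",
                             "cefotaxime": "third-generation cephalosporins",
                             "lincomycin": "lincomycins"})

    def test_direct_count(self):
        ids = [str(i) for i in range(10)]
        flagged = {"0", "1", "2"}
        exposures = {pid: {"ceftriaxone"} for pid in ["0", "1", "3", "4",
                                                      "5", "6"]}
        t = build_contingency(ids, flagged, exposures, "ceftriaxone")
        assert (t.a, t.b, t.c, t.d) == (2, 4, 1, 3)
        assert t.n == 10

    def test_class_level_counts_report_once(self):
        ids = ["1", "2"]
        flagged = {"1"}
        exposures = {"1": {"ceftriaxone", "cefotaxime"}}  # two drugs, one class
        t = build_contingency(ids, flagged, exposures,
                              "third-generation cephalosporins",
                              level="class", dictionary=self.dictionary)
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigurationError):
            build_contingency([], set(), {}, "no-such-class", level="class",
                              dictionary=self.dictionary)

    def test_margins_constant_across_targets(self, small_synthetic):
        from aadsignal.case_definition import CaseDefinition, flag_aad_reports
        from aadsignal.cleaning import clean_table_set, \
            primary_suspect_exposures

        cfg, ts, gt = small_synthetic
        clean = clean_table_set(ts, gt.dictionary())
        flagged = flag_aad_reports(clean.reactions, CaseDefinition.default())
        exposures = primary_suspect_exposures(clean.drugs)
        ids = clean.reports["primaryid"].tolist()
        margins = set()
        for spec in cfg.drugs:
            t = build_contingency(ids, flagged, exposures, spec.ingredient)
            margins.add((t.a + t.c, t.b + t.d, t.n))
        assert len(margins) == 1
        assert margins.pop()[2] == clean.n_reports


class TestRanking:
    def make(self, target, ror, a=10):
        return SignalResult(target=target, level="class", a=a, ror=ror,
                            ci_lower=ror * 0.9, ci_upper=ror * 1.1,
                            computable=True, is_signal=True)

    def test_descending_with_published_ordering(self):
        results = [self.make("first/second-generation cephalosporins", 15.29),
                   self.make("lincomycins", 29.19),
                   self.make("third-generation cephalosporins", 15.96)]
        ranked = rank_signals(results)
        assert [r.target for r in ranked] == [
            "lincomycins", "third-generation cephalosporins",
            "first/second-generation cephalosporins"]

    def test_ties_alphabetical_and_noncomputable_last(self):
        nc = SignalResult(target="zzz", level="class", a=0, ror=None,
                          ci_lower=None, ci_upper=None, computable=False,
                          is_signal=False)
        ranked = rank_signals([self.make("b", 2.0), nc, self.make("a", 2.0)])
        assert [r.target for r in ranked] == ["a", "b", "zzz"]

    def test_single_entry(self):
        only = self.make("a", 1.5)
        assert rank_signals([only]) == [only]


def test_signal_table_agrees_with_per_target_tables(small_synthetic):
    from aadsignal.case_definition import CaseDefinition, flag_aad_reports
    from aadsignal.cleaning import clean_table_set, primary_suspect_exposures

    cfg, ts, gt = small_synthetic
    clean = clean_table_set(ts, gt.dictionary())
    flagged = flag_aad_reports(clean.reactions, CaseDefinition.default())
    exposures = primary_suspect_exposures(clean.drugs)
    ids = clean.reports["primaryid"].tolist()
    results = {r.target: r for r in
               signal_table(ids, flagged, exposures, gt.dictionary(), "drug")}
    for spec in cfg.drugs:
        t = build_contingency(ids, flagged, exposures, spec.ingredient)
        direct = compute_ror(t, target=spec.ingredient)
        via_table = results[spec.ingredient]
        assert via_table.a == direct.a
        if direct.computable:
            assert via_table.ror == pytest.approx(direct.ror, rel=1e-12)
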