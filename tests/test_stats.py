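"""Exact correctness null, enrichment p-values, composite scoring, GO ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crengine import (DOWN, UP, Hypothesis, correctness_null,
                      correctness_pvalue, enrichment_pvalue, go_enrichment,
                      map_changes, predict_downstream, read_results,
                      score_hypothesis, score_hypotheses, write_results)
from crengine.engine import classify

from conftest import (enumerate_null_oracle, hypergeom_tail_oracle, make_kg,
                      make_oc)


class TestCorrectnessNull:
    def test_no_predictions_forces_zero_score(self):
        nd = correctness_null(10, 3, 2, 0, 0)
        assert nd.support.tolist() == [0] and nd.pmf.tolist() == [1.0]

    def test_single_label_uniform_over_three_nodes(self):
        nd = correctness_null(3, 1, 0, 1, 0)
        pmf = dict(zip(nd.support.tolist(), nd.pmf.tolist()))
        assert pmf[1] == pytest.approx(1 / 3, abs=1e-12)
        assert pmf[0] == pytest.approx(2 / 3, abs=1e-12)

    @pytest.mark.parametrize("params", [
        (12, 4, 3, 3, 2), (10, 5, 2, 4, 4), (8, 4, 4, 3, 3), (12, 6, 3, 5, 4),
    ])
    def test_matches_exhaustive_enumeration(self, params):
        nd = correctness_null(*params)
        oracle = enumerate_null_oracle(*params)
        mine = dict(zip(nd.support.tolist(), nd.pmf.tolist()))
        tv = 0.5 * sum(abs(mine.get(k, 0.0) - oracle.get(k, 0.0))
                       for k in set(mine) | set(oracle))
        assert tv <= 1e-12

    def test_pmf_sums_to_one_and_support_bounded(self):
        nd = correctness_null(200, 30, 25, 12, 9)
        assert nd.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        D = 12 + 9
        assert nd.support.min() >= -D and nd.support.max() <= D

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_mean_matches_closed_form(self, data):
        N = data.draw(st.integers(2, 60))
        G_up = data.draw(st.integers(0, N))
        G_down = data.draw(st.integers(0, N - G_up))
        d_up = data.draw(st.integers(0, N))
        d_down = data.draw(st.integers(0, N - d_up))
        nd = correctness_null(N, G_up, G_down, d_up, d_down)
        expected = (G_up - G_down) * (d_up - d_down) / N
        assert nd.mean == pytest.approx(expected, abs=1e-9)

    def test_parameter_violations_rejected(self):
        with pytest.raises(ValueError):
            correctness_null(5, 4, 2, 1, 1)
        with pytest.raises(ValueError):
            correctness_null(5, 1, 1, 3, 3)


class TestCorrectnessPvalue:
    def test_score_at_or_below_minimum_gives_one(self):
        nd = correctness_null(12, 4, 3, 3, 2)
        assert correctness_pvalue(int(nd.support.min()), nd) == 1.0
        assert correctness_pvalue(-100, nd) == 1.0

    def test_score_above_maximum_gives_empty_tail(self):
        nd = correctness_null(12, 4, 3, 3, 2)
        assert correctness_pvalue(int(nd.support.max()) + 1, nd) == 0.0

    def test_tail_matches_enumeration(self):
        nd = correctness_null(12, 4, 3, 3, 2)
        oracle = enumerate_null_oracle(12, 4, 3, 3, 2)
        expected = sum(p for s, p in oracle.items() if s >= 3)
        assert correctness_pvalue(3, nd) == pytest.approx(expected, abs=1e-12)


class TestEnrichment:
    def test_perfect_overlap_small_tail(self):
        kg = make_kg([("A", UP, f"t{i:02d}") for i in range(10)])
        direction = {f"t{i:02d}": UP for i in range(10)}
        extra = [f"t{i:02d}" for i in range(10, 100)]
        mapped = map_changes(make_kg([("A", UP, f"t{i:02d}") for i in range(100)]),
                             make_oc(direction, extra_universe=extra))
        pred = predict_downstream(Hypothesis("A", UP), kg)
        cls = classify(pred, mapped)
        p = enrichment_pvalue(cls, pred, mapped)
        assert p == pytest.approx(hypergeom_tail_oracle(10, 100, 10, 10), rel=1e-10)
        assert p == pytest.approx(5.776904234533875e-14, rel=1e-6)

    def test_disjoint_downstream_gives_one(self):
        kg = make_kg([("A", UP, "t1"), ("B", UP, "t2")])
        mapped = map_changes(kg, make_oc({"t2": UP}, extra_universe=["t1"]))
        pred = predict_downstream(Hypothesis("A", UP), kg)
        cls = classify(pred, mapped)
        assert enrichment_pvalue(cls, pred, mapped) == pytest.approx(1.0)

    def test_empty_downstream_warns_and_returns_one(self):
        kg = make_kg([("A", UP, "t1"), ("B", UP, "t2")])
        mapped = map_changes(kg, make_oc({"t2": UP}))  # t1 not measured
        pred = predict_downstream(Hypothesis("A", UP), kg)
        cls = classify(pred, mapped)
        with pytest.warns(UserWarning):
            assert enrichment_pvalue(cls, pred, mapped) == 1.0

    def test_small_table_matches_brute_force(self):
        # universe 20, significant 5, downstream 4, hits 3
        kg_stmts = [("A", UP, f"t{i:02d}") for i in range(4)]
        kg = make_kg(kg_stmts + [("B", UP, f"t{i:02d}") for i in range(4, 20)])
        direction = {"t00": UP, "t01": UP, "t02": UP, "t10": UP, "t11": UP}
        mapped = map_changes(kg, make_oc(direction,
                                         extra_universe=[f"t{i:02d}" for i in range(20)]))
        pred = predict_downstream(Hypothesis("A", UP), kg)
        cls = classify(pred, mapped)
        assert enrichment_pvalue(cls, pred, mapped) == pytest.approx(
            hypergeom_tail_oracle(3, 20, 5, 4), rel=1e-12)


class TestScoreHypothesis:
    def test_score_and_percent_from_counts(self, demo):
        kg, oc, h = demo
        mapped = map_changes(kg, oc)
        r = score_hypothesis(h, kg, mapped)
        assert (r.n_correct, r.n_incorrect, r.n_ambiguous) == (36, 14, 6)
        assert r.score == 22
        assert r.percent_correct == pytest.approx(0.72)
        assert 0 < r.correctness_p < 1 and 0 < r.enrichment_p < 1

    def test_all_correct(self):
        kg = make_kg([("A", UP, "t1"), ("A", UP, "t2"), ("A", UP, "t3")])
        mapped = map_changes(kg, make_oc({"t1": UP, "t2": UP, "t3": UP}))
        r = score_hypothesis(Hypothesis("A", UP), kg, mapped)
        assert r.score == 3 and r.percent_correct == 1.0

    def test_direction_flip_negates_score(self, demo):
        kg, oc, h = demo
        mapped = map_changes(kg, oc)
        r = score_hypothesis(h, kg, mapped)
        flipped = score_hypothesis(Hypothesis(h.entity, -h.direction), kg, mapped)
        assert flipped.score == -r.score
        assert flipped.n_correct == r.n_incorrect
        assert flipped.n_incorrect == r.n_correct
        assert flipped.n_ambiguous == r.n_ambiguous

    def test_bulk_scoring_matches_single(self, demo):
        kg, oc, h = demo
        mapped = map_changes(kg, oc)
        bulk = {r.hypothesis: r for r in score_hypotheses(kg, mapped)}
        single = score_hypothesis(h, kg, mapped)
        r = bulk[h]
        assert (r.score, r.correctness_p, r.enrichment_p) == (
            single.score, single.correctness_p, single.enrichment_p)


class TestResultsIO:
    def test_round_trip(self, tmp_path, demo):
        kg, oc, h = demo
        mapped = map_changes(kg, oc)
        results = score_hypotheses(kg, mapped)
        path = tmp_path / "results.tsv"
        write_results(results, path)
        loaded = read_results(path)
        assert len(loaded) == len(results)
        for a, b in zip(results, loaded):
            assert a.hypothesis == b.hypothesis
            assert a.classification == b.classification
            assert a.evidence == b.evidence
            assert a.correctness_p == pytest.approx(b.correctness_p, rel=1e-12)


class TestGOEnrichment:
    def make_mapped(self, n=100, n_sig=10):
        kg = make_kg([("A", UP, f"t{i:03d}") for i in range(n)])
        direction = {f"t{i:03d}": UP for i in range(n_sig)}
        universe = [f"t{i:03d}" for i in range(n)]
        return map_changes(kg, make_oc(direction, extra_universe=universe))

    def test_term_equal_to_significant_set_reports_infinity(self):
        mapped = self.make_mapped(100, 4)
        sets = {"termA": {f"t{i:03d}" for i in range(4)}}
        df = go_enrichment(sets, mapped)
        assert math.isinf(df.loc[0, "odds_ratio"])
        assert df.loc[0, "size"] == 4

    def test_independent_term_odds_one_p_one(self):
        mapped = self.make_mapped(100, 10)
        # term hits 1 of 10 members: same 10% proportion as the universe
        sets = {"t": {f"t{i:03d}" for i in [0, 20, 21, 22, 23, 24, 25, 26, 27, 28]}}
        df = go_enrichment(sets, mapped)
        assert df.loc[0, "odds_ratio"] == pytest.approx(1.0)
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_two_sided_p_matches_brute_force(self):
        # table: hits 8, sig-only 2, term-only 6, rest 84
        from math import comb
        mapped = self.make_mapped(100, 10)
        term = {f"t{i:03d}" for i in range(8)} | {f"t{i:03d}" for i in range(50, 56)}
        df = go_enrichment({"term": term}, mapped)
        N, K, n = 100, 10, 14
        probs = {k: comb(K, k) * comb(N - K, n - k) / comb(N, n)
                 for k in range(max(0, n - (N - K)), min(K, n) + 1)}
        p_two = sum(p for p in probs.values() if p <= probs[8] * (1 + 1e-12))
        assert df.loc[0, "p_value"] == pytest.approx(p_two, rel=1e-9)
        assert df.loc[0, "odds_ratio"] == pytest.approx(8 * 84 / (2 * 6))

    def test_desirability_peaks_at_target_size_and_sorts(self):
        mapped = self.make_mapped(400, 40)
        sig = [f"t{i:03d}" for i in range(40)]
        rest = [f"t{i:03d}" for i in range(40, 400)]
        sets = {
            "at_target": set(sig[:10]) | set(rest[:10]),      # size 20
            "too_big": set(sig[:10]) | set(rest[:290]),       # size 300
        }
        df = go_enrichment(sets, mapped).set_index("term")
        assert df.loc["too_big", "desirability"] == 0.0
        assert df.loc["at_target", "desirability"] > 0
        assert df.index[0] == "at_target"

    def test_term_outside_universe_skipped_with_warning(self):
        mapped = self.make_mapped(50, 5)
        with pytest.warns(UserWarning, match="skipped"):
            df = go_enrichment({"ghost": {"zzz"}}, mapped)
        assert df.empty

    def test_long_dataframe_input(self):
        mapped = self.make_mapped(50, 5)
        table = pd.DataFrame({"term": ["a", "a", "b"],
                              "gene": ["t000", "t001", "t010"]})
        df = go_enrichment(table, mapped)
        assert set(df["term"]) == {"a", "b"}
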