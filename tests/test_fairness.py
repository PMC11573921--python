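import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_fairness_metrics, youden_scan

from faim.fairness import (
    SelectionError,
    fairness_profile,
    fri,
    select_model,
    subgroup_rates,
    tabulate_by_case,
    youden_threshold,
)


class TestYoudenThreshold:
    def test_separable_example(self):
        t = youden_threshold(np.array([0.1, 0.2, 0.7, 0.9]), np.array([0, 0, 1, 1]))
        assert t == 0.7

    def test_all_equal_scores(self):
        t = youden_threshold(np.full(6, 0.4), np.array([0, 1, 0, 1, 0, 1]))
        assert t == 0.4

    def test_tie_broken_to_largest_threshold(self):
        # J = 0.5 at both t=0.6 (spec 0.5) and t=0.8 (sens 0.5); largest wins
        t = youden_threshold(np.array([0.4, 0.6, 0.6, 0.8]), np.array([0, 1, 0, 1]))
        assert t == 0.8

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            youden_threshold(np.array([0.1, 0.9]), np.array([1, 1]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.choice(np.round(rng.random(8), 2), n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        t_oracle, _ = youden_scan(scores, labels)
        assert youden_threshold(scores, labels) == pytest.approx(t_oracle)


class TestSubgroupRates:
    def test_hand_counted_confusion_tables(self):
        y = np.array([1, 1, 0, 0, 1, 1, 1, 0])
        yhat = np.array([1, 0, 0, 1, 1, 1, 1, 0])
        g = np.array(["g1"] * 4 + ["g2"] * 4)
        rates = subgroup_rates(yhat, y, g, min_count=1)
        assert rates.table.loc["g1", "tpr"] == 0.5
        assert rates.table.loc["g1", "fpr"] == 0.5
        assert rates.table.loc["g2", "tpr"] == 1.0
        assert rates.table.loc["g2", "fpr"] == 0.0

    def test_small_group_merged_conserves_counts(self):
        y = np.array([1, 0] * 5)
        yhat = np.array([1, 1] * 5)
        g = np.array(["big"] * 8 + ["tiny"] * 2)
        rates = subgroup_rates(yhat, y, g, min_count=3)
        assert "(other)" in rates.subgroups
        assert rates.merged == ["tiny"]
        assert rates.table["count"].sum() == 10

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            subgroup_rates(np.array([]), np.array([]), np.array([]))


class TestFairnessProfile:
    def test_hand_computed_example(self):
        y = np.array([1, 1, 0, 0, 1, 1, 1, 0])
        yhat = np.array([1, 0, 0, 1, 1, 1, 1, 0])
        g = np.array(["g1"] * 4 + ["g2"] * 4)
        prof = fairness_profile(subgroup_rates(yhat, y, g, min_count=1))
        assert prof.equal_opportunity == pytest.approx(0.5)
        assert prof.equalized_odds == pytest.approx(0.5)
        assert prof.ber_equality == pytest.approx(1.0)

    def test_identical_subgroups_are_perfectly_fair(self):
        y = np.tile([1, 0], 10)
        yhat = np.tile([1, 1], 10)
        g = np.repeat(["a", "b"], 10)
        prof = fairness_profile(subgroup_rates(yhat, y, g, min_count=1))
        assert prof.metrics() == (0.0, 0.0, 0.0)

    def test_single_subgroup_gives_zero_metrics(self):
        y = np.array([1, 0, 1, 0])
        prof = fairness_profile(subgroup_rates(np.array([1, 0, 0, 1]), y, np.array(["g"] * 4), min_count=1))
        assert prof.metrics() == (0.0, 0.0, 0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_equalized_odds_dominates_equal_opportunity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        y = rng.integers(0, 2, n)
        yhat = rng.integers(0, 2, n)
        g = rng.choice(["a", "b", "c"], n)
        try:
            prof = fairness_profile(subgroup_rates(yhat, y, g, min_count=1))
        except ValueError:
            return
        assert prof.equalized_odds >= prof.equal_opportunity

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(8, 200))
            k = int(rng.integers(2, 7))
            y = rng.integers(0, 2, n)
            yhat = rng.integers(0, 2, n)
            g = rng.integers(0, k, n).astype(str)
            try:
                prof = fairness_profile(subgroup_rates(yhat, y, g, min_count=1))
            except ValueError:
                continue
            eo, eod, ber = brute_fairness_metrics(yhat, y, g)
            assert prof.equal_opportunity == pytest.approx(eo, abs=1e-12)
            assert prof.equalized_odds == pytest.approx(eod, abs=1e-12)
            assert prof.ber_equality == pytest.approx(ber, abs=1e-12)


class TestFRI:
    def test_direct_formula(self):
        assert fri((0.1, 0.2, 0.3)) == pytest.approx(1.0 / 0.11)

    def test_equal_metrics_closed_form(self):
        c = 0.2
        assert fri((c, c, c)) == pytest.approx(1.0 / (3 * c * c))
        assert fri((c, c, c)) == pytest.approx(8.3333, abs=1e-4)

    def test_perfect_fairness_is_infinite(self):
        assert fri((0.0, 0.0, 0.0)) == math.inf

    def test_negative_metric_rejected(self):
        with pytest.raises(ValueError):
            fri((-0.1, 0.2, 0.3))

    def test_scaling_preserves_ranking(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            metrics = rng.random((20, 3))
            c = float(rng.uniform(0.1, 10.0))
            base = np.array([fri(m) for m in metrics])
            scaled = np.array([fri(c * m) for m in metrics])
            np.testing.assert_array_equal(np.argsort(-base), np.argsort(-scaled))
            np.testing.assert_allclose(scaled, base / c**2, rtol=1e-12)


def _fake_ranked(frii_eod_id):
    """Build a minimal ranked list from (fri, equalized_odds, candidate_id) triples."""
    from faim.fairness import FairnessProfile, RankedModel
    from faim.glm import ExclusionCase

    class _Cand:
        def __init__(self, cid, case):
            self.candidate_id = cid
            self.case = case
            self.beta = np.zeros(2)
            self.columns = ("(Intercept)", "x")
            self.register = {"x": "x"}
            self.validation_metric = 0.9

    out = []
    for f, eod, cid, *case in frii_eod_id:
        case = ExclusionCase(retained=tuple(case[0]) if case else ("race",))
        prof = FairnessProfile(equal_opportunity=eod, equalized_odds=eod, ber_equality=eod)
        out.append(RankedModel(candidate=_Cand(cid, case), profile=prof, fri=f, threshold=0.5))
    out.sort(key=lambda r: (-r.fri, r.profile.equalized_odds, r.candidate_id))
    for i, r in enumerate(out, 1):
        r.rank = i
    return out


class TestRankingAndSelection:
    def test_single_model_gets_rank_one(self):
        ranked = _fake_ranked([(2.0, 0.1, 7)])
        assert ranked[0].rank == 1

    def test_infinite_fri_ties_resolved_by_id(self):
        ranked = _fake_ranked([(math.inf, 0.0, 5), (math.inf, 0.0, 2)])
        assert [r.candidate_id for r in ranked] == [2, 5]

    def test_select_default_is_rank_one(self):
        ranked = _fake_ranked([(3.0, 0.1, 1), (2.0, 0.2, 2)])
        assert select_model(ranked).candidate_id == 1

    def test_select_with_exclusion_constraint(self):
        ranked = _fake_ranked([(3.0, 0.1, 1, ("race",)), (2.0, 0.2, 2, ())])
        sel = select_model(ranked, must_exclude=("race", "sex"))
        assert sel.candidate_id == 2
        assert sel.case.case_id == "keep:none"

    def test_unsatisfiable_constraint_raises(self):
        ranked = _fake_ranked([(3.0, 0.1, 1, ("race",))])
        with pytest.raises(SelectionError, match="keep:race"):
            select_model(ranked, must_exclude=("race",))

    def test_explicit_choice_overrides(self):
        ranked = _fake_ranked([(3.0, 0.1, 1), (2.0, 0.2, 2)])
        assert select_model(ranked, choice=2).candidate_id == 2


class TestCaseTable:
    def test_bin_counts_conserved(self):
        triples = [(float(10 - i), 0.1, i, ("race",) if i % 2 else ()) for i in range(8)]
        ranked = _fake_ranked(triples)
        table = tabulate_by_case(ranked, n_bins=4)
        assert int(table.drop(columns="best_rank").to_numpy().sum()) == 8
        assert (table.drop(columns="best_rank").sum(axis=1) == 4).all()

    def test_best_rank_matches_recomputation(self):
        triples = [(float(10 - i), 0.1, i, ("race",) if i % 3 == 0 else ()) for i in range(9)]
        ranked = _fake_ranked(triples)
        table = tabulate_by_case(ranked, n_bins=3)
        for case_id in table.index:
            expected = min(r.rank for r in ranked if r.case_id == case_id)
            assert table.loc[case_id, "best_rank"] == expected

    def test_too_many_bins_rejected(self):
        ranked = _fake_ranked([(2.0, 0.1, 1)])
        with pytest.raises(ValueError):
            tabulate_by_case(ranked, n_bins=2)
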