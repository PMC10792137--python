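"""Consensus, median-rank aggregation, rank-sum weights, certification."""

import dataclasses
from fractions import Fraction

import pandas as pd
import pytest

from metriscore import load_instrument
from metriscore.delphi import (
    ConsensusResult,
    RankMatrix,
    VoteTable,
    aggregate_median_ranks,
    apply_round_flow,
    consensus_status,
    derive_weight_table,
    invert_weights_to_ranks,
    rank_to_scores,
    round_weight,
)
from metriscore.errors import (
    CertificationError,
    DomainError,
    FlowError,
    SchemaError,
)
from metriscore.instrument import Instrument

# The median-rank configuration that reproduces the published weight table
# (certified below by the inversion oracle). Category medians over N=9 and
# per-category item medians keyed by item id.
CATEGORY_MEDIANS = {
    "Study design": 1,
    "Imaging data": 3.5,
    "Segmentation": 7,
    "Image processing and feature extraction": 4,
    "Feature processing": 6,
    "Preparation for modeling": 6,
    "Metrics and comparison": 4,
    "Testing": 5,
    "Open science": 9,
}
ITEM_MEDIANS = {
    "Study design": {1: 3, 2: 2, 3: 1.5},
    "Imaging data": {4: 2, 5: 3, 6: 2, 7: 3},
    "Segmentation": {8: 1, 9: 2, 10: 3},
    "Image processing and feature extraction": {11: 1, 12: 2.5, 13: 2},
    "Feature processing": {14: 3, 15: 3, 16: 2, 17: 3},
    "Preparation for modeling": {18: 1, 19: 2},
    "Metrics and comparison": {20: 1, 21: 3, 22: 4, 23: 5, 24: 2, 25: 4},
    "Testing": {26: 2, 27: 1},
    "Open science": {28: 2, 29: 2, 30: 2},
}


def fraction_chain(category_medians, item_medians):
    """Independent oracle: the full rank-sum chain in exact arithmetic."""
    n_cat = len(category_medians)
    cat_scores = {
        c: Fraction(n_cat + 1) - Fraction(m).limit_denominator(2)
        for c, m in category_medians.items()
    }
    cat_total = sum(cat_scores.values())
    final = {}
    for cat, medians in item_medians.items():
        n = len(medians)
        scores = {
            k: Fraction(n + 1) - Fraction(m).limit_denominator(2)
            for k, m in medians.items()
        }
        total = sum(scores.values())
        for k, s in scores.items():
            final[k] = (cat_scores[cat] / cat_total) * (s / total)
    return final


def votes_from_counts(n_strong_agree=0, n_agree=0, n_neutral=0, n_disagree=0,
                      n_strong_disagree=0, item_key="item1"):
    rows = []
    labels = (
        ["strongly_agree"] * n_strong_agree
        + ["agree"] * n_agree
        + ["neutral"] * n_neutral
        + ["disagree"] * n_disagree
        + ["strongly_disagree"] * n_strong_disagree
    )
    for k, vote in enumerate(labels):
        rows.append({"panelist_id": f"P{k}", "item_key": item_key, "vote": vote})
    return VoteTable(pd.DataFrame(rows))


class TestConsensus:
    def test_threshold_reached_exactly(self):
        votes = votes_from_counts(15, 15, 5, 3, 2)
        r = consensus_status(votes, "item1")
        assert r.n_votes == 40
        assert r.agreement_rate == pytest.approx(0.75)
        assert r.status == "consensus_agree"

    def test_unanimous_agreement(self):
        r = consensus_status(votes_from_counts(20, 20), "item1")
        assert r.agreement_rate == pytest.approx(1.0)
        assert r.status == "consensus_agree"

    def test_just_below_threshold_is_no_consensus(self):
        r = consensus_status(votes_from_counts(14, 15, 6, 3, 2), "item1")
        assert r.agreement_rate == pytest.approx(29 / 40)
        assert r.status == "no_consensus"

    def test_disagreement_consensus(self):
        r = consensus_status(votes_from_counts(2, 3, 0, 20, 15), "item1")
        assert r.disagreement_rate == pytest.approx(35 / 40)
        assert r.status == "consensus_disagree"

    def test_trichotomy_and_rate_bound(self):
        for counts in [(10, 5, 5, 5, 15), (30, 0, 5, 0, 5), (0, 0, 40, 0, 0),
                       (5, 5, 0, 15, 15)]:
            r = consensus_status(votes_from_counts(*counts), "item1")
            assert r.status in (
                "consensus_agree", "consensus_disagree", "no_consensus"
            )
            assert r.agreement_rate + r.disagreement_rate <= 1.0 + 1e-12

    def test_neutral_excluded_from_denominator_mode(self):
        votes = votes_from_counts(10, 5, 15, 5, 5)
        strict = consensus_status(votes, "item1")
        lenient = consensus_status(
            votes, "item1", include_neutral_in_denominator=False
        )
        assert strict.agreement_rate == pytest.approx(15 / 40)
        assert lenient.agreement_rate == pytest.approx(15 / 25)

    def test_no_votes_is_an_error(self):
        with pytest.raises(SchemaError, match="item2"):
            consensus_status(votes_from_counts(5, 5), "item2")

    def test_duplicate_vote_rejected(self):
        frame = pd.DataFrame(
            [
                {"panelist_id": "P1", "item_key": "a", "vote": "agree"},
                {"panelist_id": "P1", "item_key": "a", "vote": "neutral"},
            ]
        )
        with pytest.raises(SchemaError, match="duplicate"):
            VoteTable(frame)

    def test_labels_case_insensitive(self):
        frame = pd.DataFrame(
            [{"panelist_id": "P1", "item_key": "a", "vote": "Strongly Agree"}]
        )
        assert VoteTable(frame).frame.loc[0, "vote"] == "strongly_agree"


def _result(key, status):
    return ConsensusResult(
        item_key=key, n_votes=40, agreement_rate=0.5,
        disagreement_rate=0.1, status=status,
    )


class TestRoundFlow:
    def test_late_agreement_retains(self):
        out = apply_round_flow(
            {"a": _result("a", "no_consensus")},
            {"a": _result("a", "consensus_agree")},
        )
        assert out["a"] == "retained"

    def test_two_failed_rounds_remove(self):
        out = apply_round_flow(
            {"a": _result("a", "no_consensus")},
            {"a": _result("a", "no_consensus")},
        )
        assert out["a"] == "removed_no_consensus"

    def test_disagreement_removes_immediately(self):
        out = apply_round_flow(
            {"a": _result("a", "consensus_disagree")}, {}
        )
        assert out["a"] == "removed_disagreement"

    def test_new_item_flows(self):
        out = apply_round_flow(
            {"a": _result("a", "consensus_agree")},
            {"new": _result("new", "no_consensus")},
        )
        assert out == {"a": "retained", "new": "pending"}

    def test_resolved_item_revoted_is_a_flow_error(self):
        with pytest.raises(FlowError, match="a"):
            apply_round_flow(
                {"a": _result("a", "consensus_agree")},
                {"a": _result("a", "consensus_agree")},
            )

    def test_unresolved_item_missing_is_a_flow_error(self):
        with pytest.raises(FlowError, match="a"):
            apply_round_flow({"a": _result("a", "no_consensus")}, {})


class TestMedians:
    def test_even_panel_gives_half_integer(self):
        m = RankMatrix(pd.DataFrame([[1, 2], [2, 1]], columns=["A", "B"]))
        assert aggregate_median_ranks(m) == {"A": 1.5, "B": 1.5}

    def test_odd_panel(self):
        m = RankMatrix(
            pd.DataFrame([[2, 1, 3], [2, 3, 1], [3, 1, 2]], columns=list("ABC"))
        )
        assert aggregate_median_ranks(m)["A"] == 2.0

    def test_split_panel_of_42(self):
        rows = [[1, 2]] * 21 + [[2, 1]] * 21
        m = RankMatrix(pd.DataFrame(rows, columns=["A", "B"]))
        assert aggregate_median_ranks(m) == {"A": 1.5, "B": 1.5}

    def test_non_permutation_row_names_panelist(self):
        frame = pd.DataFrame([[1, 1], [1, 2]], columns=["A", "B"], index=["p1", "p2"])
        with pytest.raises(SchemaError, match="p1"):
            RankMatrix(frame)

    def test_incomplete_rows_dropped_listwise(self):
        frame = pd.DataFrame(
            [[1.0, 2.0], [2.0, None]], columns=["A", "B"], index=["p1", "p2"]
        )
        m = RankMatrix(frame)
        assert m.n_panelists == 1


class TestRankToScores:
    @pytest.mark.parametrize(
        "medians, n, expected",
        [
            ({"x": 1.5}, 3, {"x": 2.5}),
            ({"x": 9}, 9, {"x": 1.0}),
            ({"x": 1, "y": 2}, 2, {"x": 2.0, "y": 1.0}),
        ],
    )
    def test_formula(self, medians, n, expected):
        assert rank_to_scores(medians, n) == expected

    @pytest.mark.parametrize("bad", [0.5, 9.5])
    def test_out_of_domain(self, bad):
        with pytest.raises(DomainError):
            rank_to_scores({"x": bad}, 9)


class TestDeriveWeights:
    def test_matches_exact_fraction_oracle(self):
        derived = derive_weight_table(CATEGORY_MEDIANS, ITEM_MEDIANS)
        expected = fraction_chain(CATEGORY_MEDIANS, ITEM_MEDIANS)
        for item_id, frac in expected.items():
            assert derived.final_weights[item_id] == pytest.approx(
                float(frac), abs=1e-12
            )

    def test_reproduces_every_published_weight_at_4dp(self, instrument):
        derived = derive_weight_table(CATEGORY_MEDIANS, ITEM_MEDIANS)
        for item in instrument.items:
            assert derived.final_weights_4dp[item.item_id] == pytest.approx(
                item.weight
            ), f"item {item.item_id}"

    def test_final_weights_sum_to_one(self):
        derived = derive_weight_table(CATEGORY_MEDIANS, ITEM_MEDIANS)
        assert sum(derived.final_weights.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(derived.category_level.weights.values()) == pytest.approx(
            1.0, abs=1e-12
        )
        for level in derived.item_levels.values():
            assert sum(level.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_order_preserved_and_ties_equal(self):
        derived = derive_weight_table(CATEGORY_MEDIANS, ITEM_MEDIANS)
        level = derived.item_levels["Metrics and comparison"]
        medians = ITEM_MEDIANS["Metrics and comparison"]
        keys = list(medians)
        for a in keys:
            for b in keys:
                if medians[a] < medians[b]:
                    assert level.weights[a] > level.weights[b]
                elif medians[a] == medians[b]:
                    assert level.weights[a] == pytest.approx(level.weights[b])

    def test_scale_equivariance_of_scores(self):
        # medians (4,5,5.5,6,4.5,5.5) give scores exactly half of those from
        # (1,3,4,5,2,4): same normalized weights
        half = {20: 4, 21: 5, 22: 5.5, 23: 6, 24: 4.5, 25: 5.5}
        full = {20: 1, 21: 3, 22: 4, 23: 5, 24: 2, 25: 4}
        item_a = dict(ITEM_MEDIANS, **{"Metrics and comparison": half})
        item_b = dict(ITEM_MEDIANS, **{"Metrics and comparison": full})
        da = derive_weight_table(CATEGORY_MEDIANS, item_a)
        db = derive_weight_table(CATEGORY_MEDIANS, item_b)
        for item_id in range(20, 26):
            assert da.final_weights[item_id] == pytest.approx(
                db.final_weights[item_id], abs=1e-12
            )

    def test_category_set_mismatch_rejected(self):
        item_medians = dict(ITEM_MEDIANS)
        del item_medians["Testing"]
        with pytest.raises(SchemaError, match="category sets differ"):
            derive_weight_table(CATEGORY_MEDIANS, item_medians)

    def test_rounding_is_half_away_from_zero(self):
        assert round_weight(0.12345) == 0.1235
        assert round_weight(0.00005) == 0.0001


class TestCertification:
    def test_canonical_table_certifies(self, instrument):
        cat_medians, item_medians = invert_weights_to_ranks(instrument)
        derived = derive_weight_table(cat_medians, item_medians)
        for item in instrument.items:
            assert abs(derived.final_weights[item.item_id] - item.weight) < 5e-5
            assert derived.final_weights_4dp[item.item_id] == pytest.approx(
                item.weight
            )

    def test_recovered_study_design_order(self, instrument):
        _, item_medians = invert_weights_to_ranks(instrument)
        medians = item_medians["Study design"]
        # heavier weight <=> lower (better) median rank: item3 < item2 < item1
        assert medians[3] < medians[2] < medians[1]

    def test_perturbed_table_fails_certification(self, instrument):
        items = []
        for item in instrument.items:
            if item.item_id == 3:
                item = dataclasses.replace(item, weight=0.05)
            items.append(item)
        cats = []
        for cat in instrument.categories:
            weight = sum(i.weight for i in items if i.category_id == cat.category_id)
            cats.append(dataclasses.replace(cat, weight=weight))
        broken = Instrument(items=tuple(items), categories=tuple(cats))
        with pytest.raises(CertificationError):
            invert_weights_to_ranks(broken)
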