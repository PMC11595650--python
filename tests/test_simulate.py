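"""Intra-cohort ranking simulations: rankings, classification, aggregation."""

import numpy as np
import pandas as pd
import pytest

from qsea_morph import (
    classify_sim_one,
    classify_sim_two,
    rank_by_embryologist,
    rank_by_qsea,
    run_sim_one,
    run_sim_two,
    sim_one_reference_fixture,
    sim_two_reference_fixture,
    summarize_sim_one,
    summarize_sim_two,
)
from qsea_morph.simulate import IneligibleCycleError, round_pct
from qsea_morph.synth import gardner_tier


def cycle_df(rows):
    defaults = {
        "transferred": False,
        "transfer_order": pd.NA,
        "live_birth": pd.NA,
        "cycle_id": "c1",
    }
    out = []
    for i, r in enumerate(rows):
        rec = dict(defaults, embryo_id=f"e{i}", **r)
        out.append(rec)
    return pd.DataFrame(out)


def wide(values_by_id):
    cols = list(range(0, 301, 30))
    data = {k: np.linspace(16.0, v, 11) for k, v in values_by_id.items()}
    df = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    df.index.name = "embryo_id"
    return df


class TestEmbryologistRanking:
    def test_single_best_grade(self):
        df = cycle_df(
            [{"ploidy": "euploid", "grade_tier": gardner_tier(g)} for g in ("AA", "BB", "CC")]
        )
        assert rank_by_embryologist(df) == ["e0"]

    def test_same_tier_letters_tie(self):
        df = cycle_df(
            [{"ploidy": "euploid", "grade_tier": gardner_tier(g)} for g in ("AB", "BA", "CC")]
        )
        assert rank_by_embryologist(df) == ["e0", "e1"]

    def test_single_embryo_is_its_own_top(self):
        df = cycle_df([{"ploidy": "euploid", "grade_tier": "low"}])
        assert rank_by_embryologist(df) == ["e0"]

    def test_missing_grade_rejected(self):
        df = cycle_df([{"ploidy": "euploid", "grade_tier": None}])
        with pytest.raises(ValueError, match="grade"):
            rank_by_embryologist(df)


class TestQseaRanking:
    def test_ascending_sort_for_thickness(self):
        q = wide({"a": 6.0, "b": 9.0, "c": 7.5})
        assert rank_by_qsea(q, ["a", "b", "c"]) == ["a", "c", "b"]

    def test_descending_for_areas(self):
        q = wide({"a": 20000.0, "b": 25000.0})
        assert rank_by_qsea(q, ["a", "b"], direction="desc") == ["b", "a"]

    def test_tie_breaks_by_slope_then_id(self):
        cols = list(range(0, 301, 30))
        q = pd.DataFrame(
            {
                "x": np.linspace(16.0, 6.0, 11),  # same final, steeper thinning
                "y": np.linspace(10.0, 6.0, 11),
                "z": np.linspace(10.0, 6.0, 11),  # identical profile to y
            }
        ).T
        q.columns = cols
        order = rank_by_qsea(q, ["z", "y", "x"])
        assert order == ["x", "y", "z"]  # slope first, then lexicographic id
        assert order == rank_by_qsea(q, ["y", "z", "x"])  # input order irrelevant

    def test_alternative_scores(self):
        cols = list(range(0, 301, 30))
        q = pd.DataFrame(
            {"a": np.linspace(20.0, 8.0, 11), "b": np.linspace(10.0, 9.0, 11)}
        ).T
        q.columns = cols
        assert rank_by_qsea(q, ["a", "b"], score="final_value") == ["a", "b"]
        assert rank_by_qsea(q, ["a", "b"], score="slope") == ["a", "b"]
        # percent change: a drops 60%, b drops 10%
        assert rank_by_qsea(q, ["a", "b"], score="pct_change") == ["a", "b"]

    def test_missing_values_rejected(self):
        q = wide({"a": 6.0})
        with pytest.raises(ValueError, match="no assay values"):
            rank_by_qsea(q, ["a", "zz"])


class TestSimOneClassification:
    def test_singleton_euploid_agreement_is_both_right(self):
        df = cycle_df(
            [
                {"ploidy": "euploid", "grade_tier": "excellent"},
                {"ploidy": "aneuploid", "grade_tier": "good"},
            ]
        )
        out = classify_sim_one(df, ["e0", "e1"])
        assert out["concordance"] == "agree"
        assert out["effectiveness"] == "both_right"

    def test_mixed_tie_with_euploid_top(self):
        df = cycle_df(
            [
                {"ploidy": "euploid", "grade_tier": "excellent"},
                {"ploidy": "aneuploid", "grade_tier": "excellent"},
            ]
        )
        out = classify_sim_one(df, ["e0", "e1"])
        assert out["concordance"] == "embryologist_multi_top"
        assert out["effectiveness"] == "qsea_right_vs_mixed"

    def test_embryologist_wrong_qsea_right(self):
        df = cycle_df(
            [
                {"ploidy": "aneuploid", "grade_tier": "excellent"},
                {"ploidy": "euploid", "grade_tier": "good"},
            ]
        )
        out = classify_sim_one(df, ["e1", "e0"])
        assert out["effectiveness"] == "qsea_better"

    def test_all_euploid_tie_counts_as_right(self):
        df = cycle_df(
            [
                {"ploidy": "euploid", "grade_tier": "excellent"},
                {"ploidy": "euploid", "grade_tier": "excellent"},
                {"ploidy": "aneuploid", "grade_tier": "low"},
            ]
        )
        out = classify_sim_one(df, ["e1", "e0", "e2"])
        assert out["concordance"] == "embryologist_multi_top"
        assert out["effectiveness"] == "both_right"

    def test_single_ploidy_cycle_ineligible(self):
        df = cycle_df([{"ploidy": "euploid", "grade_tier": "good"}] * 2)
        with pytest.raises(IneligibleCycleError):
            classify_sim_one(df, ["e0", "e1"])


class TestSimTwoClassification:
    def base(self):
        return cycle_df(
            [
                {"ploidy": "euploid", "grade_tier": "good", "transferred": True,
                 "transfer_order": 1, "live_birth": True},
                {"ploidy": "euploid", "grade_tier": "good", "transferred": True,
                 "transfer_order": 2, "live_birth": False},
                {"ploidy": "euploid", "grade_tier": "good"},
            ]
        )

    def test_agree_and_correct(self):
        out = classify_sim_two(self.base(), ["e0", "e1", "e2"])
        assert out["agreement"] == "agree"
        assert out["embryologist_correct"] is True
        assert out["qsea_status"] == "correct"

    def test_top_untransferred(self):
        out = classify_sim_two(self.base(), ["e2", "e0", "e1"])
        assert out["qsea_status"] == "top_untransferred"
        assert out["agreement"] == "disagree"

    def test_embryologist_wrong_qsea_correct(self):
        df = self.base()
        df.loc[0, "live_birth"] = False
        df.loc[1, "live_birth"] = True
        out = classify_sim_two(df, ["e1", "e0", "e2"])
        assert out["embryologist_correct"] is False
        assert out["qsea_status"] == "correct"

    def test_no_transfer_ineligible(self):
        df = cycle_df([{"ploidy": "euploid", "grade_tier": "good"}] * 2)
        with pytest.raises(IneligibleCycleError):
            classify_sim_two(df, ["e0", "e1"])


class TestRounding:
    @pytest.mark.parametrize(
        "n,d,expected",
        [(151, 352, 43), (85, 352, 24), (199, 352, 57), (1, 2, 50), (1, 8, 13), (0, 5, 0)],
    )
    def test_round_half_away_from_zero(self, n, d, expected):
        assert round_pct(n, d) == expected

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            round_pct(1, 0)


class TestFixturePartitions:
    def test_sim_one_outcomes_partition_eligible_cycles(self):
        cohort, qsea = sim_one_reference_fixture()
        out = run_sim_one(cohort, qsea)
        assert len(out) == cohort["cycle_id"].nunique()
        assert out["cycle_id"].is_unique
        # agreement implies a shared single top, hence both right or both wrong
        agree = out[out.concordance == "agree"]
        assert set(agree.effectiveness) <= {"both_right", "both_wrong"}
        s = summarize_sim_one(out)
        assert sum(v["n"] for v in s["concordance"].values()) == s["n_cycles"]
        assert sum(v["n"] for v in s["effectiveness"].values()) == s["n_cycles"]

    def test_sim_one_deterministic(self):
        cohort, qsea = sim_one_reference_fixture()
        a = run_sim_one(cohort, qsea)
        b = run_sim_one(cohort, qsea)
        pd.testing.assert_frame_equal(a, b)

    def test_sim_two_outcomes_partition_eligible_cycles(self):
        cohort, wides = sim_two_reference_fixture()
        out = run_sim_two(cohort, wides["zp_T"])
        assert len(out) == cohort["cycle_id"].nunique()
        s = summarize_sim_two(out)
        assert sum(v["n"] for v in s["qsea"].values()) == s["n_cycles"]
        n_agree = s["agreement"]["agree"]["n"] + s["agreement"]["disagree"]["n"]
        assert n_agree == s["n_cycles"]

    def test_summaries_reject_wrong_outcome_type(self):
        cohort, qsea = sim_one_reference_fixture()
        out = run_sim_one(cohort, qsea)
        with pytest.raises(ValueError, match="not from simulation 2"):
            summarize_sim_two(out)
        with pytest.raises(ValueError):
            summarize_sim_one(pd.DataFrame())
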