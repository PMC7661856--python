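import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from benefitscore.burden import (
    classify_clonal_ccf,
    classify_clonal_ci,
    compute_benefit_score,
    compute_clonal_tmb,
    compute_math,
    compute_tmb,
    score_cohort,
)
from benefitscore.errors import DataError, RuleInapplicableError

from conftest import make_mutation_table
from oracles import math_bruteforce


class TestMath:
    def test_hand_worked_value(self):
        # median 0.3, raw MAD 0.1, scaled 0.14826 -> 49.42
        assert compute_math([0.1, 0.2, 0.3, 0.4, 0.5]) == pytest.approx(49.42)

    def test_zero_dispersion_gives_zero(self):
        assert compute_math([0.3] * 5) == 0.0

    def test_too_few_vafs_is_inestimable(self):
        assert math.isnan(compute_math([0.2, 0.4]))

    def test_out_of_range_vaf_rejected(self):
        with pytest.raises(DataError):
            compute_math([0.1, 0.2, 1.4, 0.3, 0.2])

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(200):
            vafs = rng.uniform(0.01, 1.0, size=rng.integers(5, 40))
            assert compute_math(vafs) == pytest.approx(math_bruteforce(vafs), abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(
        vafs=st.lists(st.floats(0.01, 1.0, allow_nan=False), min_size=5, max_size=30),
        seed=st.integers(0, 10_000),
    )
    def test_invariant_under_duplication_and_reorder(self, vafs, seed):
        base = compute_math(vafs)
        doubled = compute_math(vafs + vafs)
        shuffled = list(vafs)
        np.random.default_rng(seed).shuffle(shuffled)
        if math.isnan(base):
            assert math.isnan(compute_math(shuffled))
        else:
            assert doubled == pytest.approx(base, abs=1e-9)
            assert compute_math(shuffled) == pytest.approx(base, abs=1e-9)


class TestBenefitScore:
    def test_math_zero_substituted_by_one(self):
        score = compute_benefit_score(50, 0.0)
        assert score.score == 50.0 and score.math_substituted

    @pytest.mark.parametrize("tmb,math_val,expected", [(100, 50.0, 2.0), (0, 25.0, 0.0)])
    def test_plain_ratio(self, tmb, math_val, expected):
        score = compute_benefit_score(tmb, math_val)
        assert score.score == pytest.approx(expected) and not score.math_substituted

    def test_sentinel_propagates(self):
        assert math.isnan(compute_benefit_score(10, float("nan")).score)

    def test_negative_tmb_rejected(self):
        with pytest.raises(DataError):
            compute_benefit_score(-1, 10.0)

    @settings(max_examples=60, derandomize=True)
    @given(
        tmb=st.integers(1, 500),
        math_val=st.floats(1.0, 100.0),
        delta=st.floats(0.5, 50.0),
    )
    def test_monotone_in_both_arguments(self, tmb, math_val, delta):
        base = compute_benefit_score(tmb, math_val).score
        assert compute_benefit_score(tmb + 1, math_val).score > base
        assert compute_benefit_score(tmb, math_val + delta).score < base


class TestClonalityRules:
    @pytest.mark.parametrize("lower,expected", [(0.96, True), (0.95, False), (0.10, False)])
    def test_ci_rule_strict_boundary(self, lower, expected):
        assert classify_clonal_ci(lower) is expected

    def test_ci_rule_inapplicable_without_bound(self):
        with pytest.raises(RuleInapplicableError, match="CCF"):
            classify_clonal_ci(float("nan"))

    @pytest.mark.parametrize(
        "ccf,pc,ps,expected",
        [
            (1.0, None, None, True),
            (1.0 - 5e-10, None, None, True),  # within tolerance of 1
            (0.6, 0.7, 0.3, True),
            (0.6, 0.3, 0.7, False),
            (0.6, None, None, False),
        ],
    )
    def test_ccf_rule(self, ccf, pc, ps, expected):
        assert classify_clonal_ccf(ccf, pc, ps) is expected

    def test_clonal_tmb_under_ci_rule(self):
        ann = pd.DataFrame(
            {"sample_id": "S1", "chromosome": "1", "position": [1, 2, 3],
             "alt_allele": "T", "ccf_lower_ci": [0.97, 0.99, 0.40]}
        )
        assert compute_clonal_tmb(ann, rule="ci") == 2

    def test_clonal_tmb_empty_and_all_clonal(self):
        assert compute_clonal_tmb(pd.DataFrame(), rule="ccf") == 0
        ann = pd.DataFrame({"sample_id": "S1", "chromosome": "1",
                            "position": range(7), "alt_allele": "T", "ccf": [1.0] * 7})
        assert compute_clonal_tmb(ann, rule="ccf") == 7


class TestScoreCohort:
    def test_tmb_is_record_count(self):
        table = make_mutation_table(
            [("S1", "Missense_Mutation", 30, 70)] * 3 + [("S1", "Nonsense_Mutation", 30, 70)]
        )
        assert compute_tmb(table) == 4

    def test_exclusions_reported_not_dropped(self):
        rows = []
        for s in range(10):
            n = 3 if s < 2 else 8  # two samples below the MATH minimum
            rows += [(f"S{s}", "Missense_Mutation", 20 + i, 80 - i) for i in range(n)]
        scores = score_cohort(make_mutation_table(rows))
        assert len(scores) == 10
        assert int(scores["valid"].sum()) == 8
        assert math.isnan(scores.loc[~scores["valid"], "benefit_score"].iloc[0])

    def test_identical_vafs_give_score_equal_to_tmb(self):
        rows = [("S1", "Missense_Mutation", 40, 60)] * 6
        scores = score_cohort(make_mutation_table(rows))
        row = scores.iloc[0]
        assert row["math"] == 0.0
        assert row["math_substituted"]
        assert row["benefit_score"] == row["tmb"] == 6

    def test_empty_cohort(self):
        scores = score_cohort(make_mutation_table([]))
        assert len(scores) == 0

    def test_clonal_tmb_never_exceeds_tmb(self, small_cohort):
        from benefitscore.mutation_io import FilterPolicy
        from benefitscore.pipeline import _clonal_tmb_per_sample

        scores = score_cohort(small_cohort.mutation_table).set_index("sample_id")
        for rule in ("ci", "ccf"):
            ctmb = _clonal_tmb_per_sample(
                small_cohort.mutation_table,
                small_cohort.clonal_annotations,
                policy=FilterPolicy(),
                rule=rule,
            )
            merged = scores.join(ctmb.rename("ctmb")).fillna({"ctmb": 0})
            assert (merged["ctmb"] <= merged["tmb"]).all()
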