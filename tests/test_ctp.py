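"""CTP decision rule: worked examples, properties, and oracle equivalence."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from carescore import (
    CareTrajectory,
    CTPCategory,
    CTPConfig,
    Intervention,
    UndefinedInitiationError,
    Visit,
    classify_cohort_ctp,
    classify_ctp,
)
from conftest import ctp_oracle, make_cohort, make_trajectory

I = Intervention


class TestWorkedExamples:
    def test_late_initiation_is_inadequate_regardless_of_content(self):
        # plenty of content, but care starts after 14 completed weeks
        t = make_trajectory(
            [(16, {I.US: 1, I.BP: 1, I.BS: 1}),
             (20, {I.US: 1, I.BP: 2}),
             (32, {I.US: 1, I.BP: 4, I.BS: 1})]
        )
        assert classify_ctp(t).category is CTPCategory.INADEQUATE

    def test_below_minimum_without_exceedance_is_inadequate(self):
        # 2 US, 1 BP, 1 BS: BP and BS below their minima, nothing above range
        t = make_trajectory([(8, {I.US: 2, I.BP: 1, I.BS: 1})])
        assert classify_ctp(t).category is CTPCategory.INADEQUATE

    def test_below_minimum_with_exceedance_is_intermediate(self):
        # 8 US, 1 BP, 1 BS: under-provision of BP/BS but over-provision of US
        t = make_trajectory([(8, {I.US: 8, I.BP: 1, I.BS: 1})])
        assert classify_ctp(t).category is CTPCategory.INTERMEDIATE

    def test_minimum_package_at_recommended_times_is_appropriate(self):
        t = make_trajectory(
            [(8, {I.US: 1, I.BP: 1, I.BS: 1}),
             (20, {I.US: 1, I.BP: 2}),
             (32, {I.BP: 3, I.BS: 1})]
        )
        assert classify_ctp(t).category is CTPCategory.APPROPRIATE

    def test_right_totals_wrong_timing_is_sufficient(self):
        # totals meet every lower range but both ultrasounds fall in T3
        t = make_trajectory(
            [(8, {I.BP: 1, I.BS: 1}),
             (20, {I.BP: 2}),
             (32, {I.US: 2, I.BP: 3, I.BS: 1})]
        )
        assert classify_ctp(t).category is CTPCategory.SUFFICIENT

    def test_week_14_initiation_is_still_timely(self):
        t = make_trajectory([(14, {I.US: 2, I.BP: 6, I.BS: 2})])
        assert classify_ctp(t).category is not CTPCategory.INADEQUATE

    def test_count_equal_to_upper_range_is_not_exceedance(self):
        # US exactly at the upper bound, BP/BS below minimum: Inadequate,
        # not Intermediate ("exceeds the range" is read strictly)
        t = make_trajectory([(8, {I.US: 7, I.BP: 1, I.BS: 1})])
        assert classify_ctp(t).category is CTPCategory.INADEQUATE

    def test_timely_initiation_with_zero_content_is_inadequate(self):
        t = make_trajectory([(8, {}), (20, {}), (32, {})])
        assert classify_ctp(t).category is CTPCategory.INADEQUATE

    def test_rule_trace_ends_with_the_decision(self):
        t = make_trajectory([(8, {I.US: 8, I.BP: 1, I.BS: 1})])
        result = classify_ctp(t)
        assert result.rule_trace[-1] == "decision:intermediate"


class TestConfig:
    def test_minima_must_sum_to_lower_range(self):
        with pytest.raises(ValueError, match="sum"):
            CTPConfig(lower_range={I.US: 3, I.BP: 6, I.BS: 2})

    def test_lower_must_not_exceed_upper(self):
        with pytest.raises(ValueError, match="exceeds"):
            CTPConfig(upper_range={I.US: 1, I.BP: 10, I.BS: 10})

    def test_round_trips_through_json_dump(self):
        cfg = CTPConfig()
        assert CTPConfig.model_validate(cfg.model_dump(mode="json")) == cfg


class TestBatch:
    def test_composition_of_single_examples(self):
        cohort = make_cohort(
            make_trajectory([(16, {I.US: 2, I.BP: 6, I.BS: 2})], woman_id="late"),
            make_trajectory([(8, {I.US: 2, I.BP: 1, I.BS: 1})], woman_id="low"),
            make_trajectory([(8, {I.US: 8, I.BP: 1, I.BS: 1})], woman_id="over"),
            make_trajectory(
                [(8, {I.US: 1, I.BP: 1, I.BS: 1}),
                 (20, {I.US: 1, I.BP: 2}),
                 (32, {I.BP: 3, I.BS: 1})],
                woman_id="full",
            ),
        )
        labels = {
            w: r.category.label
            for w, r in classify_cohort_ctp(cohort).results.items()
        }
        assert labels == {
            "late": "Inadequate",
            "low": "Inadequate",
            "over": "Intermediate",
            "full": "Appropriate",
        }

    def test_empty_cohort(self):
        from carescore import Cohort

        out = classify_cohort_ctp(Cohort())
        assert out.results == {} and out.errors == {}

    def test_lenient_mode_reports_empty_trajectory(self):
        cohort = make_cohort(
            make_trajectory([(8, {I.US: 2, I.BP: 1, I.BS: 1})], woman_id="ok"),
            CareTrajectory("none", (), 40),
        )
        out = classify_cohort_ctp(cohort, strict=False)
        assert set(out.results) == {"ok"} and set(out.errors) == {"none"}
        with pytest.raises(UndefinedInitiationError):
            classify_cohort_ctp(cohort, strict=True)


# --- properties -----------------------------------------------------------

counts_strategy = st.fixed_dictionaries({c: st.integers(0, 12) for c in I})


class TestProperties:
    @given(
        start=st.integers(15, 40),
        t2=counts_strategy,
        t3=counts_strategy,
    )
    @settings(max_examples=100, derandomize=True)
    def test_late_initiation_dominates_any_content(self, start, t2, t3):
        visits = [(start, t2)]
        if start < 33:
            visits.append((start + 2, t3))
        t = make_trajectory(visits)
        assert classify_ctp(t).category is CTPCategory.INADEQUATE

    @given(
        extra_week=st.integers(0, 40),
        extra_code=st.sampled_from(list(I)),
        extra_n=st.integers(1, 5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_appropriate_is_monotone_under_added_interventions(
        self, extra_week, extra_code, extra_n
    ):
        base = [
            (8, {I.US: 1, I.BP: 1, I.BS: 1}),
            (20, {I.US: 1, I.BP: 2}),
            (32, {I.BP: 3, I.BS: 1}),
        ]
        t = make_trajectory(base + [(extra_week, {extra_code: extra_n})])
        assert classify_ctp(t).category is CTPCategory.APPROPRIATE

    @given(
        per_trimester=st.tuples(counts_strategy, counts_strategy, counts_strategy),
        split=st.integers(1, 4),
    )
    @settings(max_examples=100, derandomize=True)
    def test_label_invariant_to_visit_granularity(self, per_trimester, split):
        """Distributing the same (week, intervention) multiset over more
        visit rows never changes the CTP label: the tool counts actions,
        not visits."""
        weeks = (8, 20, 32)
        merged = make_trajectory(list(zip(weeks, per_trimester)))
        shredded = []
        for week, counts in zip(weeks, per_trimester):
            for code, n in counts.items():
                for _ in range(n):
                    shredded.append((week, {code: 1}))
            shredded.append((week, {}))  # keep the visit even if empty
        assert (
            classify_ctp(merged).category
            is classify_ctp(make_trajectory(shredded)).category
        )


class TestOracleEquivalence:
    def test_exhaustive_small_trajectory_grid(self):
        """Every classification over a dense grid of small trajectories
        matches an independently coded brute-force rule table."""
        us_levels = [0, 1, 2, 8]       # 8 exceeds the US upper range (7)
        bp_levels = [0, 2, 3, 11]      # 11 exceeds the BP upper range (10)
        bs_levels = [0, 1, 2]
        checked = 0
        for start in (6, 16):
            weeks = (start, 20, 32)
            for us in itertools.product(us_levels, repeat=3):
                for bp in itertools.product(bp_levels, repeat=3):
                    for bs in itertools.product(bs_levels, repeat=3):
                        t = CareTrajectory(
                            "w",
                            tuple(
                                Visit(w, {I.US: u, I.BP: b, I.BS: s})
                                for w, u, b, s in zip(weeks, us, bp, bs)
                            ),
                            40,
                        )
                        assert classify_ctp(t).category.label == ctp_oracle(t)
                        checked += 1
        assert checked >= 10_000
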