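import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneupr.scna import (
    EventCounts,
    arm_intensity,
    classify_sample_events,
    cohort_scna_scores,
    region_events,
)

from _oracles import brute_classify, random_profile_regions
from conftest import toy_profile


class TestRegionEvents:
    @pytest.mark.parametrize(
        "log2fc, expected",
        [
            (0.5, (1, 1)),
            (-1.2, (2, -1)),
            (0.05, (0, 0)),
            (0.1, (0, 0)),  # boundary is strictly not an event
            (-0.1, (0, 0)),
            (1.0, (1, 1)),  # exactly 1 stays a single event
            (-1.0, (1, -1)),
            (1.0000001, (2, 1)),
        ],
    )
    def test_thresholds(self, log2fc, expected):
        assert region_events(log2fc) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            region_events(float("nan"))

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=-3, max_value=3, allow_nan=False))
    def test_count_direction_consistency(self, fc):
        count, direction = region_events(fc)
        assert count in (0, 1, 2)
        if count == 0:
            assert direction == 0
        else:
            assert direction == (1 if fc > 0 else -1)


class TestArmIntensity:
    def test_length_weighted_mean(self, arms):
        # 40 kb at +1.0 and 60 kb at 0.0 inside chr1 p -> 0.40
        prof = toy_profile(
            "S1", [("1", 1, 40_000, 1.0), ("1", 40_001, 100_000, 0.0)]
        )
        intensity, covered = arm_intensity(prof, "1", "p", arms)
        assert covered
        assert intensity == pytest.approx(0.40)

    def test_full_arm_identity(self, arms):
        start, end = arms.arm_interval("2", "q")
        prof = toy_profile("S1", [("2", start, end, -0.3)])
        intensity, covered = arm_intensity(prof, "2", "q", arms)
        assert intensity == pytest.approx(-0.3)

    def test_uncovered_arm_flagged(self, arms):
        prof = toy_profile("S1", [("1", 1, 100, 0.5)])
        intensity, covered = arm_intensity(prof, "2", "p", arms)
        assert intensity == 0.0
        assert not covered

    def test_unknown_arm_errors(self, arms):
        prof = toy_profile("S1", [("1", 1, 100, 0.5)])
        with pytest.raises(KeyError):
            arm_intensity(prof, "1", "z", arms)


def _full_genome_profile(arms, p_fc, q_fc):
    rows = []
    for chrom in arms.table.index:
        for arm, fc in (("p", p_fc), ("q", q_fc)):
            s, e = arms.arm_interval(chrom, arm)
            rows.append((chrom, s, e, fc))
    return toy_profile("S1", rows)


class TestClassification:
    def test_all_chromosomes_doubly_gained_reaches_46(self, arms):
        prof = _full_genome_profile(arms, 1.5, 1.5)
        counts = classify_sample_events(prof, arms)
        assert counts.chromosomal == 46
        assert counts.arm == 0

    def test_opposite_arm_directions_reach_92(self, arms):
        prof = _full_genome_profile(arms, 1.5, -1.5)
        counts = classify_sample_events(prof, arms)
        assert counts.chromosomal == 0
        assert counts.arm == 92

    def test_small_gain_inside_neutral_arm_is_focal(self, arms):
        s, e = arms.arm_interval("5", "q")
        prof = toy_profile(
            "S1",
            [
                ("5", s, s + 2_000_000 - 1, 0.5),
                ("5", s + 2_000_000, e, 0.0),
            ],
        )
        counts = classify_sample_events(prof, arms)
        assert (counts.chromosomal, counts.arm, counts.focal) == (0, 0, 1)

    def test_whole_arm_event_is_not_focal(self, arms):
        s, e = arms.arm_interval("3", "p")
        prof = toy_profile("S1", [("3", s, e, 0.5)])
        counts = classify_sample_events(prof, arms)
        assert counts.arm == 1
        assert counts.focal == 0

    def test_matches_brute_force_oracle_on_random_profiles(self, arms, arm_dict):
        rng = np.random.default_rng(2024)
        for i in range(60):
            regions = random_profile_regions(rng, arm_dict)
            if not regions:
                continue
            prof = toy_profile(
                f"R{i}",
                regions,
            )
            got = classify_sample_events(prof, arms)
            want = brute_classify(regions, arm_dict)
            assert (got.chromosomal, got.arm, got.focal) == want

    def test_region_order_invariance(self, arms, arm_dict):
        rng = np.random.default_rng(5)
        regions = random_profile_regions(rng, arm_dict)
        a = classify_sample_events(toy_profile("A", regions), arms)
        b = classify_sample_events(toy_profile("B", regions[::-1]), arms)
        assert (a.chromosomal, a.arm, a.focal) == (b.chromosomal, b.arm, b.focal)

    def test_bounds_enforced_by_type(self):
        with pytest.raises(ValueError):
            EventCounts("S", 47, 0, 0)
        with pytest.raises(ValueError):
            EventCounts("S", 0, 93, 0)
        with pytest.raises(ValueError):
            EventCounts("S", -1, 0, 0)


class TestCohortScores:
    def test_linear_rescale(self):
        counts = [
            EventCounts("a", 0, 0, 0),
            EventCounts("b", 23, 10, 5),
            EventCounts("c", 46, 20, 10),
        ]
        scores = cohort_scna_scores(counts)
        assert scores.loc["a", "scaled_chromosomal"] == 0.0
        assert scores.loc["b", "scaled_chromosomal"] == pytest.approx(0.5)
        assert scores.loc["c", "scaled_chromosomal"] == 1.0
        assert scores.loc["c", "combined"] == pytest.approx(3.0)
        assert scores.loc["a", "combined"] == 0.0

    def test_combined_is_sum_of_components(self):
        rng = np.random.default_rng(1)
        counts = [
            EventCounts(f"s{i}", int(rng.integers(0, 47)), int(rng.integers(0, 93)),
                        int(rng.integers(0, 200)))
            for i in range(30)
        ]
        scores = cohort_scna_scores(counts)
        np.testing.assert_allclose(
            scores["combined"],
            scores[["scaled_chromosomal", "scaled_arm", "scaled_focal"]].sum(axis=1),
        )

    def test_rescaling_is_monotone(self):
        rng = np.random.default_rng(2)
        counts = [
            EventCounts(f"s{i}", int(rng.integers(0, 47)), 0, 0) for i in range(20)
        ]
        scores = cohort_scna_scores(counts)
        ordered = scores.sort_values("chromosomal")
        assert ordered["scaled_chromosomal"].is_monotonic_increasing

    def test_degenerate_category_warns_and_zeroes(self):
        counts = [EventCounts("a", 5, 0, 1), EventCounts("b", 5, 0, 2)]
        with pytest.warns(UserWarning, match="degenerate"):
            scores = cohort_scna_scores(counts)
        assert (scores["scaled_chromosomal"] == 0).all()

    def test_single_sample_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_scna_scores([EventCounts("a", 1, 1, 1)])

    def test_sample_order_invariance(self):
        counts = [
            EventCounts("a", 3, 7, 2),
            EventCounts("b", 10, 1, 9),
            EventCounts("c", 0, 4, 4),
        ]
        s1 = cohort_scna_scores(counts)
        s2 = cohort_scna_scores(counts[::-1]).loc[s1.index]
        pd.testing.assert_frame_equal(s1, s2)
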