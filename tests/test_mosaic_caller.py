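"""Unit and property tests for AAF estimation and mosaic classification."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from mosascan.caller import (
    CallStatus,
    ChromClass,
    ThresholdMode,
    ThresholdPolicy,
    classify_chrom,
    classify_observation,
    compute_aaf,
    concordance,
    derive_het_thresholds,
    filter_common,
)
from mosascan.cohort import Sex


class TestComputeAaf:
    def test_exact_ratio(self):
        assert compute_aaf(18, 100).value == pytest.approx(0.18)

    def test_zero_boundary(self):
        estimate = compute_aaf(0, 50)
        assert estimate.value == 0.0
        assert estimate.ci_low == 0.0

    def test_full_boundary(self):
        estimate = compute_aaf(50, 50)
        assert estimate.value == 1.0
        assert estimate.ci_high == 1.0

    def test_ci_contains_half_for_balanced_counts(self):
        estimate = compute_aaf(65, 130, alpha=0.05)
        assert estimate.ci_low < 0.5 < estimate.ci_high

    def test_matches_independent_clopper_pearson(self):
        # statsmodels 'beta' method is an independent Clopper-Pearson source
        for alt, total in [(1, 20), (18, 100), (65, 130), (199, 200)]:
            estimate = compute_aaf(alt, total, alpha=0.05)
            low, high = proportion_confint(alt, total, alpha=0.05, method="beta")
            assert estimate.ci_low == pytest.approx(low, abs=1e-9)
            assert estimate.ci_high == pytest.approx(high, abs=1e-9)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            compute_aaf(5, 0)
        with pytest.raises(ValueError):
            compute_aaf(11, 10)
        with pytest.raises(ValueError):
            compute_aaf(-1, 10)

    @given(
        total=st.integers(min_value=1, max_value=500),
        data=st.data(),
    )
    def test_ci_ordering_invariant(self, total, data):
        alt = data.draw(st.integers(min_value=0, max_value=total))
        estimate = compute_aaf(alt, total)
        assert 0.0 <= estimate.ci_low <= estimate.value <= estimate.ci_high <= 1.0


class TestDeriveHetThresholds:
    def test_normal_matches_published_cutoffs_at_depth_48(self):
        lower, upper = derive_het_thresholds(48, 0.05, "normal")
        assert lower == pytest.approx(0.5 - 1.959964 * 0.5 / math.sqrt(48), abs=1e-6)
        assert abs(lower - 0.36) < 0.005
        assert abs(upper - 0.64) < 0.005

    def test_normal_tight_alpha_at_depth_130(self):
        lower, upper = derive_het_thresholds(130, 0.001, "normal")
        assert lower == pytest.approx(0.3557, abs=5e-4)
        assert upper == pytest.approx(0.6443, abs=5e-4)

    def test_interval_shrinks_with_depth(self):
        widths = []
        for depth in (20, 80, 320, 1280, 100_000):
            lower, upper = derive_het_thresholds(depth, 0.05, "normal")
            widths.append(upper - lower)
        assert widths == sorted(widths, reverse=True)
        assert widths[-1] < 0.01  # collapses toward (0.5, 0.5)

    def test_exact_symmetric_and_contains_half(self):
        for depth in (20, 48, 130):
            lower, upper = derive_het_thresholds(depth, 0.05, "exact")
            assert lower < 0.5 < upper
            assert lower + upper == pytest.approx(1.0)

    def test_exact_narrows_over_depth_doublings(self):
        widths = []
        for depth in (20, 40, 80, 160, 320, 640):
            lower, upper = derive_het_thresholds(depth, 0.05, "exact")
            widths.append(upper - lower)
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_exact_tail_mass_respects_alpha(self):
        from scipy.stats import binom

        for depth in (20, 48, 130, 333):
            lower, _ = derive_het_thresholds(depth, 0.05, "exact")
            k = round(lower * depth)
            assert 2 * binom.cdf(k - 1, depth, 0.5) <= 0.05
            # one more read of slack would break the alpha budget
            assert 2 * binom.cdf(k, depth, 0.5) > 0.05

    def test_errors(self):
        with pytest.raises(ValueError):
            derive_het_thresholds(0, 0.05)
        with pytest.raises(ValueError):
            derive_het_thresholds(100, 0.0)
        with pytest.raises(ValueError):
            derive_het_thresholds(100, 0.05, "bogus")


class TestClassifyObservation:
    def test_low_fraction_diploid_flagged(self, policy):
        call = classify_observation(23, 130, Sex.FEMALE, ChromClass.AUTOSOME, policy)
        assert call.aaf.value == pytest.approx(0.1769, abs=1e-3)
        assert call.status is CallStatus.CANDIDATE_MOSAIC_LOW

    def test_high_fraction_diploid_flagged(self, policy):
        call = classify_observation(104, 130, Sex.FEMALE, ChromClass.AUTOSOME, policy)
        assert call.status is CallStatus.CANDIDATE_MOSAIC_HIGH

    def test_high_fraction_male_x_is_hemi_candidate(self, policy):
        call = classify_observation(111, 130, Sex.MALE, ChromClass.X_NONPAR, policy)
        assert call.aaf.value == pytest.approx(0.8538, abs=1e-3)
        assert call.status is CallStatus.CANDIDATE_MOSAIC_HEMI

    def test_balanced_het_consistent(self, policy):
        call = classify_observation(50, 100, Sex.MALE, ChromClass.AUTOSOME, policy)
        assert call.status is CallStatus.CONSISTENT_HET

    def test_insufficient_depth(self, policy):
        call = classify_observation(3, 10, Sex.FEMALE, ChromClass.AUTOSOME, policy)
        assert call.status is CallStatus.INSUFFICIENT_DEPTH

    def test_male_x_below_detection_and_consistent(self, policy):
        low = classify_observation(4, 100, Sex.MALE, ChromClass.X_NONPAR, policy)
        assert low.status is CallStatus.BELOW_DETECTION
        high = classify_observation(95, 100, Sex.MALE, ChromClass.X_NONPAR, policy)
        assert high.status is CallStatus.CONSISTENT_HEMI

    def test_hemi_band_inclusive_at_ten_percent(self, policy):
        call = classify_observation(10, 100, Sex.MALE, ChromClass.X_NONPAR, policy)
        assert call.status is CallStatus.CANDIDATE_MOSAIC_HEMI

    def test_tie_at_het_lower_stays_consistent(self, policy):
        # strict inequality: AAF exactly 0.36 is not "less than 36%"
        call = classify_observation(36, 100, Sex.FEMALE, ChromClass.AUTOSOME, policy)
        assert call.status is CallStatus.CONSISTENT_HET

    def test_unknown_sex_on_x_is_uncallable(self, policy):
        call = classify_observation(30, 100, Sex.UNKNOWN, ChromClass.X_NONPAR, policy)
        assert call.status is CallStatus.UNCALLABLE

    def test_female_x_uses_diploid_thresholds(self, policy):
        call = classify_observation(20, 100, Sex.FEMALE, ChromClass.X_NONPAR, policy)
        assert call.status is CallStatus.CANDIDATE_MOSAIC_LOW

    def test_depth_adaptive_mode_uses_exact_interval(self):
        policy = ThresholdPolicy(mode=ThresholdMode.DEPTH_ADAPTIVE, alpha=0.05)
        lower, _ = derive_het_thresholds(200, 0.05, "exact")
        alt_inside = math.ceil(lower * 200)
        inside = classify_observation(alt_inside, 200, Sex.FEMALE, ChromClass.AUTOSOME, policy)
        outside = classify_observation(alt_inside - 1, 200, Sex.FEMALE, ChromClass.AUTOSOME, policy)
        assert inside.status is CallStatus.CONSISTENT_HET
        assert outside.status is CallStatus.CANDIDATE_MOSAIC_LOW

    @given(
        total=st.integers(min_value=20, max_value=400),
        data=st.data(),
    )
    def test_diploid_symmetry(self, total, data):
        alt = data.draw(st.integers(min_value=0, max_value=total))
        policy = ThresholdPolicy()
        low = classify_observation(alt, total, Sex.FEMALE, ChromClass.AUTOSOME, policy)
        high = classify_observation(total - alt, total, Sex.FEMALE, ChromClass.AUTOSOME, policy)
        is_low = low.status is CallStatus.CANDIDATE_MOSAIC_LOW
        mirrored_high = high.status is CallStatus.CANDIDATE_MOSAIC_HIGH
        assert is_low == mirrored_high

    def test_fixed_mode_is_deterministic(self, policy):
        calls = {
            classify_observation(23, 130, Sex.FEMALE, ChromClass.AUTOSOME, policy).status
            for _ in range(5)
        }
        assert len(calls) == 1


class TestClassifyChrom:
    @pytest.mark.parametrize(
        ("chrom", "pos", "expected"),
        [
            ("1", 1000, ChromClass.AUTOSOME),
            ("chr22", 5, ChromClass.AUTOSOME),
            ("X", 10_000_000, ChromClass.X_NONPAR),
            ("chrX", 1_000_000, ChromClass.AUTOSOME),  # PAR1 is diploid
            ("X", 155_000_000, ChromClass.AUTOSOME),  # PAR2
            ("Y", 1_000_000, ChromClass.OTHER),
            ("MT", 100, ChromClass.OTHER),
        ],
    )
    def test_examples(self, chrom, pos, expected):
        assert classify_chrom(chrom, pos) is expected


class TestConcordance:
    def test_identical_lists(self):
        assert concordance([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == pytest.approx(1.0)

    def test_reversed_lists(self):
        assert concordance([0.1, 0.2, 0.3], [0.3, 0.2, 0.1]) == pytest.approx(-1.0)

    def test_rank_agreement(self):
        # same ranks despite different values -> rho 1 by rank-agreement oracle
        assert concordance(
            [0.1, 0.2, 0.3, 0.4], [0.12, 0.18, 0.33, 0.41]
        ) == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            concordance([0.1, 0.2], [0.1, 0.2])
        with pytest.raises(ValueError):
            concordance([0.1, 0.2, 0.3], [0.1, 0.2])


class _Record:
    def __init__(self, locus):
        self.locus = locus


class TestFilterCommon:
    def test_common_removed(self):
        records = [_Record("a"), _Record("b")]
        kept = list(filter_common(records, {"a": 0.2, "b": 0.001}, threshold=0.01))
        assert [r.locus for r in kept] == ["b"]

    def test_missing_frequency_kept(self):
        records = [_Record("a")]
        kept = list(filter_common(records, {}, threshold=0.01))
        assert len(kept) == 1

    def test_empty_stream(self):
        assert list(filter_common([], {"a": 0.5})) == []

    def test_counts_conserved(self):
        records = [_Record(x) for x in "abcdef"]
        af = {"a": 0.5, "b": 0.001, "c": 0.01}
        kept = list(filter_common(records, af, threshold=0.01))
        removed = len(records) - len(kept)
        assert removed == 2  # 'a' (0.5) and 'c' (exactly at threshold)
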