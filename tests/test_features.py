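"""Expression features (hand-counted oracle), sequence composition, CFS."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ssmirna.features import (
    EXPRESSION_FEATURE_NAMES,
    Interval,
    PrecursorProfile,
    best_first_cfs,
    cfs_merit,
    compute_basic_sequence_features,
    compute_expression_features,
    correlations_for_cfs,
    select_features_cfs,
)
from tests.conftest import TOY_PROFILE_EXPECTED


def make_profile(**overrides):
    base = dict(
        id="p",
        sequence="ACGU" * 15,
        structure="(" * 20 + "." * 20 + ")" * 20,
        mature=Interval(1, 20),
        star=Interval(41, 60),
        loop=Interval(21, 40),
        reads=[(1, 20, 10)],
        library_size=1000,
    )
    base.update(overrides)
    return PrecursorProfile(**base)


class TestPrecursorProfileValidation:
    def test_unbalanced_structure_rejected(self):
        with pytest.raises(ValueError, match="brackets"):
            make_profile(structure="(" * 21 + "." * 19 + ")" * 20)

    def test_structure_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            make_profile(structure="(.)")

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_profile(mature=Interval(1, 25))

    def test_read_outside_precursor_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_profile(reads=[(50, 70, 3)])

    def test_zero_count_read_rejected(self):
        with pytest.raises(ValueError, match="count"):
            make_profile(reads=[(1, 20, 0)])

    def test_t_mapped_to_u(self):
        profile = make_profile(sequence="ACGT" * 15)
        assert set(profile.sequence) == {"A", "C", "G", "U"}


class TestExpressionFeatures:
    def test_hand_counted_fixture(self, toy_profile):
        vector = compute_expression_features(toy_profile).to_array()
        np.testing.assert_allclose(vector, TOY_PROFILE_EXPECTED, atol=1e-12)

    def test_all_reads_on_mature_with_matching_ends(self):
        profile = make_profile(reads=[(1, 20, 10)])
        v = compute_expression_features(profile)
        assert v.pct_reads_mature == 100.0
        assert v.pct_reads_loop == 0.0 and v.pct_reads_star == 0.0
        assert v.pct_reads_dicer_consistent == 100.0
        assert v.pct_reads_dicer_inconsistent == 0.0

    def test_fully_paired_mature_gives_100_percent(self):
        profile = make_profile()
        assert compute_expression_features(profile).pct_mature_paired == 100.0

    def test_zero_reads_is_an_error(self):
        profile = make_profile()
        profile.reads = []
        with pytest.raises(ValueError, match="no expression evidence"):
            compute_expression_features(profile)

    def test_region_percentages_bounded_and_tight_when_reads_covered(self, toy_profile):
        v = compute_expression_features(toy_profile)
        total = v.pct_reads_mature + v.pct_reads_loop + v.pct_reads_star
        assert total <= 100.0 + 1e-9
        # every fixture read overlaps a region, so shares are exhaustive
        assert total == pytest.approx(100.0)

    def test_read_outside_all_regions_lowers_the_sum(self):
        profile = make_profile(
            mature=Interval(5, 20),
            reads=[(5, 20, 8), (1, 3, 2)],  # second read overlaps nothing
        )
        v = compute_expression_features(profile)
        assert v.pct_reads_mature + v.pct_reads_loop + v.pct_reads_star == pytest.approx(80.0)

    def test_lower_stem_inferred_from_arm_flanks(self):
        # no annotation: flanks [1,4]+[57,60] of the fixture layout
        profile = make_profile(
            structure="(" * 8 + "." + "(" * 15 + "." * 12 + ")" * 15 + "." + ")" * 8,
            mature=Interval(5, 24),
            star=Interval(37, 56),
            loop=Interval(25, 36),
            reads=[(5, 24, 10)],
        )
        v = compute_expression_features(profile)
        assert v.n_paired_lower_stem == 8.0  # 4 paired nts on each flank

    def test_rpm_normalization(self):
        profile = make_profile(reads=[(1, 20, 50)], library_size=2_000_000)
        assert compute_expression_features(profile).total_reads_rpm == pytest.approx(25.0)


class TestSequenceFeatures:
    def test_gc_fraction_of_pure_gc(self):
        v = compute_basic_sequence_features("GCGC")
        assert v[16] == 1.0

    def test_homopolymer_dinucleotides(self):
        v = compute_basic_sequence_features("AAAA")
        assert v[0] == 1.0  # AA
        assert v[1:16].sum() == 0.0

    def test_dinucleotide_frequencies_normalized(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGU"), 100))
        v = compute_basic_sequence_features(seq)
        assert v[:16].sum() == pytest.approx(1.0, abs=1e-12)

    def test_structure_entries(self):
        v = compute_basic_sequence_features("GGGAAACCC", "(((...)))")
        assert v[17] == pytest.approx(6 / 9)  # paired fraction
        assert v[18] == 1.0  # one hairpin loop

    def test_invalid_alphabet_reports_positions(self):
        with pytest.raises(ValueError, match=r"positions \[2"):
            compute_basic_sequence_features("AXGU")


class TestCfsMerit:
    def names(self, k):
        return [f"f{i}" for i in range(k)]

    def corr_inputs(self, r_cf_values, r_ff_matrix):
        names = self.names(len(r_cf_values))
        return (
            pd.Series(r_cf_values, index=names),
            pd.DataFrame(r_ff_matrix, index=names, columns=names),
        )

    def test_singleton_collapses_to_class_correlation(self):
        r_cf, r_ff = self.corr_inputs([0.8], [[1.0]])
        assert cfs_merit(["f0"], r_cf, r_ff) == pytest.approx(0.8)

    def test_two_uncorrelated_features(self):
        r_cf, r_ff = self.corr_inputs([0.5, 0.5], [[1, 0], [0, 1]])
        assert cfs_merit(["f0", "f1"], r_cf, r_ff) == pytest.approx(2 * 0.5 / np.sqrt(2))

    def test_zero_class_correlation_gives_zero_merit(self):
        r_cf, r_ff = self.corr_inputs([0.0, 0.0], [[1, 0.3], [0.3, 1]])
        assert cfs_merit(["f0", "f1"], r_cf, r_ff) == 0.0

    def test_empty_subset_rejected(self):
        r_cf, r_ff = self.corr_inputs([0.5], [[1.0]])
        with pytest.raises(ValueError):
            cfs_merit([], r_cf, r_ff)

    def test_adding_uninformative_correlated_feature_never_helps(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            r = rng.random()
            r_cf, r_ff = self.corr_inputs(
                [rng.random() * 0.9 + 0.05, 0.0],
                [[1, r], [r, 1]],
            )
            alone = cfs_merit(["f0"], r_cf, r_ff)
            both = cfs_merit(["f0", "f1"], r_cf, r_ff)
            assert both <= alone + 1e-12


class TestCfsSearch:
    def test_duplicate_feature_collapses(self):
        rng = np.random.default_rng(4)
        n = 200
        y = rng.integers(0, 2, n)
        signal = y + rng.normal(0, 0.5, n)
        other = -y + rng.normal(0, 0.5, n)
        frame = pd.DataFrame({"f1": signal, "f2": signal.copy(), "f3": other})
        result = select_features_cfs(frame, y)
        assert "f3" in result.selected
        assert len({"f1", "f2"} & set(result.selected)) == 1

    def test_single_informative_feature_found_among_noise(self):
        rng = np.random.default_rng(9)
        n = 400
        y = rng.integers(0, 2, n)
        frame = pd.DataFrame(rng.standard_normal((n, 6)), columns=[f"n{i}" for i in range(6)])
        frame["signal"] = y + rng.normal(0, 0.4, n)
        result = select_features_cfs(frame, y)
        assert "signal" in result.selected

    def test_constant_column_dropped_not_fatal(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 50)
        frame = pd.DataFrame(
            {"c": np.ones(50), "a": y + rng.normal(0, 1, 50), "b": rng.standard_normal(50)}
        )
        result = select_features_cfs(frame, y)
        assert result.dropped_constant == ["c"]
        assert "c" not in result.selected

    def test_fewer_than_two_features_rejected(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="at least two"):
            select_features_cfs(frame, [0, 1, 0, 1])

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_on_small_data_designs(self, trial):
        rng = np.random.default_rng(300 + trial)
        k = int(rng.integers(3, 8))
        n = 60
        y = rng.integers(0, 2, n)
        shifts = rng.random(k) * rng.integers(0, 2, k)
        X = rng.standard_normal((n, k)) + np.outer(y, shifts)
        frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(k)])
        result = select_features_cfs(frame, y)
        r_cf, r_ff, _ = correlations_for_cfs(frame, y)
        brute = max(
            cfs_merit(list(s), r_cf, r_ff)
            for r in range(1, k + 1)
            for s in itertools.combinations(frame.columns, r)
        )
        assert result.merit == pytest.approx(brute, abs=1e-9)

    def test_deterministic_tie_break_prefers_smaller_names(self):
        names = ["a", "b"]
        r_cf = pd.Series([0.6, 0.6], index=names)
        r_ff = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=names, columns=names)
        result = best_first_cfs(r_cf, r_ff)
        assert result.selected == ["a"]
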