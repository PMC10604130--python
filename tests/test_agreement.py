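"""Bland-Altman agreement, maximum allowed limits, repeatability."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from qpmorph import (
    InsufficientDataError,
    MorphometryRecord,
    UndefinedRatioError,
    bland_altman,
    characteristic_values,
    compare_repeatability,
    max_allowed_limit,
    per_cell_differences,
    repeatability_summary,
    with_allowed_limit,
)


def _rec(cell, modality, replicate, length, width=3.0, acro=50.0):
    return MorphometryRecord(
        subject_id="s", cell_id=cell, modality=modality, replicate=replicate,
        head_length_um=length, head_width_um=width, lw_ratio=length / width,
        acrosome_pct=acro,
    )


@pytest.fixture
def paired_cell():
    """One cell: qpm replicates (4.6, 4.8), reference replicates (4.5, 4.5)."""
    return [
        _rec("c1", "qpm", 1, 4.6),
        _rec("c1", "qpm", 2, 4.8),
        _rec("c1", "reference", 1, 4.5),
        _rec("c1", "reference", 2, 4.5),
    ]


class TestDifferences:
    def test_between_modalities_uses_replicate_means(self, paired_cell):
        diffs = per_cell_differences(paired_cell, "head_length_um")
        assert diffs.values == pytest.approx([0.2])

    def test_within_modality_identical_replicates(self):
        recs = [_rec("c1", "qpm", 1, 4.6), _rec("c1", "qpm", 2, 4.6)]
        diffs = per_cell_differences(recs, "head_length_um", "within_modality", "qpm")
        assert diffs.values == pytest.approx([0.0])

    def test_count_conservation(self, clean_bundle):
        diffs = per_cell_differences(clean_bundle.records_frame(), "head_length_um")
        assert diffs.n == clean_bundle.config.n_cells
        assert diffs.n_dropped == 0

    def test_one_sided_cells_dropped_and_counted(self, paired_cell):
        extra = [_rec("c2", "qpm", 1, 4.0), _rec("c2", "qpm", 2, 4.1)]
        diffs = per_cell_differences(paired_cell + extra, "head_length_um")
        assert diffs.n == 1
        assert diffs.n_dropped == 1

    def test_no_eligible_cells_raises(self):
        recs = [_rec("c1", "qpm", 1, 4.6)]
        with pytest.raises(InsufficientDataError):
            per_cell_differences(recs, "head_length_um")


class TestBlandAltman:
    def test_hand_computed_example(self):
        result = bland_altman([0.1, 0.2, 0.3])
        assert result.bias == pytest.approx(0.2)
        assert result.sd == pytest.approx(0.1)  # n-1 denominator
        assert result.loa_lower == pytest.approx(0.004)
        assert result.loa_upper == pytest.approx(0.396)

    def test_zero_differences(self):
        result = bland_altman([0.0, 0.0, 0.0])
        assert (result.bias, result.sd) == (0.0, 0.0)
        assert result.loa_lower == result.loa_upper == 0.0

    def test_printed_inputs_reproduce_reported_interval(self):
        """bias 0.18, sd 0.32 give LoA (-0.447, 0.807); the reported
        (-0.442, 0.808) agrees within the rounding of two-decimal inputs."""
        lower, upper = 0.18 - 1.96 * 0.32, 0.18 + 1.96 * 0.32
        assert round(lower, 3) == -0.447
        assert round(upper, 3) == 0.807
        assert lower == pytest.approx(-0.442, abs=0.015)
        assert upper == pytest.approx(0.808, abs=0.015)

    def test_loa_width_invariant(self):
        rng = np.random.default_rng(0)
        result = bland_altman(rng.normal(0.2, 0.5, 40))
        assert result.loa_upper - result.loa_lower == pytest.approx(2 * 1.96 * result.sd, abs=1e-9)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([0.1])

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.3, 0.2, 50)
        a, b = bland_altman(d), bland_altman(-d)
        assert b.bias == pytest.approx(-a.bias)
        assert b.sd == pytest.approx(a.sd)
        assert b.loa_lower == pytest.approx(-a.loa_upper)
        ala = with_allowed_limit(a, 0.32)
        alb = with_allowed_limit(b, 0.32)
        assert alb.al == pytest.approx(ala.al)


@given(st.lists(st.floats(-100, 100), min_size=2, max_size=60))
def test_bias_sd_match_two_pass_oracle(values):
    """Implementation agrees with a brute-force two-pass mean/SD to 1e-12."""
    result = bland_altman(values)
    mean = sum(values) / len(values)
    var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
    assert result.bias == pytest.approx(mean, abs=1e-12, rel=1e-12)
    assert result.sd == pytest.approx(math.sqrt(var), abs=1e-12, rel=1e-12)


class TestMaxAllowedLimit:
    @pytest.mark.parametrize(
        "ref_sd,agr_sd,expected",
        [(0.0, 0.0, 0.0), (3.0, 0.0, 3.0), (0.32, 0.32, math.sqrt(0.32**2 * 1.1))],
    )
    def test_default_variant(self, ref_sd, agr_sd, expected):
        assert max_allowed_limit(ref_sd, agr_sd) == pytest.approx(expected)
        assert max_allowed_limit(0.32, 0.32) == pytest.approx(0.3356, abs=5e-4)

    def test_alternate_variants(self):
        assert max_allowed_limit(0.3, 0.4, "rss_scaled") == pytest.approx(
            math.sqrt(0.09 + 0.0016)
        )
        assert max_allowed_limit(0.3, 0.4, "linear") == pytest.approx(0.34)

    def test_negative_input_raises(self):
        with pytest.raises(ValueError):
            max_allowed_limit(-0.1, 0.2)

    @given(
        r=st.floats(0, 10), a=st.floats(0, 10), dr=st.floats(0, 5), da=st.floats(0, 5)
    )
    def test_monotone_nondecreasing(self, r, a, dr, da):
        for variant in ("rss_downweighted", "rss_scaled", "linear"):
            assert max_allowed_limit(r + dr, a + da, variant) >= max_allowed_limit(r, a, variant)

    def test_outer_limits_bracket_loa(self):
        result = with_allowed_limit(bland_altman([0.1, 0.2, 0.35]), 0.3)
        assert result.outer_lower < result.loa_lower
        assert result.outer_upper > result.loa_upper


class TestRepeatability:
    def test_identical_replicates(self):
        recs = [_rec(f"c{i}", "qpm", r, 4.5) for i in range(3) for r in (1, 2)]
        result = repeatability_summary(recs, "head_length_um", "qpm")
        assert result.bias == 0.0 and result.sd == 0.0

    def test_swapping_replicates_negates_bias(self):
        recs, swapped = [], []
        rng = np.random.default_rng(2)
        for i in range(20):
            v1, v2 = 4.5 + rng.normal(0, 0.1, 2)
            recs += [_rec(f"c{i}", "qpm", 1, v1), _rec(f"c{i}", "qpm", 2, v2)]
            swapped += [_rec(f"c{i}", "qpm", 1, v2), _rec(f"c{i}", "qpm", 2, v1)]
        a = repeatability_summary(recs, "head_length_um", "qpm")
        b = repeatability_summary(swapped, "head_length_um", "qpm")
        assert b.bias == pytest.approx(-a.bias)
        assert b.sd == pytest.approx(a.sd)

    def test_single_replicate_cells_insufficient(self):
        recs = [_rec(f"c{i}", "qpm", 1, 4.5) for i in range(5)]
        with pytest.raises(InsufficientDataError):
            repeatability_summary(recs, "head_length_um", "qpm")


class TestSdRatio:
    def _result(self, sd, n, seed):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            v = 4.5 + rng.normal(0, sd / math.sqrt(2), 2)
            recs += [_rec(f"c{i}", "qpm", 1, v[0]), _rec(f"c{i}", "qpm", 2, v[1])]
        return repeatability_summary(recs, "head_length_um", "qpm")

    def test_identical_vectors_ratio_one(self):
        a = self._result(0.2, 60, seed=3)
        cmp = compare_repeatability(a, a, bootstrap_reps=500, seed=0)
        assert cmp.ratio == pytest.approx(1.0)
        assert cmp.ci_lower <= 1.0 <= cmp.ci_upper
        assert not cmp.significant

    def test_clearly_different_sds_detected(self):
        a = self._result(0.13, 114, seed=4)
        b = self._result(0.32, 300, seed=5)
        cmp = compare_repeatability(a, b, bootstrap_reps=500, seed=1)
        assert cmp.ratio < 1
        assert cmp.significant

    def test_deterministic_under_seed(self):
        a, b = self._result(0.1, 40, 6), self._result(0.2, 40, 7)
        r1 = compare_repeatability(a, b, bootstrap_reps=300, seed=9)
        r2 = compare_repeatability(a, b, bootstrap_reps=300, seed=9)
        assert (r1.ci_lower, r1.ci_upper) == (r2.ci_lower, r2.ci_upper)

    def test_zero_denominator_raises(self):
        a = self._result(0.1, 20, 8)
        zero = repeatability_summary(
            [_rec(f"z{i}", "qpm", r, 4.5) for i in range(3) for r in (1, 2)],
            "head_length_um", "qpm",
        )
        with pytest.raises(UndefinedRatioError):
            compare_repeatability(a, zero, bootstrap_reps=300, seed=0)


class TestCharacteristicValues:
    def test_median_of_two_cells(self):
        recs = []
        for cell, val in (("c1", 4.6), ("c2", 4.8)):
            recs += [_rec(cell, "qpm", 1, val), _rec(cell, "reference", 1, val)]
        assert characteristic_values(recs)["head_length_um"] == pytest.approx(4.7)

    def test_single_cell_is_its_own_mean(self, paired_cell):
        # qpm mean 4.7, reference mean 4.5 -> cell mean 4.6
        assert characteristic_values(paired_cell)["head_length_um"] == pytest.approx(4.6)

    def test_normal_cohort_medians_inside_who_ranges(self, ranges, clean_bundle):
        df = clean_bundle.records_frame()
        normal = df[df["a_priori_class"] == "normal"]
        values = characteristic_values(normal)
        for endpoint, median in values.items():
            assert ranges[endpoint].contains(median)
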