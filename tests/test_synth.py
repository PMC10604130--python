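"""Synthetic study generator: sampling, rendering, measurement simulation."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from qpmorph import (
    ConfigurationError,
    EndpointNoise,
    ENDPOINTS,
    ModalityNoiseModel,
    ResolutionError,
    SpermGroundTruth,
    StudyConfig,
    bland_altman,
    default_noise_models,
    per_cell_differences,
    records_to_frame,
    render_masks,
    render_phase_image,
    sample_ground_truth,
    simulate_measurement_table,
    simulate_study,
    zero_noise_models,
)
from qpmorph.synth import cap_cut_fraction, solve_cap_cut


class TestSampleGroundTruth:
    def test_cohort_counts(self, ranges):
        truths = sample_ground_truth(326, normal_share=0.61, seed=3)
        n_normal = sum(t.a_priori_class == "normal" for t in truths)
        assert n_normal == 199
        assert len(truths) - n_normal == 127

    def test_class_separation(self, ranges):
        """Normal truths violate no WHO range; abnormal truths clearly violate one."""
        truths = sample_ground_truth(400, normal_share=0.5, seed=5)
        for t in truths:
            violations = [
                e
                for e in ENDPOINTS
                if not ranges[e].contains(t.endpoint(e))
            ]
            if t.a_priori_class == "normal":
                assert violations == []
            else:
                assert violations, f"abnormal truth {t.cell_id} violates no range"
                # at least one violation clears the 5%-of-width margin
                assert any(
                    t.endpoint(e) < ranges[e].lower - 0.05 * ranges[e].width
                    or t.endpoint(e) > ranges[e].upper + 0.05 * ranges[e].width
                    for e in violations
                )

    def test_single_normal_within_ranges(self):
        (t,) = sample_ground_truth(1, normal_share=1.0, seed=0)
        assert 3.7 <= t.head_length_um <= 4.7
        assert 2.5 <= t.head_width_um <= 3.2
        assert 1.3 <= t.lw_ratio <= 1.8
        assert 40 <= t.acrosome_pct <= 70

    def test_ratio_consistency_exact(self):
        for t in sample_ground_truth(50, normal_share=0.5, seed=1):
            assert t.lw_ratio == t.head_length_um / t.head_width_um

    def test_deterministic(self):
        a = sample_ground_truth(30, normal_share=0.6, seed=42)
        b = sample_ground_truth(30, normal_share=0.6, seed=42)
        assert a == b

    @pytest.mark.parametrize("n,share", [(0, 0.5), (-3, 0.5), (5, 1.2), (5, -0.1)])
    def test_invalid_arguments(self, n, share):
        with pytest.raises(ValueError):
            sample_ground_truth(n, normal_share=share, seed=0)


class TestRendering:
    def test_cap_cut_roundtrip(self):
        for f in (0.0, 0.1, 0.4, 0.5, 0.7, 1.0):
            assert cap_cut_fraction(solve_cap_cut(f)) == pytest.approx(f, abs=1e-10)

    def test_mask_area_oracle(self, canonical_truth):
        """Pixel-counting the noiseless mask recovers the analytic ellipse area."""
        masks = render_masks(canonical_truth, pixel_size=0.05)
        area = masks["head"].sum() * 0.05**2
        analytic = math.pi * 2.25 * 1.5
        assert area == pytest.approx(analytic, rel=0.02)
        cap_frac = 100.0 * masks["cap"].sum() / masks["head"].sum()
        assert cap_frac == pytest.approx(50.0, abs=1.0)

    @pytest.mark.parametrize("acro", [31.0, 40.0, 60.0, 70.0])
    def test_cap_fraction_matches_request(self, acro):
        t = SpermGroundTruth("c", "s", 4.5, 3.0, 1.5, acro, orientation=0.7)
        masks = render_masks(t, pixel_size=0.05)
        cap_frac = 100.0 * masks["cap"].sum() / masks["head"].sum()
        assert cap_frac == pytest.approx(acro, abs=1.0)

    def test_zero_acrosome_has_empty_cap(self):
        t = SpermGroundTruth("c", "s", 4.5, 3.0, 1.5, 0.0)
        masks = render_masks(t, pixel_size=0.05)
        assert masks["cap"].sum() == 0

    def test_render_deterministic(self, canonical_truth):
        a = render_phase_image(canonical_truth, 0.05, blur_sigma=1, noise_sigma=0.05, seed=9)
        b = render_phase_image(canonical_truth, 0.05, blur_sigma=1, noise_sigma=0.05, seed=9)
        assert np.array_equal(a.pixels, b.pixels)

    def test_background_border_near_zero(self, canonical_truth):
        img = render_phase_image(canonical_truth, 0.05, noise_sigma=0.02, seed=1)
        border = np.concatenate(
            [img.pixels[0], img.pixels[-1], img.pixels[:, 0], img.pixels[:, -1]]
        )
        assert abs(border.mean()) < 3 * 0.02 / math.sqrt(len(border))

    def test_too_coarse_pixel_raises(self, canonical_truth):
        with pytest.raises(ResolutionError):
            render_phase_image(canonical_truth, pixel_size=1.0)

    def test_cap_density_below_nucleus(self, clean_image, canonical_truth):
        masks = render_masks(canonical_truth, 0.05)
        nucleus = masks["head"] & ~masks["cap"]
        assert clean_image.pixels[masks["cap"]].mean() < clean_image.pixels[nucleus].mean()


class TestMeasurementTable:
    def test_zero_noise_equals_truth(self):
        truths = sample_ground_truth(10, 0.5, seed=2)
        records = simulate_measurement_table(truths, zero_noise_models(), replicates=2, seed=0)
        assert len(records) == 10 * 2 * 2
        by_cell = {t.cell_id: t for t in truths}
        for r in records:
            t = by_cell[r.cell_id]
            assert r.head_length_um == pytest.approx(t.head_length_um, abs=1e-12)
            assert r.head_width_um == pytest.approx(t.head_width_um, abs=1e-12)
            assert r.acrosome_pct == pytest.approx(t.acrosome_pct, abs=1e-12)
            assert not r.truncated_flag

    def test_bias_recovery_through_bland_altman(self):
        """The configured 0.18 um head-length bias is recovered within 3 SE."""
        truths = sample_ground_truth(326, 0.61, seed=8)
        records = simulate_measurement_table(truths, default_noise_models(), seed=8)
        result = bland_altman(per_cell_differences(records, "head_length_um"))
        assert result.n == 326
        assert result.bias == pytest.approx(0.18, abs=3 * 0.32 / math.sqrt(326))

    def test_truncation_floor_and_flag(self):
        truths = sample_ground_truth(5, 1.0, seed=1)
        models = dict(zero_noise_models())
        models["qpm"] = ModalityNoiseModel(
            modality="qpm", head_length_um=EndpointNoise(bias=-50.0)
        )
        records = simulate_measurement_table(truths, models, replicates=1, seed=0)
        qpm = [r for r in records if r.modality == "qpm"]
        assert all(r.head_length_um >= 0.1 for r in qpm)
        assert all(r.truncated_flag for r in qpm)

    def test_ratio_recomputed_from_noisy_axes(self):
        truths = sample_ground_truth(20, 0.5, seed=3)
        records = simulate_measurement_table(truths, default_noise_models(), seed=3)
        for r in records:
            assert r.lw_ratio == pytest.approx(r.head_length_um / r.head_width_um, rel=1e-12)

    def test_missing_model_raises(self):
        truths = sample_ground_truth(2, 1.0, seed=0)
        with pytest.raises(ConfigurationError):
            simulate_measurement_table(truths, {"qpm": zero_noise_models()["qpm"]}, seed=0)

    def test_deterministic(self):
        truths = sample_ground_truth(8, 0.5, seed=4)
        a = simulate_measurement_table(truths, default_noise_models(), seed=4)
        b = simulate_measurement_table(truths, default_noise_models(), seed=4)
        assert a == b


class TestSimulateStudy:
    def test_default_design_counts(self):
        cfg = StudyConfig()
        assert cfg.n_cells == 73 * 22 == 1606

    def test_small_study_structure(self, small_bundle):
        cfg = small_bundle.config
        assert len(small_bundle.truths) == cfg.n_cells
        # one record per cell x modality x replicate
        assert len(small_bundle.records) == cfg.n_cells * 2 * cfg.replicates
        df = small_bundle.records_frame()
        excluded = df[df["exclusion_reason"] != "none"]
        assert len(excluded) > 0
        assert excluded["head_length_um"].isna().all()

    def test_minimal_bundle(self):
        bundle = simulate_study(
            StudyConfig(subjects=1, normal_per_subject=1, abnormal_per_subject=1, seed=0)
        )
        assert len(bundle.truths) == 2

    def test_csv_bytes_reproducible(self, tmp_path):
        cfg = StudyConfig(subjects=2, seed=13)
        paths = []
        for name in ("a.csv", "b.csv"):
            p = tmp_path / name
            records_to_frame(simulate_study(cfg).records).to_csv(p, index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_rendered_images_keyed_by_cell(self):
        bundle = simulate_study(
            StudyConfig(subjects=1, seed=0, render_images=True, max_images=3)
        )
        assert len(bundle.images) == 3
        for cell_id, img in bundle.images.items():
            assert img.metadata["cell_id"] == cell_id


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_truth_invariants_hold_for_any_seed(seed):
    """Sampled truths always satisfy their structural invariants."""
    for t in sample_ground_truth(4, normal_share=0.5, seed=seed):
        assert t.head_length_um >= t.head_width_um > 0
        assert t.lw_ratio == t.head_length_um / t.head_width_um
        assert 0 <= t.acrosome_pct <= 100
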