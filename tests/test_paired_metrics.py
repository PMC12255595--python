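"""Full-reference metrics against brute-force oracles and closed forms."""

import math

import numpy as np
import pytest

import oracles
from reconqc import paired_metrics as pm
from reconqc.errors import UndefinedMetricError, ValidationError
from reconqc.image_io import pair_series
from reconqc.types import Arm, HistogramSpec, ImageSlice, RoiSpec
from reconqc.synthetic_cohort import generate_exam, CohortConfig

HIST16 = HistogramSpec(n_bins=16)


def test_shape_mismatch_rejected():
    with pytest.raises(ValidationError):
        pm.mse(np.zeros((4, 4)), np.zeros((4, 5)))


@pytest.mark.parametrize(
    "func,oracle",
    [
        (pm.mse, oracles.mse_loop),
        (pm.psnr, oracles.psnr_loop),
        (pm.sam, oracles.sam_loop),
        (pm.frobenius_norm, oracles.frobenius_loop),
        (pm.weighted_jaccard, oracles.wjs_loop),
        (pm.bray_curtis, oracles.bcd_loop),
    ],
)
def test_pixelwise_metrics_match_loop_oracle(func, oracle, seeded_pairs):
    for I, ref in seeded_pairs:
        assert func(I, ref) == pytest.approx(oracle(I, ref), rel=1e-12)


def test_histogram_metrics_match_loop_oracle(seeded_pairs):
    for I, ref in seeded_pairs:
        bc, bd = pm.bhattacharyya(I, ref, HIST16)
        bc_o, bd_o = oracles.bhattacharyya_loop(I, ref, 16)
        assert bc == pytest.approx(bc_o, rel=1e-12)
        assert bd == pytest.approx(bd_o, rel=1e-12)
        assert pm.chi_square_distance(I, ref, HIST16) == pytest.approx(
            oracles.chi2d_loop(I, ref, 16), rel=1e-12
        )


def test_ssim_global_matches_closed_form(seeded_pairs):
    for I, ref in seeded_pairs:
        D = pm.dynamic_range(I, ref)
        assert pm.ssim(I, ref, window_policy="global") == pytest.approx(
            oracles.ssim_global_loop(I, ref, 0.01, 0.03, D), rel=1e-10
        )


class TestPsnr:
    def test_unit_offset_peak_255(self):
        ref = np.zeros((8, 8))
        ref[0, 0] = 255.0
        I = ref + 1.0  # MSE exactly 1
        assert pm.psnr(I, ref) == pytest.approx(10 * math.log10(255**2), abs=1e-12)

    def test_identical_images_infinite_sentinel(self):
        img = np.full((4, 4), 7.0)
        assert math.isinf(pm.psnr(img, img))

    def test_zero_reference_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pm.psnr(np.ones((4, 4)), np.zeros((4, 4)))


class TestIdentityValues:
    """Every paired metric returns its analytic value when I == ref."""

    def test_identity_suite(self, phantom):
        I = phantom
        assert pm.mse(I, I) == 0.0
        assert math.isinf(pm.psnr(I, I))
        assert pm.ssim(I, I) == pytest.approx(1.0, abs=1e-12)
        assert pm.vif(I, I) == pytest.approx(1.0, abs=1e-6)
        assert pm.sam(I, I) == pytest.approx(0.0, abs=1e-7)
        bc, bd = pm.bhattacharyya(I, I)
        assert bc == pytest.approx(1.0, abs=1e-12)
        assert bd == pytest.approx(0.0, abs=1e-12)
        assert pm.chi_square_distance(I, I) == 0.0
        assert pm.frobenius_norm(I, I) == 0.0
        assert pm.weighted_jaccard(I, I) == 1.0
        assert pm.bray_curtis(I, I) == 0.0


class TestClosedForms:
    def test_wjs_of_doubled_image(self):
        I = np.random.default_rng(3).uniform(1.0, 10.0, (8, 8))
        assert pm.weighted_jaccard(2 * I, I) == pytest.approx(0.5, rel=1e-12)

    def test_bcd_of_doubled_image(self):
        I = np.random.default_rng(3).uniform(1.0, 10.0, (8, 8))
        assert pm.bray_curtis(2 * I, I) == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_sam_scale_invariance(self):
        I = np.random.default_rng(4).uniform(0.0, 5.0, (8, 8))
        assert pm.sam(2.0 * I, I) == pytest.approx(0.0, abs=1e-7)

    def test_sam_orthogonal_vectors(self):
        I = np.array([[1.0, 0.0], [0.0, 0.0]])
        ref = np.array([[0.0, 1.0], [0.0, 0.0]])
        assert pm.sam(I, ref) == pytest.approx(math.pi / 2, rel=1e-12)

    def test_fn_three_four_five(self):
        ref = np.zeros((2, 2))
        I = np.array([[3.0, 4.0], [0.0, 0.0]])
        assert pm.frobenius_norm(I, ref) == pytest.approx(5.0, rel=1e-15)

    def test_fn_mse_algebraic_identity(self, seeded_pairs):
        for I, ref in seeded_pairs:
            assert pm.frobenius_norm(I, ref) == pytest.approx(
                math.sqrt(I.size * pm.mse(I, ref)), rel=1e-10
            )

    def test_chi2_disjoint_two_bins(self):
        # all mass of I in the low bin, of ref in the high bin
        I = np.zeros((4, 4))
        ref = np.full((4, 4), 10.0)
        assert pm.chi_square_distance(I, ref, HistogramSpec(n_bins=2)) == (
            pytest.approx(1.0, rel=1e-12)
        )

    def test_bhattacharyya_disjoint_supports(self):
        I = np.zeros((4, 4))
        ref = np.full((4, 4), 10.0)
        bc, bd = pm.bhattacharyya(I, ref, HistogramSpec(n_bins=2))
        assert bc == 0.0
        assert math.isinf(bd)


class TestVif:
    def test_single_scale_matches_loop_oracle(self, seeded_pairs):
        for I, ref in seeded_pairs[:5]:
            assert pm.vif(I, ref, n_scales=1) == pytest.approx(
                oracles.vif_single_scale_loop(I, ref), rel=1e-8
            )

    def test_blur_degrades_more_than_tiny_noise(self, phantom):
        from scipy.ndimage import gaussian_filter

        blurred = gaussian_filter(phantom, 4.0)
        tiny = np.clip(
            phantom + np.random.default_rng(0).normal(0, 0.05, phantom.shape),
            0,
            None,
        )
        assert pm.vif(blurred, phantom) < pm.vif(tiny, phantom)

    def test_constant_reference_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pm.vif(np.random.default_rng(0).uniform(0, 1, (128, 128)),
                   np.full((128, 128), 5.0))


class TestSymmetryAndMonotonicity:
    def test_symmetric_metrics(self, seeded_pairs):
        I, ref = seeded_pairs[0]
        assert pm.mse(I, ref) == pm.mse(ref, I)
        assert pm.frobenius_norm(I, ref) == pm.frobenius_norm(ref, I)
        assert pm.sam(I, ref) == pm.sam(ref, I)
        assert pm.bhattacharyya(I, ref) == pm.bhattacharyya(ref, I)
        assert pm.chi_square_distance(I, ref) == pm.chi_square_distance(ref, I)
        assert pm.weighted_jaccard(I, ref) == pm.weighted_jaccard(ref, I)
        assert pm.bray_curtis(I, ref) == pm.bray_curtis(ref, I)

    def test_reference_directional_metrics(self):
        rng = np.random.default_rng(8)
        ref = rng.uniform(10.0, 100.0, (64, 64))
        I = np.clip(ref + rng.normal(0, 5.0, ref.shape), 0, None)
        assert pm.psnr(I, ref) != pm.psnr(ref, I)  # peak from the reference
        assert pm.vif(I, ref) != pm.vif(ref, I)

    def test_monotone_degradation_under_noise(self, phantom):
        rng = np.random.default_rng(17)
        noise = rng.normal(0.0, 1.0, phantom.shape)
        results = []
        for sd in (2.0, 6.0, 18.0):
            I = np.clip(phantom + sd * noise, 0.0, None)
            results.append(
                (
                    pm.mse(I, phantom),
                    pm.frobenius_norm(I, phantom),
                    pm.bray_curtis(I, phantom),
                    pm.ssim(I, phantom),
                    pm.weighted_jaccard(I, phantom),
                )
            )
        for a, b in zip(results, results[1:]):
            assert b[0] > a[0] and b[1] > a[1] and b[2] > a[2]  # errors grow
            assert b[3] < a[3] and b[4] < a[4]  # similarities shrink


class TestComputePaired:
    def _pair(self, n=3, size=96):
        cfg = CohortConfig(image_size=size, slices_min=n, slices_max=n, master_seed=5)
        return generate_exam(2, cfg, "e1", "s1")

    def test_record_count_is_metrics_times_slices(self):
        pair = self._pair(n=3)
        metrics = ("mse", "psnr", "ssim", "sam", "fn")
        recs = pm.compute_paired(pair, RoiSpec.third_of(96), metrics=metrics)
        assert len(recs) == len(metrics) * 3
        assert all(r.arm is Arm.PAIRED for r in recs)

    def test_zero_standard_slice_flags_psnr_only(self):
        pair = self._pair(n=3)
        dead = ImageSlice(
            pixels=np.zeros_like(pair.pairs[1][1].pixels),
            slice_position_mm=pair.pairs[1][1].slice_position_mm,
            exam_id="e1",
            scanner_id="s1",
            arm=Arm.STANDARD,
        )
        pair.pairs[1] = (pair.pairs[1][0], dead)
        recs = pm.compute_paired(
            pair, RoiSpec.third_of(96), metrics=("mse", "psnr", "fn")
        )
        flagged = {(r.metric, r.slice_index): r.flag for r in recs}
        assert flagged[("psnr", 1)] == "undefined"
        assert flagged[("mse", 1)] == "" and flagged[("fn", 1)] == ""

    def test_per_slice_values_match_direct_calls(self):
        pair = self._pair(n=2)
        roi = RoiSpec.third_of(96)
        recs = pm.compute_paired(pair, roi, metrics=("mse", "sam"))
        from reconqc.image_io import extract_central_roi

        for r in recs:
            ai, std = pair.pairs[r.slice_index]
            expected = {"mse": pm.mse, "sam": pm.sam}[r.metric](
                extract_central_roi(ai, roi), extract_central_roi(std, roi)
            )
            assert r.value == pytest.approx(expected, rel=1e-12)
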