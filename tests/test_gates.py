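import math

import numpy as np
import pytest

from splitgfr.core import AcquisitionMeta, DynamicRenogram, PatientInfo
from splitgfr.gates import (
    GatesConfig,
    attenuation_correct,
    bsa_dubois,
    extract_tac,
    gates_gfr,
    injected_counts,
    kidney_depth,
    net_rate,
    roi_rate,
    sum_window,
)


def _scan_from(counts, patient=None):
    counts = np.asarray(counts)
    meta = AcquisitionMeta(n_frames=counts.shape[0], matrix_size=counts.shape[1])
    patient = patient or PatientInfo(age=50, sex="male", weight_kg=70.0, height_cm=170.0)
    return DynamicRenogram(counts=counts, meta=meta, patient=patient)


class TestSumWindow:
    def test_all_ones_window_9_12(self):
        scan = _scan_from(np.ones((80, 64, 64)))
        assert np.array_equal(sum_window(scan, (9, 12)), np.full((64, 64), 4.0))

    def test_single_frame_window_is_identity(self):
        rng = np.random.default_rng(0)
        scan = _scan_from(rng.integers(0, 50, (80, 64, 64)))
        assert np.array_equal(sum_window(scan, (9, 9)), scan.counts[8])

    def test_matches_elementwise_addition_oracle(self):
        rng = np.random.default_rng(1)
        scan = _scan_from(rng.integers(0, 100, (80, 10, 10)))
        expected = scan.counts[8] + scan.counts[9] + scan.counts[10] + scan.counts[11]
        assert np.array_equal(sum_window(scan, (9, 12)), expected)

    def test_out_of_range_window(self):
        scan = _scan_from(np.ones((20, 8, 8)))
        with pytest.raises(ValueError):
            sum_window(scan, (9, 21))
        with pytest.raises(ValueError):
            sum_window(scan, (0, 4))


class TestRoiRate:
    def test_constant_image(self):
        image = np.full((8, 8), 3.0)
        mask = np.zeros((8, 8), bool)
        mask[2:4, 2:7] = True  # 10 pixels
        assert roi_rate(image, mask) == (30.0, 10)

    def test_full_grid(self):
        rng = np.random.default_rng(2)
        image = rng.random((6, 6))
        total, n = roi_rate(image, np.ones((6, 6), bool))
        assert total == pytest.approx(image.sum())
        assert n == 36

    def test_matches_pixel_loop_oracle(self):
        rng = np.random.default_rng(3)
        image = rng.integers(0, 20, (5, 5))
        mask = rng.random((5, 5)) > 0.5
        expected = 0.0
        for r in range(5):
            for c in range(5):
                if mask[r, c]:
                    expected += image[r, c]
        total, n = roi_rate(image, mask)
        assert total == expected
        assert n == int(mask.sum())

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            roi_rate(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestNetRate:
    def test_hand_arithmetic(self):
        assert net_rate((5000.0, 100), (200.0, 20)) == 4000.0

    def test_zero_background(self):
        assert net_rate((5000.0, 100), (0.0, 20)) == 5000.0

    def test_clamped_at_zero(self):
        assert net_rate((100.0, 100), (200.0, 20)) == 0.0
        assert net_rate((100.0, 100), (200.0, 20), clamp_negative=False) == -900.0

    def test_empty_background_raises(self):
        with pytest.raises(ValueError):
            net_rate((100.0, 10), (0.0, 0))


class TestKidneyDepth:
    def test_tonnesen_hand_values(self, patient):
        assert kidney_depth(patient, "right", "tonnesen") == pytest.approx(
            13.3 * 70 / 170 + 0.7, abs=1e-12
        )
        assert kidney_depth(patient, "left", "tonnesen") == pytest.approx(
            13.2 * 70 / 170 + 0.7, abs=1e-12
        )
        # frozen hand evaluation
        assert kidney_depth(patient, "right", "tonnesen") == pytest.approx(6.1765, abs=1e-4)
        assert kidney_depth(patient, "left", "tonnesen") == pytest.approx(6.1353, abs=1e-4)

    def test_zero_ratio_limit(self):
        thin = PatientInfo(age=30, sex="female", weight_kg=0.001, height_cm=200.0)
        assert kidney_depth(thin, "right", "tonnesen") == pytest.approx(0.7, abs=1e-4)
        assert kidney_depth(thin, "left", "tonnesen") == pytest.approx(0.7, abs=1e-4)

    def test_taylor_hand_value(self, patient):
        assert kidney_depth(patient, "right", "taylor") == pytest.approx(
            15.31 * 70 / 170 + 0.022 * 50 + 0.077, abs=1e-12
        )
        assert kidney_depth(patient, "right", "taylor") == pytest.approx(7.4811, abs=1e-4)
        assert kidney_depth(patient, "left", "taylor") == pytest.approx(
            16.17 * 70 / 170 + 0.027 * 50 - 0.94, abs=1e-12
        )

    def test_unknown_formula(self, patient):
        with pytest.raises(ValueError):
            kidney_depth(patient, "right", "nosuch")


class TestAttenuation:
    def test_zero_depth_identity(self):
        assert attenuation_correct(123.0, 0.0) == 123.0

    def test_hand_multiplier(self):
        assert attenuation_correct(1.0, 6.0, mu=0.153) == pytest.approx(
            math.exp(0.918), rel=1e-12
        )
        assert attenuation_correct(1.0, 6.0, mu=0.153) == pytest.approx(2.5043, abs=1e-4)

    def test_monotone_in_depth(self):
        rates = [attenuation_correct(100.0, d) for d in np.linspace(0, 10, 11)]
        assert all(a < b for a, b in zip(rates, rates[1:]))


class TestInjectedCounts:
    def test_no_decay(self):
        meta = AcquisitionMeta(syringe_pre_counts=1000.0, syringe_post_counts=100.0)
        assert injected_counts(meta) == pytest.approx(900.0)

    def test_pre_one_half_life_before_injection(self):
        # pre measured T1/2 before injection: its activity has halved by t_inj
        hl = 6.0067
        meta = AcquisitionMeta(
            syringe_pre_counts=1000.0,
            syringe_post_counts=0.0,
            t_pre=0.0,
            t_inj=hl * 3600.0,
            t_post=hl * 3600.0,
        )
        assert injected_counts(meta, half_life_h=hl) == pytest.approx(500.0, rel=1e-12)

    def test_post_zero(self):
        meta = AcquisitionMeta(syringe_pre_counts=1234.0, syringe_post_counts=0.0)
        assert injected_counts(meta) == pytest.approx(1234.0)

    def test_measurement_error_raises(self):
        meta = AcquisitionMeta(
            syringe_pre_counts=1000.0,
            syringe_post_counts=999.0,
            t_pre=0.0,
            t_inj=3600.0 * 6.0,
            t_post=3600.0 * 6.0,
        )
        with pytest.raises(ValueError):
            injected_counts(meta)


class TestBsa:
    def test_hand_value(self, patient):
        assert bsa_dubois(patient) == pytest.approx(0.007184 * 70**0.425 * 170**0.725, rel=1e-12)
        assert bsa_dubois(patient) == pytest.approx(1.8097, abs=2e-4)

    def test_identity_point(self):
        # a patient whose BSA is ~1.73 has gfr_normalized == gfr
        p = PatientInfo(age=40, sex="female", weight_kg=66.0, height_cm=168.0)
        assert bsa_dubois(p) == pytest.approx(1.75, abs=0.02)

    def test_monotone(self, patient):
        heavier = PatientInfo(age=50, sex="male", weight_kg=80.0, height_cm=170.0)
        taller = PatientInfo(age=50, sex="male", weight_kg=70.0, height_cm=180.0)
        assert bsa_dubois(heavier) > bsa_dubois(patient)
        assert bsa_dubois(taller) > bsa_dubois(patient)


class TestExtractTac:
    def test_flat_curve_and_length(self):
        scan = _scan_from(np.full((80, 8, 8), 2.0))
        mask = np.zeros((8, 8), bool)
        mask[2:5, 2:5] = True
        tac = extract_tac(scan, mask)
        assert tac.shape == (80, 2)
        assert np.allclose(tac[:, 1], 18.0)
        assert tac[0, 0] == 7.5  # first frame mid-point at 15 s/frame

    def test_summation_exchange(self):
        rng = np.random.default_rng(4)
        scan = _scan_from(rng.integers(0, 30, (80, 10, 10)))
        mask = rng.random((10, 10)) > 0.4
        tac = extract_tac(scan, mask)
        window_total, _ = roi_rate(sum_window(scan, (9, 12)), mask)
        assert tac[8:12, 1].sum() == pytest.approx(window_total)

    def test_empty_mask(self):
        scan = _scan_from(np.ones((80, 8, 8)))
        with pytest.raises(ValueError):
            extract_tac(scan, np.zeros((8, 8), bool))


class TestGatesGfr:
    def test_uptake_five_percent_hand_value(self):
        # 9.8127 * 5 - 6.82519 = 42.23831
        cfg = GatesConfig()
        assert cfg.gates_slope * 5.0 + cfg.gates_intercept == pytest.approx(42.23831, abs=1e-9)

    def test_zero_net_rates_clamped_and_split_missing(self, patient):
        # uniform image: kidney rate equals background rate -> net 0 everywhere
        counts = np.full((80, 64, 64), 5.0)
        scan = _scan_from(counts, patient)
        from splitgfr.phantom import make_kidney_masks
        from splitgfr.roi_tools import auto_background_roi

        rois = make_kidney_masks(((32, 20), (32, 44)), (16, 10))
        rois.bg_left = auto_background_roi(rois.kidney_left, "left")
        rois.bg_right = auto_background_roi(rois.kidney_right, "right")
        with pytest.warns(UserWarning, match="clamped"):
            res = gates_gfr(scan, rois)
        assert res.total_gfr == 0.0
        assert res.clamped
        assert res.left.split_pct is None and res.right.split_pct is None
        assert res.left.gfr is None

    def test_linearity_scaling_counts_and_injection(self, scene, noiseless_scan):
        res1 = gates_gfr(noiseless_scan, scene.truth.rois, depths=scene.truth.depths())
        import dataclasses

        meta2 = dataclasses.replace(
            scene.meta,
            syringe_pre_counts=scene.meta.syringe_pre_counts * 3.0,
            syringe_post_counts=scene.meta.syringe_post_counts * 3.0,
        )
        scan2 = DynamicRenogram(
            counts=noiseless_scan.counts * 3.0, meta=meta2, patient=scene.patient
        )
        res2 = gates_gfr(scan2, scene.truth.rois, depths=scene.truth.depths())
        assert res2.total_uptake_pct == pytest.approx(res1.total_uptake_pct, rel=1e-12)
        assert res2.total_gfr == pytest.approx(res1.total_gfr, rel=1e-12)
        assert res2.left.split_pct == pytest.approx(res1.left.split_pct, rel=1e-12)

    def test_background_choice_irrelevant_for_uniform_background(self, scene, noiseless_scan):
        res1 = gates_gfr(noiseless_scan, scene.truth.rois, depths=scene.truth.depths())
        rois2 = scene.truth.rois.copy()
        # swap in a completely different uniform-background sampling region
        other = np.zeros((64, 64), bool)
        other[2:6, 2:6] = True
        rois2.bg_left = other
        other2 = np.zeros((64, 64), bool)
        other2[58:62, 58:62] = True
        rois2.bg_right = other2
        res2 = gates_gfr(noiseless_scan, rois2, depths=scene.truth.depths())
        assert res2.total_gfr == pytest.approx(res1.total_gfr, rel=1e-9)

    def test_split_sums_to_100(self, scene, noisy_scan):
        res = gates_gfr(noisy_scan, scene.truth.rois, depths=scene.truth.depths())
        assert res.left.split_pct + res.right.split_pct == pytest.approx(100.0, abs=1e-12)

    def test_missing_roi_raises(self, scene, noiseless_scan):
        rois = scene.truth.rois.copy()
        rois.kidney_left = np.zeros((64, 64), bool)
        with pytest.raises(ValueError, match="kidney_left"):
            gates_gfr(noiseless_scan, rois)

    def test_normalized_gfr_scaling(self, scene, noiseless_scan):
        res = gates_gfr(noiseless_scan, scene.truth.rois, depths=scene.truth.depths())
        assert res.total_gfr_normalized == pytest.approx(res.total_gfr * 1.73 / res.bsa_m2)


class TestBruteForceAgreement:
    """All intermediates vs an explicit pixel-loop computation on small scans."""

    def test_random_small_scan(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 50, (80, 10, 10))
        scan = _scan_from(counts)
        kid = np.zeros((10, 10), bool)
        kid[2:5, 2:5] = True
        bg = np.zeros((10, 10), bool)
        bg[7:9, 7:9] = True

        window = np.zeros((10, 10))
        for f in range(8, 12):
            for r in range(10):
                for c in range(10):
                    window[r, c] += counts[f, r, c]
        assert np.array_equal(sum_window(scan, (9, 12)), window)

        k_total = sum(window[r, c] for r in range(10) for c in range(10) if kid[r, c])
        b_total = sum(window[r, c] for r in range(10) for c in range(10) if bg[r, c])
        assert roi_rate(window, kid) == (k_total, 9)
        assert roi_rate(window, bg) == (b_total, 4)
        expected_net = k_total - 9 * (b_total / 4)
        assert net_rate((k_total, 9), (b_total, 4), clamp_negative=False) == pytest.approx(
            expected_net
        )
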