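import numpy as np
import pytest

from bmseg.inference import find_lesions
from bmseg.metrics import (
    DetectionResult,
    UndefinedMetricError,
    avg_fp_rate,
    combine_detections,
    dice,
    dice_with_dilation,
    dilate_mask,
    hd95,
    match_lesions,
    per_lesion_report,
    sensitivity,
)

from conftest import make_label


# ------------------------------------------------------------- oracles

def oracle_dice(a, b):
    A = {tuple(v) for v in np.argwhere(np.asarray(a, bool))}
    B = {tuple(v) for v in np.argwhere(np.asarray(b, bool))}
    if not A and not B:
        return 1.0
    return 2 * len(A & B) / (len(A) + len(B))


def oracle_dilate(mask, radius, spacing):
    """Set-union dilation with an explicitly enumerated anisotropic ball."""
    mask = np.asarray(mask, bool)
    half = [int(np.floor(radius / s)) for s in spacing]
    ball = [
        (i, j, k)
        for i in range(-half[0], half[0] + 1)
        for j in range(-half[1], half[1] + 1)
        for k in range(-half[2], half[2] + 1)
        if (i * spacing[0]) ** 2 + (j * spacing[1]) ** 2 + (k * spacing[2]) ** 2
        <= radius**2 + 1e-9
    ]
    out = np.zeros_like(mask)
    for v in np.argwhere(mask):
        for off in ball:
            w = v + off
            if np.all(w >= 0) and np.all(w < mask.shape):
                out[tuple(w)] = True
    return out


def oracle_hd95(gt, pr, spacing):
    """All-pairs directed 95th-percentile distance, PR to nearest GT."""
    gt_pts = np.argwhere(np.asarray(gt, bool)) * np.asarray(spacing)
    pr_pts = np.argwhere(np.asarray(pr, bool)) * np.asarray(spacing)
    dists = [np.min(np.linalg.norm(gt_pts - p, axis=1)) for p in pr_pts]
    return float(np.percentile(dists, 95))


def random_mask_pair(seed, shape=(8, 8, 8)):
    r = np.random.default_rng(seed)
    spacing = tuple(r.uniform(0.3, 2.0, size=3).round(2))
    a = r.random(shape) < r.uniform(0.05, 0.3)
    b = r.random(shape) < r.uniform(0.05, 0.3)
    return make_label(a, spacing), make_label(b, spacing), spacing


# ------------------------------------------------------------- detection

class TestMatchLesions:
    def _sets(self, gt_data, pr_data, spacing=(1, 1, 1)):
        gt = find_lesions(make_label(gt_data, spacing), source="ground_truth")
        pr = find_lesions(make_label(pr_data, spacing), source="prediction")
        return gt, pr

    def test_perfect_prediction(self):
        data = np.zeros((4, 10, 10), dtype=np.uint8)
        data[1, 2:4, 2:4] = 1
        data[2, 7:9, 7:9] = 1
        gt, pr = self._sets(data, data)
        d = match_lesions(gt, pr)
        assert (d.tp, d.fn, d.total_fp) == (len(gt.lesions), 0, 0)

    def test_empty_prediction_all_missed(self):
        gt_data = np.zeros((3, 6, 6), dtype=np.uint8)
        gt_data[0, 0, 0] = 1
        gt_data[2, 4:6, 4:6] = 1
        gt, pr = self._sets(gt_data, np.zeros_like(gt_data))
        d = match_lesions(gt, pr)
        assert (d.tp, d.fn) == (0, len(gt.lesions))

    def test_one_blob_validates_two_lesions(self):
        gt_data = np.zeros((1, 5, 12), dtype=np.uint8)
        gt_data[0, 1:3, 1:3] = 1
        gt_data[0, 1:3, 8:10] = 1
        pr_data = np.zeros_like(gt_data)
        pr_data[0, 1:3, 1:10] = 1  # spans both lesions
        gt, pr = self._sets(gt_data, pr_data)
        d = match_lesions(gt, pr)
        assert (d.tp, d.fn, d.total_fp) == (2, 0, 0)

    def test_nonoverlapping_prediction_is_fp(self):
        gt_data = np.zeros((2, 6, 6), dtype=np.uint8)
        gt_data[0, 0:2, 0:2] = 1
        pr_data = np.zeros_like(gt_data)
        pr_data[1, 4:6, 4:6] = 1
        gt, pr = self._sets(gt_data, pr_data)
        d = match_lesions(gt, pr)
        assert (d.tp, d.fn, d.total_fp) == (0, 1, 1)

    def test_bookkeeping_conserved_on_random_masks(self):
        for seed in range(15):
            gt_m, pr_m, _ = random_mask_pair(seed, shape=(6, 10, 10))
            gt = find_lesions(gt_m, "ground_truth")
            pr = find_lesions(pr_m, "prediction")
            d = match_lesions(gt, pr)
            assert d.tp + d.fn == len(gt.lesions)
            matched = {p for _, preds in d.matches for p in preds}
            assert d.total_fp == len(pr.lesions) - len(matched)


class TestDetectionRates:
    def test_sensitivity_from_test_set_counts(self):
        # 56 of 58 lesions detected -> 96.6% at one decimal
        d = DetectionResult(tp=56, fn=2, fp_per_patient=[0], matches=[])
        assert round(100 * sensitivity(d), 1) == 96.6

    def test_perfect_sensitivity(self):
        assert sensitivity(DetectionResult(5, 0, [0], [])) == 1.0

    def test_small_bin_sensitivity(self):
        assert sensitivity(DetectionResult(12, 2, [0], [])) == pytest.approx(
            0.857, abs=5e-4
        )

    def test_undefined_without_gt_lesions(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(DetectionResult(0, 0, [0], []))

    def test_avg_fp_rate_cohort(self):
        # 15 false positives over 12 patients
        d = DetectionResult(56, 2, [6, 0, 0, 2, 1, 1, 0, 2, 0, 1, 2, 0], [])
        assert avg_fp_rate(d) == pytest.approx(1.25)

    def test_avg_fp_rate_examples(self):
        assert avg_fp_rate(DetectionResult(1, 0, [0, 0, 0], [])) == 0.0
        assert avg_fp_rate(DetectionResult(1, 0, [6, 0, 0], [])) == 2.0

    def test_combine_detections_pools_patients(self):
        a = DetectionResult(3, 1, [2], [])
        b = DetectionResult(5, 0, [0], [])
        c = combine_detections([a, b])
        assert (c.tp, c.fn, c.fp_per_patient) == (8, 1, [2, 0])


# ------------------------------------------------------------- segmentation

class TestDice:
    def test_identical_masks(self, rng):
        m = make_label(rng.random((4, 6, 6)) < 0.3)
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((2, 4, 4), dtype=np.uint8)
        b = np.zeros((2, 4, 4), dtype=np.uint8)
        a[0, 0, 0] = 1
        b[1, 3, 3] = 1
        assert dice(make_label(a), make_label(b)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((1, 1, 4), dtype=np.uint8)
        b = np.zeros((1, 1, 4), dtype=np.uint8)
        a[0, 0, :2] = 1
        b[0, 0, 1:3] = 1
        assert dice(make_label(a), make_label(b)) == 0.5

    def test_both_empty_convention(self):
        e = make_label(np.zeros((2, 2, 2)))
        assert dice(e, e) == 1.0

    def test_symmetry_and_range_on_random_masks(self):
        for seed in range(20):
            a, b, _ = random_mask_pair(seed)
            assert dice(a, b) == dice(b, a)
            assert 0 <= dice(a, b) <= 1

    def test_grid_mismatch_rejected(self):
        a = make_label(np.zeros((2, 2, 2)), (1, 1, 1))
        b = make_label(np.zeros((2, 2, 2)), (2, 1, 1))
        with pytest.raises(ValueError):
            dice(a, b)


class TestDilation:
    def test_radius_zero_identity(self, rng):
        m = make_label(rng.random((4, 6, 6)) < 0.2)
        np.testing.assert_array_equal(dilate_mask(m, 0.0).data, m.data)

    def test_unit_spacing_radius3_ball_count(self):
        data = np.zeros((9, 9, 9), dtype=np.uint8)
        data[4, 4, 4] = 1
        out = dilate_mask(make_label(data), 3.0)
        # integer-lattice ball of radius 3: 123 voxels
        assert int(out.data.sum()) == 123

    def test_monotone_growth(self, rng):
        m = make_label(rng.random((5, 8, 8)) < 0.1)
        d1 = dilate_mask(m, 1.0).data
        d2 = dilate_mask(m, 2.5).data
        assert not np.any(m.data & ~d1)
        assert not np.any(d1 & ~d2)

    def test_matches_enumeration_oracle_anisotropic(self):
        for seed in range(10):
            m, _, spacing = random_mask_pair(seed, shape=(6, 8, 8))
            got = dilate_mask(m, 3.0).data.astype(bool)
            want = oracle_dilate(m.data, 3.0, spacing)
            np.testing.assert_array_equal(got, want)


class TestDiceWithDilation:
    def test_identical_masks_any_radius(self, rng):
        m = make_label(rng.random((4, 6, 6)) < 0.2, (1, 0.5, 0.5))
        for r in (0.0, 1.0, 3.0):
            assert dice_with_dilation(m, m, r) == 1.0

    def test_radius_zero_reduces_to_dice(self):
        for seed in range(10):
            a, b, _ = random_mask_pair(seed)
            assert dice_with_dilation(a, b, 0.0) == dice(a, b)

    def test_two_voxels_2mm_apart_with_3mm_margin(self):
        a = np.zeros((1, 9, 9), dtype=np.uint8)
        b = np.zeros((1, 9, 9), dtype=np.uint8)
        a[0, 4, 3] = 1
        b[0, 4, 5] = 1  # 2 mm apart at unit spacing
        ga, gb = make_label(a), make_label(b)
        got = dice_with_dilation(ga, gb, 3.0)
        da = oracle_dilate(a, 3.0, (1, 1, 1))
        db = oracle_dilate(b, 3.0, (1, 1, 1))
        assert got == pytest.approx(oracle_dice(da, db), abs=1e-12)
        assert got > 0.5  # most of the two dilated balls overlap

    def test_matches_oracle_on_random_pairs(self):
        for seed in range(15):
            a, b, spacing = random_mask_pair(seed)
            got = dice_with_dilation(a, b, 3.0)
            want = oracle_dice(
                oracle_dilate(a.data, 3.0, spacing),
                oracle_dilate(b.data, 3.0, spacing),
            )
            assert got == pytest.approx(want, abs=1e-12)


class TestHD95:
    def test_identical_masks_zero(self, rng):
        m = make_label(rng.random((4, 6, 6)) < 0.3)
        assert hd95(m, m) == 0.0

    def test_single_voxels_5mm_apart(self):
        gt = np.zeros((1, 3, 11), dtype=np.uint8)
        pr = np.zeros((1, 3, 11), dtype=np.uint8)
        gt[0, 1, 2] = 1
        pr[0, 1, 7] = 1  # 5 voxels * 1 mm
        assert hd95(make_label(gt), make_label(pr)) == pytest.approx(5.0)

    def test_empty_mask_undefined(self):
        m = make_label(np.zeros((2, 2, 2)))
        n = make_label(np.ones((2, 2, 2)))
        with pytest.raises(UndefinedMetricError):
            hd95(m, n)
        with pytest.raises(UndefinedMetricError):
            hd95(n, m)

    def test_agrees_with_all_pairs_oracle(self):
        checked = 0
        for seed in range(40):
            gt, pr, spacing = random_mask_pair(seed, shape=(7, 9, 9))
            if not gt.data.any() or not pr.data.any():
                continue
            got = hd95(gt, pr)
            want = oracle_hd95(gt.data, pr.data, spacing)
            assert got == pytest.approx(want, abs=1e-9)
            checked += 1
        assert checked >= 20

    def test_symmetric_variant_upper_bounds_directed(self):
        for seed in range(10):
            gt, pr, _ = random_mask_pair(seed)
            if not gt.data.any() or not pr.data.any():
                continue
            assert hd95(gt, pr, symmetric=True) >= hd95(gt, pr) - 1e-12


# ------------------------------------------------------------- report

class TestPerLesionReport:
    def _gt_with_lesions(self):
        data = np.zeros((8, 24, 24), dtype=np.uint8)
        data[2:4, 2:6, 2:6] = 1      # 32 voxels
        data[5:7, 14:20, 14:20] = 1  # 72 voxels
        return make_label(data, (1, 1, 1))

    def test_perfect_prediction_rows(self):
        gt = self._gt_with_lesions()
        gt_ls = find_lesions(gt, "ground_truth")
        rep = per_lesion_report(gt_ls, gt)
        assert rep.per_lesion.detected.all()
        assert (rep.per_lesion.dice == 1.0).all()
        assert (rep.per_lesion.hd95_mm == 0.0).all()
        assert rep.sensitivity == 1.0
        assert rep.avg_fp_rate == 0.0

    def test_undetected_lesion_flagged_and_hd_excluded(self):
        gt = self._gt_with_lesions()
        gt_ls = find_lesions(gt, "ground_truth")
        pr_data = np.zeros_like(gt.data)
        pr_data[2:4, 2:6, 2:6] = 1  # only the first lesion predicted
        rep = per_lesion_report(gt_ls, make_label(pr_data))
        table = rep.per_lesion.sort_values("lesion_id")
        assert list(table.detected) == [True, False]
        missed = table[~table.detected].iloc[0]
        assert missed.dice == 0.0
        assert np.isnan(missed.hd95_mm)
        assert rep.hd95_mm == 0.0  # aggregate over detected lesions only

    def test_bin_counts_partition_lesions(self, small_phantom_spec):
        from bmseg.phantom import generate_phantom

        _, gt, gt_ls = generate_phantom(small_phantom_spec)
        rep = per_lesion_report(gt_ls, gt)
        coarse = rep.volume_bins[rep.volume_bins.volume_bin.isin([">0.1", "<=0.1"])]
        assert coarse.n_lesions.sum() == len(gt_ls.lesions)

    def test_locality_shields_neighbour_errors(self):
        gt = self._gt_with_lesions()
        gt_ls = find_lesions(gt, "ground_truth")
        pr_data = gt.data.copy()
        pr_data[5:7, 14:20, 14:20] = 0      # miss lesion 2 entirely
        pr_data[7, 20:23, 20:23] = 1        # spurious blob far from lesion 1
        rep = per_lesion_report(gt_ls, make_label(pr_data))
        row1 = rep.per_lesion.sort_values("lesion_id").iloc[0]
        assert row1.dice == 1.0  # untouched by the distant error
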