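import numpy as np
import pytest

from rsibreast import (
    PatientMaps,
    TissueMask,
    build_cohort_table,
    define_healthy_control_roi,
    roi_median,
)
from rsibreast.roi import METRICS, RoiError

GRID = (32, 32, 8)


def _malignant_mask(grid=GRID):
    m = np.zeros(grid, dtype=bool)
    m[4:9, 10:16, 2:5] = True  # low-x (ipsilateral) half
    return TissueMask("malignant", m)


class TestHealthyControlRoi:
    def test_exact_voxel_count(self):
        roi = define_healthy_control_roi(GRID, [_malignant_mask()], n_target=500)
        assert roi.n_voxels == 500
        assert roi.label == "healthy"
        # entirely contralateral: no voxel in the malignant (low-x) half
        assert not roi.mask[: GRID[0] // 2].any()

    def test_benign_overlap_excluded_count_preserved(self):
        benign = np.zeros(GRID, dtype=bool)
        benign[20:24, 14:18, 3:5] = True  # inside the contralateral half
        masks = [_malignant_mask(), TissueMask("benign", benign)]
        roi = define_healthy_control_roi(GRID, masks, n_target=500)
        assert roi.n_voxels == 500
        assert not np.any(roi.mask & benign)

    def test_exclusion_masks_respected(self):
        excl = np.zeros(GRID, dtype=bool)
        excl[16:, :, :4] = True
        roi = define_healthy_control_roi(GRID, [_malignant_mask()], [excl], n_target=300)
        assert roi.n_voxels == 300
        assert not np.any(roi.mask & excl)

    def test_insufficient_voxels_reports_achievable_count(self):
        small = (8, 8, 2)
        m = np.zeros(small, dtype=bool)
        m[1:3, 2:5, :] = True
        with pytest.raises(RoiError, match=r"\d+ eligible"):
            define_healthy_control_roi(small, [TissueMask("malignant", m)], n_target=500)

    def test_empty_malignant_mask_rejected(self):
        empty = TissueMask("malignant", np.zeros(GRID, dtype=bool))
        with pytest.raises(RoiError, match="non-empty"):
            define_healthy_control_roi(GRID, [empty], n_target=10)

    def test_contralateral_flips_with_lesion_side(self):
        m = np.zeros(GRID, dtype=bool)
        m[24:28, 10:16, 2:5] = True  # high-x lesion
        roi = define_healthy_control_roi(GRID, [TissueMask("malignant", m)], n_target=200)
        assert not roi.mask[GRID[0] // 2 :].any()


class TestRoiMedian:
    def test_odd_count(self):
        vol = np.array([1.0, 2.0, 9.0]).reshape(3, 1, 1)
        med, n = roi_median(vol, np.ones((3, 1, 1), bool))
        assert (med, n) == (2.0, 3)

    def test_even_count_midpoint(self):
        vol = np.array([1.0, 3.0]).reshape(2, 1, 1)
        med, n = roi_median(vol, np.ones((2, 1, 1), bool))
        assert (med, n) == (2.0, 2)

    def test_invariant_to_mask_representation(self):
        rng = np.random.default_rng(0)
        vol = rng.random((6, 6, 3))
        mask = rng.random((6, 6, 3)) > 0.5
        med1, _ = roi_median(vol, mask)
        med2, _ = roi_median(vol.copy(order="F"), mask.copy())
        assert med1 == med2

    def test_all_invalid_is_error(self):
        vol = np.ones((2, 2, 1))
        mask = np.ones((2, 2, 1), bool)
        with pytest.raises(RoiError):
            roi_median(vol, mask, validity=np.zeros((2, 2, 1), bool))


def _fake_patient(pid, rng, n_benign=1, grid=(16, 16, 4)):
    metrics = {m: rng.random(grid) for m in METRICS}
    mal = np.zeros(grid, bool)
    mal[2:5, 2:5, 1:3] = True
    benign = []
    for j in range(n_benign):
        b = np.zeros(grid, bool)
        b[8 + 2 * j : 10 + 2 * j, 2:4, 1:3] = True
        benign.append(TissueMask("benign", b))
    healthy = np.zeros(grid, bool)
    healthy[10:14, 10:14, :] = True
    return PatientMaps(
        patient_id=pid,
        metrics=metrics,
        malignant=TissueMask("malignant", mal),
        benign=benign,
        healthy=TissueMask("healthy", healthy),
        voxel_size_mm=(2.5, 2.5, 5.0),
        adc_validity=np.ones(grid, bool),
    )


class TestCohortTable:
    def test_twelve_patient_completeness(self):
        rng = np.random.default_rng(1)
        patients = [_fake_patient(f"p{i:02d}", rng) for i in range(12)]
        table = build_cohort_table(patients)
        assert len(table) == 12 * 3 * 6
        counts = table.groupby(["patient_id", "tissue"]).size()
        assert (counts == 6).all()

    def test_multiple_benign_lesions_single_record(self):
        rng = np.random.default_rng(2)
        table = build_cohort_table([_fake_patient("p00", rng, n_benign=2)])
        benign = table[(table.tissue == "benign") & (table.metric == "C1")]
        assert len(benign) == 1
        # pooled count equals sum of per-lesion counts
        assert benign.iloc[0]["n_voxels"] == 2 * (2 * 2 * 2)

    def test_pooled_median_lies_between_per_lesion_medians(self):
        rng = np.random.default_rng(3)
        patient = _fake_patient("p00", rng, n_benign=2)
        pooled = build_cohort_table([patient], benign_pooling="pooled")
        per = [
            roi_median(patient.metrics["C1"], b)[0] for b in patient.benign
        ]
        val = pooled[(pooled.tissue == "benign") & (pooled.metric == "C1")].iloc[0]["median"]
        assert min(per) <= val <= max(per)

    def test_median_of_medians_pooling_rule(self):
        rng = np.random.default_rng(4)
        patient = _fake_patient("p00", rng, n_benign=3)
        table = build_cohort_table([patient], benign_pooling="median_of_medians")
        per = [roi_median(patient.metrics["C2"], b)[0] for b in patient.benign]
        val = table[(table.tissue == "benign") & (table.metric == "C2")].iloc[0]["median"]
        assert val == float(np.median(per))

    def test_roi_volume_arithmetic(self):
        rng = np.random.default_rng(5)
        grid = (32, 32, 8)
        patient = _fake_patient("p00", rng, grid=grid)
        healthy = np.zeros(grid, bool)
        healthy.ravel()[:500] = True
        patient.healthy = TissueMask("healthy", healthy)
        table = build_cohort_table([patient])
        row = table[(table.tissue == "healthy") & (table.metric == "C1")].iloc[0]
        assert row["n_voxels"] == 500
        assert row["roi_volume_cm3"] == pytest.approx(15.625)

    def test_missing_tissue_names_patient(self):
        rng = np.random.default_rng(6)
        patient = _fake_patient("p07", rng)
        patient.benign = []
        with pytest.raises(RoiError, match="p07.*benign"):
            build_cohort_table([patient])

    def test_noiseless_roi_medians_equal_truth(self, noiseless_phantom):
        from rsibreast import fit_volume
        from rsibreast.preprocess import average_shells

        ph = noiseless_phantom
        avg = average_shells(ph.dwi)
        maps = fit_volume(avg, mask=ph.malignant_mask)
        med_fit, _ = roi_median(maps.c1, ph.malignant_mask)
        med_truth = float(np.median(ph.truth[..., 0][ph.malignant_mask]))
        assert med_fit == pytest.approx(med_truth, abs=1e-10)
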