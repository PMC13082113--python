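"""ROI summaries, NAWM normalization, grouping, trajectories, paired voxels."""

import numpy as np
import pandas as pd
import pytest

import hp13c
from hp13c import (
    RoiLabel,
    classify_treatment,
    cohort_table,
    group_trajectories,
    normalize_to_nawm,
    paired_voxel_change,
    parse_clinical_table,
    summarize_scan,
)
from hp13c.rois import RoiLabelMap
from hp13c.summary import ScanSummary

from conftest import masked_median_oracle


def label_map_from(labels: np.ndarray) -> RoiLabelMap:
    labels = np.asarray(labels, dtype=np.int8)
    zeros = np.zeros(labels.shape)
    return RoiLabelMap(labels=labels, t2l_fraction=zeros, nawm_fraction=zeros, factor=1)


class TestSummarizeScan:
    def test_single_voxel_roi(self):
        labels = np.zeros((2, 2, 1), dtype=int)
        labels[0, 0, 0] = RoiLabel.T2L
        vals = np.arange(4, dtype=float).reshape(2, 2, 1) + 1
        s = summarize_scan({"kpl": vals}, label_map_from(labels))
        assert s.t2l_median["kpl"] == 1.0
        assert s.t2l_n_voxels["kpl"] == 1
        assert np.isnan(s.nawm_median["kpl"]) and s.nawm_n_voxels["kpl"] == 0

    def test_median_robust_to_outlier(self):
        labels = np.full((3, 1, 1), int(RoiLabel.T2L))
        vals = np.array([1.0, 2.0, 100.0]).reshape(3, 1, 1)
        s = summarize_scan({"lac_pyr": vals}, label_map_from(labels))
        assert s.t2l_median["lac_pyr"] == 2.0

    def test_nan_voxels_excluded(self):
        labels = np.full((4, 1, 1), int(RoiLabel.NAWM))
        vals = np.array([np.nan, 3.0, 1.0, np.nan]).reshape(4, 1, 1)
        s = summarize_scan({"kpb": vals}, label_map_from(labels))
        assert s.nawm_median["kpb"] == 2.0
        assert s.nawm_n_voxels["kpb"] == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_masked_median_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 3, size=(6, 6, 3))
        vals = rng.normal(size=(6, 6, 3))
        vals[rng.random((6, 6, 3)) < 0.2] = np.nan
        s = summarize_scan({"x": vals}, label_map_from(labels))
        want_t2l = masked_median_oracle(vals, labels == 1)
        want_nawm = masked_median_oracle(vals, labels == 2)
        assert s.t2l_median["x"] == pytest.approx(want_t2l, nan_ok=True)
        assert s.nawm_median["x"] == pytest.approx(want_nawm, nan_ok=True)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            summarize_scan({"x": np.zeros((2, 2, 2))}, label_map_from(np.zeros((3, 3, 3))))


class TestNormalizeToNawm:
    def _summary(self, t2l, nawm):
        s = ScanSummary(patient_id="P", months_post_treatment=0)
        s.t2l_median = {"kpl": t2l}
        s.nawm_median = {"kpl": nawm}
        return s

    def test_equal_values_give_unity(self):
        assert normalize_to_nawm(self._summary(0.2, 0.2)).normalized_t2l["kpl"] == 1.0

    def test_ratio(self):
        assert normalize_to_nawm(self._summary(0.3, 0.2)).normalized_t2l["kpl"] == pytest.approx(1.5)

    def test_zero_or_missing_nawm_gives_missing(self):
        assert np.isnan(normalize_to_nawm(self._summary(0.3, 0.0)).normalized_t2l["kpl"])
        assert np.isnan(normalize_to_nawm(self._summary(0.3, float("nan"))).normalized_t2l["kpl"])

    def test_scale_covariance(self):
        """Scaling all map values by c > 0 leaves normalized values unchanged."""
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 3, size=(6, 6, 3))
        vals = np.abs(rng.normal(1.0, 0.3, size=(6, 6, 3)))
        lm = label_map_from(labels)
        a = normalize_to_nawm(summarize_scan({"x": vals}, lm))
        b = normalize_to_nawm(summarize_scan({"x": 37.5 * vals}, lm))
        assert a.normalized_t2l["x"] == pytest.approx(b.normalized_t2l["x"], rel=1e-12)


class TestGrouping:
    @pytest.mark.parametrize(
        "treatment,expected",
        [
            ("Bevacizumab + CCNU", "BEV+"),
            ("Bevacizumab + [RT, TMZ]", "BEV+"),
            ("Everolimus + [TMZ, Olaparib]", "EVER+"),
            ("TMZ + [Olaparib, Abemaciclib]", "ALKYL+"),
            ("CCNU + Afatinib", "ALKYL+"),
            ("TMZ", "control"),
            ("CCNU", "control"),
            ("Olaparib", "unclassified"),
            ("", "unclassified"),
        ],
    )
    def test_classify_treatment(self, treatment, expected):
        assert classify_treatment(treatment) == expected


class TestClinicalTable:
    def test_packaged_cohort_counts(self):
        _, counts = parse_clinical_table(hp13c.clinical_table_path())
        assert counts["n_patients"] == 20
        assert counts["n_baseline_scans"] == 12
        assert counts["n_total_scans"] == 41
        assert counts["n_early_progressors"] == 11
        assert counts["n_controls"] == 2

    def test_followup_token_counting(self):
        df, _ = parse_clinical_table(hp13c.clinical_table_path())
        p19 = df.set_index("patient_id").loc["P19"]
        assert p19["followup_list"] == [1, 3]
        assert p19["n_scans"] == 3  # baseline + two follow-ups

    def test_baseline_only_patient(self):
        rows = pd.DataFrame(
            [
                {"patient_id": "A", "treatment": "TMZ", "pfs6_flag": 0, "baseline_acquired": "Yes", "followup_months": ""},
                {"patient_id": "B", "treatment": "TMZ", "pfs6_flag": 1, "baseline_acquired": "No", "followup_months": ""},
            ]
        )
        df, counts = parse_clinical_table(rows)
        assert list(df["n_scans"]) == [1, 0]
        assert counts["n_total_scans"] == 1

    def test_malformed_month_token_names_row(self):
        rows = pd.DataFrame(
            [{"patient_id": "P7", "treatment": "TMZ", "pfs6_flag": 0, "baseline_acquired": "Yes", "followup_months": "2x"}]
        )
        with pytest.raises(ValueError, match="P7"):
            parse_clinical_table(rows)


def _mk_summary(pid, month, value):
    s = ScanSummary(patient_id=pid, months_post_treatment=month)
    for p in hp13c.PARAMETERS:
        s.t2l_median[p] = value
        s.nawm_median[p] = 1.0
        s.normalized_t2l[p] = value
    return s


class TestTrajectories:
    def _cohort(self, values_by_patient_month, clinical):
        summaries = [_mk_summary(pid, m, v) for (pid, m), v in values_by_patient_month.items()]
        return cohort_table(summaries, clinical)

    def _clinical(self):
        return pd.DataFrame(
            [
                {"patient_id": "A", "treatment": "TMZ", "pfs6_flag": 0, "baseline_acquired": "Yes", "followup_months": ""},
                {"patient_id": "B", "treatment": "TMZ + CCNU", "pfs6_flag": 1, "baseline_acquired": "Yes", "followup_months": ""},
                {"patient_id": "C", "treatment": "TMZ + CCNU", "pfs6_flag": 1, "baseline_acquired": "Yes", "followup_months": ""},
            ]
        )

    def test_single_patient_bin(self):
        cohort = self._cohort({("A", 0): 2.0}, self._clinical())
        traj = group_trajectories(cohort, "norm_kpl", "treatment")
        row = traj.iloc[0]
        assert row["mean"] == 2.0 and row["n"] == 1
        assert np.isnan(row["sd"]) and np.isnan(row["se"])

    def test_identical_values_zero_sd(self):
        cohort = self._cohort({("B", 1): 3.0, ("C", 1): 3.0}, self._clinical())
        traj = group_trajectories(cohort, "norm_kpl", "treatment")
        row = traj[traj["group"] == "ALKYL+"].iloc[0]
        assert row["sd"] == 0.0 and row["se"] == 0.0 and row["n"] == 2

    def test_first_scan_per_bin_rule(self):
        summaries = [_mk_summary("A", 1.2, 5.0), _mk_summary("A", 0.8, 9.0)]
        cohort = cohort_table(summaries, self._clinical())
        traj = group_trajectories(cohort, "norm_kpl", "treatment")
        assert traj.iloc[0]["mean"] == 5.0  # both bin to month 1; first kept

    def test_progressor_grouping(self):
        cohort = self._cohort({("A", 0): 1.0, ("B", 0): 2.0, ("C", 0): 4.0}, self._clinical())
        traj = group_trajectories(cohort, "norm_kpl", "progressor")
        early = traj[traj["group"] == "early"].iloc[0]
        assert early["mean"] == 3.0 and early["n"] == 2


class TestPairedVoxelChange:
    def _labels(self, shape=(4, 4, 2), frac=0.5, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.where(rng.random(shape) < frac, int(RoiLabel.T2L), int(RoiLabel.NONE))
        return label_map_from(labels)

    def test_identical_scans_zero_change(self):
        lm = self._labels()
        vals = np.abs(np.random.default_rng(1).normal(1, 0.2, lm.labels.shape))
        cmp = paired_voxel_change({"kpl": vals}, {"kpl": vals.copy()}, lm, lm)
        assert cmp.mean_pct_change["kpl"] == pytest.approx(0.0, abs=1e-12)
        assert cmp.n_voxels["kpl"] == int(lm.t2l.sum())

    def test_uniform_scaling_gives_that_percent(self):
        lm = self._labels()
        vals = np.abs(np.random.default_rng(2).normal(1, 0.2, lm.labels.shape))
        cmp = paired_voxel_change({"x": vals}, {"x": 1.1 * vals}, lm, lm)
        assert cmp.mean_pct_change["x"] == pytest.approx(10.0, rel=1e-9)

    def test_voxel_set_symmetric_in_scan_order(self):
        lm_a, lm_b = self._labels(seed=3), self._labels(seed=4)
        rng = np.random.default_rng(5)
        a = rng.normal(1, 0.5, lm_a.labels.shape)
        b = rng.normal(1, 0.5, lm_a.labels.shape)
        a[rng.random(a.shape) < 0.2] = np.nan
        fwd = paired_voxel_change({"x": a}, {"x": b}, lm_a, lm_b)
        rev = paired_voxel_change({"x": b}, {"x": a}, lm_b, lm_a)
        assert fwd.n_voxels["x"] == rev.n_voxels["x"]

    def test_no_shared_voxels_empty(self):
        shape = (2, 2, 1)
        lm_a = label_map_from(np.full(shape, int(RoiLabel.T2L)))
        lm_b = label_map_from(np.zeros(shape, dtype=int))
        cmp = paired_voxel_change({"x": np.ones(shape)}, {"x": np.ones(shape)}, lm_a, lm_b)
        assert cmp.n_voxels["x"] == 0
        assert np.isnan(cmp.mean_pct_change["x"])
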