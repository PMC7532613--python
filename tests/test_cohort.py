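"""Cohort aggregation, relative factors, paired t tests and report tables."""

import numpy as np
import pytest
from scipy import stats as sps

from scrkit import (
    BaselineRiskTable,
    Cohort,
    DoseVolumeHistogram,
    InputError,
    PatientPlan,
    RiskConfig,
    RiskModelParams,
    build_report,
    compare_cohorts,
    generate_cohort,
    load_manifest,
    paired_t_test,
    relative_factor,
    summarize_cohort,
    SyntheticCohortConfig,
)
from scrkit.cohort import ORGANS

LINEAR = RiskModelParams("linear")
TABLE = BaselineRiskTable.default()


def uniform_patient(pid, doses):
    return PatientPlan(
        patient_id=pid,
        dvhs={
            organ: DoseVolumeHistogram.uniform(d, organ_id=organ, patient_id=pid)
            for organ, d in zip(ORGANS, doses)
        },
    )


def uniform_cohort(doses_per_patient, label="GroupX", **kw):
    patients = [uniform_patient(f"P{i:02d}", d) for i, d in enumerate(doses_per_patient)]
    meta = dict(group=2, technique="PT", setup="FB")
    meta.update(kw)
    return Cohort(label=label, patients=patients, **meta)


class TestSummarize:
    def test_identical_patients_match_hand_computation(self):
        cohort = uniform_cohort([(8.4, 0.0, 0.0)] * 5)
        s = summarize_cohort(cohort, LINEAR, TABLE, 30)
        assert s.organ_ear.loc["ipsilateral_lung", "mean"] == pytest.approx(63.0)
        assert round(s.organ_ear.loc["ipsilateral_lung", "mean"]) == 63
        assert s.organ_ear.loc["ipsilateral_lung", "sd"] == pytest.approx(0.0)
        assert s.cumulative_mean == pytest.approx(63.0)

    def test_single_patient_cohort_rejected(self):
        cohort = uniform_cohort([(8.4, 0.3, 0.1)])
        with pytest.raises(InputError, match="at least 2"):
            summarize_cohort(cohort, LINEAR, TABLE, 30)

    def test_missing_organ_names_patient_and_organ(self):
        cohort = uniform_cohort([(1, 1, 1), (2, 2, 2)])
        del cohort.patients[1].dvhs["contralateral_breast"]
        with pytest.raises(InputError, match="P01.*contralateral_breast"):
            summarize_cohort(cohort, LINEAR, TABLE, 30)

    def test_sem_is_sd_over_sqrt_n(self, rng):
        doses = rng.uniform(1, 20, size=(6, 3))
        s = summarize_cohort(uniform_cohort(doses), LINEAR, TABLE, 30)
        np.testing.assert_allclose(
            s.organ_ear["sem"], s.organ_ear["sd"] / np.sqrt(6), atol=1e-12
        )
        assert s.cumulative_sem == pytest.approx(s.cumulative_sd / np.sqrt(6))

    def test_cumulative_mean_equals_sum_of_organ_means(self, rng):
        doses = rng.uniform(0.1, 20, size=(5, 3))
        s = summarize_cohort(uniform_cohort(doses), LINEAR, TABLE, 30)
        assert s.cumulative_mean == pytest.approx(s.organ_ear["mean"].sum(), abs=1e-9)

    def test_synthetic_group2_pt_cohort_near_published_column(self):
        # means calibrated to the study dose table -> organ EARs within 10%
        cohort, _ = generate_cohort(
            SyntheticCohortConfig(group=2, technique="PT", setup="FB", seed=11)
        )
        s = summarize_cohort(cohort, LINEAR, TABLE, 30)
        assert s.organ_ear.loc["ipsilateral_lung", "mean"] == pytest.approx(63, rel=0.10)
        assert s.organ_ear.loc["contralateral_lung", "mean"] == pytest.approx(2, abs=2)
        assert s.organ_ear.loc["contralateral_breast", "mean"] == pytest.approx(0, abs=2)


class TestPairedT:
    def test_identical_samples_degenerate_p_one(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == 1.0 and res.degenerate and not res.significant

    def test_constant_nonzero_difference_flagged(self):
        res = paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p == 1.0

    def test_matches_textbook_formula(self, rng):
        a, b = rng.normal(10, 2, 5), rng.normal(8, 2, 5)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * sps.t.sf(abs(t), len(d) - 1)
        res = paired_t_test(a, b)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_symmetric_in_swap(self, rng):
        a, b = rng.normal(10, 2, 8), rng.normal(8, 2, 8)
        assert paired_t_test(a, b).p == pytest.approx(paired_t_test(b, a).p, abs=1e-12)

    def test_invariant_under_common_shift_of_all_values(self, rng):
        a, b = rng.normal(10, 2, 6), rng.normal(8, 2, 6)
        shifted = paired_t_test(a + 5.0, b + 5.0)
        assert shifted.p == pytest.approx(paired_t_test(a, b).p, abs=1e-12)

    def test_input_errors(self):
        with pytest.raises(InputError):
            paired_t_test([1, 2], [1, 2, 3])
        with pytest.raises(InputError):
            paired_t_test([1], [2])


class TestRelativeFactor:
    def test_published_ratio_of_means(self):
        # cumulative means from the published per-organ EAR columns
        rom, _, _ = relative_factor([131 + 55 + 44.0], [63 + 2 + 0.0])
        assert round(rom, 1) == 3.5
        rom, _, _ = relative_factor([40 + 35 + 35.0], [21.0])
        assert round(rom, 1) == 5.2
        rom, _, _ = relative_factor([85 + 3 + 7.0], [44 + 1 + 0.0])
        assert round(rom, 1) == 2.1

    def test_identical_cohorts_give_unity(self):
        rom, ppm, _ = relative_factor([2.0, 3.0], [2.0, 3.0])
        assert rom == 1.0 and ppm == 1.0

    def test_zero_denominator_mean_rejected(self):
        with pytest.raises(InputError, match="undefined"):
            relative_factor([1.0, 2.0], [0.0, 0.0])

    def test_both_conventions_reported(self):
        rom, ppm, pps = relative_factor([4.0, 9.0], [2.0, 3.0])
        assert rom == pytest.approx(13 / 5)
        assert ppm == pytest.approx((2.0 + 3.0) / 2)
        assert pps == pytest.approx(np.std([2.0, 3.0], ddof=1) / np.sqrt(2))


class TestCompareCohorts:
    def _cohorts(self, rng, scale=1.0):
        a = uniform_cohort(scale * rng.uniform(5, 20, size=(5, 3)), label="A",
                           technique="VMAT")
        b = uniform_cohort(scale * rng.uniform(1, 4, size=(5, 3)), label="B")
        return a, b

    def test_factor_invariant_under_common_dose_rescaling(self, rng):
        a, b = self._cohorts(rng)
        r1 = compare_cohorts(a, b, LINEAR, TABLE, 30)
        rng2 = np.random.default_rng(20260921)  # same stream, doses doubled
        a3, b3 = self._cohorts(rng2, scale=2.0)
        r2 = compare_cohorts(a3, b3, LINEAR, TABLE, 30)
        assert r2.factor_ratio_of_means == pytest.approx(r1.factor_ratio_of_means)

    def test_swapping_inverts_factor_and_keeps_p(self, rng):
        a, b = self._cohorts(rng)
        fwd = compare_cohorts(a, b, LINEAR, TABLE, 30)
        rev = compare_cohorts(b, a, LINEAR, TABLE, 30)
        assert rev.factor_ratio_of_means == pytest.approx(1 / fwd.factor_ratio_of_means)
        assert rev.p_value == pytest.approx(fwd.p_value, abs=1e-12)

    def test_unpaired_cohorts_rejected(self, rng):
        a, _ = self._cohorts(rng)
        b = uniform_cohort(np.ones((4, 3)), label="B4")
        with pytest.raises(InputError, match="not paired"):
            compare_cohorts(a, b, LINEAR, TABLE, 30)


@pytest.fixture(scope="module")
def cohorts():
    pt, _ = generate_cohort(
        SyntheticCohortConfig(group=2, technique="PT", setup="FB", seed=5)
    )
    vmat, _ = generate_cohort(
        SyntheticCohortConfig(group=2, technique="VMAT", setup="FB", seed=6)
    )
    return [vmat, pt]


class TestReport:
    def test_tables_have_expected_structure(self, cohorts):
        report = build_report(cohorts, RiskConfig())
        assert set(report.mean_dose["organ"]) == set(ORGANS)
        assert len(report.mean_dose) == 2 * 3
        assert len(report.organ_ear) == 2 * 3 * 2 * 3  # cohorts x models x ages x organs
        assert len(report.cumulative) == 2 * 3 * 2
        assert len(report.comparisons) == 3 * 2  # models x ages for the one pair
        assert len(report.delta_ear) == 2 * 3 * 5 * 3
        text = report.to_text()
        assert "paired t tests" in text and "reference only" in text

    def test_single_cohort_report_has_no_comparisons(self, cohorts):
        report = build_report(cohorts[:1], RiskConfig())
        assert len(report.comparisons) == 0
        assert len(report.mean_dose) == 3

    def test_zero_breast_dose_gives_zero_delta(self):
        cohort = uniform_cohort([(8.0, 1.0, 0.0)] * 2, label="Z")
        report = build_report([cohort], RiskConfig())
        breast = report.delta_ear[report.delta_ear["organ"] == "contralateral_breast"]
        assert breast["delta_ear"].abs().max() < 1e-9

    def test_report_written_to_disk(self, cohorts, tmp_path):
        report = build_report(cohorts, RiskConfig())
        report.write(tmp_path)
        for name in ("mean_dose", "organ_ear", "cumulative", "comparisons", "delta_ear"):
            assert (tmp_path / f"{name}.csv").exists()
        assert (tmp_path / "report.txt").read_text().startswith("Mean organ dose")


class TestManifest:
    def test_round_trip_via_disk(self, tmp_path):
        config = SyntheticCohortConfig(group=1, technique="PT", setup="FB", seed=2)
        cohort, _ = generate_cohort(config, out_dir=tmp_path)
        (loaded,) = load_manifest(tmp_path / "manifest.csv")
        assert loaded.label == cohort.label
        assert loaded.patient_ids == cohort.patient_ids
        for p_disk, p_mem in zip(loaded.patients, cohort.patients):
            for organ in ORGANS:
                np.testing.assert_array_equal(
                    p_disk.dvhs[organ].bin_values, p_mem.dvhs[organ].bin_values
                )

    def test_missing_dvh_file_reported(self, tmp_path):
        config = SyntheticCohortConfig(group=1, technique="PT", setup="FB", seed=2)
        generate_cohort(config, out_dir=tmp_path)
        (tmp_path / "P01_ipsilateral_lung.csv").unlink()
        with pytest.raises(InputError, match="P01_ipsilateral_lung.csv"):
            load_manifest(tmp_path / "manifest.csv")

    def test_missing_column_reported(self, tmp_path):
        (tmp_path / "m.csv").write_text("patient_id,organ\nP1,lung\n")
        with pytest.raises(InputError, match="lacks columns"):
            load_manifest(tmp_path / "m.csv")
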