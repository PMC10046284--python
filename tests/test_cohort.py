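"""Patient aggregation, biomarker summaries and t-tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scistats

from _oracles import brute_paired_t, brute_unpaired_t

from ihcscore import (
    PatientScore,
    ROIStats,
    SlideScore,
    aggregate_cohort,
    aggregate_patient,
    paired_t,
    preop_subgroup_report,
    summarize_biomarker,
    unpaired_t,
)
from ihcscore.errors import DegenerateTestError, InvalidParameterError, SampleSizeError


def _score(tumor_mean, bg_mean, sample_id="s1", biomarker="TEM-1", tumor_sd=5.0):
    return SlideScore(
        sample_id=sample_id,
        biomarker=biomarker,
        tumor=ROIStats(mean=tumor_mean, sd=tumor_sd, n_pixels=100),
        background=ROIStats(mean=bg_mean, sd=2.0, n_pixels=100),
        tbr=tumor_mean / bg_mean,
    )


def _patient(tumor, tbr, biomarker="TEM-1", preop=True, pid="p"):
    return PatientScore(
        patient_id=pid,
        biomarker=biomarker,
        tumor_mean=tumor,
        tumor_sd_mean=5.0,
        background_mean=tumor / tbr,
        tbr=tbr,
        preop_therapy=preop,
    )


class TestAggregatePatient:
    def test_single_sample_passes_through(self):
        s = _score(80.0, 40.0)
        p = aggregate_patient([s])
        assert p.tumor_mean == 80.0 and p.background_mean == 40.0 and p.tbr == 2.0

    def test_unweighted_mean_of_samples(self):
        p = aggregate_patient([_score(80.0, 30.0), _score(90.0, 30.0)])
        assert p.tumor_mean == 85.0

    def test_tbr_recomputed_from_averaged_means(self):
        p = aggregate_patient([_score(60.0, 30.0), _score(90.0, 30.0)])
        assert np.isclose(p.tbr, 75.0 / 30.0)  # 2.5, not mean of (2.0, 3.0)

    def test_permutation_invariant(self):
        scores = [_score(60.0, 20.0), _score(90.0, 35.0), _score(75.0, 28.0)]
        a = aggregate_patient(scores)
        b = aggregate_patient(scores[::-1])
        assert a == b

    def test_mixed_biomarkers_rejected(self):
        with pytest.raises(InvalidParameterError, match="mixed"):
            aggregate_patient([_score(80, 40, biomarker="TEM-1"), _score(80, 40, biomarker="VEGF-A")])


class TestSummarizeBiomarker:
    def test_single_patient_echoes_values(self):
        s = summarize_biomarker([_patient(81.0, 3.1)])
        assert s.n_patients == 1
        assert s.mean_tumor_intensity == 81.0
        assert np.isclose(s.mean_tbr, 3.1)
        assert s.n_tbr_below_1 == 0

    def test_counts_tbr_below_unity(self):
        pats = [_patient(50, r, pid=str(i)) for i, r in enumerate((0.9, 1.1, 2.0))]
        assert summarize_biomarker(pats).n_tbr_below_1 == 1

    def test_expression_fraction_uses_threshold(self):
        pats = [_patient(5.0, 1.2, pid="a"), _patient(50.0, 1.2, pid="b")]
        s = summarize_biomarker(pats, expression_threshold=10.0)
        assert s.fraction_expressed == 0.5


class TestPairedT:
    def test_symmetric_differences_give_null(self):
        res = paired_t([1.0, 0.0], [0.0, 1.0])
        assert res.statistic == 0.0 and res.p == 1.0 and not res.significant

    def test_constant_difference_is_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_t([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])

    def test_needs_two_pairs(self):
        with pytest.raises(SampleSizeError):
            paired_t([1.0], [0.0])

    def test_matches_reference_implementation(self):
        a, b = [10.0, 12.0, 14.0, 16.0], [8.0, 9.0, 11.0, 12.0]
        res = paired_t(a, b)
        ref = scistats.ttest_rel(a, b)
        assert abs(res.statistic - ref.statistic) < 1e-10
        assert abs(res.p - ref.pvalue) < 1e-10

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_formula(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        a = rng.normal(10, 3, n)
        b = a + rng.normal(1, 2, n)
        res = paired_t(a, b)
        t_ref, p_ref = brute_paired_t(a, b)
        assert abs(res.statistic - t_ref) < 1e-10
        assert abs(res.p - p_ref) < 1e-10


class TestUnpairedT:
    def test_identical_groups_are_null(self):
        res = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_needs_two_per_group(self):
        with pytest.raises(SampleSizeError):
            unpaired_t([1.0], [1.0, 2.0])

    @pytest.mark.parametrize("equal_var", [True, False])
    def test_matches_reference_implementation(self, equal_var):
        rng = np.random.default_rng(19)
        a = rng.normal(85, 20, 11)
        b = rng.normal(74, 15, 6)
        res = unpaired_t(a, b, equal_var=equal_var)
        ref = scistats.ttest_ind(a, b, equal_var=equal_var)
        assert abs(res.statistic - ref.statistic) < 1e-10
        assert abs(res.p - ref.pvalue) < 1e-10

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000), st.booleans())
    def test_matches_brute_force_formula(self, seed, equal_var):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, int(rng.integers(2, 10)))
        b = rng.normal(0.5, 2, int(rng.integers(2, 10)))
        res = unpaired_t(a, b, equal_var=equal_var)
        t_ref, p_ref = brute_unpaired_t(a, b, equal_var=equal_var)
        assert abs(res.statistic - t_ref) < 1e-10
        assert abs(res.p - p_ref) < 1e-10


class TestSubgroupReport:
    def _patients(self):
        pats = []
        for biomarker in ("TEM-1", "VEGF-A", "PDGFR-alpha"):
            for i in range(4):
                pats.append(_patient(80 + i, 2.0 + 0.1 * i, biomarker=biomarker, preop=True, pid=f"{biomarker}{i}"))
            for i in range(3):
                pats.append(_patient(70 + i, 1.5 + 0.1 * i, biomarker=biomarker, preop=False, pid=f"{biomarker}n{i}"))
        return pats

    def test_three_biomarkers_two_metrics(self):
        report = preop_subgroup_report(self._patients())
        assert len(report) == 6
        assert set(report["metric"]) == {"mean_tumor_intensity", "mean_tbr"}
        assert report["p"].notna().all()

    def test_all_preop_marks_p_not_computable(self):
        pats = [_patient(80 + i, 2.0, preop=True, pid=str(i)) for i in range(5)]
        report = preop_subgroup_report(pats)
        assert report["p"].isna().all()
        assert (report["n_no_preop"] == 0).all()

    def test_identical_subgroups_give_null_p(self):
        pats = [
            _patient(80.0, 2.0, preop=True, pid="a"),
            _patient(90.0, 3.0, preop=True, pid="b"),
            _patient(80.0, 2.0, preop=False, pid="c"),
            _patient(90.0, 3.0, preop=False, pid="d"),
        ]
        report = preop_subgroup_report(pats)
        assert np.allclose(report["p"], 1.0)


class TestAggregateCohort:
    def test_joins_metadata_and_averages_duplicate_samples(self):
        scores = pd.DataFrame(
            [
                _score(60.0, 30.0, sample_id="s1").as_row(),
                _score(90.0, 30.0, sample_id="s2").as_row(),
                _score(50.0, 25.0, sample_id="s3").as_row(),
            ]
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "patient_id": [1, 1, 2],
                "biomarker": ["TEM-1"] * 3,
                "preoperative_therapy": ["Radiotherapy", "Radiotherapy", "None"],
            }
        )
        patients = aggregate_cohort(scores, meta)
        assert len(patients) == 2
        p1 = next(p for p in patients if p.patient_id == "1")
        assert p1.tumor_mean == 75.0 and np.isclose(p1.tbr, 2.5)
        assert p1.preop_therapy is True
        p2 = next(p for p in patients if p.patient_id == "2")
        assert p2.preop_therapy is False

    def test_unknown_sample_rejected(self):
        scores = pd.DataFrame([_score(60.0, 30.0, sample_id="sX").as_row()])
        meta = pd.DataFrame({"sample_id": ["s1"], "patient_id": [1]})
        with pytest.raises(InvalidParameterError, match="sX"):
            aggregate_cohort(scores, meta)
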