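import math

import numpy as np
import pandas as pd
import pytest

from tiadose import (
    LU177,
    BiExp3Params,
    CohortConfig,
    FitSpec,
    MonoExpParams,
    PiecewiseTIAMethod,
    RegionKineticsSpec,
    SCHEDULES,
    combine_kidneys,
    default_regions,
    make_truth,
    qcd,
    recovery_suite,
    sample_series,
    simulate_cohort,
)
from tiadose.cohort import default_dose_factors


@pytest.fixture
def organ_spec():
    return RegionKineticsSpec("kidney", "organ_instant_uptake",
                              MonoExpParams(A=100.0, lam=0.01))


@pytest.fixture
def lesion_spec():
    return RegionKineticsSpec("lesion", "lesion",
                              BiExp3Params(A=100.0, lam1=0.02, lam2=0.2),
                              schedule="patientB")


class TestTruth:
    def test_monoexp_truth_tia(self, organ_spec):
        truth = make_truth(organ_spec)
        assert truth.tia == pytest.approx(10000.0, rel=1e-12)

    def test_biexp3_truth_tia(self, lesion_spec):
        truth = make_truth(lesion_spec)
        assert truth.tia == pytest.approx(4500.0, rel=1e-12)

    def test_deterministic(self, organ_spec):
        assert make_truth(organ_spec, seed=1) == make_truth(organ_spec, seed=2)

    def test_spec_invariants(self):
        with pytest.raises(ValueError, match="below physical"):
            RegionKineticsSpec("k", "organ_instant_uptake",
                               MonoExpParams(A=10, lam=0.001))
        with pytest.raises(ValueError, match="monoexponential"):
            RegionKineticsSpec("k", "organ_instant_uptake",
                               BiExp3Params(A=10, lam1=0.01, lam2=0.1))
        with pytest.raises(ValueError, match="biexponential"):
            RegionKineticsSpec("l", "lesion", MonoExpParams(A=10, lam=0.01))


class TestSampleSeries:
    def test_zero_noise_lies_on_model(self, organ_spec):
        from tiadose import eval_model
        from dataclasses import replace
        spec = replace(organ_spec, noise_sd=0.0)
        series = sample_series(make_truth(spec), spec, seed=0)
        expected = eval_model("monoexp", spec.params, series.t)
        assert series.a == pytest.approx(expected, rel=1e-15)

    def test_patient_schedules(self, organ_spec, lesion_spec):
        sa = sample_series(make_truth(organ_spec), organ_spec, seed=0)
        assert sa.times == pytest.approx((3.7, 27.7, 103.1, 124.0))
        sb = sample_series(make_truth(lesion_spec), lesion_spec, seed=0)
        assert sb.times == pytest.approx((3.7, 32.6, 99.6, 193.3))

    def test_seeding_contract(self, organ_spec):
        truth = make_truth(organ_spec)
        s1 = sample_series(truth, organ_spec, seed=1)
        s1b = sample_series(truth, organ_spec, seed=1)
        s2 = sample_series(truth, organ_spec, seed=2)
        assert s1.a == pytest.approx(s1b.a, rel=0)
        assert not np.allclose(s1.a, s2.a)

    def test_emitted_convention(self):
        spec = RegionKineticsSpec("k", "organ_instant_uptake",
                                  MonoExpParams(A=100, lam=0.01),
                                  decay_convention="corrected_to_injection",
                                  noise_sd=0.0)
        series = sample_series(make_truth(spec), spec, seed=0)
        assert series.decay_convention == "corrected_to_injection"
        raw = 100 * np.exp(-0.01 * series.t)
        assert series.a == pytest.approx(
            raw * np.exp(LU177.lam_physical * series.t), rel=1e-12)


def single_method_catalog():
    return [PiecewiseTIAMethod("m05", "model_extension",
                               FitSpec("monoexp",
                                       constrain_lambda_physical=True),
                               "model_extension"),
            PiecewiseTIAMethod("m09", "model_extension", FitSpec("biexp3"),
                               "model_extension")]


class TestSimulateCohort:
    def test_determinism_byte_identical(self, tmp_path):
        regions = default_regions("A", noise_sd=0.05)
        cfg = CohortConfig(n_participants=6, seed=42,
                           error_rates={"sum_kidneys_unweighted": 0.5})
        out1, out2 = tmp_path / "c1.csv", tmp_path / "c2.csv"
        for out in (out1, out2):
            cohort, _ = simulate_cohort(regions, cfg)
            cohort.to_csv(out, index=False)
        assert out1.read_bytes() == out2.read_bytes()

    def test_zero_noise_single_method_recovers_truth(self):
        regions = default_regions("A", noise_sd=0.0,
                                  decay_convention="none")
        matched = {"liver": "m05", "spleen": "m05"}
        cfg = CohortConfig(n_participants=4, seed=0,
                           method_freq={"m05": 1.0})
        cohort, ledger = simulate_cohort(regions, cfg,
                                         catalog=single_method_catalog())
        truth = ledger["truth_tia_MBq_h"]
        table = default_dose_factors(regions)
        t4 = cohort[cohort.task == "task4"]
        for region in ("liver", "spleen", "kidney_left", "kidney_right"):
            ads = t4[t4.region == region]["ad_Gy"]
            expected = truth[region] * table[region].factor
            assert ads.to_numpy() == pytest.approx(expected, rel=1e-6)
        # per-region QCD of a uniform cohort is exactly zero
        for region, sub in t4.groupby("region"):
            assert qcd(sub["ad_Gy"]) == pytest.approx(0.0, abs=1e-12)

    def test_task5_shared_reference(self):
        regions = default_regions("A", noise_sd=0.05)
        cfg = CohortConfig(n_participants=5, seed=3)
        cohort, ledger = simulate_cohort(regions, cfg)
        t5 = cohort[(cohort.task == "task5") & (cohort.region == "liver")]
        assert t5["ad_Gy"].nunique() == 1  # same TIA, same dose step

    def test_unknown_error_mode_rejected(self):
        with pytest.raises(ValueError, match="error mode"):
            CohortConfig(error_rates={"forgets_lunch": 0.1})

    def test_method_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortConfig(method_freq={"m05": 0.7})


class TestErrorModeMonotonicity:
    def _cohorts(self, patient="A", mode=None, seed=11):
        regions = default_regions(patient, noise_sd=0.0)
        base = CohortConfig(n_participants=3, seed=seed,
                            method_freq={"m05": 1.0})
        err = CohortConfig(n_participants=3, seed=seed,
                           method_freq={"m05": 1.0},
                           error_rates={mode: 1.0})
        cat = single_method_catalog()
        c0, _ = simulate_cohort(regions, base, catalog=cat)
        c1, _ = simulate_cohort(regions, err, catalog=cat)
        return c0, c1

    def _t4(self, cohort, region):
        sub = cohort[(cohort.task == "task4") & (cohort.region == region)]
        return sub["ad_Gy"].to_numpy()

    def test_decay_skip_inflates_every_region(self):
        c0, c1 = self._cohorts(mode="skip_decay_uncorrection")
        for region in ("liver", "spleen", "kidney_left", "lesion1"):
            assert np.all(self._t4(c1, region) > self._t4(c0, region))

    def test_decay_skip_noop_for_scan_start_convention(self):
        c0, c1 = self._cohorts(patient="B", mode="skip_decay_uncorrection")
        for region in ("liver", "kidney_left"):
            assert self._t4(c1, region) == pytest.approx(
                self._t4(c0, region), rel=1e-12)

    def test_lesion_inclusion_inflates_liver_only(self):
        c0, c1 = self._cohorts(mode="include_lesions_in_liver")
        assert np.all(self._t4(c1, "liver") > self._t4(c0, "liver"))
        assert self._t4(c1, "spleen") == pytest.approx(
            self._t4(c0, "spleen"), rel=1e-12)

    def test_kidney_sum_exceeds_weighted_average(self):
        c0, c1 = self._cohorts(mode="sum_kidneys_unweighted")
        assert np.all(self._t4(c1, "kidney_total") > self._t4(c0, "kidney_total"))
        # and the correct combination is the mass-weighted mean
        table = default_dose_factors(default_regions("A"))
        left = self._t4(c0, "kidney_left")
        right = self._t4(c0, "kidney_right")
        expected = combine_kidneys(left[0], table["kidney_left"].mass,
                                   right[0], table["kidney_right"].mass)
        assert self._t4(c0, "kidney_total")[0] == pytest.approx(expected)


class TestRecoverySuite:
    def test_matched_model_zero_noise_bias(self, organ_spec):
        from dataclasses import replace
        spec = replace(organ_spec, noise_sd=0.0)
        table = recovery_suite([spec], catalog=single_method_catalog(),
                               n_replicates=2, seed=0)
        m05 = table[table.method_id == "m05"].iloc[0]
        assert abs(m05["rel_bias_median"]) < 1e-6

    def test_mismatched_model_biases_more(self, lesion_spec):
        """Fitting a monoexponential to uptake-phase lesion kinetics biases
        TIA more than the matched biexponential model."""
        monoexp_only = [PiecewiseTIAMethod(
            "mono", "model_extension",
            FitSpec("monoexp", constrain_lambda_physical=True),
            "model_extension")]
        matched = [PiecewiseTIAMethod("bi", "model_extension",
                                      FitSpec("biexp3"), "model_extension")]
        t_mono = recovery_suite([lesion_spec], catalog=monoexp_only,
                                n_replicates=40, seed=5)
        t_bi = recovery_suite([lesion_spec], catalog=matched,
                              n_replicates=40, seed=5)
        assert abs(t_mono.iloc[0]["rel_bias_median"]) > \
            abs(t_bi.iloc[0]["rel_bias_median"])

    def test_trapezoid_physical_tail_positive_bias_on_washout(self, organ_spec):
        trap = [PiecewiseTIAMethod("m01", "linear_from_origin", "trapezoid",
                                   "physical_decay")]
        table = recovery_suite([organ_spec], catalog=trap,
                               n_replicates=40, seed=7)
        assert table.iloc[0]["rel_bias_median"] > 0
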