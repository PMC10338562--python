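import numpy as np
import pytest

from smo.formulas import whyte_hrmax
from smo.synthetic import (CohortRanges, SyntheticSubjectTruth, generate_test,
                           sample_cohort, true_vo2max_for)


class TestSampleCohort:
    def test_same_seed_gives_identical_cohort(self):
        a = sample_cohort(5, seed=99)
        b = sample_cohort(5, seed=99)
        for x, y in zip(a, b):
            assert x == y

    def test_different_seed_differs(self):
        a = sample_cohort(3, seed=1)
        b = sample_cohort(3, seed=2)
        assert any(x != y for x, y in zip(a, b))

    def test_demographics_match_reference_moments(self):
        cohort = sample_cohort(17, seed=12345)
        ages = np.array([t.subject.age for t in cohort])
        # sample mean within 2 standard errors of the target 23.5 y
        assert abs(ages.mean() - 23.5) < 2 * 2.0 / np.sqrt(17)

    def test_point_mass_ranges_give_identical_subjects(self):
        r = CohortRanges(age_sd=0.0, bmi_sd=0.0, height_sd_m=0.0,
                         rhr_range=(60.0, 60.0), k_hr_range=(0.4, 0.4),
                         tau_hr_range=(40.0, 40.0), x0_hr_range=(70.0, 70.0),
                         k_vo2_range=(0.01, 0.01),
                         tau_vo2_range=(35.0, 35.0),
                         x0_vo2_range=(0.35, 0.35), hrmax_offset_sd=0.0)
        cohort = sample_cohort(4, seed=0, ranges=r)
        first = cohort[0]
        for t in cohort[1:]:
            assert t.hr_params == first.hr_params
            assert t.subject.age == first.subject.age
            assert t.true_hrmax == pytest.approx(first.true_hrmax)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            CohortRanges(k_hr_range=(0.6, 0.3))

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            sample_cohort(0, seed=1)

    def test_truth_json_round_trip(self):
        truth = sample_cohort(1, seed=4)[0]
        back = SyntheticSubjectTruth.from_dict(truth.to_dict())
        assert back == truth


class TestGenerateTest:
    def test_noise_free_maximal_peaks_at_true_hrmax(self, noisefree_truth):
        hr, vo2, prot = generate_test(noisefree_truth, mode="maximal", seed=0)
        peak = float(hr.values.max())
        # grid-step effect: one second may overshoot by one model increment
        assert peak >= noisefree_truth.true_hrmax - 0.5
        assert peak <= noisefree_truth.true_hrmax + 2.0

    def test_noise_free_vo2_at_ramp_end_is_true_vo2max(self, noisefree_truth):
        hr, vo2, prot = generate_test(noisefree_truth, mode="maximal", seed=0)
        ramp_end = prot.ramp_segment().end_s
        vo2_end = vo2.values[vo2.times <= ramp_end][-1]
        assert vo2_end == pytest.approx(noisefree_truth.true_vo2max,
                                        rel=0.005)

    def test_truth_rederivable_from_params(self, noisefree_truth):
        again = true_vo2max_for(noisefree_truth.hr_params,
                                noisefree_truth.vo2_params,
                                noisefree_truth.true_hrmax)
        assert again == pytest.approx(noisefree_truth.true_vo2max)

    def test_submaximal_cut_at_80_percent_whyte(self, noisefree_truth):
        hr, vo2, prot = generate_test(noisefree_truth, mode="submaximal_80",
                                      seed=0)
        target = 0.8 * whyte_hrmax(noisefree_truth.subject)
        ramp_hr = hr.values[hr.phases == "ramp"]
        assert ramp_hr.max() == pytest.approx(target, abs=2.0)

    def test_submaximal_is_prefix_of_maximal(self):
        truth = sample_cohort(1, seed=77)[0]
        hr_max, vo2_max, prot_max = generate_test(truth, mode="maximal",
                                                  seed=5)
        hr_sub, vo2_sub, prot_sub = generate_test(truth,
                                                  mode="submaximal_80",
                                                  seed=5)
        cut = prot_sub.ramp_segment().end_s
        m = hr_sub.times < cut
        np.testing.assert_array_equal(hr_sub.values[m],
                                      hr_max.values[:int(m.sum())])
        mv = vo2_sub.times < cut
        np.testing.assert_array_equal(vo2_sub.values[mv],
                                      vo2_max.values[:int(mv.sum())])

    def test_noise_scaling_increases_estimator_error(self, submax_protocol):
        """Estimator RMSE grows with the generator's noise level."""
        from smo.estimation import KineticsModel
        from smo.preprocessing import moving_average
        errs_by_sd = []
        for sd in (0.0, 6.0):
            errs = []
            for rep in range(5):
                r = CohortRanges(noise_sd_hr=sd, hrmax_offset_sd=0.0)
                truth = sample_cohort(1, seed=300 + rep, ranges=r)[0]
                hr, vo2, prot = generate_test(truth, mode="submaximal_80",
                                              seed=rep)
                res = KineticsModel(moving_average(hr, 15), prot,
                                    excitation_smooth_window=15).fit(
                    "derivative_regression")
                if res.converged:
                    errs.append(abs(res.params.tau - truth.hr_params.tau))
            errs_by_sd.append(np.median(errs))
        assert errs_by_sd[0] < errs_by_sd[1]

    def test_unknown_mode_rejected(self, noisefree_truth):
        with pytest.raises(ValueError):
            generate_test(noisefree_truth, mode="sprint", seed=0)

    def test_irregular_sampling_flag(self, noisefree_truth):
        hr, vo2, prot = generate_test(noisefree_truth, mode="submaximal_80",
                                      seed=3, irregular_sampling=True)
        dt = np.diff(hr.times)
        assert np.any(np.abs(dt - 1.0) > 1e-9)
        assert np.all(dt > 0)
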