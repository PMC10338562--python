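import numpy as np
import pytest

from smo.preprocessing import moving_average
from smo.synthetic import CohortRanges, generate_test, sample_cohort
from smo.truncation import (MaximalRecording, NotAttainedError,
                            TruncationStudyResult, recommend_termination,
                            run_truncation_study, truncate_at_fraction)


@pytest.fixture(scope="module")
def maximal_recordings():
    """Three noise-free synthetic maximal tests with ground truth."""
    ranges = CohortRanges(noise_sd_hr=0.0, noise_sd_vo2=0.0)
    cohort = sample_cohort(3, seed=5, ranges=ranges)
    recs = []
    for i, truth in enumerate(cohort):
        hr, vo2, prot = generate_test(truth, mode="maximal", seed=i)
        recs.append(MaximalRecording(
            subject=truth.subject, hr_series=moving_average(hr, 15),
            vo2_series=moving_average(vo2, 15), protocol=prot,
            hrmax_measured=truth.true_hrmax,
            vo2max_reference=truth.true_vo2max))
    return recs


class TestTruncateAtFraction:
    def test_splice_is_continuous_and_conservative(self, maximal_recordings):
        rec = maximal_recordings[0]
        tp = truncate_at_fraction(rec.hr_series, rec.vo2_series, rec.protocol,
                                  rec.hrmax_measured, 0.85)
        for spliced, original in ((tp.hr_series, rec.hr_series),
                                  (tp.vo2_series, rec.vo2_series)):
            # every spliced value exists in the original recording
            assert np.all(np.isin(spliced.values, original.values))
            # continuity at the cut within one sample's step
            i_cut = int(np.argmax(spliced.times == tp.t_cut))
            jump = abs(spliced.values[i_cut + 1] - spliced.values[i_cut])
            step = np.max(np.abs(np.diff(original.values)))
            assert jump <= max(3 * step, 0.05 * np.ptp(original.values))
        assert np.all(np.diff(tp.hr_series.times) > 0)

    def test_cut_time_monotone_in_fraction(self, maximal_recordings):
        rec = maximal_recordings[0]
        cuts = [truncate_at_fraction(rec.hr_series, rec.vo2_series,
                                     rec.protocol, rec.hrmax_measured,
                                     f).t_cut
                for f in (0.71, 0.80, 0.95)]
        assert cuts[0] < cuts[1] < cuts[2]

    def test_cut_lies_in_ramp(self, maximal_recordings):
        rec = maximal_recordings[0]
        tp = truncate_at_fraction(rec.hr_series, rec.vo2_series, rec.protocol,
                                  rec.hrmax_measured, 0.80)
        ramp = rec.protocol.ramp_segment()
        assert ramp.start_s < tp.t_cut < ramp.end_s

    def test_fraction_crossed_before_ramp_rejected(self, maximal_recordings):
        rec = maximal_recordings[0]
        warm_hr = float(np.max(
            rec.hr_series.values[rec.hr_series.phases == "warmup"]))
        frac = (warm_hr - 1.0) / rec.hrmax_measured
        with pytest.raises(NotAttainedError):
            truncate_at_fraction(rec.hr_series, rec.vo2_series, rec.protocol,
                                 rec.hrmax_measured, frac)

    def test_unattained_fraction_rejected(self, maximal_recordings):
        rec = maximal_recordings[0]
        with pytest.raises(NotAttainedError):
            truncate_at_fraction(rec.hr_series, rec.vo2_series, rec.protocol,
                                 rec.hrmax_measured * 2.0, 0.95)


class TestRunTruncationStudy:
    def test_noise_free_errors_near_zero_at_every_fraction(
            self, maximal_recordings):
        """With model-generated noise-free data, predicted VO2max is nearly
        fraction-independent: the study's error is attributable to noise,
        not to the truncation machinery."""
        res = run_truncation_study(maximal_recordings,
                                   fractions=[0.72, 0.80, 0.88, 0.95])
        assert res.n_failed == 0
        assert np.all(res.mean_delta < 0.75)
        assert np.ptp(res.mean_delta) < 0.5

    def test_single_fraction_degenerate(self, maximal_recordings):
        res = run_truncation_study(maximal_recordings, fractions=[0.80])
        assert res.mean_delta.size == 1
        assert np.isnan(res.slope)

    def test_whyte_mode_runs(self, maximal_recordings):
        res = run_truncation_study(maximal_recordings, hrmax_source="whyte",
                                   fractions=[0.75, 0.85])
        assert res.hrmax_source == "whyte"
        assert np.all(np.isfinite(res.mean_delta))

    def test_plot_smoke(self, maximal_recordings):
        import matplotlib
        matplotlib.use("Agg")
        res = run_truncation_study(maximal_recordings,
                                   fractions=[0.75, 0.85, 0.95])
        ax = res.plot()
        assert ax.get_xlabel()
        import matplotlib.pyplot as plt
        plt.close(ax.figure)

    def test_result_round_trip_and_summary(self, maximal_recordings):
        res = run_truncation_study(maximal_recordings,
                                   fractions=[0.75, 0.85, 0.95])
        d = res.to_dict()
        assert len(d["mean_delta_pct"]) == 3
        assert "recommended termination" in res.summary()
        frame = res.to_frame()
        assert list(frame.columns) == ["fraction", "mean_delta_pct",
                                       "sd_delta_pct"]


class TestRecommendTermination:
    def _result(self, fractions, deltas):
        n = len(fractions)
        return TruncationStudyResult(
            fractions=np.asarray(fractions), mean_delta=np.asarray(deltas),
            sd_delta=np.zeros(n), per_subject=None, slope=0.0, intercept=0.0,
            r_squared=0.0, pearson_rho=0.0, pearson_p=1.0, spearman_rho=0.0,
            spearman_p=1.0, hrmax_source="measured", n_failed=0)

    def test_all_below_threshold_gives_smallest(self):
        res = self._result([0.71, 0.80, 0.90], [1.0, 0.5, 0.2])
        assert recommend_termination(res, 5.0) == 0.71

    def test_decreasing_curve_crossing_threshold(self):
        fractions = [0.71, 0.75, 0.80, 0.85, 0.90]
        deltas = [9.0, 7.0, 4.9, 3.0, 2.0]
        assert recommend_termination(self._result(fractions, deltas),
                                     5.0) == 0.80

    def test_nothing_qualifies_warns_and_returns_largest(self):
        res = self._result([0.71, 0.80], [3.0, 2.0])
        with pytest.warns(UserWarning):
            out = recommend_termination(res, 0.0)
        assert out == 0.80
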