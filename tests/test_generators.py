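"""Sampling distributions, arrival processes, and calibration."""

import numpy as np
import pytest

from ctqsim import (
    EP_EXAM_DURATIONS,
    GP_EXAM_DURATIONS,
    ArrivalProfile,
    CalibrationError,
    PatientClass,
    ServiceDistribution,
    calibrate,
    default_profile,
    sample_day,
    sample_ep_arrivals,
    sample_gp_arrivals,
    substream,
)
from ctqsim.generators import _pilot_means


class TestServiceDistribution:
    def test_builtin_means(self):
        # expectations of the printed frequency columns
        assert GP_EXAM_DURATIONS.mean == pytest.approx(2.26, abs=1e-9)
        assert EP_EXAM_DURATIONS.mean == pytest.approx(3.195, abs=1e-9)

    def test_builtin_cdfs(self):
        assert GP_EXAM_DURATIONS.cdf(3) == pytest.approx(0.939)
        assert EP_EXAM_DURATIONS.cdf(4) == pytest.approx(0.840)
        assert GP_EXAM_DURATIONS.cdf(4) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "support, probs",
        [
            ((1, 2), (0.5, 0.6)),  # does not sum to 1
            ((2, 1), (0.5, 0.5)),  # not increasing
            ((0, 1), (0.5, 0.5)),  # nonpositive duration
            ((1, 2), (-0.1, 1.1)),  # negative probability
            ((), ()),
        ],
    )
    def test_rejects_invalid(self, support, probs):
        with pytest.raises(ValueError):
            ServiceDistribution(support, probs)

    def test_degenerate_always_returns_support(self):
        d = ServiceDistribution((2,), (1.0,))
        rng = np.random.default_rng(0)
        assert all(d.sample(rng) == 2 for _ in range(50))

    def test_sampling_matches_cumulative_frequencies(self):
        # every printed cumulative frequency, within 3 SE at n = 100,000
        rng = np.random.default_rng(12345)
        n = 100_000
        for dist in (GP_EXAM_DURATIONS, EP_EXAM_DURATIONS):
            draws = dist.sample(rng, size=n)
            for s in dist.support:
                p = dist.cdf(s)
                se = np.sqrt(max(p * (1 - p), 1e-12) / n)
                assert abs(np.mean(draws <= s) - p) <= 3 * se + 1e-12

    def test_round_trip(self):
        d = ServiceDistribution.from_dict(EP_EXAM_DURATIONS.to_dict())
        assert d == EP_EXAM_DURATIONS


class TestArrivalProfile:
    def test_default_profile_shape(self):
        prof = default_profile()
        assert prof.gp_rates[0][0] == 0.0 and prof.horizon == 780.0
        assert all(r >= 0 for _, _, r in prof.gp_rates)
        assert prof.expected_gp_count == pytest.approx(162.0)
        assert prof.ep_mean_interarrival == 7.0
        assert prof.urgent_fraction == 0.7

    @pytest.mark.parametrize(
        "rates",
        [
            (),
            ((0.0, 60.0, 0.1), (61.0, 120.0, 0.1)),  # gap
            ((0.0, 60.0, -0.1),),  # negative rate
            ((10.0, 60.0, 0.1),),  # does not start at 0
        ],
    )
    def test_rejects_invalid(self, rates):
        with pytest.raises(ValueError):
            ArrivalProfile(gp_rates=rates)

    def test_scaled_and_round_trip(self):
        prof = default_profile().scaled(0.5)
        assert prof.expected_gp_count == pytest.approx(81.0)
        assert ArrivalProfile.from_dict(prof.to_dict()) == prof


class TestGPArrivals:
    def test_zero_rates_give_empty_stream(self):
        prof = ArrivalProfile(gp_rates=((0.0, 780.0, 0.0),))
        assert sample_gp_arrivals(prof, 780.0, np.random.default_rng(0)) == []

    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            sample_gp_arrivals(default_profile(), 0, np.random.default_rng(0))

    def test_constant_rate_poisson_mean(self):
        # rate 0.2/min over 780 min: mean count 156, 10,000 days, 3 SE
        prof = ArrivalProfile(gp_rates=((0.0, 780.0, 0.2),))
        rng = np.random.default_rng(42)
        counts = [len(sample_gp_arrivals(prof, 780.0, rng)) for _ in range(10_000)]
        se = np.sqrt(156.0 / 10_000)
        assert abs(np.mean(counts) - 156.0) <= 3 * se
        assert all(0 <= t < 780.0 for t in sample_gp_arrivals(prof, 780.0, rng))

    def test_piecewise_interval_counts(self):
        # independent increments: per-interval counts match their own means
        prof = ArrivalProfile(gp_rates=((0.0, 300.0, 0.4), (300.0, 780.0, 0.1)))
        rng = np.random.default_rng(7)
        n_days = 4000
        c1 = c2 = 0
        for _ in range(n_days):
            times = np.asarray(sample_gp_arrivals(prof, 780.0, rng))
            c1 += int((times < 300).sum())
            c2 += int((times >= 300).sum())
        for total, mean in ((c1, 120.0), (c2, 48.0)):
            se = np.sqrt(mean / n_days)
            assert abs(total / n_days - mean) <= 3 * se

    def test_sorted_output(self):
        times = sample_gp_arrivals(default_profile(), 780.0, np.random.default_rng(3))
        assert times == sorted(times)


class TestEPArrivals:
    def test_count_mean_and_exponential_moments(self):
        prof = default_profile()  # mean interarrival 7 min
        rng = np.random.default_rng(11)
        counts, gaps = [], []
        for _ in range(10_000):
            arr = sample_ep_arrivals(prof, 780.0, rng)
            counts.append(len(arr))
            t = [a for a, _ in arr]
            gaps.extend(np.diff(t))
        mean_count = 780.0 / 7.0
        assert abs(np.mean(counts) - mean_count) <= 3 * np.sqrt(mean_count / 10_000)
        # exponential signature: sd ~ mean (variance ~ mean^2)
        assert np.std(gaps) == pytest.approx(np.mean(gaps), rel=0.05)

    def test_urgent_fraction(self):
        rng = np.random.default_rng(2)
        labels = []
        for _ in range(300):
            labels.extend(c for _, c in sample_ep_arrivals(default_profile(), 780.0, rng))
        share = np.mean([c is PatientClass.UP for c in labels])
        se = np.sqrt(0.7 * 0.3 / len(labels))
        assert abs(share - 0.7) <= 3 * se

    def test_zero_urgent_fraction_all_ep(self):
        prof = ArrivalProfile(gp_rates=((0.0, 780.0, 0.0),), urgent_fraction=0.0)
        arr = sample_ep_arrivals(prof, 780.0, np.random.default_rng(1))
        assert arr and all(c is PatientClass.EP for _, c in arr)


class TestSampleDay:
    def test_stream_is_sorted_with_sequential_ids(self):
        stream = sample_day(
            default_profile(), 780.0, GP_EXAM_DURATIONS, EP_EXAM_DURATIONS, 9, 0
        )
        assert [p.id for p in stream] == list(range(len(stream)))
        arr = [p.arrival for p in stream]
        assert arr == sorted(arr)
        assert {p.cls for p in stream} == set(PatientClass)

    def test_substreams_reproducible_and_distinct(self):
        a = substream(1, 2, "gp_arrivals").random(4)
        b = substream(1, 2, "gp_arrivals").random(4)
        c = substream(1, 3, "gp_arrivals").random(4)
        assert np.array_equal(a, b) and not np.array_equal(a, c)


class TestCalibration:
    def test_load_monotonicity(self):
        # doubling the GP rates strictly increases the pilot GP wait
        prof = default_profile()
        w1, _ = _pilot_means(prof.scaled(0.6), n_pilot=20, seed=3)
        w2, _ = _pilot_means(prof.scaled(1.2), n_pilot=20, seed=3)
        assert w2 > w1

    def test_zero_wait_target_infeasible(self):
        with pytest.raises(CalibrationError):
            calibrate(default_profile(), target_gp_wait=0.0)
        with pytest.raises(CalibrationError):
            calibrate(default_profile(), target_gp_wait=1.0, n_pilot=20, seed=3)

    def test_calibration_hits_targets_and_is_deterministic(self, calibration):
        res = calibration
        assert abs(res.achieved_gp_wait - 66.8) <= 0.10 * 66.8
        assert abs(res.achieved_daily_quantity - 245.0) <= 0.05 * 245.0
        assert 7.0 <= res.profile.ep_mean_interarrival <= 9.3
        rerun = calibrate(default_profile(), seed=1)
        assert rerun.profile == res.profile and rerun.scale == res.scale

    def test_calibration_idempotent_within_tolerance(self, calibration):
        again = calibrate(calibration.profile, seed=1)
        assert abs(again.scale - 1.0) < 0.05
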