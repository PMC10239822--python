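"""Metric tests on synthetic fixtures with known ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pumpneuron.electrophys_metrics import (
    ResponseClass,
    SpikeTrain,
    adaptation_slope,
    ahp_metrics,
    burst_segmentation,
    classify_step_response,
    detect_spikes,
    ifr_series,
    make_ahp_trace,
    make_burst_train,
    make_constant_rate_train,
    make_linear_ifr_train,
    make_spiking_trace,
    time_to_first_spike,
)


class TestDetectSpikes:
    def test_counts_constructed_crossings(self):
        train = make_constant_rate_train(20.0, 7, t0=20.0)
        trace = make_spiking_trace(train)
        assert len(detect_spikes(trace)) == 7

    def test_subthreshold_sinusoid_has_no_spikes(self):
        t = np.arange(0.0, 1000.0, 0.1)
        trace = type("T", (), {"t": t, "V": -60.0 + 15.0 * np.sin(t / 50.0)})()
        assert len(detect_spikes(trace)) == 0  # peaks at -45 mV

    def test_interpolated_crossing_times(self):
        train = make_constant_rate_train(10.0, 5, t0=10.0)
        trace = make_spiking_trace(train, dt=0.05)
        detected = detect_spikes(trace).spike_times
        # crossing occurs on the rising flank within the spike half-width
        assert np.all(np.abs(detected - train.spike_times) < 0.5)

    def test_refractory_merging(self):
        t = np.arange(0.0, 10.0, 0.01)
        V = np.full_like(t, -60.0)
        V[(t > 2) & (t < 2.4)] = 0.0
        V[(t > 2.8) & (t < 3.2)] = 0.0  # second crossing 0.8 ms later
        trace = type("T", (), {"t": t, "V": V})()
        assert len(detect_spikes(trace, refractory=2.0)) == 1

    def test_count_stable_under_grid_refinement(self):
        train = make_constant_rate_train(50.0, 30)
        for dt in (0.05, 0.01):
            trace = make_spiking_trace(train, dt=dt)
            assert len(detect_spikes(trace)) == 30


class TestIFRSeries:
    def test_length_and_values(self):
        train = make_constant_rate_train(25.0, 10)
        ifr = ifr_series(train)
        assert len(ifr) == 9
        assert np.allclose(ifr.ifr, 25.0)
        # timestamped at the later spike of each interval
        assert np.allclose(ifr.t, train.spike_times[1:])

    def test_short_trains_give_empty_series(self):
        assert len(ifr_series(SpikeTrain(np.array([5.0])))) == 0


class TestAdaptationSlope:
    def test_constant_rate_gives_zero(self):
        ifr = ifr_series(make_constant_rate_train(20.0, 30))
        assert adaptation_slope(ifr) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("slope", [-1.0, -5.0, 2.0])
    def test_linear_ifr_train_roundtrips_slope(self, slope):
        train = make_linear_ifr_train(40.0, slope, 60)
        measured = adaptation_slope(ifr_series(train))
        assert measured == pytest.approx(slope, rel=0.01)

    def test_undefined_below_19_intervals(self):
        ifr = ifr_series(make_constant_rate_train(20.0, 19))  # 18 IFR values
        assert adaptation_slope(ifr) is None

    def test_translation_invariance(self):
        train = make_linear_ifr_train(40.0, -2.0, 40)
        a = adaptation_slope(ifr_series(train))
        b = adaptation_slope(ifr_series(train.shifted(12345.6)))
        assert a == pytest.approx(b, rel=1e-12)

    def test_ignores_final_interval(self):
        """The last IFR value (possibly truncated mid-spike) must not
        contribute."""
        train = make_constant_rate_train(20.0, 40)
        st_times = train.spike_times.copy()
        st_times[-1] = st_times[-2] + 1.0  # absurd final ISI
        slope = adaptation_slope(ifr_series(SpikeTrain(st_times)))
        assert slope == pytest.approx(0.0, abs=1e-9)


class TestAHPMetrics:
    def test_fixture_roundtrip(self):
        trace = make_ahp_trace(baseline=-60.0, trough=-63.9, injection_end=5000.0)
        amp, t_half = ahp_metrics(trace, 5000.0, -60.0)
        assert amp == pytest.approx(-3.9, abs=1e-9)
        expected_thalf = (500.0 + 3000.0 * np.log(2.0)) / 1000.0
        assert t_half == pytest.approx(expected_thalf, rel=1e-3)

    def test_offset_invariance(self):
        trace = make_ahp_trace(-60.0, -64.0, 5000.0)
        a1, th1 = ahp_metrics(trace, 5000.0, -60.0)
        trace.V = trace.V + 7.5
        a2, th2 = ahp_metrics(trace, 5000.0, -52.5)
        assert a1 == pytest.approx(a2, rel=1e-12)
        assert th1 == pytest.approx(th2, rel=1e-9)

    def test_no_ahp_reported_for_flat_trace(self):
        trace = make_ahp_trace(-60.0, -60.0, 5000.0)
        amp, t_half = ahp_metrics(trace, 5000.0, -60.0)
        assert amp is None and t_half is None

    def test_unrecovered_trough_has_undefined_half_duration(self):
        trace = make_ahp_trace(-60.0, -64.0, 5000.0, trough_delay=500.0,
                               tau_decay=1e9, duration=20_000.0)
        amp, t_half = ahp_metrics(trace, 5000.0, -60.0)
        assert amp == pytest.approx(-4.0, abs=1e-6)
        assert t_half is None


class TestClassification:
    def test_no_spikes_is_subthreshold(self):
        t = np.arange(0.0, 6000.0, 1.0)
        trace = type("T", (), {"t": t, "V": np.full_like(t, -58.0)})()
        cls = classify_step_response(SpikeTrain(np.empty(0)), trace, 500.0, 5500.0)
        assert cls == ResponseClass.SUBTHRESHOLD

    def test_spiking_to_the_end_is_sustained(self):
        train = make_constant_rate_train(20.0, 100, t0=500.0)  # spans 5 s
        trace = make_spiking_trace(train, duration=6000.0)
        cls = classify_step_response(train, trace, 500.0, 5500.0)
        assert cls == ResponseClass.SUSTAINED

    def test_early_stop_is_premature_termination(self):
        train = make_constant_rate_train(20.0, 40, t0=500.0)  # stops at 2.45 s
        trace = make_spiking_trace(train, duration=6000.0)
        cls = classify_step_response(train, trace, 500.0, 5500.0)
        assert cls == ResponseClass.PREMATURE_TERMINATION

    def test_sustained_depolarization_without_spikes_is_block(self):
        t = np.arange(0.0, 6000.0, 1.0)
        V = np.full_like(t, -58.0)
        V[(t > 1000.0) & (t < 5500.0)] = -20.0
        V[np.abs(t - 1000.0) < 2] = 0.0  # a single initial spike
        trace = type("T", (), {"t": t, "V": V})()
        train = detect_spikes(trace)
        cls = classify_step_response(train, trace, 500.0, 5500.0)
        assert cls == ResponseClass.DEPOLARIZATION_BLOCK


class TestBurstSegmentation:
    def test_fixture_roundtrip(self):
        # 5 spikes at 100 ms ISI repeated every 2 s
        train = make_burst_train(20, 5, 100.0, 2000.0)
        bm = burst_segmentation(train, record_end=train.spike_times[-1] + 1600.0)
        assert bm is not None
        assert bm.period == pytest.approx(2.0, rel=1e-9)
        assert bm.burst_duration == pytest.approx(0.4, rel=1e-9)
        assert bm.duty_cycle == pytest.approx(0.2, rel=1e-9)

    def test_duty_cycle_consistency(self):
        train = make_burst_train(12, 8, 50.0, 3000.0)
        bm = burst_segmentation(train, record_end=40_000.0)
        assert bm.duty_cycle == pytest.approx(bm.burst_duration / bm.period, rel=1e-12)

    def test_tonic_train_is_not_bursting(self):
        assert burst_segmentation(make_constant_rate_train(20.0, 200)) is None

    def test_too_few_cycles_is_not_bursting(self):
        train = make_burst_train(2, 5, 100.0, 2000.0)
        assert burst_segmentation(train) is None


class TestTimeToFirstSpike:
    def test_simple_latency(self):
        train = SpikeTrain(np.array([512.0, 600.0]))
        assert time_to_first_spike(train, 500.0) == pytest.approx(12.0)

    def test_no_spike_after_onset(self):
        train = SpikeTrain(np.array([100.0]))
        assert time_to_first_spike(train, 500.0) is None


@given(st.floats(-4.0, -0.5), st.integers(200, 900))
@settings(max_examples=20, derandomize=True, deadline=None)
def test_ahp_fixture_roundtrip_property(amp, delay):
    # integer trough delays keep the trough on the 1 ms sampling grid
    trace = make_ahp_trace(-60.0, -60.0 + amp, 3000.0, trough_delay=float(delay),
                           duration=30_000.0)
    measured, _ = ahp_metrics(trace, 3000.0, -60.0)
    assert measured == pytest.approx(amp, abs=1e-9)
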