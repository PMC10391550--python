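"""Event detection, classification, and per-cell metrics on constructed traces."""

import math

import numpy as np
import pytest

from corticotroph.events import (ABClass, Event, EventTable, Trace,
                                 burst_factor, classify_cell_ab,
                                 classify_event, count_spikelets,
                                 detect_events, estimate_baseline,
                                 first_consecutive_spike_run,
                                 membrane_potential, spike_shape,
                                 summarize_cell)
from conftest import BASELINE, FS, add_triangle, make_flat_trace


class TestBaseline:
    def test_flat_trace(self, flat_trace):
        assert estimate_baseline(flat_trace) == BASELINE

    def test_robust_to_spike_contamination(self):
        tr = make_flat_trace(2.0)
        n = tr.v_mv.size
        tr.v_mv[: n // 20] = -20.0  # 5% of samples sit at spike level
        assert estimate_baseline(tr) == pytest.approx(BASELINE, abs=0.1)

    def test_pure_noise(self):
        rng = np.random.default_rng(0)
        tr = Trace(v_mv=-50.0 + rng.normal(0, 1.0, 20_000), fs_hz=FS)
        assert estimate_baseline(tr) == pytest.approx(-50.0, abs=0.3)


class TestDetect:
    def test_flat_trace_no_events(self, flat_trace):
        assert len(detect_events(flat_trace)) == 0

    def test_single_triangle(self, triangle_trace):
        table = detect_events(triangle_trace, baseline_mv=BASELINE)
        assert len(table) == 1
        ev = table.events[0]
        # the triangle spends (31-20)/31 and (31-5)/31 of each flank between
        # the threshold and re-arm levels
        up = 20.0 / 31.0 * 20.0
        down = 5.0 / 31.0 * 20.0
        expected_ms = 40.0 - up - down
        assert ev.duration_ms == pytest.approx(expected_ms, abs=1.0)
        assert ev.klass == "spike"

    def test_subthreshold_excursion_ignored(self):
        tr = make_flat_trace(3.0)
        add_triangle(tr.v_mv, FS, 1.0, 40.0, 15.0)  # peaks below delta 20
        assert len(detect_events(tr, baseline_mv=BASELINE)) == 0

    def test_threshold_monotonicity(self):
        tr = make_flat_trace(5.0)
        rng = np.random.default_rng(1)
        for t0, amp in zip((0.5, 1.5, 2.5, 3.5), (22.0, 28.0, 35.0, 50.0)):
            add_triangle(tr.v_mv, FS, t0, 30.0, amp)
        tr.v_mv += rng.normal(0, 0.5, tr.v_mv.size)
        counts = [len(detect_events(tr, delta_threshold_mv=thr,
                                    baseline_mv=BASELINE))
                  for thr in (10.0, 20.0, 30.0, 45.0)]
        assert counts == sorted(counts, reverse=True)

    def test_determinism(self, triangle_trace):
        t1 = detect_events(triangle_trace).to_dataframe()
        t2 = detect_events(triangle_trace).to_dataframe()
        assert t1.equals(t2)

    def test_partition_of_classes(self):
        from corticotroph.synthgen import TraceSpec, make_trace
        lt = make_trace(TraceSpec(duration_s=40, event_rate_hz=1.0,
                                  burst_fraction=0.4, min_bursts=1, seed=5))
        table = detect_events(lt.trace)
        n = sum(len(table.of_class(k)) for k in ("spike", "burst", "other"))
        assert n == len(table)

    def test_rejects_bad_thresholds(self, flat_trace):
        with pytest.raises(ValueError):
            detect_events(flat_trace, delta_threshold_mv=5, delta_rearm_mv=20)


class TestSpikelets:
    @staticmethod
    def _plateau_trace(bump_mv):
        tr = make_flat_trace(2.0)
        i0 = int(1.0 * FS)
        n = int(0.150 * FS)
        tr.v_mv[i0:i0 + n] += 22.0
        t = np.arange(n) / FS * 1000.0
        for c in (30.0, 75.0, 120.0):
            tr.v_mv[i0:i0 + n] += bump_mv * np.exp(-0.5 * ((t - c) / 3.0) ** 2)
        return tr, i0, i0 + n

    def test_three_prominent_peaks(self):
        tr, i0, i1 = self._plateau_trace(10.0)
        assert count_spikelets(tr, i0, i1, BASELINE) == 3

    def test_small_ripples_ignored(self):
        tr, i0, i1 = self._plateau_trace(1.0)
        assert count_spikelets(tr, i0, i1, BASELINE) == 1

    def test_single_smooth_spike(self, triangle_trace):
        table = detect_events(triangle_trace, baseline_mv=BASELINE)
        assert table.events[0].n_spikelets == 1


class TestClassifyEvent:
    @pytest.mark.parametrize("duration_ms,n_spikelets,expected", [
        (50.0, 1, "spike"),
        (150.0, 3, "burst"),
        (150.0, 1, "other"),
        (100.0, 5, "spike"),   # boundary duration counts as a spike
        (100.1, 2, "burst"),
    ])
    def test_rules(self, duration_ms, n_spikelets, expected):
        ev = Event(start_s=1.0, end_s=1.0 + duration_ms / 1000.0,
                   peak_v_mv=-20.0, amplitude_mv=31.0,
                   n_spikelets=n_spikelets)
        assert classify_event(ev) == expected


class TestSpikeShape:
    def test_triangle_width_and_peak(self, triangle_trace):
        table = detect_events(triangle_trace, baseline_mv=BASELINE)
        shape = spike_shape(triangle_trace, table.events[0], BASELINE)
        assert shape.width_ms == pytest.approx(20.0, abs=1.0)
        assert shape.peak_amplitude_mv == pytest.approx(31.0, abs=0.5)
        assert shape.ahp_amplitude_mv == 0.0  # no dip below baseline

    def test_ahp_depth(self):
        tr = make_flat_trace(3.0)
        add_triangle(tr.v_mv, FS, 1.0, 30.0, 31.0)
        i0 = int(1.05 * FS)
        tr.v_mv[i0:i0 + int(0.05 * FS)] -= 28.0  # post-spike dip to -79
        table = detect_events(tr, baseline_mv=BASELINE)
        shape = spike_shape(tr, table.events[0], BASELINE)
        assert shape.ahp_amplitude_mv == pytest.approx(28.0, abs=0.5)

    def test_truncated_ahp_window_flagged(self):
        tr = make_flat_trace(1.0)
        add_triangle(tr.v_mv, FS, 0.93, 40.0, 31.0)
        table = detect_events(tr, baseline_mv=BASELINE)
        shape = spike_shape(tr, table.events[0], BASELINE)
        assert math.isnan(shape.ahp_amplitude_mv)


class TestCellClassification:
    @staticmethod
    def _shapes(ahps):
        from corticotroph.events import SpikeShape
        return [SpikeShape(width_ms=10, time_to_peak_ms=3,
                           ahp_amplitude_mv=a, peak_amplitude_mv=30)
                for a in ahps]

    @pytest.mark.parametrize("mean_ahp,label", [
        (30.0, "A"), (15.0, "B"), (22.0, "ambiguous"),
    ])
    def test_band_assignment(self, mean_ahp, label):
        res = classify_cell_ab(self._shapes([mean_ahp] * 10))
        assert res.label == label
        assert res.n_spikes_used == 10

    def test_too_few_spikes(self):
        res = classify_cell_ab(self._shapes([30.0] * 7))
        assert res.label == "none"
        assert res.n_spikes_used == 7

    def test_first_consecutive_run_skips_interrupted(self):
        events = []
        t = 0.0
        for i in range(25):
            klass = "burst" if i in (4, 16) else "spike"
            events.append(Event(start_s=t, end_s=t + 0.01, peak_v_mv=-20,
                                amplitude_mv=31, n_spikelets=1, klass=klass))
            t += 1.0
        table = EventTable(events=events, recording_duration_s=30.0,
                           baseline_mv=BASELINE)
        run = first_consecutive_spike_run(table)
        assert len(run) == 10
        assert run[0].start_s == 5.0  # run starts after the first burst


class TestMembranePotential:
    def test_flat(self):
        assert membrane_potential(make_flat_trace(2.0, -51.4)) == -51.4

    def test_linear_ramp(self):
        n = int(60 * FS)
        tr = Trace(v_mv=np.linspace(-55.0, -45.0, n), fs_hz=FS)
        assert membrane_potential(tr) == pytest.approx(-50.0, abs=0.1)

    def test_median_windows_reject_a_spike(self):
        tr = make_flat_trace(60.0)
        add_triangle(tr.v_mv, FS, 30.0, 40.0, 31.0)  # mid-recording spike
        assert membrane_potential(tr) == pytest.approx(BASELINE, abs=0.2)


class TestSummaries:
    @staticmethod
    def _table(n_spikes, n_bursts, duration_s=60.0):
        events = []
        t = 0.5
        for _ in range(n_spikes):
            events.append(Event(start_s=t, end_s=t + 0.02, peak_v_mv=-20,
                                amplitude_mv=31, n_spikelets=1, klass="spike"))
            t += 1.0
        for _ in range(n_bursts):
            events.append(Event(start_s=t, end_s=t + 0.15, peak_v_mv=-25,
                                amplitude_mv=26, n_spikelets=3, klass="burst"))
            t += 1.0
        return EventTable(events=events, recording_duration_s=duration_s,
                          baseline_mv=BASELINE)

    def test_burst_factor_definition(self):
        assert burst_factor(self._table(2, 2)) == 0.5

    def test_burst_factor_empty_is_missing(self):
        assert math.isnan(burst_factor(self._table(0, 0)))

    def test_frequencies_and_active_time(self):
        tr = make_flat_trace(60.0)
        s = summarize_cell(tr, self._table(30, 10))
        assert s.event_freq_hz == pytest.approx(40 / 60)
        assert s.spike_freq_hz == pytest.approx(0.5)
        assert s.burst_freq_hz == pytest.approx(10 / 60)
        assert s.burst_factor == pytest.approx(0.25)
        assert s.active_time_frac == pytest.approx(
            (30 * 0.02 + 10 * 0.15) / 60.0)
        assert s.spike_duration_ms == pytest.approx(20.0)
        assert s.burst_duration_ms == pytest.approx(150.0)

    def test_empty_table(self):
        tr = make_flat_trace(60.0)
        s = summarize_cell(tr, self._table(0, 0))
        assert s.event_freq_hz == 0.0
        assert math.isnan(s.burst_factor)
        assert s.active_time_frac == 0.0

    def test_rejects_window_longer_than_trace(self):
        tr = make_flat_trace(10.0)
        with pytest.raises(ValueError):
            summarize_cell(tr, self._table(1, 0), analysis_duration_s=60.0)
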