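"""Event detection, segment extraction and the per-event metrics."""

import numpy as np
import pytest

from vocrisk.preprocessing import UniformSeries
from vocrisk.vasoconstriction import (
    DetectorParams,
    Segment,
    VasoEvent,
    detect_events,
    event_metrics,
    extract_segment,
    subject_event_summary,
)


def drop_series(events, n=7200, base=1.0, rate=2.0):
    """Baseline-1 PPGa trace with raised-cosine drops planted directly."""
    t = np.arange(n) / rate
    v = np.full(n, base)
    for onset, dur, depth in events:
        ramp = 10.0
        rel = t - onset
        env = np.zeros(n)
        m1 = (rel >= 0) & (rel < ramp)
        env[m1] = 0.5 * (1 - np.cos(np.pi * rel[m1] / ramp))
        m2 = (rel >= ramp) & (rel < dur - ramp)
        env[m2] = 1.0
        m3 = (rel >= dur - ramp) & (rel < dur)
        env[m3] = 0.5 * (1 + np.cos(np.pi * (rel[m3] - (dur - ramp)) / ramp))
        v -= base * depth / 100.0 * env
    return UniformSeries(values=v, channel="PPGa")


class TestDetectEvents:
    def test_flat_series_has_no_events(self):
        assert detect_events(drop_series([])) == []

    def test_single_planted_drop_detected_with_accurate_onset(self):
        events = detect_events(drop_series([(1000.0, 60.0, 30.0)]))
        assert len(events) == 1
        assert abs(events[0].onset_time - 1000.0) <= 5.0
        assert events[0].duration == pytest.approx(60.0, abs=10.0)

    def test_event_without_flat_baseline_is_missed(self):
        """A second drop 20 s after the first lacks a flat 30-s baseline."""
        series = drop_series([(1000.0, 60.0, 30.0), (1080.0, 60.0, 30.0)])
        events = detect_events(series)
        assert len(events) == 1
        assert abs(events[0].onset_time - 1000.0) <= 5.0

    def test_events_are_ordered_and_non_overlapping(self):
        series = drop_series(
            [(500.0, 60.0, 25.0), (1000.0, 50.0, 20.0), (1500.0, 70.0, 35.0)]
        )
        events = detect_events(series)
        assert len(events) == 3
        for a, b in zip(events, events[1:]):
            assert b.onset_time > a.end_time

    def test_event_inside_masked_interval_never_detected(self):
        series = drop_series([(1000.0, 60.0, 30.0)])
        from vocrisk.preprocessing import mask_artifacts

        masked = mask_artifacts(series, [(990.0, 1080.0)])
        assert detect_events(masked) == []

    def test_shallow_drop_below_threshold_ignored(self):
        series = drop_series([(1000.0, 60.0, 5.0)])  # under the 10% trigger
        assert detect_events(series) == []

    def test_thresholds_are_configurable(self):
        series = drop_series([(1000.0, 60.0, 8.0)])
        params = DetectorParams(d_min=0.05)
        assert len(detect_events(series, params)) == 1


class TestExtractSegment:
    def test_window_geometry(self):
        series = drop_series([(1000.0, 60.0, 30.0)])
        rri = UniformSeries(values=np.full(len(series), 0.8), channel="RRI")
        ev = VasoEvent(onset_time=1000.0, end_time=1060.0)
        seg = extract_segment(series, rri, ev, subject_id="S1")
        assert seg is not None
        assert len(seg.ppga) == 360 and len(seg.rri) == 360
        assert seg.onset_index == 60
        assert len(seg.flatten()) == 720
        # window covers [onset-30, onset+150)
        assert seg.ppga[0] == series.values[int((1000.0 - 30.0) * 2)]

    def test_event_too_close_to_start_is_skipped(self):
        series = drop_series([])
        rri = UniformSeries(values=np.full(len(series), 0.8), channel="RRI")
        ev = VasoEvent(onset_time=10.0, end_time=60.0)
        assert extract_segment(series, rri, ev) is None

    def test_masked_window_is_skipped(self):
        from vocrisk.preprocessing import mask_artifacts

        series = mask_artifacts(drop_series([]), [(1100.0, 1110.0)])
        rri = UniformSeries(values=np.full(len(series), 0.8), channel="RRI")
        ev = VasoEvent(onset_time=1000.0, end_time=1060.0)
        assert extract_segment(series, rri, ev) is None


def rect_segment(depth_pct=30.0, duration=60.0, rri_delta=0.0):
    """Segment with an exactly rectangular drop spanning the event."""
    ppga = np.ones(360)
    rri = np.full(360, 0.8)
    onset, end = 60, 60 + int(duration * 2)
    ppga[onset : end + 1] = 1.0 - depth_pct / 100.0
    rri[onset : end + 1] = 0.8 + rri_delta
    ev = VasoEvent(onset_time=0.0, end_time=duration)
    return Segment(ppga=ppga, rri=rri, onset_index=60, subject_id="S", event=ev)


class TestEventMetrics:
    def test_rectangular_drop_closed_form(self):
        m = event_metrics(rect_segment(30.0, 60.0))
        assert m.M_vasoc == pytest.approx(30.0, abs=1e-12)
        assert m.T_vasoc == pytest.approx(60.0)
        assert m.A_vasoc == m.M_vasoc * m.T_vasoc  # identity by construction

    def test_flat_signal_gives_zero_metrics(self):
        seg = rect_segment(0.0, 60.0)
        m = event_metrics(seg)
        assert m.A_vasoc == 0.0 and m.M_vasoc == 0.0

    def test_constant_rri_gives_zero_areas(self):
        m = event_metrics(rect_segment(30.0, 60.0, rri_delta=0.0))
        assert m.A_RRI_minus == pytest.approx(0.0, abs=1e-9)
        assert m.A_RRI_plus == pytest.approx(0.0, abs=1e-9)

    def test_rri_dip_fills_area_below_baseline(self):
        m = event_metrics(rect_segment(30.0, 60.0, rri_delta=-0.1))
        assert m.A_RRI_minus == pytest.approx(0.1 * 60.0, rel=0.05)
        assert m.A_RRI_plus == 0.0

    def test_excursions_above_ppga_baseline_contribute_zero(self):
        seg = rect_segment(0.0, 60.0)
        ppga = seg.ppga.copy()
        ppga[60:180] = 1.2  # above baseline throughout the event
        seg2 = Segment(ppga=ppga, rri=seg.rri, onset_index=60, subject_id="S",
                       event=seg.event)
        assert event_metrics(seg2).A_vasoc == 0.0


class TestSubjectSummary:
    def test_medians_across_events(self):
        metrics = [event_metrics(rect_segment(d, 60.0)) for d in (10.0, 20.0, 30.0)]
        s = subject_event_summary(metrics)
        assert s.n_vasoc == 3
        assert s.median_M_vasoc == pytest.approx(20.0, abs=1e-9)

    def test_single_event_medians_equal_event(self):
        m = event_metrics(rect_segment(25.0, 40.0))
        s = subject_event_summary([m])
        assert s.median_M_vasoc == pytest.approx(m.M_vasoc)
        assert s.median_A_RRI_minus == pytest.approx(m.A_RRI_minus)

    def test_empty_night_flags_missing(self):
        s = subject_event_summary([])
        assert s.n_vasoc == 0
        assert np.isnan(s.median_M_vasoc)
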