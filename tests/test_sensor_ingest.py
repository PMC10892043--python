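"""Segmentation of raw signal/consumption streams into events."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adlgraph.sensor_ingest import (
    ConsumptionEvent,
    IngestConfig,
    IngestError,
    SignalEvent,
    extract_consumption_events,
    extract_signal_events,
    normalize_events,
    read_readings,
)

from conftest import at, signal_reading, watt_reading


class TestReadReadings:
    def test_csv_door_sensor(self, tmp_path, registry):
        p = tmp_path / "r.csv"
        p.write_text(
            "device_id,timestamp,old_value,new_value,watts\n"
            "d1,2024-03-04T10:00:00Z,0,1,\n"
            "d1,2024-03-04T10:00:30Z,1,0,\n"
            "d1,2024-03-04T10:01:00Z,0,1,\n"
        )
        readings = read_readings(p, registry)
        assert len(readings) == 3
        assert [r.payload.new_value for r in readings] == [1, 0, 1]
        assert readings[0].timestamp == at(0)

    def test_jsonl_wall_plug(self, tmp_path, registry):
        p = tmp_path / "r.jsonl"
        p.write_text(
            '{"device_id": "w1", "timestamp": "2024-03-04T10:00:00Z", "watts": 42.5}\n'
        )
        (r,) = read_readings(p, registry)
        assert r.payload.watts == 42.5

    def test_empty_file_with_header(self, tmp_path, registry):
        p = tmp_path / "r.csv"
        p.write_text("device_id,timestamp,old_value,new_value,watts\n")
        assert read_readings(p, registry) == []

    def test_unknown_device_rejected(self, tmp_path, registry):
        p = tmp_path / "r.csv"
        p.write_text(
            "device_id,timestamp,old_value,new_value,watts\n"
            "ghost,2024-03-04T10:00:00Z,0,1,\n"
        )
        with pytest.raises(IngestError, match="ghost"):
            read_readings(p, registry)

    def test_malformed_timestamp_names_line(self, tmp_path, registry):
        p = tmp_path / "r.csv"
        p.write_text(
            "device_id,timestamp,old_value,new_value,watts\n"
            "d1,2024-03-04T10:00:00Z,0,1,\n"
            "d1,not-a-time,1,0,\n"
        )
        with pytest.raises(IngestError, match=":3"):
            read_readings(p, registry)

    def test_payload_kind_mismatch(self, tmp_path, registry):
        p = tmp_path / "r.csv"
        p.write_text(
            "device_id,timestamp,old_value,new_value,watts\n"
            "d1,2024-03-04T10:00:00Z,,,17.0\n"
        )
        with pytest.raises(IngestError, match="d1"):
            read_readings(p, registry)

    def test_sorted_by_device_then_time(self, tmp_path, registry):
        p = tmp_path / "r.csv"
        p.write_text(
            "device_id,timestamp,old_value,new_value,watts\n"
            "d2,2024-03-04T10:00:00Z,0,1,\n"
            "d1,2024-03-04T10:02:00Z,0,1,\n"
            "d1,2024-03-04T10:01:00Z,1,0,\n"
        )
        readings = read_readings(p, registry)
        assert [(r.device_id, r.timestamp) for r in readings] == sorted(
            (r.device_id, r.timestamp) for r in readings
        )


class TestSignalEvents:
    def test_open_close_pair(self, ingest_config):
        readings = [
            signal_reading("d1", at(0), 0, 1),
            signal_reading("d1", at(30), 1, 0),
        ]
        (ev,) = extract_signal_events(readings, ingest_config)
        assert (ev.start, ev.end, ev.terminated) == (at(0), at(30), True)

    def test_empty(self, ingest_config):
        assert extract_signal_events([], ingest_config) == []

    def test_unterminated_closed_at_stream_end(self, ingest_config):
        readings = [signal_reading("d1", at(0), 0, 1)]
        (ev,) = extract_signal_events(readings, ingest_config, stream_end=at(300))
        assert (ev.start, ev.end, ev.terminated) == (at(0), at(300), False)

    def test_unterminated_dropped_under_drop_policy(self):
        config = IngestConfig(unterminated_policy="drop")
        readings = [signal_reading("d1", at(0), 0, 1)]
        assert extract_signal_events(readings, config, stream_end=at(300)) == []

    def test_repeated_opening_ignored(self, ingest_config):
        readings = [
            signal_reading("d1", at(0), 0, 1),
            signal_reading("d1", at(10), 0, 1),
            signal_reading("d1", at(30), 1, 0),
        ]
        (ev,) = extract_signal_events(readings, ingest_config)
        assert (ev.start, ev.end) == (at(0), at(30))

    def test_noop_transitions_discarded(self, ingest_config):
        readings = [
            signal_reading("d1", at(0), 1, 1),
            signal_reading("d1", at(5), 0, 0),
        ]
        assert extract_signal_events(readings, ingest_config) == []

    def test_unordered_input_rejected(self, ingest_config):
        readings = [
            signal_reading("d1", at(30), 0, 1),
            signal_reading("d1", at(0), 1, 0),
        ]
        with pytest.raises(IngestError, match="time-ordered"):
            extract_signal_events(readings, ingest_config)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 3600), st.integers(0, 1), st.integers(0, 1)), max_size=40))
    def test_events_never_overlap(self, transitions):
        """Per-device events are pairwise non-overlapping and ordered."""
        config = IngestConfig()
        readings = [
            signal_reading("d1", at(t), old, new)
            for t, old, new in sorted(transitions)
        ]
        events = extract_signal_events(readings, config, stream_end=at(4000))
        for a, b in zip(events, events[1:]):
            assert a.end <= b.start
            assert a.start <= b.start


class TestConsumptionEvents:
    def test_excursion_above_threshold(self, ingest_config):
        readings = [
            watt_reading("w1", at(0), 0.8),
            watt_reading("w1", at(60), 42.0),
            watt_reading("w1", at(120), 55.0),
            watt_reading("w1", at(180), 0.9),
        ]
        (ev,) = extract_consumption_events(readings, ingest_config)
        assert (ev.start, ev.end) == (at(60), at(180))
        assert ev.max_watts == 55.0
        assert ev.mean_watts == pytest.approx((42.0 + 55.0) / 2)

    def test_all_idle(self, ingest_config):
        readings = [watt_reading("w1", at(i * 60), 0.0) for i in range(5)]
        assert extract_consumption_events(readings, ingest_config) == []

    @pytest.mark.parametrize(
        "watts,n_events", [(4.9, 0), (5.0, 1), (5.1, 1)]
    )
    def test_threshold_boundary_is_inclusive(self, ingest_config, watts, n_events):
        """At exactly 5 W the appliance counts as in use (idle is < 5 W)."""
        readings = [watt_reading("w1", at(0), watts)]
        assert len(extract_consumption_events(readings, ingest_config)) == n_events

    def test_open_at_stream_end_closes_at_last_reading(self, ingest_config):
        readings = [
            watt_reading("w1", at(0), 900.0),
            watt_reading("w1", at(60), 950.0),
        ]
        (ev,) = extract_consumption_events(readings, ingest_config)
        assert (ev.start, ev.end) == (at(0), at(60))

    def test_segmentation_idempotent_on_boundary_readings(self, ingest_config):
        """Re-extracting from events' boundary readings keeps the intervals."""
        rng = np.random.default_rng(7)
        readings = [
            watt_reading("w1", at(i * 30), float(w))
            for i, w in enumerate(rng.uniform(0, 100, size=60))
        ]
        events = extract_consumption_events(readings, ingest_config)
        rebuilt = []
        for ev in events:
            rebuilt.append(watt_reading("w1", ev.start, ev.max_watts))
            rebuilt.append(watt_reading("w1", ev.end, 0.0))
        again = extract_consumption_events(rebuilt, ingest_config)
        assert [(e.start, e.end) for e in again] == [(e.start, e.end) for e in events]

    def test_raising_threshold_shrinks_in_use_time(self):
        """Total in-use time is monotone non-increasing in the threshold.

        (The *number* of events is not monotone: a higher threshold can
        split one excursion at a dip. The covered duration is.)
        """
        rng = np.random.default_rng(11)
        walk = np.abs(np.cumsum(rng.normal(0, 8, size=80)))
        readings = [
            watt_reading("w1", at(i * 15), float(w)) for i, w in enumerate(walk)
        ]
        totals = [
            sum(
                e.duration_s
                for e in extract_consumption_events(
                    readings, IngestConfig(consumption_threshold_watts=thr)
                )
            )
            for thr in (1.0, 5.0, 10.0, 25.0, 50.0)
        ]
        assert totals == sorted(totals, reverse=True)

    def test_raising_threshold_never_adds_events_on_single_excursion(self):
        """On a unimodal excursion the event count is monotone in the threshold."""
        profile = [0.5, 8.0, 40.0, 900.0, 1200.0, 700.0, 30.0, 6.0, 0.4]
        readings = [watt_reading("w1", at(i * 15), w) for i, w in enumerate(profile)]
        counts = [
            len(
                extract_consumption_events(
                    readings, IngestConfig(consumption_threshold_watts=thr)
                )
            )
            for thr in (1.0, 5.0, 100.0, 1000.0, 5000.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestNormalization:
    def test_implausibly_long_event_truncated(self):
        config = IngestConfig(max_plausible_signal_duration_s=600.0)
        ev = SignalEvent(device_id="d1", start=at(0), end=at(4 * 3600))
        (out,) = normalize_events([ev], config)
        assert (out.end, out.terminated) == (at(600), False)

    def test_short_event_unchanged(self):
        config = IngestConfig(max_plausible_signal_duration_s=600.0)
        ev = SignalEvent(device_id="d1", start=at(0), end=at(30))
        assert normalize_events([ev], config) == [ev]

    def test_consumption_events_pass_through(self):
        config = IngestConfig(max_plausible_signal_duration_s=600.0)
        ev = ConsumptionEvent(
            device_id="w1", start=at(0), end=at(7200), max_watts=900, mean_watts=880
        )
        assert normalize_events([ev], config) == [ev]

    def test_empty(self, ingest_config):
        assert normalize_events([], ingest_config) == []
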