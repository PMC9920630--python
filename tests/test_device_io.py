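"""Raw log dialect, session validation and per-song segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import edaffect as ea
from edaffect.device_io import GAP, NONMONOTONE_TIME, OUT_OF_RANGE, TRUNCATED


class TestRawLogIO:
    def test_parses_timestamp_resistance_records(self, tmp_path):
        p = tmp_path / "log.csv"
        p.write_text("0,1000000\n125,990000\n")
        session = ea.read_raw_log(p)
        assert len(session) == 2
        assert session.resistance_ohm.tolist() == [1000000.0, 990000.0]
        assert session.timestamps_ms.tolist() == [0.0, 125.0]

    def test_header_line_is_skipped(self, tmp_path):
        p = tmp_path / "log.csv"
        p.write_text("timestamp_ms,resistance_ohm\n0,1000000\n125,990000\n250,985000\n")
        assert len(ea.read_raw_log(p)) == 3

    def test_malformed_line_error_names_line_number(self, tmp_path):
        p = tmp_path / "log.csv"
        p.write_text("0,1000000\nbroken-record\n")
        with pytest.raises(ValueError, match="line 2"):
            ea.read_raw_log(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "log.csv"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            ea.read_raw_log(p)

    def test_write_then_read_round_trip(self, tmp_path, constant_session):
        p = tmp_path / "out.csv"
        ea.write_raw_log(constant_session, p)
        # one header + one line per sample
        assert len(p.read_text().strip().splitlines()) == len(constant_session) + 1
        back = ea.read_raw_log(p)
        np.testing.assert_array_equal(back.timestamps_ms, constant_session.timestamps_ms)
        np.testing.assert_array_equal(back.resistance_ohm, constant_session.resistance_ohm)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        resistances=st.lists(
            st.floats(min_value=1e4, max_value=1e7, allow_nan=False).map(lambda r: float(f"{r:.6g}")),
            min_size=1,
            max_size=50,
        )
    )
    def test_round_trip_identity_on_generated_sessions(self, tmp_path_factory, resistances):
        t = np.arange(len(resistances)) * 125.0
        session = ea.RawSession(t, np.array(resistances), session_id="prop")
        p = tmp_path_factory.mktemp("roundtrip") / "log.csv"
        ea.write_raw_log(session, p)
        back = ea.read_raw_log(p)
        np.testing.assert_array_equal(back.timestamps_ms, session.timestamps_ms)
        np.testing.assert_array_equal(back.resistance_ohm, session.resistance_ohm)

    def test_refuses_to_write_empty_session(self, tmp_path):
        empty = ea.RawSession(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            ea.write_raw_log(empty, tmp_path / "x.csv")


def _protocol_3x10():
    """Three quadrant songs of 10 s with 15 s pauses (no relax slot)."""
    return ea.ProtocolSpec(
        songs=(
            (ea.QuadrantLabel.HAPPY, 10.0),
            (ea.QuadrantLabel.SAD, 10.0),
            (ea.QuadrantLabel.AGGRESSIVE, 10.0),
        ),
        pause_s=15.0,
        relax_first=False,
    )


class TestValidation:
    def _clean_session(self, duration_s, rate=8.0):
        n = int(duration_s * rate)
        return ea.RawSession(np.arange(n) * 1000.0 / rate, np.full(n, 2e5), nominal_rate=rate)

    def test_clean_full_coverage_session_is_valid(self):
        protocol = _protocol_3x10()
        report = ea.validate_session(self._clean_session(protocol.total_duration_s + 1), protocol)
        assert report.valid and report.reasons == []

    def test_half_truncated_session_fails_coverage(self):
        protocol = _protocol_3x10()
        report = ea.validate_session(self._clean_session(protocol.total_duration_s * 0.5), protocol)
        assert not report.valid
        assert TRUNCATED in report.reasons

    def test_decreasing_timestamp_pair_flagged(self):
        protocol = _protocol_3x10()
        session = self._clean_session(protocol.total_duration_s + 1)
        session.timestamps_ms[10], session.timestamps_ms[11] = (
            session.timestamps_ms[11],
            session.timestamps_ms[10],
        )
        report = ea.validate_session(session, protocol)
        assert not report.valid and NONMONOTONE_TIME in report.reasons

    def test_out_of_range_resistance_flagged(self):
        protocol = _protocol_3x10()
        session = self._clean_session(protocol.total_duration_s + 1)
        session.resistance_ohm[5] = 1e3
        assert OUT_OF_RANGE in ea.validate_session(session, protocol).reasons

    def test_long_acquisition_gap_flagged(self):
        protocol = _protocol_3x10()
        session = self._clean_session(protocol.total_duration_s + 10)
        keep = (session.timestamps_ms < 20000) | (session.timestamps_ms > 27000)
        session = ea.RawSession(session.timestamps_ms[keep], session.resistance_ohm[keep])
        assert GAP in ea.validate_session(session, protocol).reasons

    def test_valid_iff_reasons_empty_and_deterministic(self):
        protocol = _protocol_3x10()
        session = self._clean_session(protocol.total_duration_s * 0.4)
        r1 = ea.validate_session(session, protocol)
        r2 = ea.validate_session(session, protocol)
        assert r1.valid == (not r1.reasons)
        assert r1.valid == r2.valid and r1.reasons == r2.reasons


class TestSegmentation:
    def test_nine_song_protocol_yields_eight_segments_two_per_quadrant(self):
        protocol = ea.default_protocol(song_duration_s=20.0, pause_s=5.0)
        n = int((protocol.total_duration_s + 1) * 8)
        session = ea.RawSession(np.arange(n) * 125.0, np.full(n, 2e5), nominal_rate=8.0)
        segments = ea.segment_session(session, protocol)
        assert len(segments) == 8
        counts = {q: sum(1 for s in segments if s.label == q) for q in ea.QUADRANT_ORDER}
        assert all(c == 2 for c in counts.values())

    def test_empty_protocol_yields_no_segments(self, constant_session):
        assert ea.segment_session(constant_session, ea.ProtocolSpec(songs=(), relax_first=False)) == []

    def test_segment_boundaries_match_cumulative_schedule(self):
        # 3 songs of 10 s with 15 s pauses -> segments at [0,10), [25,35), [50,60)
        protocol = _protocol_3x10()
        rate = 2.0
        n = int(protocol.total_duration_s * rate) + 1
        t = np.arange(n) * 500.0
        session = ea.RawSession(t, np.full(n, 2e5), nominal_rate=rate)
        segments = ea.segment_session(session, protocol)
        expected = [(0.0, 10.0), (25.0, 35.0), (50.0, 60.0)]
        for seg, (start, end) in zip(segments, expected):
            original = seg.session.timestamps_ms + start * 1000.0
            assert original.min() >= start * 1000.0
            assert original.max() < end * 1000.0  # half-open interval
            assert len(seg.session) == int((end - start) * rate)

    def test_session_shorter_than_schedule_raises(self):
        protocol = _protocol_3x10()
        n = int(protocol.total_duration_s * 8 * 0.5)
        short = ea.RawSession(np.arange(n) * 125.0, np.full(n, 2e5), nominal_rate=8.0)
        with pytest.raises(ValueError, match="shorter"):
            ea.segment_session(short, protocol)

    def test_relax_song_and_pauses_are_excluded(self):
        protocol = ea.default_protocol(song_duration_s=20.0, pause_s=5.0)
        n = int((protocol.total_duration_s + 1) * 8)
        session = ea.RawSession(np.arange(n) * 125.0, np.full(n, 2e5), nominal_rate=8.0)
        segments = ea.segment_session(session, protocol)
        assert all(isinstance(s.label, ea.QuadrantLabel) for s in segments)
        total_song_time = sum(s.duration_s for s in segments)
        assert total_song_time < 8 * 20.0  # strictly inside the song slots


def test_load_protocol_from_config(tmp_path):
    cfg = tmp_path / "protocol.yaml"
    cfg.write_text(
        "pause_s: 10\nrelax_first: true\nsongs:\n"
        "  - [Relax, 30]\n  - [Happy, 30]\n  - [Sad, 30]\n"
    )
    protocol = ea.load_protocol(cfg)
    assert protocol.pause_s == 10.0
    assert protocol.songs[0][0] == ea.RELAX
    assert protocol.songs[1] == (ea.QuadrantLabel.HAPPY, 30.0)
    assert protocol.total_duration_s == 3 * 30 + 2 * 10


def test_write_segments_manifest(tmp_path):
    protocol = ea.default_protocol(song_duration_s=20.0, pause_s=5.0)
    n = int((protocol.total_duration_s + 1) * 8)
    session = ea.RawSession(np.arange(n) * 125.0, np.full(n, 2e5), session_id="s0", nominal_rate=8.0)
    segments = ea.segment_session(session, protocol)
    manifest = ea.write_segments(segments, tmp_path / "segs")
    lines = manifest.read_text().strip().splitlines()
    assert lines[0] == "segment_file,label,session_id,song_index"
    assert len(lines) == 9  # header + 8 segments
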