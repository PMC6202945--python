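"""Tests for I/O round-trips, session assembly and segmentation QC."""

import numpy as np
import pytest

from motorbattery import sessionio, synthgen
from motorbattery.sessionio import (
    RawRecording,
    SegmentationConfig,
    apply_segmentation,
    assemble_sessions,
    segment_task,
    session_to_recordings,
)
from motorbattery.synthgen import AccelStream, GroupParams, VoiceRecording


def _session(seed=0, **kw):
    base = dict(n_per_group=2, sessions_per_subject=1.0, seed=seed,
                voice_s=2.0, accel_s=10.0, tap_s=5.0, n_reaction_trials=5)
    base.update(kw)
    cfg = synthgen.CohortConfig(**base)
    _, sessions = synthgen.generate_cohort(cfg)
    return sessions[0]


class TestRoundTrip:
    def test_write_read_cohort(self, tmp_path):
        cfg = synthgen.CohortConfig(n_per_group=2, sessions_per_subject=1.0,
                                    seed=3, voice_s=1.5, accel_s=10.0,
                                    tap_s=4.0, n_reaction_trials=4)
        subjects, sessions = synthgen.generate_cohort(cfg)
        synthgen.write_cohort(subjects, sessions, tmp_path / "cohort")
        subjects2, sessions2 = sessionio.read_cohort_dir(tmp_path / "cohort")
        assert subjects.equals(subjects2)
        assert len(sessions2) == len(sessions)
        s0 = sessions[0]
        r0 = next(s for s in sessions2 if s.subject_id == s0.subject_id
                  and s.session_time == pytest.approx(s0.session_time))
        # WAV PCM16 quantization: amplitudes equal to 1 LSB after peak scaling
        peak = np.abs(s0.voice.samples).max()
        np.testing.assert_allclose(r0.voice.samples * peak, s0.voice.samples,
                                   atol=peak / 32000)
        np.testing.assert_allclose(r0.accel["gait"].az, s0.accel["gait"].az,
                                   rtol=0, atol=1e-9)
        assert [t.t for t in r0.taps] == pytest.approx([t.t for t in s0.taps])

    def test_jsonl_ingestion_skips_bad_lines(self, tmp_path):
        import json
        ses = _session()
        recs = session_to_recordings(ses)
        lines = []
        for r in recs[:2]:
            if r.task == "voice":
                payload = {"samples": list(np.asarray(r.payload.samples)[:100]),
                           "rate_hz": r.payload.rate_hz}
            else:
                st = r.payload
                payload = {"t": list(st.t[:10]), "ax": list(st.ax[:10]),
                           "ay": list(st.ay[:10]), "az": list(st.az[:10])}
            lines.append(json.dumps({"subject_id": r.subject_id, "task": r.task,
                                     "start_time": r.start_time,
                                     "payload": payload}))
        lines.append("{not json")
        lines.append(json.dumps({"subject_id": "x", "task": "teleport",
                                 "start_time": 0, "payload": {}}))
        path = tmp_path / "stream.jsonl"
        path.write_text("\n".join(lines))
        out = sessionio.read_jsonl(path)
        assert len(out) == 2


class TestAssembleSessions:
    def test_complete_set_in_window(self):
        ses = _session()
        result = assemble_sessions(session_to_recordings(ses))
        assert len(result.sessions) == 1
        assert result.sessions[0].subject_id == ses.subject_id

    def test_six_of_seven_dropped(self):
        ses = _session()
        recs = [r for r in session_to_recordings(ses) if r.task != "gait"]
        result = assemble_sessions(recs)
        assert result.sessions == []
        assert result.n_dropped_incomplete == 1

    def test_out_of_window_dropped(self):
        recs = session_to_recordings(_session())
        recs[-1].start_time += 31 * 60  # push last task out of the window
        result = assemble_sessions(recs)
        assert result.sessions == []

    def test_interleaved_sets_matched_greedily(self):
        s1, s2 = _session(seed=1), _session(seed=2)
        # same subject, two sessions offset by 10 minutes
        offset = 600.0
        recs = []
        for r in session_to_recordings(s1):
            r.subject_id = "sub"
            recs.append(r)
        for r in session_to_recordings(s2):
            r.subject_id = "sub"
            r.start_time = r.start_time - s2.session_time + s1.session_time + offset
            recs.append(r)
        result = assemble_sessions(recs)
        assert len(result.sessions) == 2
        # greedy nearest-in-time matches exhaustive assignment here:
        # each session keeps its own 7 tasks
        t0 = sorted(result.sessions[0].task_start_times.values())
        t1 = sorted(result.sessions[1].task_start_times.values())
        assert max(t0) < min(t1)

    def test_unparseable_timestamp_skipped(self):
        recs = session_to_recordings(_session())
        recs[0].start_time = "not-a-time"
        result = assemble_sessions(recs)
        assert result.n_skipped_records == 1
        assert result.sessions == []  # voice record was dropped


class TestSegmentTask:
    def test_voice_silence_trimmed(self):
        rate = 16000
        rng = np.random.default_rng(0)
        p = GroupParams(hnr_db=30.0)
        voiced = synthgen.synth_voice(p, 8.0, rate, 1).samples
        silence = 1e-4 * rng.standard_normal(rate)  # 1 s quiet either end
        x = np.concatenate([silence, voiced, silence])
        seg = segment_task("voice", VoiceRecording(samples=x, rate_hz=rate))
        assert seg.qc_pass
        (start, end), = seg.intervals
        assert start == pytest.approx(1.0, abs=0.15)
        assert end == pytest.approx(9.0, abs=0.15)

    def test_flat_accelerometer_fails(self):
        t = np.arange(0, 10, 0.01)
        st = AccelStream(t=t, ax=np.zeros_like(t), ay=np.zeros_like(t),
                         az=np.full_like(t, 9.81))
        seg = segment_task("rest_tremor", st)
        assert not seg.qc_pass
        assert "flat" in seg.qc_reason

    def test_short_imu_fails_min_duration(self):
        t = np.arange(0, 4, 0.01)
        rng = np.random.default_rng(1)
        st = AccelStream(t=t, ax=rng.standard_normal(len(t)),
                         ay=rng.standard_normal(len(t)),
                         az=9.81 + rng.standard_normal(len(t)))
        seg = segment_task("balance", st)
        assert not seg.qc_pass
        assert "minimum" in seg.qc_reason

    def test_empty_payload(self):
        seg = segment_task("tapping", [])
        assert not seg.qc_pass
        assert seg.qc_reason == "empty"

    def test_imu_trim_two_seconds(self):
        t = np.arange(0, 20, 0.01)
        rng = np.random.default_rng(2)
        st = AccelStream(t=t, ax=rng.standard_normal(len(t)),
                         ay=rng.standard_normal(len(t)),
                         az=9.81 + rng.standard_normal(len(t)))
        seg = segment_task("gait", st)
        assert seg.qc_pass
        (start, end), = seg.intervals
        assert start == pytest.approx(2.0, abs=0.02)
        assert end == pytest.approx(17.99, abs=0.05)


class TestSegmentationProperties:
    def test_never_extends_signal(self):
        ses = _session()
        trimmed, segs = apply_segmentation(ses)
        assert len(trimmed.voice.samples) <= len(ses.voice.samples)
        for task in synthgen.ACCEL_TASKS:
            assert len(trimmed.accel[task].t) <= len(ses.accel[task].t)
        assert len(trimmed.taps) <= len(ses.taps)

    def test_idempotent(self):
        ses = _session()
        once, _ = apply_segmentation(ses)
        twice, _ = apply_segmentation(once)
        assert len(twice.voice.samples) == len(once.voice.samples)
        for task in synthgen.ACCEL_TASKS:
            np.testing.assert_array_equal(twice.accel[task].t,
                                          once.accel[task].t)
        assert len(twice.taps) == len(once.taps)
        assert len(twice.reactions) == len(once.reactions)

    def test_config_exposes_thresholds(self):
        cfg = SegmentationConfig(imu_trim_s=0.5, imu_min_retained_s=3.0)
        t = np.arange(0, 4.5, 0.01)
        rng = np.random.default_rng(3)
        st = AccelStream(t=t, ax=rng.standard_normal(len(t)),
                         ay=rng.standard_normal(len(t)),
                         az=9.81 + rng.standard_normal(len(t)))
        assert segment_task("balance", st, cfg).qc_pass
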