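"""Session reading/writing, timestamp-based assembly and segmentation QC.

A valid session requires all 7 tasks within a configurable window
(default 30 min) in protocol order; incomplete sets are dropped and
counted. Segmentation is a conservative stand-in for the study's
unpublished algorithm: energy-gated trimming for voice, fixed
transient trimming plus flat-signal checks for accelerometry, and a
settle-in cut for event streams. All thresholds live in
:class:`SegmentationConfig`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synthgen import (
    ACCEL_TASKS,
    TASK_ORDER,
    AccelStream,
    ReactionEvent,
    Session,
    TapEvent,
    VoiceRecording,
)

logger = logging.getLogger(__name__)

_SHORT = {"balance": "balance", "gait": "gait",
          "rest_tremor": "rest", "postural_tremor": "postural"}


@dataclass
class RawRecording:
    """One task recording with its own timestamp, possibly orphaned."""

    subject_id: str
    task: str  # one of TASK_ORDER
    start_time: float  # seconds since epoch, UTC
    payload: object  # VoiceRecording | AccelStream | list of events


@dataclass
class SegmentedTask:
    task: str
    intervals: list[tuple[float, float]]  # retained [start_s, end_s)
    qc_pass: bool
    qc_reason: str = ""


@dataclass
class SegmentationConfig:
    session_window_s: float = 30 * 60.0
    imu_trim_s: float = 2.0
    imu_min_retained_s: float = 5.0
    voice_rms_gate: float = 0.10  # fraction of median voiced frame RMS
    voice_frame_s: float = 0.05
    event_settle_s: float = 1.0


@dataclass
class AssemblyResult:
    sessions: list[Session]
    n_dropped_incomplete: int = 0
    n_dropped_order: int = 0
    n_skipped_records: int = 0


# ---------------------------------------------------------------------------
# cohort directory I/O (synthgen layout)

def read_cohort_dir(root: str | Path) -> tuple[pd.DataFrame, list[Session]]:
    """Read a cohort written by :func:`motorbattery.synthgen.write_cohort`."""
    root = Path(root)
    subjects = pd.read_csv(root / "subjects.csv")
    sessions: list[Session] = []
    for meta_path in sorted(root.glob("*/ses-*/session.json")):
        sdir = meta_path.parent
        meta = json.loads(meta_path.read_text())
        rate, pcm = wavfile.read(sdir / "voice.wav")
        voice = VoiceRecording(samples=pcm.astype(float) / 32767.0, rate_hz=int(rate))
        accel = {}
        for task in ACCEL_TASKS:
            df = pd.read_csv(sdir / f"{_SHORT[task]}.csv")
            accel[task] = AccelStream(t=df["t"].to_numpy(), ax=df["ax"].to_numpy(),
                                      ay=df["ay"].to_numpy(), az=df["az"].to_numpy())
        taps_df = pd.read_csv(sdir / "taps.csv")
        taps = [TapEvent(**row) for row in taps_df.to_dict("records")]
        rx_df = pd.read_csv(sdir / "reactions.csv")
        reactions = [ReactionEvent(**row) for row in rx_df.to_dict("records")]
        sessions.append(Session(
            subject_id=meta["subject_id"], session_time=meta["session_time"],
            task_start_times=meta["task_start_times"], voice=voice,
            accel=accel, taps=taps, reactions=reactions))
    return subjects, sessions


def read_jsonl(path: str | Path) -> list[RawRecording]:
    """Ingest a JSON-lines stream of typed raw-device records.

    Each line: {"subject_id", "task", "start_time", "payload"} where the
    payload matches the task kind. Unparseable lines are skipped with a
    warning.
    """
    records: list[RawRecording] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
            task = obj["task"]
            if task not in TASK_ORDER:
                raise ValueError(f"unknown task {task!r}")
            payload = _payload_from_json(task, obj["payload"])
            records.append(RawRecording(subject_id=str(obj["subject_id"]),
                                        task=task,
                                        start_time=float(obj["start_time"]),
                                        payload=payload))
        except (KeyError, ValueError, TypeError) as exc:
            logger.warning("skipping line %d of %s: %s", lineno, path, exc)
    return records


def _payload_from_json(task: str, payload: dict) -> object:
    if task == "voice":
        return VoiceRecording(samples=np.asarray(payload["samples"], dtype=float),
                              rate_hz=int(payload["rate_hz"]))
    if task in ACCEL_TASKS:
        return AccelStream(t=np.asarray(payload["t"], dtype=float),
                           ax=np.asarray(payload["ax"], dtype=float),
                           ay=np.asarray(payload["ay"], dtype=float),
                           az=np.asarray(payload["az"], dtype=float))
    if task == "tapping":
        return [TapEvent(**e) for e in payload]
    if task == "reaction":
        return [ReactionEvent(**e) for e in payload]
    raise ValueError(task)


def session_to_recordings(session: Session) -> list[RawRecording]:
    """Explode a Session into per-task raw recordings (for round-trips)."""
    recs = []
    for task in TASK_ORDER:
        if task == "voice":
            payload: object = session.voice
        elif task == "tapping":
            payload = session.taps
        elif task == "reaction":
            payload = session.reactions
        else:
            payload = session.accel[task]
        recs.append(RawRecording(subject_id=session.subject_id, task=task,
                                 start_time=session.task_start_times[task],
                                 payload=payload))
    return recs


# ---------------------------------------------------------------------------
# session assembly

def assemble_sessions(recordings: list[RawRecording],
                      config: SegmentationConfig | None = None) -> AssemblyResult:
    """Group per-task recordings into complete in-order 7-task sessions.

    A session is emitted iff all 7 tasks from one subject fall within
    ``session_window_s`` in protocol order. When several complete sets
    interleave, tasks are matched greedily nearest-in-time to the
    session's voice anchor.
    """
    cfg = config or SegmentationConfig()
    result = AssemblyResult(sessions=[])
    by_subject: dict[str, list[RawRecording]] = {}
    for rec in recordings:
        try:
            float(rec.start_time)
        except (TypeError, ValueError):
            logger.warning("unparseable timestamp on %s/%s; record skipped",
                           rec.subject_id, rec.task)
            result.n_skipped_records += 1
            continue
        if rec.task not in TASK_ORDER:
            logger.warning("unknown task %r; record skipped", rec.task)
            result.n_skipped_records += 1
            continue
        by_subject.setdefault(rec.subject_id, []).append(rec)

    for sid in sorted(by_subject):
        recs = sorted(by_subject[sid], key=lambda r: (r.start_time, TASK_ORDER.index(r.task)))
        pools: dict[str, list[RawRecording]] = {t: [] for t in TASK_ORDER}
        for r in recs:
            pools[r.task].append(r)
        # anchor on each voice recording, greedily pick the nearest
        # not-yet-used recording of every other task that keeps protocol
        # order inside the window
        used: set[int] = set()
        for anchor in pools["voice"]:
            chosen = {"voice": anchor}
            t_prev = anchor.start_time
            ok = True
            for task in TASK_ORDER[1:]:
                cands = [r for r in pools[task]
                         if id(r) not in used
                         and r.start_time >= t_prev
                         and r.start_time - anchor.start_time <= cfg.session_window_s]
                if not cands:
                    ok = False
                    break
                best = min(cands, key=lambda r: r.start_time - t_prev)
                chosen[task] = best
                t_prev = best.start_time
            if not ok:
                result.n_dropped_incomplete += 1
                continue
            for r in chosen.values():
                used.add(id(r))
            result.sessions.append(Session(
                subject_id=sid,
                session_time=anchor.start_time,
                task_start_times={t: chosen[t].start_time for t in TASK_ORDER},
                voice=chosen["voice"].payload,
                accel={t: chosen[t].payload for t in ACCEL_TASKS},
                taps=chosen["tapping"].payload,
                reactions=chosen["reaction"].payload))
        n_loose = sum(1 for r in recs if id(r) not in used)
        if n_loose:
            logger.info("subject %s: %d recordings left unassembled", sid, n_loose)
    result.sessions.sort(key=lambda s: (s.subject_id, s.session_time))
    return result


# ---------------------------------------------------------------------------
# segmentation / QC

def segment_task(task: str, payload: object,
                 config: SegmentationConfig | None = None) -> SegmentedTask:
    """QC one task payload; returns retained intervals and a pass flag."""
    cfg = config or SegmentationConfig()
    if payload is None or (hasattr(payload, "__len__") and len(payload) == 0):
        return SegmentedTask(task, [], qc_pass=False, qc_reason="empty")
    if task == "voice":
        return _segment_voice(payload, cfg)
    if task in ACCEL_TASKS:
        return _segment_imu(task, payload, cfg)
    if task in ("tapping", "reaction"):
        return _segment_events(task, payload, cfg)
    raise ValueError(f"unknown task {task!r}")


def _segment_voice(voice: VoiceRecording, cfg: SegmentationConfig) -> SegmentedTask:
    x = np.asarray(voice.samples, dtype=float)
    if len(x) == 0:
        return SegmentedTask("voice", [], False, "empty")
    frame = max(int(cfg.voice_frame_s * voice.rate_hz), 1)
    n_frames = len(x) // frame
    if n_frames < 2:
        return SegmentedTask("voice", [], False, "too short")
    rms = np.sqrt((x[: n_frames * frame].reshape(n_frames, frame) ** 2).mean(axis=1))
    med = np.median(rms[rms > 0]) if (rms > 0).any() else 0.0
    if med == 0:
        return SegmentedTask("voice", [], False, "silent")
    voiced = rms >= cfg.voice_rms_gate * med
    # longest contiguous voiced run
    best_len, best_start, cur_len, cur_start = 0, 0, 0, 0
    for i, v in enumerate(voiced):
        if v:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    if best_len * cfg.voice_frame_s < 1.0:
        return SegmentedTask("voice", [], False, "voiced run < 1 s")
    start_s = best_start * frame / voice.rate_hz
    end_s = (best_start + best_len) * frame / voice.rate_hz
    return SegmentedTask("voice", [(start_s, end_s)], True)


def _segment_imu(task: str, stream: AccelStream, cfg: SegmentationConfig) -> SegmentedTask:
    t = np.asarray(stream.t, dtype=float)
    if len(t) < 2:
        return SegmentedTask(task, [], False, "too short")
    # raw device streams start at t ~ 0; a later start means the
    # placement transients were already removed (keeps QC idempotent)
    already_trimmed = t[0] >= cfg.imu_trim_s
    trim = 0.0 if already_trimmed else cfg.imu_trim_s
    start = t[0] + trim
    end = t[-1] + (1e-9 if already_trimmed else -cfg.imu_trim_s)
    if end - start < cfg.imu_min_retained_s:
        return SegmentedTask(
            task, [], False,
            f"retained {max(end - start, 0):.1f} s < {cfg.imu_min_retained_s:.0f} s minimum")
    mask = (t >= start) & (t < end)
    for name in ("ax", "ay", "az"):
        axis = np.asarray(getattr(stream, name), dtype=float)[mask]
        if np.ptp(axis) == 0:
            return SegmentedTask(task, [], False, "flat signal")
    return SegmentedTask(task, [(start, end)], True)


def _segment_events(task: str, events: list, cfg: SegmentationConfig) -> SegmentedTask:
    times = [e.t if task == "tapping" else e.stim_on_t for e in events]
    t0, t1 = min(times), max(times)
    start = t0 + cfg.event_settle_s if t0 < cfg.event_settle_s else t0
    # events use task-relative clocks in this pipeline: settle cut applies
    # only when the stream starts near zero
    if t1 <= start:
        return SegmentedTask(task, [], False, "no events after settle-in cut")
    return SegmentedTask(task, [(start, t1 + 1e-9)], True)


def apply_segmentation(session: Session,
                       config: SegmentationConfig | None = None
                       ) -> tuple[Session, dict[str, SegmentedTask]]:
    """Segment all 7 tasks of a session; returns trimmed session + QC map.

    Idempotent: re-applying to the returned session is a no-op (the trim
    offsets are anchored to the signal's own time axis).
    """
    cfg = config or SegmentationConfig()
    segs: dict[str, SegmentedTask] = {}

    seg_v = segment_task("voice", session.voice, cfg)
    segs["voice"] = seg_v
    voice = session.voice
    if seg_v.qc_pass:
        s, e = seg_v.intervals[0]
        i0, i1 = int(s * voice.rate_hz), int(e * voice.rate_hz)
        voice = VoiceRecording(samples=np.asarray(voice.samples, dtype=float)[i0:i1],
                               rate_hz=voice.rate_hz)

    accel = {}
    for task in ACCEL_TASKS:
        seg = segment_task(task, session.accel[task], cfg)
        segs[task] = seg
        st = session.accel[task]
        if seg.qc_pass:
            s, e = seg.intervals[0]
            m = (st.t >= s) & (st.t < e)
            st = AccelStream(t=st.t[m], ax=st.ax[m], ay=st.ay[m], az=st.az[m])
        accel[task] = st

    seg_tap = segment_task("tapping", session.taps, cfg)
    segs["tapping"] = seg_tap
    taps = session.taps
    if seg_tap.qc_pass:
        s, e = seg_tap.intervals[0]
        taps = [ev for ev in taps if s <= ev.t < e]

    seg_rx = segment_task("reaction", session.reactions, cfg)
    segs["reaction"] = seg_rx
    reactions = session.reactions
    if seg_rx.qc_pass:
        s, e = seg_rx.intervals[0]
        reactions = [ev for ev in reactions if s <= ev.stim_on_t < e]

    trimmed = replace(session, voice=voice, accel=accel, taps=taps,
                      reactions=reactions)
    return trimmed, segs
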