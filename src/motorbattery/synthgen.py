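"""Synthetic multi-task smartphone cohort generator.

Produces control / iRBD / PD cohorts of 7-task sessions (sustained
phonation, balance, gait, rest tremor, postural tremor accelerometry,
alternating finger tapping, simple reaction time) with configurable,
documented effect sizes, including a null (zero-effect) configuration.
Every generative dial corresponds to a downstream feature family so the
whole pipeline is testable without any clinical data.

The default effect magnitudes are design choices for testing, not
calibrated estimates: directions are PD > iRBD > control for tremor
amplitude, phonation perturbation, tapping interval and reaction
latency, with iRBD at roughly one third of the PD shift.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

GROUPS = ("control", "irbd", "pd")
ACCEL_TASKS = ("balance", "gait", "rest_tremor", "postural_tremor")
#: protocol order of the 7 tasks within a session
TASK_ORDER = ("voice", "balance", "gait", "tapping", "reaction",
              "rest_tremor", "postural_tremor")

#: fixed tapping-target geometry (screen pixels), shared with the
#: tapping feature extractor
BUTTON_CENTERS = {"left": (90.0, 240.0), "right": (270.0, 240.0)}
BUTTON_RADIUS_PX = 60.0

GRAVITY_MS2 = 9.81


class ConfigurationError(ValueError):
    """Raised when a cohort/group configuration violates its invariants."""


@dataclass
class GroupParams:
    """Generative dials for one clinical group.

    Amplitudes are m/s^2, times are seconds, fractions dimensionless.
    """

    f0_hz: float = 120.0
    f0_sd_hz: float = 10.0
    jitter_frac: float = 0.006
    shimmer_frac: float = 0.04
    hnr_db: float = 22.0
    tremor_amp_rest_ms2: float = 0.02
    tremor_amp_postural_ms2: float = 0.02
    tremor_freq_hz: float = 5.0
    sway_rms_ms2: float = 0.08
    cadence_hz: float = 1.85
    step_amp_ms2: float = 2.0
    iti_mean_s: float = 0.22
    iti_cv: float = 0.08
    iti_drift: float = 0.0
    tap_scatter_px: float = 12.0
    rt_mu_s: float = 0.28
    rt_sigma_s: float = 0.04
    rt_tau_s: float = 0.06

    def validate(self) -> None:
        nonneg = ("f0_sd_hz", "jitter_frac", "shimmer_frac",
                  "tremor_amp_rest_ms2", "tremor_amp_postural_ms2",
                  "sway_rms_ms2", "step_amp_ms2", "iti_cv",
                  "tap_scatter_px", "rt_sigma_s", "rt_tau_s")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"GroupParams.{name} must be >= 0")
        if not 3.0 <= self.tremor_freq_hz <= 8.0:
            raise ConfigurationError("GroupParams.tremor_freq_hz must be in [3, 8]")
        if self.iti_mean_s <= 0:
            raise ConfigurationError("GroupParams.iti_mean_s must be > 0")
        if self.f0_hz <= 0:
            raise ConfigurationError("GroupParams.f0_hz must be > 0")
        if self.rt_mu_s <= 0:
            raise ConfigurationError("GroupParams.rt_mu_s must be > 0")
        if self.cadence_hz <= 0:
            raise ConfigurationError("GroupParams.cadence_hz must be > 0")


@dataclass
class CohortConfig:
    """Cohort-level generative configuration."""

    n_per_group: int = 10
    sessions_per_subject: float = 3.0
    sex_ratio: float = 0.6  # fraction male, all groups
    seed: int = 0
    group_params: dict[str, GroupParams] = field(default_factory=dict)
    subject_sd_frac: float = 0.05  # between-subject fractional variation
    voice_s: float = 10.0
    accel_s: float = 45.0
    tap_s: float = 20.0
    n_reaction_trials: int = 20
    voice_rate_hz: int = 16000
    accel_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        for g in GROUPS:
            self.group_params.setdefault(g, GroupParams())

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("CohortConfig.n_per_group must be >= 2")
        if self.sessions_per_subject < 1:
            raise ConfigurationError("CohortConfig.sessions_per_subject must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("CohortConfig.sex_ratio must be in [0, 1]")
        if self.subject_sd_frac < 0:
            raise ConfigurationError("CohortConfig.subject_sd_frac must be >= 0")
        for g, p in self.group_params.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")
            p.validate()


@dataclass
class VoiceRecording:
    samples: np.ndarray
    rate_hz: int


@dataclass
class AccelStream:
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)


@dataclass
class TapEvent:
    t: float
    x: float
    y: float
    target_id: str


@dataclass
class ReactionEvent:
    stim_on_t: float
    press_t: float
    stim_off_t: float
    release_t: float
    x: float
    y: float


@dataclass
class Session:
    subject_id: str
    session_time: float  # seconds since epoch, UTC
    task_start_times: dict[str, float]
    voice: VoiceRecording
    accel: dict[str, AccelStream]
    taps: list[TapEvent]
    reactions: list[ReactionEvent]


def synth_voice(params: GroupParams, duration_s: float, rate_hz: int,
                seed: int | np.random.Generator) -> VoiceRecording:
    """Sustained-phonation synthesis: 5-harmonic source + noise.

    Cycle periods are perturbed with CV ``jitter_frac``, cycle amplitudes
    with CV ``shimmer_frac``; Gaussian noise is added to reach ``hnr_db``.
    """
    if duration_s < 1:
        raise ValueError("voice duration must be >= 1 s")
    if rate_hz < 2 * 5 * params.f0_hz:
        raise ValueError(
            f"rate {rate_hz} Hz below Nyquist need of 5*f0 = {5 * params.f0_hz} Hz")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    t0 = 1.0 / params.f0_hz
    n_cycles = int(np.ceil(duration_s / t0)) + 2
    periods = t0 * (1.0 + params.jitter_frac * rng.standard_normal(n_cycles))
    periods = np.clip(periods, 0.3 * t0, 3.0 * t0)
    amps = 1.0 + params.shimmer_frac * rng.standard_normal(n_cycles)
    amps = np.clip(amps, 0.05, None)

    harm_amp = np.array([1.0, 0.5, 0.25, 0.125, 0.0625])  # fixed rolloff
    n_total = int(duration_s * rate_hz)
    out = np.zeros(n_total)
    pos = 0.0
    for k in range(n_cycles):
        start = int(round(pos * rate_hz))
        pos += periods[k]
        stop = min(int(round(pos * rate_hz)), n_total)
        if start >= n_total:
            break
        tt = (np.arange(start, stop) / rate_hz - (pos - periods[k])) / periods[k]
        cyc = np.zeros(stop - start)
        for h, a in enumerate(harm_amp, start=1):
            cyc += a * np.sin(2 * np.pi * h * tt)
        out[start:stop] = amps[k] * cyc
    sig_power = float(np.mean(out**2))
    if np.isfinite(params.hnr_db):
        noise_power = sig_power / (10.0 ** (params.hnr_db / 10.0))
        out = out + np.sqrt(noise_power) * rng.standard_normal(n_total)
    return VoiceRecording(samples=out, rate_hz=int(rate_hz))


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec = spec / np.sqrt(f)
    spec[0] = 0.0
    pink = np.fft.irfft(spec, n=n)
    rms = pink.std()
    return pink / rms if rms > 0 else pink


def synth_accel(task: str, params: GroupParams, duration_s: float,
                rate_hz: float, seed: int | np.random.Generator) -> AccelStream:
    """Triaxial accelerometry for one of the 4 IMU tasks.

    Gravity on z + pink-noise sway on all axes; tremor tasks add an
    amplitude-modulated sinusoid at ``tremor_freq_hz`` on x/y; gait adds
    periodic step impulses at ``cadence_hz``.
    """
    if task not in ACCEL_TASKS:
        raise ValueError(f"unknown accelerometer task {task!r}")
    if duration_s < 10:
        raise ValueError("accelerometer tasks require duration >= 10 s")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = int(duration_s * rate_hz)
    t = np.arange(n) / rate_hz
    axes = [params.sway_rms_ms2 * _pink_noise(n, rng) for _ in range(3)]
    axes[2] = axes[2] + GRAVITY_MS2

    if task in ("rest_tremor", "postural_tremor"):
        amp = (params.tremor_amp_rest_ms2 if task == "rest_tremor"
               else params.tremor_amp_postural_ms2)
        if amp > 0:
            # slow random amplitude modulation (0.1-0.3 Hz)
            mod = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.1, 0.3) * t
                                     + rng.uniform(0, 2 * np.pi))
            phase = rng.uniform(0, 2 * np.pi)
            tremor = amp * mod * np.sin(2 * np.pi * params.tremor_freq_hz * t + phase)
            # projection onto all axes: the device is never axis-aligned,
            # and a z component makes the magnitude signal carry the peak
            axes[0] = axes[0] + tremor
            axes[1] = axes[1] + 0.5 * tremor
            axes[2] = axes[2] + 0.3 * tremor
    elif task == "gait":
        step_t = 1.0 / params.cadence_hz
        # half-sine step impulses, 100 ms wide, on the vertical axis
        width = max(int(0.1 * rate_hz), 2)
        pulse = params.step_amp_ms2 * np.sin(np.linspace(0, np.pi, width))
        impulses = np.zeros(n)
        pos = rng.uniform(0, step_t)
        while pos < duration_s:
            i0 = int(pos * rate_hz)
            i1 = min(i0 + width, n)
            impulses[i0:i1] += pulse[: i1 - i0]
            pos += step_t * (1.0 + 0.03 * rng.standard_normal())
        axes[2] = axes[2] + impulses
        axes[0] = axes[0] + 0.3 * impulses

    return AccelStream(t=t, ax=axes[0], ay=axes[1], az=axes[2])


def synth_taps(params: GroupParams, duration_s: float,
               seed: int | np.random.Generator) -> list[TapEvent]:
    """Alternating two-target tapping with drift and lognormal ITI noise.

    Interval k = iti_mean_s * (1 + iti_drift*k) * lognormal(cv=iti_cv).
    """
    if duration_s <= 0:
        raise ValueError("tap task duration must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    events: list[TapEvent] = []
    t = 0.5  # settle-in offset
    k = 0
    sigma = np.sqrt(np.log(1.0 + params.iti_cv**2))
    while t < duration_s:
        target = "left" if k % 2 == 0 else "right"
        cx, cy = BUTTON_CENTERS[target]
        x = cx + params.tap_scatter_px * rng.standard_normal()
        y = cy + params.tap_scatter_px * rng.standard_normal()
        events.append(TapEvent(t=t, x=float(x), y=float(y), target_id=target))
        base = params.iti_mean_s * max(1.0 + params.iti_drift * k, 0.05)
        noise = np.exp(sigma * rng.standard_normal() - sigma**2 / 2) if sigma > 0 else 1.0
        t += base * noise
        k += 1
    return events


def synth_reactions(params: GroupParams, n_trials: int,
                    seed: int | np.random.Generator) -> list[ReactionEvent]:
    """Simple reaction-time trials with ex-Gaussian latencies.

    Negative latency draws are rejected and resampled.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def _latency() -> float:
        for _ in range(100):
            lat = (params.rt_mu_s + params.rt_sigma_s * rng.standard_normal()
                   + (rng.exponential(params.rt_tau_s) if params.rt_tau_s > 0 else 0.0))
            if lat > 0:
                return float(lat)
        return params.rt_mu_s  # pathological config fallback

    events: list[ReactionEvent] = []
    t = 1.0
    for _ in range(n_trials):
        stim_on = t + rng.uniform(0.5, 2.0)
        press = stim_on + _latency()
        stim_off = press + 0.5
        release = stim_off + _latency()
        cx, cy = BUTTON_CENTERS["left"]
        events.append(ReactionEvent(
            stim_on_t=float(stim_on), press_t=float(press),
            stim_off_t=float(stim_off), release_t=float(release),
            x=float(cx + 5 * rng.standard_normal()),
            y=float(cy + 5 * rng.standard_normal())))
        t = release
    return events


def _perturb(params: GroupParams, frac: float,
             rng: np.random.Generator) -> GroupParams:
    """Subject-level random effects: multiplicative jitter on the dials."""
    if frac <= 0:
        return dataclasses.replace(params)
    out = dataclasses.replace(params)
    for f in ("f0_hz", "jitter_frac", "shimmer_frac", "tremor_amp_rest_ms2",
              "tremor_amp_postural_ms2", "sway_rms_ms2", "cadence_hz",
              "iti_mean_s", "iti_cv", "tap_scatter_px", "rt_mu_s",
              "rt_sigma_s", "rt_tau_s"):
        val = getattr(out, f) * float(np.exp(frac * rng.standard_normal()))
        setattr(out, f, val)
    out.tremor_freq_hz = float(np.clip(
        out.tremor_freq_hz + 0.5 * frac * 10 * rng.standard_normal(), 3.0, 8.0))
    return out


def synth_session(subject_id: str, params: GroupParams, cfg: CohortConfig,
                  session_time: float, rng: np.random.Generator) -> Session:
    """One 7-task session; task start times spaced 10-60 s apart."""
    starts = {}
    t = session_time
    for task in TASK_ORDER:
        starts[task] = t
        t += rng.uniform(10.0, 60.0) + cfg.accel_s
    voice = synth_voice(params, cfg.voice_s, cfg.voice_rate_hz, rng)
    accel = {task: synth_accel(task, params, cfg.accel_s, cfg.accel_rate_hz, rng)
             for task in ACCEL_TASKS}
    taps = synth_taps(params, cfg.tap_s, rng)
    reactions = synth_reactions(params, cfg.n_reaction_trials, rng)
    return Session(subject_id=subject_id, session_time=session_time,
                   task_start_times=starts, voice=voice, accel=accel,
                   taps=taps, reactions=reactions)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, list[Session]]:
    """Generate the full cohort: subject table + list of sessions.

    Deterministic given ``config.seed``. Session counts per subject are
    Poisson(sessions_per_subject - 1) + 1 (truncated at 1).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    rows = []
    sessions: list[Session] = []
    base_time = 1_600_000_000.0  # fixed epoch anchor for reproducibility
    for g in GROUPS:
        params = config.group_params[g]
        for i in range(config.n_per_group):
            sid = f"{g}_{i:03d}"
            sex = "male" if rng.uniform() < config.sex_ratio else "female"
            age = float(np.clip(rng.normal(64, 8), 35, 90))
            rows.append({"subject_id": sid, "group": g, "sex": sex,
                         "age": round(age, 1)})
            sub_params = _perturb(params, config.subject_sd_frac, rng)
            n_sessions = 1 + rng.poisson(max(config.sessions_per_subject - 1.0, 0.0))
            for s in range(n_sessions):
                stime = base_time + s * 7 * 86400.0 + rng.uniform(0, 3600)
                sessions.append(synth_session(sid, sub_params, config, stime, rng))
    subjects = pd.DataFrame(rows)
    return subjects, sessions


# ---------------------------------------------------------------------------
# effect-size presets

def make_cohort_config(effect_size: float = 1.0, irbd_scale: float = 1 / 3,
                       **kwargs) -> CohortConfig:
    """Cohort with documented group-effect directions.

    ``effect_size=0`` is the null configuration (all groups identical);
    ``effect_size=1`` is a clearly separable test cohort. iRBD shifts are
    ``irbd_scale`` of the PD shifts.
    """
    base = GroupParams()

    def shifted(scale: float) -> GroupParams:
        e = effect_size * scale
        return dataclasses.replace(
            base,
            jitter_frac=base.jitter_frac * (1 + 5.0 * e),
            shimmer_frac=base.shimmer_frac * (1 + 2.0 * e),
            hnr_db=base.hnr_db - 8.0 * e,
            tremor_amp_rest_ms2=base.tremor_amp_rest_ms2 + 0.5 * e,
            tremor_amp_postural_ms2=base.tremor_amp_postural_ms2 + 0.4 * e,
            sway_rms_ms2=base.sway_rms_ms2 * (1 + 1.0 * e),
            cadence_hz=base.cadence_hz * (1 - 0.1 * e),
            iti_mean_s=base.iti_mean_s * (1 + 0.5 * e),
            iti_cv=base.iti_cv * (1 + 1.5 * e),
            iti_drift=-0.002 * e,
            tap_scatter_px=base.tap_scatter_px * (1 + 1.0 * e),
            rt_mu_s=base.rt_mu_s * (1 + 0.4 * e),
            rt_tau_s=base.rt_tau_s * (1 + 1.0 * e),
        )

    params = {"control": dataclasses.replace(base),
              "irbd": shifted(irbd_scale),
              "pd": shifted(1.0)}
    return CohortConfig(group_params=params, **kwargs)


# ---------------------------------------------------------------------------
# on-disk layout

def write_cohort(subjects: pd.DataFrame, sessions: list[Session],
                 out_dir: str | Path) -> Path:
    """Write a cohort in the standard directory layout.

    out_dir/subjects.csv plus one directory per session containing
    voice.wav (PCM16), {balance,gait,rest,postural}.csv (t,ax,ay,az),
    taps.csv, reactions.csv and session.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects.to_csv(out / "subjects.csv", index=False)
    counters: dict[str, int] = {}
    short = {"balance": "balance", "gait": "gait",
             "rest_tremor": "rest", "postural_tremor": "postural"}
    for ses in sessions:
        k = counters.get(ses.subject_id, 0)
        counters[ses.subject_id] = k + 1
        sdir = out / ses.subject_id / f"ses-{k:03d}"
        sdir.mkdir(parents=True, exist_ok=True)

        pcm = np.clip(ses.voice.samples / max(np.abs(ses.voice.samples).max(), 1e-9),
                      -1.0, 1.0)
        wavfile.write(sdir / "voice.wav", ses.voice.rate_hz,
                      (pcm * 32767).astype(np.int16))

        for task, name in short.items():
            st = ses.accel[task]
            pd.DataFrame({"t": st.t, "ax": st.ax, "ay": st.ay, "az": st.az}
                         ).to_csv(sdir / f"{name}.csv", index=False)
        pd.DataFrame([dataclasses.asdict(e) for e in ses.taps]
                     ).to_csv(sdir / "taps.csv", index=False)
        pd.DataFrame([dataclasses.asdict(e) for e in ses.reactions]
                     ).to_csv(sdir / "reactions.csv", index=False)
        meta = {"subject_id": ses.subject_id,
                "session_time": ses.session_time,
                "task_start_times": ses.task_start_times,
                "voice_rate_hz": ses.voice.rate_hz}
        (sdir / "session.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return out
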