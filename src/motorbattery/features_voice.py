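"""Sustained-phonation feature extraction: exactly 330 named features.

Catalog (names carry the ``voice.`` prefix when placed in the session
vector):

========================  =====
family                    count
========================  =====
jitter (period)               8
shimmer (amplitude)          10
HNR / NHR                     4
pitch period entropy          1
recurrence period entropy     1
DFA scaling exponent          1
vocal-fold excitation         9
glottal quotients             4
MFCC 0-12 + deltas x 4      104
f0 contour statistics        12
vocal tremor modulation       8
spectral shape               16
wavelet bands               152
========================  =====

The glottal-quotient and excitation-ratio definitions are documented
stand-ins for unpublished originals. An input with fewer than 50 %
voiced frames yields the full name list with every value NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.linalg import solve_toeplitz

from . import _dsp
from .synthgen import VoiceRecording

F0_MIN_HZ, F0_MAX_HZ = 50.0, 500.0
FRAME_S, HOP_S = 0.040, 0.010
VOICED_MIN_FRACTION = 0.5
_RPDE_MAX_SAMPLES = 12000
_DFA_MAX_SAMPLES = 12000


@dataclass
class F0Contour:
    f0_hz: np.ndarray          # per-frame f0, NaN where unvoiced
    voiced: np.ndarray         # bool per frame
    frame_times: np.ndarray    # frame centers, s
    cycle_marks: np.ndarray    # glottal cycle onsets, s

    @property
    def voiced_fraction(self) -> float:
        return float(self.voiced.mean()) if len(self.voiced) else 0.0


def track_f0(voice: VoiceRecording) -> F0Contour:
    """Autocorrelation f0 tracker (40 ms frames, 10 ms hop, 50-500 Hz)."""
    x = np.asarray(voice.samples, dtype=float)
    rate = voice.rate_hz
    frame_len = int(FRAME_S * rate)
    hop = int(HOP_S * rate)
    frames = _dsp.frame_signal(x, frame_len, hop)
    n_frames = frames.shape[0]
    f0 = np.full(n_frames, np.nan)
    voiced = np.zeros(n_frames, dtype=bool)
    times = (np.arange(n_frames) * hop + frame_len / 2) / rate

    lag_min = int(rate / F0_MAX_HZ)
    lag_max = min(int(rate / F0_MIN_HZ), frame_len - 1)
    rms_all = np.sqrt((frames**2).mean(axis=1))
    energy_gate = 0.1 * np.median(rms_all) if n_frames else 0.0
    acs = _dsp.batch_autocorr(frames - frames.mean(axis=1, keepdims=True))

    for i in range(n_frames):
        if rms_all[i] < energy_gate:
            continue
        ac = acs[i]
        if ac[0] <= 0:
            continue
        seg = ac[lag_min : lag_max + 1]
        if len(seg) < 3:
            continue
        k = int(np.argmax(seg)) + lag_min
        if ac[k] < 0.45:
            continue
        # parabolic interpolation around the peak
        if 1 <= k < len(ac) - 1:
            denom = ac[k - 1] - 2 * ac[k] + ac[k + 1]
            shift = 0.5 * (ac[k - 1] - ac[k + 1]) / denom if denom != 0 else 0.0
            k_interp = k + float(np.clip(shift, -1, 1))
        else:
            k_interp = float(k)
        f0[i] = rate / k_interp
        voiced[i] = True

    marks = _cycle_marks(x, rate, f0, voiced, hop, frame_len)
    return F0Contour(f0_hz=f0, voiced=voiced, frame_times=times, cycle_marks=marks)


def _cycle_marks(x, rate, f0, voiced, hop, frame_len) -> np.ndarray:
    """Peak-picking cycle marks inside voiced regions."""
    if not voiced.any():
        return np.array([])
    med_f0 = float(np.nanmedian(f0[voiced]))
    period = int(round(rate / med_f0))
    vi = np.where(voiced)[0]
    lo = vi[0] * hop
    hi = min(vi[-1] * hop + frame_len, len(x))
    seg = x[lo:hi]
    if len(seg) < 2 * period:
        return np.array([])
    peaks, _ = sps.find_peaks(seg, distance=max(int(0.6 * period), 1),
                              height=0.2 * np.abs(seg).max())
    # sub-sample refinement (parabolic) to beat mark quantization
    refined = peaks.astype(float)
    inner = (peaks > 0) & (peaks < len(seg) - 1)
    pk = peaks[inner]
    denom = seg[pk - 1] - 2 * seg[pk] + seg[pk + 1]
    shift = np.where(denom != 0, 0.5 * (seg[pk - 1] - seg[pk + 1]) / denom, 0.0)
    refined[inner] += np.clip(shift, -0.5, 0.5)
    return (refined + lo) / rate


# ---------------------------------------------------------------------------
# period/amplitude perturbation primitives (unit-testable in isolation)

def jitter_measures(periods: np.ndarray) -> dict[str, float]:
    """Praat-style local jitter family from a cycle-period sequence (s)."""
    p = np.asarray(periods, dtype=float)
    out = {k: np.nan for k in ("jitter_local", "jitter_abs", "jitter_rap",
                               "jitter_ppq5", "jitter_ddp", "period_cv",
                               "period_sd", "period_mean")}
    if len(p) < 6 or p.mean() <= 0:
        return out
    mean_p = p.mean()
    absdiff = np.abs(np.diff(p))
    out["jitter_abs"] = float(absdiff.mean())
    out["jitter_local"] = float(absdiff.mean() / mean_p)
    rap = np.abs(p[1:-1] - (p[:-2] + p[1:-1] + p[2:]) / 3.0)
    out["jitter_rap"] = float(rap.mean() / mean_p)
    win = np.lib.stride_tricks.sliding_window_view(p, 5)
    ppq5 = np.abs(p[2:-2] - win.mean(axis=1))
    out["jitter_ppq5"] = float(ppq5.mean() / mean_p)
    out["jitter_ddp"] = 3.0 * out["jitter_rap"]
    out["period_sd"] = float(p.std(ddof=1))
    out["period_cv"] = float(p.std(ddof=1) / mean_p)
    out["period_mean"] = float(mean_p)
    return out


def shimmer_measures(amps: np.ndarray) -> dict[str, float]:
    """Praat-style shimmer family from a cycle-amplitude sequence."""
    a = np.asarray(amps, dtype=float)
    keys = ("shimmer_local", "shimmer_db", "shimmer_apq3", "shimmer_apq5",
            "shimmer_apq11", "shimmer_dda", "amp_cv", "amp_sd", "amp_mean",
            "amp_range")
    out = {k: np.nan for k in keys}
    if len(a) < 12 or a.mean() <= 0 or (a <= 0).any():
        return out
    mean_a = a.mean()
    absdiff = np.abs(np.diff(a))
    out["shimmer_local"] = float(absdiff.mean() / mean_a)
    out["shimmer_db"] = float(np.abs(20 * np.log10(a[1:] / a[:-1])).mean())
    apq3 = np.abs(a[1:-1] - (a[:-2] + a[1:-1] + a[2:]) / 3.0)
    out["shimmer_apq3"] = float(apq3.mean() / mean_a)
    w5 = np.lib.stride_tricks.sliding_window_view(a, 5)
    out["shimmer_apq5"] = float(np.abs(a[2:-2] - w5.mean(axis=1)).mean() / mean_a)
    w11 = np.lib.stride_tricks.sliding_window_view(a, 11)
    out["shimmer_apq11"] = float(np.abs(a[5:-5] - w11.mean(axis=1)).mean() / mean_a)
    out["shimmer_dda"] = 3.0 * out["shimmer_apq3"]
    out["amp_sd"] = float(a.std(ddof=1))
    out["amp_cv"] = float(a.std(ddof=1) / mean_a)
    out["amp_mean"] = float(mean_a)
    out["amp_range"] = float(np.ptp(a))
    return out


def harmonicity(x: np.ndarray, rate: int, contour: F0Contour,
                mask_halfwidth_hz: float = 50.0) -> dict[str, float]:
    """Per-frame spectral HNR summarized mean/SD.

    Per voiced frame, energy within +-50 Hz of the first 10 f0 multiples
    is split into harmonic energy and a noise share estimated from the
    flat out-of-mask noise density; HNR = 10 log10(harmonic/noise),
    clipped to +-60 dB.
    """
    out = {"hnr_mean": np.nan, "hnr_sd": np.nan,
           "nhr_mean": np.nan, "nhr_sd": np.nan}
    frame_len = int(FRAME_S * rate)
    hop = int(HOP_S * rate)
    frames = _dsp.frame_signal(x, frame_len, hop)
    if frames.shape[0] == 0:
        return out
    frames = frames - frames.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(frame_len)))
    spec = np.abs(np.fft.rfft(frames * np.hanning(frame_len), n=nfft, axis=1)) ** 2
    freqs = np.fft.rfftfreq(nfft, 1.0 / rate)
    hnrs = []
    for i in np.where(contour.voiced)[0]:
        if i >= spec.shape[0] or not np.isfinite(contour.f0_hz[i]):
            continue
        f0 = contour.f0_hz[i]
        n_harm = int(min(10, (rate / 2 - mask_halfwidth_hz) // f0))
        if n_harm < 1:
            continue
        harm = np.abs((freqs[None, :] - f0 * np.arange(1, n_harm + 1)[:, None])
                      ) <= mask_halfwidth_hz
        mask = harm.any(axis=0)
        e_in = float(spec[i, mask].sum())
        n_out = int((~mask).sum())
        if n_out < 8:
            continue
        noise_density = float(spec[i, ~mask].sum()) / n_out
        e_noise = noise_density * len(freqs)
        e_harm = max(e_in - noise_density * int(mask.sum()), 0.0)
        ratio = e_harm / max(e_noise, 1e-300)
        ratio = min(max(ratio, 1e-6), 1e6)
        hnrs.append(10.0 * np.log10(ratio))
    if len(hnrs) >= 2:
        hnrs = np.asarray(hnrs)
        nhr = 10.0 ** (-hnrs / 10.0)
        out["hnr_mean"] = float(hnrs.mean())
        out["hnr_sd"] = float(hnrs.std(ddof=1))
        out["nhr_mean"] = float(nhr.mean())
        out["nhr_sd"] = float(nhr.std(ddof=1))
    return out


def pitch_period_entropy(f0: np.ndarray) -> float:
    """Normalized entropy of log-semitone f0 deviations from the median."""
    f0 = f0[np.isfinite(f0)]
    if len(f0) < 10:
        return np.nan
    semitones = 12.0 * np.log2(f0 / np.median(f0))
    # fixed +-4 semitone support, 30 bins
    hist, _ = np.histogram(np.clip(semitones, -4, 4), bins=30, range=(-4, 4))
    return _dsp.shannon_entropy(hist.astype(float), normalize=True)


def _lpc_residual(x: np.ndarray, order: int = 12) -> np.ndarray:
    """Inverse-filter residual via autocorrelation LPC (FFT autocorr)."""
    x = x - x.mean()
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, n=nfft)
    r = np.fft.irfft(spec * np.conj(spec), n=nfft)[: order + 1]
    if r[0] <= 0:
        return x.copy()
    a = solve_toeplitz((r[:order], r[:order]), r[1 : order + 1])
    return sps.lfilter(np.concatenate([[1.0], -a]), [1.0], x)


def vfer_measures(x: np.ndarray, rate: int) -> dict[str, float]:
    """Excitation-ratio features from the LPC residual spectrum (9)."""
    keys = [f"vfer_band{i}" for i in range(1, 6)] + [
        "vfer_entropy", "vfer_low_high", "vfer_snr", "vfer_nsr"]
    out = {k: np.nan for k in keys}
    if len(x) < rate // 2:
        return out
    resid = _lpc_residual(x)
    f, pxx = _dsp.welch_psd(resid, rate, window_s=0.1)
    edges = [0, 500, 1000, 2000, 4000, rate / 2]
    bands = np.array([_dsp.band_power(f, pxx, edges[i], edges[i + 1])
                      for i in range(5)])
    total = bands.sum()
    if total <= 0:
        return out
    for i in range(5):
        out[f"vfer_band{i + 1}"] = float(bands[i] / total)
    out["vfer_entropy"] = _dsp.shannon_entropy(bands)
    hi = bands[2:].sum()
    out["vfer_low_high"] = float(np.log10((bands[:2].sum() + 1e-12) / (hi + 1e-12)))
    e_sig = float(np.mean(x**2))
    e_res = float(np.mean(resid**2))
    out["vfer_snr"] = float(10 * np.log10((e_sig + 1e-12) / (e_res + 1e-12)))
    out["vfer_nsr"] = float(e_res / (e_sig + 1e-12))
    return out


def glottal_quotients(x: np.ndarray, rate: int, marks: np.ndarray) -> dict[str, float]:
    """Cycle-shape quotient stand-ins: open and peak-position quotients."""
    out = {"gq_open_mean": np.nan, "gq_open_sd": np.nan,
           "gq_peak_mean": np.nan, "gq_peak_sd": np.nan}
    if len(marks) < 6:
        return out
    opens, peaks = [], []
    idx = (marks * rate).astype(int)
    for i0, i1 in zip(idx[:-1], idx[1:]):
        cyc = x[i0:i1]
        if len(cyc) < 4:
            continue
        opens.append(float((cyc > np.median(cyc)).mean()))
        peaks.append(float(np.argmax(cyc) / len(cyc)))
    if len(opens) >= 4:
        opens, peaks = np.asarray(opens), np.asarray(peaks)
        out["gq_open_mean"] = float(opens.mean())
        out["gq_open_sd"] = float(opens.std(ddof=1))
        out["gq_peak_mean"] = float(peaks.mean())
        out["gq_peak_sd"] = float(peaks.std(ddof=1))
    return out


_STATS4 = ("mean", "sd", "skew", "kurt")


def _stats4(x: np.ndarray) -> list[float]:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 4:
        return [np.nan] * 4
    return [float(x.mean()), float(x.std(ddof=1)),
            _dsp.safe_skew(x), _dsp.safe_kurtosis(x)]


def _mfcc_features(x: np.ndarray, rate: int) -> dict[str, float]:
    mat = _dsp.mfcc(x, rate)  # (n_frames, 13)
    dmat = _dsp.delta(mat)
    out: dict[str, float] = {}
    for c in range(13):
        for name, val in zip(_STATS4, _stats4(mat[:, c])):
            out[f"mfcc{c}_{name}"] = val
        for name, val in zip(_STATS4, _stats4(dmat[:, c])):
            out[f"dmfcc{c}_{name}"] = val
    return out


def _f0_stats(contour: F0Contour) -> dict[str, float]:
    f0 = contour.f0_hz[contour.voiced]
    keys = ("f0_mean", "f0_sd", "f0_cv", "f0_median", "f0_min", "f0_max",
            "f0_range", "f0_iqr", "f0_slope", "f0_skew", "f0_kurt",
            "f0_voiced_frac")
    out = {k: np.nan for k in keys}
    out["f0_voiced_frac"] = contour.voiced_fraction
    if len(f0) < 4:
        return out
    t = contour.frame_times[contour.voiced]
    out.update(f0_mean=float(f0.mean()), f0_sd=float(f0.std(ddof=1)),
               f0_cv=float(f0.std(ddof=1) / f0.mean()),
               f0_median=float(np.median(f0)), f0_min=float(f0.min()),
               f0_max=float(f0.max()), f0_range=float(np.ptp(f0)),
               f0_iqr=float(np.subtract(*np.percentile(f0, [75, 25]))),
               f0_slope=float(np.polyfit(t, f0, 1)[0]),
               f0_skew=_dsp.safe_skew(f0), f0_kurt=_dsp.safe_kurtosis(f0))
    return out


def _tremor_features(contour: F0Contour, x: np.ndarray, rate: int) -> dict[str, float]:
    """3-15 Hz frequency- and amplitude-modulation of the phonation."""
    out: dict[str, float] = {}
    frame_rate = 1.0 / HOP_S
    frame_len, hop = int(FRAME_S * rate), int(HOP_S * rate)
    frames = _dsp.frame_signal(x, frame_len, hop)
    env = np.sqrt((frames**2).mean(axis=1)) if frames.shape[0] else np.array([])

    for tag, series in (("fm", np.where(contour.voiced, contour.f0_hz, np.nan)),
                        ("am", env)):
        s = np.asarray(series, dtype=float)
        s = s[np.isfinite(s)]
        if len(s) < int(2 * frame_rate):
            out.update({f"tremor_{tag}_power": np.nan,
                        f"tremor_{tag}_relpower": np.nan,
                        f"tremor_{tag}_freq": np.nan,
                        f"tremor_{tag}_depth": np.nan})
            continue
        mu = s.mean()
        s = s - mu
        f, pxx = _dsp.welch_psd(s, frame_rate, window_s=2.0)
        band = _dsp.band_power(f, pxx, 3.0, 15.0)
        total = _dsp.band_power(f, pxx, 0.0, frame_rate / 2)
        mask = (f >= 3.0) & (f < 15.0)
        out[f"tremor_{tag}_power"] = float(np.log10(band + 1e-15))
        out[f"tremor_{tag}_relpower"] = float(band / total) if total > 0 else np.nan
        out[f"tremor_{tag}_freq"] = (float(f[mask][np.argmax(pxx[mask])])
                                     if mask.sum() > 1 else np.nan)
        out[f"tremor_{tag}_depth"] = float(s.std() / abs(mu)) if mu != 0 else np.nan
    return out


def _spectral_shape(x: np.ndarray, rate: int) -> dict[str, float]:
    frame_len, hop = int(FRAME_S * rate), int(HOP_S * rate)
    frames = _dsp.frame_signal(x, frame_len, hop)
    out: dict[str, float] = {}
    if frames.shape[0] < 5:
        for q in ("centroid", "spread", "flux", "rolloff"):
            for s in _STATS4:
                out[f"spec_{q}_{s}"] = np.nan
        return out
    frames = frames * np.hanning(frame_len)
    mag = np.abs(np.fft.rfft(frames, axis=1))
    freqs = np.fft.rfftfreq(frame_len, 1.0 / rate)
    psum = mag.sum(axis=1) + 1e-12
    centroid = (mag * freqs).sum(axis=1) / psum
    spread = np.sqrt((mag * (freqs[None, :] - centroid[:, None]) ** 2).sum(axis=1) / psum)
    cum = np.cumsum(mag, axis=1)
    roll_idx = (cum >= 0.85 * cum[:, -1:]).argmax(axis=1)
    rolloff = freqs[roll_idx]
    norm = mag / (np.linalg.norm(mag, axis=1, keepdims=True) + 1e-12)
    flux = np.r_[0.0, np.linalg.norm(np.diff(norm, axis=0), axis=1)]
    for q, series in (("centroid", centroid), ("spread", spread),
                      ("flux", flux[1:]), ("rolloff", rolloff)):
        for s, v in zip(_STATS4, _stats4(series)):
            out[f"spec_{q}_{s}"] = v
    return out


def _wavelet_series_features(series: np.ndarray, tag: str) -> dict[str, float]:
    """7-band Haar DWT: 5 stats per band + 3 global ratios = 38 features."""
    out: dict[str, float] = {}
    s = np.asarray(series, dtype=float)
    s = s[np.isfinite(s)]
    band_names = [f"d{i}" for i in range(1, 7)] + ["a6"]
    stat_names = ("logE", "entropy", "meanabs", "sd", "skew")
    if len(s) < 16:
        for b in band_names:
            for st in stat_names:
                out[f"wt_{tag}_{b}_{st}"] = np.nan
        for g in ("totent", "d1ratio", "a6ratio"):
            out[f"wt_{tag}_{g}"] = np.nan
        return out
    if len(s) < 64:
        s = np.pad(s, (0, 64 - len(s)), mode="reflect")
    s = s - s.mean()
    bands = _dsp.haar_dwt(s, levels=6)
    energies = []
    for b, coeffs in zip(band_names, bands):
        e = float((coeffs**2).sum())
        energies.append(e)
        out[f"wt_{tag}_{b}_logE"] = float(np.log10(e + 1e-15))
        out[f"wt_{tag}_{b}_entropy"] = _dsp.shannon_entropy(coeffs**2)
        out[f"wt_{tag}_{b}_meanabs"] = float(np.abs(coeffs).mean())
        out[f"wt_{tag}_{b}_sd"] = float(coeffs.std())
        out[f"wt_{tag}_{b}_skew"] = _dsp.safe_skew(coeffs)
    energies = np.asarray(energies)
    tot = energies.sum()
    out[f"wt_{tag}_totent"] = _dsp.shannon_entropy(energies)
    out[f"wt_{tag}_d1ratio"] = float(energies[0] / tot) if tot > 0 else np.nan
    out[f"wt_{tag}_a6ratio"] = float(energies[-1] / tot) if tot > 0 else np.nan
    return out


def voice_feature_names() -> list[str]:
    """Canonical ordered names of the 330 voice features (no prefix)."""
    names: list[str] = []
    names += ["jitter_local", "jitter_abs", "jitter_rap", "jitter_ppq5",
              "jitter_ddp", "period_cv", "period_sd", "period_mean"]
    names += ["shimmer_local", "shimmer_db", "shimmer_apq3", "shimmer_apq5",
              "shimmer_apq11", "shimmer_dda", "amp_cv", "amp_sd", "amp_mean",
              "amp_range"]
    names += ["hnr_mean", "hnr_sd", "nhr_mean", "nhr_sd"]
    names += ["ppe", "rpde", "dfa"]
    names += [f"vfer_band{i}" for i in range(1, 6)]
    names += ["vfer_entropy", "vfer_low_high", "vfer_snr", "vfer_nsr"]
    names += ["gq_open_mean", "gq_open_sd", "gq_peak_mean", "gq_peak_sd"]
    for c in range(13):
        names += [f"mfcc{c}_{s}" for s in _STATS4]
        names += [f"dmfcc{c}_{s}" for s in _STATS4]
    names += ["f0_mean", "f0_sd", "f0_cv", "f0_median", "f0_min", "f0_max",
              "f0_range", "f0_iqr", "f0_slope", "f0_skew", "f0_kurt",
              "f0_voiced_frac"]
    for tag in ("fm", "am"):
        names += [f"tremor_{tag}_power", f"tremor_{tag}_relpower",
                  f"tremor_{tag}_freq", f"tremor_{tag}_depth"]
    for q in ("centroid", "spread", "flux", "rolloff"):
        names += [f"spec_{q}_{s}" for s in _STATS4]
    for tag in ("f0", "df0", "amp", "damp"):
        for b in [f"d{i}" for i in range(1, 7)] + ["a6"]:
            names += [f"wt_{tag}_{b}_{st}"
                      for st in ("logE", "entropy", "meanabs", "sd", "skew")]
        names += [f"wt_{tag}_totent", f"wt_{tag}_d1ratio", f"wt_{tag}_a6ratio"]
    assert len(names) == 330
    return names


def voice_features(voice: VoiceRecording,
                   contour: F0Contour | None = None) -> dict[str, float]:
    """All 330 voice features; NaN-filled when tracking fails."""
    names = voice_feature_names()
    x = np.asarray(voice.samples, dtype=float)
    rate = voice.rate_hz
    if contour is None:
        contour = track_f0(voice)
    feats = dict.fromkeys(names, np.nan)
    if contour.voiced_fraction < VOICED_MIN_FRACTION or len(contour.cycle_marks) < 12:
        return feats

    marks = contour.cycle_marks
    periods = np.diff(marks)
    # cycle amplitude at the mark peak (+-2 samples): symmetric under
    # time reversal, unlike a max over the full inter-mark window
    idx = np.clip(np.round(marks * rate).astype(int), 2, len(x) - 3)
    amps = np.array([np.abs(x[i - 2 : i + 3]).max() for i in idx])
    amps = amps[np.isfinite(amps) & (amps > 0)]

    feats.update(jitter_measures(periods))
    feats.update(shimmer_measures(amps))
    feats.update(harmonicity(x, rate, contour))
    feats["ppe"] = pitch_period_entropy(contour.f0_hz[contour.voiced])

    step = max(len(x) // _RPDE_MAX_SAMPLES, 1)
    mid = x[len(x) // 4 : 3 * len(x) // 4 : step]
    feats["rpde"] = _dsp.rpde(mid)
    xd = x[:: max(len(x) // _DFA_MAX_SAMPLES, 1)]
    feats["dfa"] = _dsp.dfa_exponent(xd)

    feats.update(vfer_measures(x, rate))
    feats.update(glottal_quotients(x, rate, marks))
    feats.update(_mfcc_features(x, rate))
    feats.update(_f0_stats(contour))
    feats.update(_tremor_features(contour, x, rate))
    feats.update(_spectral_shape(x, rate))

    f0v = contour.f0_hz[contour.voiced]
    feats.update(_wavelet_series_features(f0v, "f0"))
    feats.update(_wavelet_series_features(np.diff(f0v), "df0"))
    feats.update(_wavelet_series_features(amps, "amp"))
    feats.update(_wavelet_series_features(np.diff(amps), "damp"))

    out = {k: feats[k] for k in names}
    for k, v in out.items():
        if v is not None and not np.isfinite(v):
            out[k] = np.nan
    return out
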