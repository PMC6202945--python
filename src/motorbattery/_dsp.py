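"""Shared signal-processing and statistics primitives.

Small, dependency-light building blocks used by the feature modules:
framing, Welch band powers, detrended fluctuation analysis, sample
entropy, Higuchi fractal dimension, recurrence measures, a Haar DWT and
a mel-frequency cepstrum. Everything operates on plain numpy arrays.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.fftpack import dct

__all__ = [
    "frame_signal",
    "band_power",
    "spectral_entropy",
    "dfa_exponent",
    "sample_entropy",
    "higuchi_fd",
    "recurrence_rate",
    "rpde",
    "haar_dwt",
    "mfcc",
    "autocorr_at_lag",
    "safe_skew",
    "safe_kurtosis",
    "shannon_entropy",
]


def frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Slice ``x`` into overlapping frames, shape (n_frames, frame_len)."""
    x = np.asarray(x, dtype=float)
    if len(x) < frame_len:
        return np.empty((0, frame_len))
    n_frames = 1 + (len(x) - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def batch_autocorr(frames: np.ndarray) -> np.ndarray:
    """FFT autocorrelation of each row, normalized so lag 0 == 1.

    Rows with zero energy return all-zero autocorrelation.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    n = frames.shape[1]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, :n]
    norm = ac[:, :1].copy()
    norm[norm <= 0] = 1.0
    out = ac / norm
    out[ac[:, 0] <= 0] = 0.0
    return out


def band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Integrate a PSD over [lo, hi) Hz (rectangle rule, so adjacent
    bands tile the total power exactly)."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if len(freqs) < 2:
        return 0.0
    df = float(freqs[1] - freqs[0])
    mask = (freqs >= lo) & (freqs < hi)
    return float(psd[mask].sum() * df)


def spectral_entropy(psd: np.ndarray, normalize: bool = True) -> float:
    """Shannon entropy of a normalized PSD; in [0, 1] when normalized."""
    p = np.asarray(psd, dtype=float)
    p = p[p > 0]
    if p.size < 2:
        return 0.0
    p = p / p.sum()
    h = -np.sum(p * np.log(p))
    if normalize:
        h /= np.log(p.size)
    return float(h)


def shannon_entropy(p: np.ndarray, normalize: bool = True) -> float:
    """Entropy of an arbitrary non-negative weight vector."""
    return spectral_entropy(np.asarray(p, dtype=float), normalize=normalize)


def dfa_exponent(
    x: np.ndarray,
    min_box: int = 50,
    max_box: int = 1000,
    n_boxes: int = 10,
) -> float:
    """Detrended fluctuation analysis scaling exponent.

    Classic DFA-1: integrate the mean-removed series, detrend linearly in
    log-spaced boxes, regress log F(n) on log n. White noise gives ~0.5,
    Brownian noise ~1.5.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 * min_box:
        min_box = max(4, n // 8)
    max_box = min(max_box, n // 4)
    if max_box <= min_box:
        return float("nan")
    y = np.cumsum(x - x.mean())
    sizes = np.unique(
        np.round(np.logspace(np.log10(min_box), np.log10(max_box), n_boxes)).astype(int)
    )
    flucts = []
    t_full = np.arange(n, dtype=float)
    for s in sizes:
        n_seg = n // s
        if n_seg < 2:
            continue
        segs = y[: n_seg * s].reshape(n_seg, s)
        t = t_full[:s]
        # per-segment linear detrend via closed-form least squares
        tm = t.mean()
        tv = ((t - tm) ** 2).sum()
        beta = ((t - tm)[None, :] * segs).sum(axis=1) / tv
        alpha = segs.mean(axis=1) - beta * tm
        resid = segs - (alpha[:, None] + beta[:, None] * t[None, :])
        flucts.append(np.sqrt((resid**2).mean()))
    if len(flucts) < 3:
        return float("nan")
    sizes = sizes[: len(flucts)]
    coeffs = np.polyfit(np.log(sizes), np.log(flucts), 1)
    return float(coeffs[0])


def _embed(x: np.ndarray, m: int, tau: int = 1) -> np.ndarray:
    n = len(x) - (m - 1) * tau
    if n <= 0:
        return np.empty((0, m))
    return np.column_stack([x[i * tau : i * tau + n] for i in range(m)])


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                   max_len: int = 1200) -> float:
    """Sample entropy SampEn(m, r) with Chebyshev distance.

    r defaults to 0.2*SD. Long inputs are decimated to ``max_len`` points
    to bound the O(n^2) pair count.
    """
    x = np.asarray(x, dtype=float)
    if len(x) > max_len:
        step = int(np.ceil(len(x) / max_len))
        x = x[::step]
    n = len(x)
    if n < m + 2:
        return float("nan")
    if r is None:
        r = 0.2 * x.std()
    if r <= 0:
        return float("nan")

    # Chebyshev match of m-windows = AND of the scalar match matrix
    # along its diagonal; build the boolean matrix once and reuse.
    close = np.abs(x[:, None] - x[None, :]) <= r

    def _count(dim: int) -> int:
        ne = n - dim + 1
        b = close[:ne, :ne].copy()
        for k in range(1, dim):
            b &= close[k : k + ne, k : k + ne]
        return int((int(b.sum()) - ne) // 2)  # upper triangle only

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension of a 1-D series."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < kmax * 3:
        return float("nan")
    lk = []
    ks = np.arange(1, kmax + 1)
    for k in ks:
        lengths = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (len(idx) - 1) / k
            lengths.append(dist * norm / k)
        lk.append(np.mean(lengths))
    lk = np.asarray(lk)
    good = lk > 0
    if good.sum() < 3:
        return float("nan")
    coeffs = np.polyfit(np.log(1.0 / ks[good]), np.log(lk[good]), 1)
    return float(coeffs[0])


def recurrence_rate(x: np.ndarray, m: int = 3, r_frac: float = 0.2,
                    max_len: int = 1200) -> float:
    """Fraction of embedded point pairs within r = r_frac*SD (Chebyshev)."""
    x = np.asarray(x, dtype=float)
    if len(x) > max_len:
        step = int(np.ceil(len(x) / max_len))
        x = x[::step]
    sd = x.std()
    if sd == 0:
        return float("nan")
    n = len(x)
    ne = n - m + 1
    if ne < 10:
        return float("nan")
    close = np.abs(x[:, None] - x[None, :]) <= r_frac * sd
    b = close[:ne, :ne].copy()
    for k in range(1, m):
        b &= close[k : k + ne, k : k + ne]
    n_pairs = ne * (ne - 1) // 2
    return float(((int(b.sum()) - ne) // 2) / n_pairs)


def rpde(x: np.ndarray, m: int = 4, tau: int = 8, eps_frac: float = 0.12,
         t_max: int = 400) -> float:
    """Recurrence period density entropy, normalized to [0, 1].

    For each embedded point, the first return time into an eps-ball
    (Chebyshev) is collected; the entropy of the return-time histogram is
    normalized by log(t_max).
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return float("nan")
    x = (x - x.mean()) / sd
    emb = _embed(x, m, tau)
    n = len(emb)
    if n < t_max + 10:
        t_max = max(16, n // 4)
    if n < 32:
        return float("nan")
    eps = eps_frac * np.sqrt(m)  # ball radius in embedded space
    first_ret = np.zeros(n, dtype=int)
    undecided = np.ones(n, dtype=bool)
    for t in range(1, t_max + 1):
        d = np.abs(emb[: n - t] - emb[t:]).max(axis=1)
        hit = np.zeros(n, dtype=bool)
        hit[: n - t] = d <= eps
        newly = undecided & hit
        first_ret[newly] = t
        undecided &= ~hit
    periods = first_ret[first_ret > 0]
    if periods.size < 10:
        return float("nan")
    hist = np.bincount(periods, minlength=t_max + 1)[1:]
    return shannon_entropy(hist.astype(float), normalize=False) / np.log(t_max)


def haar_dwt(x: np.ndarray, levels: int = 6) -> list[np.ndarray]:
    """Multilevel Haar DWT. Returns [d1, d2, ..., dL, aL].

    Input is reflect-padded to an even length at each level.
    """
    a = np.asarray(x, dtype=float)
    out = []
    s = np.sqrt(2.0)
    for _ in range(levels):
        if len(a) < 2:
            out.append(np.zeros(1))
            continue
        if len(a) % 2:
            a = np.concatenate([a, a[-1:]])
        ev, od = a[0::2], a[1::2]
        out.append((ev - od) / s)
        a = (ev + od) / s
    out.append(a)
    return out


def _mel(f: np.ndarray | float) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_inv(m: np.ndarray | float) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, rate_hz: float,
                   f_lo: float = 0.0, f_hi: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, shape (n_filters, n_fft//2 + 1)."""
    if f_hi is None:
        f_hi = rate_hz / 2.0
    f_hi = min(f_hi, rate_hz / 2.0)
    mel_pts = np.linspace(_mel(f_lo), _mel(f_hi), n_filters + 2)
    hz_pts = _mel_inv(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / rate_hz).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        l, c, r = bins[i], bins[i + 1], bins[i + 2]
        c = max(c, l + 1)
        r = max(r, c + 1)
        fb[i, l:c] = (np.arange(l, c) - l) / (c - l)
        fb[i, c:r] = (r - np.arange(c, r)) / (r - c)
    return fb


def mfcc(x: np.ndarray, rate_hz: float, n_coeff: int = 13,
         n_filters: int = 26, frame_s: float = 0.025,
         hop_s: float = 0.010) -> np.ndarray:
    """MFCC matrix (n_frames, n_coeff), c0 included, DCT-II ortho."""
    frame_len = int(round(frame_s * rate_hz))
    hop = int(round(hop_s * rate_hz))
    frames = frame_signal(x, frame_len, hop)
    if frames.shape[0] == 0:
        return np.empty((0, n_coeff))
    frames = frames * np.hanning(frame_len)
    n_fft = int(2 ** np.ceil(np.log2(frame_len)))
    spec = np.abs(np.fft.rfft(frames, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(n_filters, n_fft, rate_hz, f_lo=0.0, f_hi=8000.0)
    mel_energy = spec @ fb.T
    mel_energy = np.maximum(mel_energy, 1e-12)
    return dct(np.log(mel_energy), type=2, axis=1, norm="ortho")[:, :n_coeff]


def delta(series: np.ndarray, width: int = 2) -> np.ndarray:
    """Regression delta coefficients over +-width frames (per column)."""
    series = np.atleast_2d(series)
    n = series.shape[0]
    if n < 2 * width + 1:
        return np.zeros_like(series)
    pad = np.pad(series, ((width, width), (0, 0)), mode="edge")
    num = sum(k * (pad[width + k : width + k + n] - pad[width - k : width - k + n])
              for k in range(1, width + 1))
    den = 2 * sum(k * k for k in range(1, width + 1))
    return num / den


def autocorr_at_lag(x: np.ndarray, lag: int) -> float:
    """Normalized autocorrelation of a mean-removed series at ``lag``."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0 or lag >= len(x) or lag < 1:
        return float("nan")
    return float(np.dot(x[:-lag], x[lag:]) / denom)


def safe_skew(x: np.ndarray) -> float:
    """Biased sample skewness (scipy convention); 0 for degenerate input."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return 0.0
    d = x - x.mean()
    m2 = float((d**2).mean())
    if m2 == 0:
        return 0.0
    return float((d**3).mean() / m2**1.5)


def safe_kurtosis(x: np.ndarray) -> float:
    """Biased excess kurtosis (scipy convention); 0 for degenerate input."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        return 0.0
    d = x - x.mean()
    m2 = float((d**2).mean())
    if m2 == 0:
        return 0.0
    return float((d**4).mean() / m2**2 - 3.0)


def welch_psd(x: np.ndarray, rate_hz: float, window_s: float = 4.0):
    """Welch PSD with Hann windows of ``window_s`` seconds, 50% overlap."""
    nper = min(int(window_s * rate_hz), len(x))
    if nper < 8:
        nper = len(x)
    return sps.welch(x, fs=rate_hz, window="hann", nperseg=nper,
                     noverlap=nper // 2, detrend="constant")
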