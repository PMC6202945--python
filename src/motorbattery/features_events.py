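"""Finger-tapping (60) and reaction-time (20) feature extraction.

Tapping: 40 temporal features on the inter-tap interval (ITI) sequence —
13 descriptive/drift statistics, 4 deficit counts (freezing/hastening
proxies, alternation failures, rate), 7 statistics on each half of the
ITI sequence plus their deltas (fatigue), tap count and duration — and
20 spatial features around the two fixed targets.

Reaction time: descriptive statistics of press and release latencies
(8 each) plus lapse fraction (> 0.5 s), anticipation fraction (< 0.1 s),
press-release mean difference and valid-trial count. Cut-offs are
conventional simple-RT bounds.

Both extractors always emit the full name list; below the minimum event
count every value is NaN. All features are invariant to shifting event
times by a constant.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._dsp import safe_kurtosis, safe_skew
from .synthgen import BUTTON_CENTERS, BUTTON_RADIUS_PX, ReactionEvent, TapEvent

MIN_TAPS = 10
MIN_REACTION_TRIALS = 5
LAPSE_CUTOFF_S = 0.5
ANTICIPATION_CUTOFF_S = 0.1

_HALF_STATS = ("mean", "sd", "cv", "median", "iqr", "min", "max")


def _desc(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return {s: np.nan for s in _HALF_STATS}
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return {"mean": mean, "sd": sd,
            "cv": sd / mean if mean != 0 else np.nan,
            "median": float(np.median(x)),
            "iqr": float(np.subtract(*np.percentile(x, [75, 25]))),
            "min": float(x.min()), "max": float(x.max())}


def _drift_fit(y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, slope t-statistic of y against its index."""
    k = np.arange(len(y), dtype=float)
    res = stats.linregress(k, y)
    tstat = res.slope / res.stderr if res.stderr > 0 else 0.0
    return float(res.slope), float(res.intercept), float(tstat)


def tapping_feature_names() -> list[str]:
    names = ["iti_mean", "iti_sd", "iti_cv", "iti_median", "iti_iqr",
             "iti_min", "iti_max", "iti_skew", "iti_kurt", "iti_rmssd",
             "drift_slope", "drift_intercept", "drift_tstat",
             "n_freeze", "n_hasten", "tap_rate", "n_alt_fail"]
    for half in ("h1", "h2", "delta"):
        names += [f"iti_{half}_{s}" for s in _HALF_STATS]
    names += ["n_taps", "duration_s"]
    for side in ("left", "right"):
        names += [f"dist_{side}_{s}" for s in ("mean", "sd", "median", "max")]
    names += [f"travel_{s}" for s in ("mean", "sd", "median", "max")]
    names += ["xscatter_left", "xscatter_right", "yscatter_left",
              "yscatter_right", "hit_frac_left", "hit_frac_right",
              "centroid_drift_left", "centroid_drift_right"]
    assert len(names) == 60
    return names


def tapping_features(taps: list[TapEvent]) -> dict[str, float]:
    """All 60 tapping features; NaN block below MIN_TAPS events."""
    names = tapping_feature_names()
    out = dict.fromkeys(names, np.nan)
    if len(taps) < MIN_TAPS:
        return out
    taps = sorted(taps, key=lambda e: e.t)
    t = np.array([e.t for e in taps])
    iti = np.diff(t)
    med = float(np.median(iti))

    d = _desc(iti)
    out.update(iti_mean=d["mean"], iti_sd=d["sd"], iti_cv=d["cv"],
               iti_median=d["median"], iti_iqr=d["iqr"], iti_min=d["min"],
               iti_max=d["max"], iti_skew=safe_skew(iti),
               iti_kurt=safe_kurtosis(iti),
               iti_rmssd=float(np.sqrt((np.diff(iti) ** 2).mean())))
    slope, intercept, tstat = _drift_fit(iti)
    out.update(drift_slope=slope, drift_intercept=intercept, drift_tstat=tstat)
    out["n_freeze"] = float((iti > 2 * med).sum())
    out["n_hasten"] = float((iti < 0.5 * med).sum())
    duration = float(t[-1] - t[0])
    out["tap_rate"] = len(taps) / duration if duration > 0 else np.nan
    targets = [e.target_id for e in taps]
    out["n_alt_fail"] = float(sum(a == b for a, b in zip(targets, targets[1:])))

    half = len(iti) // 2
    d1, d2 = _desc(iti[:half]), _desc(iti[half:])
    for s in _HALF_STATS:
        out[f"iti_h1_{s}"] = d1[s]
        out[f"iti_h2_{s}"] = d2[s]
        out[f"iti_delta_{s}"] = (d2[s] - d1[s]
                                 if np.isfinite(d1[s]) and np.isfinite(d2[s])
                                 else np.nan)
    out["n_taps"] = float(len(taps))
    out["duration_s"] = duration

    xy = np.array([[e.x, e.y] for e in taps])
    for side in ("left", "right"):
        sel = np.array([e.target_id == side for e in taps])
        if sel.sum() < 2:
            continue
        cx, cy = BUTTON_CENTERS[side]
        pts = xy[sel]
        dist = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        out[f"dist_{side}_mean"] = float(dist.mean())
        out[f"dist_{side}_sd"] = float(dist.std(ddof=1))
        out[f"dist_{side}_median"] = float(np.median(dist))
        out[f"dist_{side}_max"] = float(dist.max())
        out[f"xscatter_{side}"] = float(pts[:, 0].std(ddof=1))
        out[f"yscatter_{side}"] = float(pts[:, 1].std(ddof=1))
        out[f"hit_frac_{side}"] = float((dist <= BUTTON_RADIUS_PX).mean())
        h = len(pts) // 2
        if h >= 1:
            c1 = pts[:h].mean(axis=0)
            c2 = pts[h:].mean(axis=0)
            out[f"centroid_drift_{side}"] = float(np.hypot(*(c2 - c1)))
    travel = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
    out["travel_mean"] = float(travel.mean())
    out["travel_sd"] = float(travel.std(ddof=1))
    out["travel_median"] = float(np.median(travel))
    out["travel_max"] = float(travel.max())
    return out


def reaction_feature_names() -> list[str]:
    names = []
    for kind in ("press", "release"):
        names += [f"{kind}_{s}" for s in ("mean", "sd", "median", "iqr",
                                          "min", "max", "skew", "slope")]
    names += ["lapse_frac", "anticip_frac", "press_release_diff", "n_valid"]
    assert len(names) == 20
    return names


def reaction_features(events: list[ReactionEvent]) -> dict[str, float]:
    """All 20 reaction-time features; NaN block below 5 valid trials."""
    names = reaction_feature_names()
    out = dict.fromkeys(names, np.nan)
    valid = [e for e in events
             if e.press_t >= e.stim_on_t and e.release_t >= e.stim_off_t]
    if len(valid) < MIN_REACTION_TRIALS:
        return out
    press = np.array([e.press_t - e.stim_on_t for e in valid])
    release = np.array([e.release_t - e.stim_off_t for e in valid])
    for kind, lat in (("press", press), ("release", release)):
        d = _desc(lat)
        for s in ("mean", "sd", "median", "iqr", "min", "max"):
            out[f"{kind}_{s}"] = d[s]
        out[f"{kind}_skew"] = safe_skew(lat)
        out[f"{kind}_slope"] = _drift_fit(lat)[0]
    out["lapse_frac"] = float((press > LAPSE_CUTOFF_S).mean())
    out["anticip_frac"] = float((press < ANTICIPATION_CUTOFF_S).mean())
    out["press_release_diff"] = float(press.mean() - release.mean())
    out["n_valid"] = float(len(valid))
    return out
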