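"""End-to-end extraction: Session -> 998-feature vector / cohort matrix.

Feature layout (canonical order, prefix = task):

    voice.*      330
    tap.*         60
    rt.*          20
    balance.*    147
    gait.*       147
    rest.*       147
    postural.*   147
    total        998
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import features_events, features_motion, features_voice
from .sessionio import SegmentationConfig, apply_segmentation
from .synthgen import Session

#: session-vector prefix for each task, in canonical column order
TASK_PREFIXES = (
    ("voice", "voice"),
    ("tapping", "tap"),
    ("reaction", "rt"),
    ("balance", "balance"),
    ("gait", "gait"),
    ("rest_tremor", "rest"),
    ("postural_tremor", "postural"),
)
PREFIX_TO_TASK = {p: t for t, p in TASK_PREFIXES}

META_COLUMNS = ("subject_id", "group", "sex", "session_time")


def feature_names() -> list[str]:
    """The 998 canonical feature column names, in order."""
    names: list[str] = []
    names += [f"voice.{n}" for n in features_voice.voice_feature_names()]
    names += [f"tap.{n}" for n in features_events.tapping_feature_names()]
    names += [f"rt.{n}" for n in features_events.reaction_feature_names()]
    for task, prefix in TASK_PREFIXES[3:]:
        names += [f"{prefix}.{n}" for n in features_motion.motion_feature_names(task)]
    assert len(names) == 998
    return names


def extract_session(session: Session,
                    config: SegmentationConfig | None = None) -> dict[str, float]:
    """Segment one session and compute all 998 features.

    Tasks failing QC contribute NaN blocks; the name set is constant.
    """
    trimmed, segs = apply_segmentation(session, config)
    out: dict[str, float] = {}

    if segs["voice"].qc_pass:
        vfeat = features_voice.voice_features(trimmed.voice)
    else:
        vfeat = dict.fromkeys(features_voice.voice_feature_names(), np.nan)
    out.update({f"voice.{k}": v for k, v in vfeat.items()})

    if segs["tapping"].qc_pass:
        tfeat = features_events.tapping_features(trimmed.taps)
    else:
        tfeat = dict.fromkeys(features_events.tapping_feature_names(), np.nan)
    out.update({f"tap.{k}": v for k, v in tfeat.items()})

    if segs["reaction"].qc_pass:
        rfeat = features_events.reaction_features(trimmed.reactions)
    else:
        rfeat = dict.fromkeys(features_events.reaction_feature_names(), np.nan)
    out.update({f"rt.{k}": v for k, v in rfeat.items()})

    for task, prefix in TASK_PREFIXES[3:]:
        if segs[task].qc_pass:
            mfeat = features_motion.motion_features(trimmed.accel[task], task)
        else:
            mfeat = dict.fromkeys(features_motion.motion_feature_names(task), np.nan)
        out.update({f"{prefix}.{k}": v for k, v in mfeat.items()})

    assert list(out) == feature_names()
    return out


def extract_cohort(subjects: pd.DataFrame, sessions: list[Session],
                   config: SegmentationConfig | None = None) -> pd.DataFrame:
    """Feature matrix: one row per session, meta columns + 998 features."""
    meta = subjects.set_index("subject_id")
    rows = []
    for ses in sessions:
        row: dict[str, object] = {
            "subject_id": ses.subject_id,
            "group": meta.loc[ses.subject_id, "group"],
            "sex": meta.loc[ses.subject_id, "sex"],
            "session_time": ses.session_time,
        }
        row.update(extract_session(ses, config))
        rows.append(row)
    return pd.DataFrame(rows)


def split_matrix(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Return (df, feature column list); validates uniqueness."""
    cols = [c for c in df.columns if c not in META_COLUMNS]
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate feature columns")
    return df, cols
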