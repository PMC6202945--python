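"""Balanced random-forest discrimination with cross-validated
sensitivity/specificity, randomized baselines and mismatch diagnostics.

Pairwise contrasts: control_vs_irbd, control_vs_pd, irbd_vs_pd. The
positive (sensitivity) class is the disease class — iRBD against
controls, PD otherwise. Schemes: kfold10 (plain shuffled 10-fold over
recordings), loso (every subject held out once per repetition), loo
(single random recordings held out; optionally first-recording-only).

Per CV iteration, everything is fit on the training split alone:
imputation medians, standardization, the 5-algorithm ranking + majority
vote and the forest. A validation fold lacking one class yields a
missing sensitivity or specificity for that iteration, excluded from
the mean/SD with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from . import selection
from .extract import META_COLUMNS

logger = logging.getLogger(__name__)

CONTRASTS = {
    "control_vs_irbd": ("control", "irbd"),
    "control_vs_pd": ("control", "pd"),
    "irbd_vs_pd": ("irbd", "pd"),
}
#: positive (sensitivity) class per contrast
POSITIVE_CLASS = {
    "control_vs_irbd": "irbd",
    "control_vs_pd": "pd",
    "irbd_vs_pd": "pd",
}
SWEEP_COUNTS = tuple(range(2, 31, 2))  # 15 points


@dataclass
class CVConfig:
    contrast: str = "control_vs_pd"
    scheme: str = "kfold10"  # kfold10 | loso | loo
    repetitions: int = 10
    n_features: int | str = 30  # int or "all"
    sex_filter: str = "all"  # all | female | male
    seed: int = 0
    n_trees: int = 500
    max_greedy: int = 60
    loo_draws: int = 100
    loo_first_recording_only: bool = False

    def validate(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if self.scheme not in ("kfold10", "loso", "loo"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.sex_filter not in ("all", "female", "male"):
            raise ValueError(f"unknown sex_filter {self.sex_filter!r}")
        if self.n_features != "all":
            if not isinstance(self.n_features, (int, np.integer)) or self.n_features < 1:
                raise ValueError("n_features must be a positive int or 'all'")


@dataclass
class IterationRecord:
    repetition: int
    fold: int
    sensitivity: float  # NaN when undefined
    specificity: float
    n_validation: int
    n_pos: int
    n_neg: int
    selected_features: list[str] = field(default_factory=list)
    train_median_checksum: float = 0.0


@dataclass
class CVResult:
    config: CVConfig
    iterations: list[IterationRecord]
    n_undefined_sens: int = 0
    n_undefined_spec: int = 0

    @property
    def sensitivities(self) -> np.ndarray:
        return np.array([r.sensitivity for r in self.iterations])

    @property
    def specificities(self) -> np.ndarray:
        return np.array([r.specificity for r in self.iterations])

    @property
    def accuracies(self) -> np.ndarray:
        """Per-iteration balanced accuracy (sens+spec)/2."""
        return (self.sensitivities + self.specificities) / 2.0

    def summary(self) -> dict[str, float]:
        sens, spec = self.sensitivities, self.specificities
        return {
            "sens_mean": float(np.nanmean(sens)) if np.isfinite(sens).any() else np.nan,
            "sens_sd": float(np.nanstd(sens, ddof=1)) if np.isfinite(sens).sum() > 1 else np.nan,
            "spec_mean": float(np.nanmean(spec)) if np.isfinite(spec).any() else np.nan,
            "spec_sd": float(np.nanstd(spec, ddof=1)) if np.isfinite(spec).sum() > 1 else np.nan,
            "n_iterations": len(self.iterations),
        }

    def to_frame(self) -> pd.DataFrame:
        cfg = self.config
        return pd.DataFrame([{
            "contrast": cfg.contrast, "scheme": cfg.scheme,
            "sex_filter": cfg.sex_filter, "n_features": cfg.n_features,
            "repetition": r.repetition, "fold": r.fold,
            "sensitivity": r.sensitivity, "specificity": r.specificity,
            "n_validation": r.n_validation,
        } for r in self.iterations])


def _feature_cols(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in META_COLUMNS]


def balanced_subsample(df: pd.DataFrame, contrast: str,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Downsample both contrast groups to the minority recording count."""
    g0, g1 = CONTRASTS[contrast]
    sizes = {}
    for g in (g0, g1):
        idx = df.index[df["group"] == g]
        if len(idx) == 0:
            raise ValueError(f"group {g!r} has no recordings")
        sizes[g] = len(idx)
    n = min(sizes.values())
    take: list[np.ndarray] = []
    for g in (g0, g1):
        idx = df.index[df["group"] == g].to_numpy()
        take.append(rng.choice(idx, size=n, replace=False))
    # original row order, so the subsample is invariant to relabelings
    # that keep group sizes (clean mutation testing of CV splits)
    keep = np.sort(np.concatenate(take))
    return df.loc[keep].reset_index(drop=True)


def _apply_sex_filter(df: pd.DataFrame, sex_filter: str) -> pd.DataFrame:
    if sex_filter == "all":
        return df
    out = df[df["sex"] == sex_filter]
    if len(out) == 0:
        raise ValueError(f"no recordings left after sex filter {sex_filter!r}")
    return out


def _splits(df: pd.DataFrame, cfg: CVConfig, rng: np.random.Generator):
    """Yield (repetition, fold, train_idx, val_idx) positional indices."""
    n = len(df)
    for rep in range(cfg.repetitions):
        if cfg.scheme == "kfold10":
            perm = rng.permutation(n)
            folds = np.array_split(perm, 10)
            for k, val in enumerate(folds):
                if len(val) == 0:
                    continue
                train = np.setdiff1d(perm, val)
                yield rep, k, train, val
        elif cfg.scheme == "loso":
            subjects = df["subject_id"].to_numpy()
            order = rng.permutation(np.unique(subjects))
            for k, sid in enumerate(order):
                val = np.where(subjects == sid)[0]
                train = np.where(subjects != sid)[0]
                if len(train) == 0:
                    continue
                yield rep, k, train, val
        else:  # loo
            pool = np.arange(n)
            draws = min(cfg.loo_draws, n)
            chosen = rng.choice(pool, size=draws, replace=False)
            for k, i in enumerate(chosen):
                val = np.array([i])
                train = np.setdiff1d(pool, val)
                yield rep, k, train, val


def _first_recordings_only(df: pd.DataFrame) -> pd.DataFrame:
    order = df.sort_values(["subject_id", "session_time"])
    return order.groupby("subject_id", as_index=False).head(1).reset_index(drop=True)


def run_cv(df: pd.DataFrame, cfg: CVConfig,
           record_artifacts: bool = False) -> CVResult:
    """Full leakage-free CV loop; deterministic under cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    df = _apply_sex_filter(df, cfg.sex_filter)
    if cfg.scheme == "loo" and cfg.loo_first_recording_only:
        df = _first_recordings_only(df)

    cols = _feature_cols(df)
    pos_class = POSITIVE_CLASS[cfg.contrast]
    result = CVResult(config=cfg, iterations=[])

    for rep in range(cfg.repetitions):
        rep_rng = np.random.default_rng([cfg.seed, rep])
        bal = balanced_subsample(df, cfg.contrast, rep_rng)
        y_all = (bal["group"] == pos_class).to_numpy().astype(int)
        one_rep = replace(cfg, repetitions=1)
        for _, fold, tr, va in _splits(bal, one_rep, rep_rng):
            train_df, val_df = bal.iloc[tr], bal.iloc[va]
            y_tr, y_va = y_all[tr], y_all[va]

            train_imp, medians = selection.impute(train_df, feature_cols=cols)
            val_imp, _ = selection.impute(train_df, val_df, feature_cols=cols)
            x_tr = train_imp[cols].to_numpy(dtype=float)
            x_va = val_imp[cols].to_numpy(dtype=float)
            x_tr_s, x_va_s = selection.standardize(x_tr, x_va)

            if cfg.n_features == "all" or int(cfg.n_features) >= len(cols):
                top_idx = np.arange(len(cols))
                selected = list(cols)
            else:
                ranking = selection.rank_features(
                    x_tr_s, y_tr, cols, contrast=cfg.contrast,
                    max_greedy=cfg.max_greedy, seed=cfg.seed)
                order = np.argsort(ranking.unified)
                top_idx = order[: int(cfg.n_features)]
                selected = [cols[i] for i in top_idx]

            clf = RandomForestClassifier(
                n_estimators=cfg.n_trees, max_features="sqrt",
                random_state=int(rep_rng.integers(2**31 - 1)), n_jobs=1)
            clf.fit(x_tr_s[:, top_idx], y_tr)
            pred = clf.predict(x_va_s[:, top_idx])

            sens, spec = _sens_spec(y_va, pred)
            if np.isnan(sens):
                result.n_undefined_sens += 1
            if np.isnan(spec):
                result.n_undefined_spec += 1
            rec = IterationRecord(
                repetition=rep, fold=fold, sensitivity=sens, specificity=spec,
                n_validation=len(va), n_pos=int(y_va.sum()),
                n_neg=int((1 - y_va).sum()))
            if record_artifacts:
                rec.selected_features = selected
                rec.train_median_checksum = float(np.nansum(medians.to_numpy()))
            result.iterations.append(rec)
    if result.n_undefined_sens or result.n_undefined_spec:
        logger.info("undefined rates: %d sens, %d spec (excluded from summary)",
                    result.n_undefined_sens, result.n_undefined_spec)
    return result


def _sens_spec(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    pos = y_true == 1
    neg = ~pos
    sens = float((y_pred[pos] == 1).mean()) if pos.any() else float("nan")
    spec = float((y_pred[neg] == 0).mean()) if neg.any() else float("nan")
    return sens, spec


def randomized_baseline(df: pd.DataFrame, cfg: CVConfig,
                        seed: int | None = None) -> CVResult:
    """Same balanced splits, predictions drawn uniformly at random."""
    cfg.validate()
    base_seed = cfg.seed if seed is None else seed
    pred_rng = np.random.default_rng([base_seed, 987654321])
    df = _apply_sex_filter(df, cfg.sex_filter)
    if cfg.scheme == "loo" and cfg.loo_first_recording_only:
        df = _first_recordings_only(df)
    pos_class = POSITIVE_CLASS[cfg.contrast]
    result = CVResult(config=cfg, iterations=[])
    for rep in range(cfg.repetitions):
        rep_rng = np.random.default_rng([cfg.seed, rep])
        bal = balanced_subsample(df, cfg.contrast, rep_rng)
        y_all = (bal["group"] == pos_class).to_numpy().astype(int)
        one_rep = replace(cfg, repetitions=1)
        for _, fold, tr, va in _splits(bal, one_rep, rep_rng):
            pred = pred_rng.integers(0, 2, size=len(va))
            sens, spec = _sens_spec(y_all[va], pred)
            result.iterations.append(IterationRecord(
                repetition=rep, fold=fold, sensitivity=sens,
                specificity=spec, n_validation=len(va),
                n_pos=int(y_all[va].sum()), n_neg=int((1 - y_all[va]).sum())))
    return result


def ks_compare(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test on finite values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 5 or len(b) < 5:
        raise ValueError("ks_compare requires n >= 5 per sample")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def sweep_features(df: pd.DataFrame, cfg: CVConfig,
                   include_all: bool = False) -> list[CVResult]:
    """CVResults at n_features = 2, 4, ..., 30 (+ optional 'all')."""
    results = []
    for k in SWEEP_COUNTS:
        results.append(run_cv(df, replace(cfg, n_features=int(k))))
    if include_all:
        results.append(run_cv(df, replace(cfg, n_features="all")))
    return results


def mismatch_diagnostic(train: pd.DataFrame, validation: pd.DataFrame,
                        feature_cols: list[str] | None = None,
                        threshold: float = 25.0) -> dict:
    """Per-feature % of validation values outside the train [min, max].

    Returns per-feature percentages, their mean, and an
    ``unreliable_validation`` flag when the mean exceeds ``threshold``.
    """
    if len(train) == 0 or len(validation) == 0:
        raise ValueError("mismatch_diagnostic requires non-empty splits")
    if feature_cols is None:
        feature_cols = _feature_cols(train)
    missing = set(feature_cols) - set(validation.columns)
    if missing:
        raise ValueError(f"validation lacks columns: {sorted(missing)[:5]}")
    per_feature: dict[str, float] = {}
    for c in feature_cols:
        tr = train[c].to_numpy(dtype=float)
        va = validation[c].to_numpy(dtype=float)
        tr = tr[np.isfinite(tr)]
        va = va[np.isfinite(va)]
        if len(tr) == 0 or len(va) == 0:
            per_feature[c] = float("nan")
            continue
        lo, hi = tr.min(), tr.max()
        per_feature[c] = float(((va < lo) | (va > hi)).mean() * 100.0)
    vals = np.array([v for v in per_feature.values() if np.isfinite(v)])
    mean_pct = float(vals.mean()) if len(vals) else float("nan")
    return {"per_feature": per_feature, "mean_pct": mean_pct,
            "threshold_pct": threshold,
            "unreliable_validation": bool(mean_pct > threshold)}


def cv_mismatch(df: pd.DataFrame, cfg: CVConfig) -> dict:
    """Mean train/validation mismatch over the splits of one CV config."""
    cfg.validate()
    df = _apply_sex_filter(df, cfg.sex_filter)
    cols = _feature_cols(df)
    pcts = []
    for rep in range(cfg.repetitions):
        rep_rng = np.random.default_rng([cfg.seed, rep])
        bal = balanced_subsample(df, cfg.contrast, rep_rng)
        one_rep = replace(cfg, repetitions=1)
        for _, _, tr, va in _splits(bal, one_rep, rep_rng):
            diag = mismatch_diagnostic(bal.iloc[tr], bal.iloc[va], cols)
            pcts.append(diag["mean_pct"])
    mean_pct = float(np.nanmean(pcts))
    return {"scheme": cfg.scheme, "mean_pct": mean_pct,
            "per_split_pct": pcts,
            "unreliable_validation": bool(mean_pct > 25.0)}
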