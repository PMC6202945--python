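"""Imputation, 5-algorithm feature ranking and majority-vote aggregation.

Algorithms (each produces a full permutation of the feature set, rank 1
= most informative; greedy stages run to ``max_greedy`` selections and
rank the remainder by the algorithm's own residual score):

1. ``lasso``  — order of entry along the LASSO regularization path
   (LARS on +-1 labels); never-entered features by |correlation|.
2. ``mrmr``   — greedy maximal relevance (mutual information with the
   label, equal-frequency discretization) minus mean redundancy.
3. ``relief`` — RELIEF-F weights, k = 10 nearest hits/misses.
4. ``gso``    — greedy forward correlation with Gram-Schmidt
   residualization of already-chosen features.
5. ``llbfs``  — local-learning margin weights (iterative, L1-shrunk).

Majority voting: features ordered by the median of the 5 ranks; ties
broken by mean rank, then best single rank, then column order. Constant
columns are ranked last by every algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import lars_path

logger = logging.getLogger(__name__)

ALGORITHMS = ("lasso", "mrmr", "relief", "gso", "llbfs")


@dataclass
class RankingResult:
    """Per-algorithm and unified ranks (permutations of 1..p)."""

    feature_names: list[str]
    ranks: dict[str, np.ndarray]  # algo -> rank vector, 1 = best
    unified: np.ndarray
    contrast: str = ""

    def top(self, k: int) -> list[str]:
        order = np.argsort(self.unified)
        return [self.feature_names[i] for i in order[:k]]

    def to_frame(self) -> pd.DataFrame:
        data = {"feature": self.feature_names}
        for a in ALGORITHMS:
            data[a] = self.ranks[a]
        data["unified"] = self.unified
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# imputation

def impute(train: pd.DataFrame, apply_to: pd.DataFrame | None = None,
           feature_cols: list[str] | None = None
           ) -> tuple[pd.DataFrame, pd.Series]:
    """Median imputation fit on ``train`` only (no leakage).

    Returns the imputed copy of ``apply_to`` (default: train itself) and
    the medians used. Columns entirely missing in train are filled with
    0 and logged.
    """
    if len(train) == 0:
        raise ValueError("empty training matrix")
    if feature_cols is None:
        feature_cols = list(train.columns)
    medians = train[feature_cols].median(axis=0, skipna=True)
    all_missing = medians.index[medians.isna()]
    if len(all_missing):
        logger.warning("%d columns all-missing in train; filled with 0",
                       len(all_missing))
        medians = medians.fillna(0.0)
    target = train if apply_to is None else apply_to
    out = target.copy()
    out[feature_cols] = target[feature_cols].fillna(medians)
    return out, medians


def standardize(train: np.ndarray, *apply_to: np.ndarray):
    """Z-score using train statistics; constant columns left at 0."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    outs = [(train - mu) / sd_safe]
    outs += [(a - mu) / sd_safe for a in apply_to]
    return outs if len(outs) > 1 else outs[0]


# ---------------------------------------------------------------------------
# individual ranking algorithms. Each returns a score (higher = better)
# plus an optional partial order for its greedy prefix.

def _scores_to_ranks(scores: np.ndarray, prefix_order: list[int] | None = None,
                     constant: np.ndarray | None = None) -> np.ndarray:
    """Convert scores (+ optional greedy prefix) to a 1..p permutation.

    Prefix features take ranks 1..len(prefix); the rest are ordered by
    descending score, ties by column order; constant columns go last.
    """
    p = len(scores)
    scores = np.where(np.isfinite(scores), scores, -np.inf)
    if constant is not None:
        scores = np.where(constant, -np.inf, scores)
    order: list[int] = list(prefix_order or [])
    chosen = set(order)
    rest = [i for i in range(p) if i not in chosen]
    rest.sort(key=lambda i: (-scores[i], i))
    order += rest
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    return ranks


def _rank_lasso(x: np.ndarray, y: np.ndarray, max_greedy: int) -> np.ndarray:
    yy = np.where(y > 0, 1.0, -1.0)
    corr = np.abs(x.T @ yy) / len(yy)
    constant = x.std(axis=0) == 0
    try:
        _, _, coefs = lars_path(x, yy, method="lasso",
                                max_iter=min(2 * max_greedy, x.shape[1]))
        entered = np.argmax(coefs != 0, axis=1).astype(float)
        entered[(coefs == 0).all(axis=1)] = np.inf
        prefix = [int(i) for i in np.argsort(entered, kind="stable")
                  if np.isfinite(entered[i])]
    except Exception as exc:  # pragma: no cover - numerical corner cases
        logger.warning("lars_path failed (%s); falling back to correlation", exc)
        prefix = []
    return _scores_to_ranks(corr, prefix_order=prefix[:max_greedy],
                            constant=constant)


def _discretize(x: np.ndarray, bins: int = 10) -> np.ndarray:
    """Equal-frequency binning per column, int codes in [0, bins)."""
    n, p = x.shape
    out = np.empty((n, p), dtype=np.int64)
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1], axis=0)
    for j in range(p):
        out[:, j] = np.searchsorted(np.unique(qs[:, j]), x[:, j], side="right")
    return out


def _mi_from_codes(a: np.ndarray, b: np.ndarray, ka: int, kb: int) -> float:
    joint = np.bincount(a * kb + b, minlength=ka * kb).astype(float)
    joint = joint.reshape(ka, kb) / len(a)
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def _mi_matrix_vs(codes: np.ndarray, target: np.ndarray, k_codes: int,
                  k_target: int) -> np.ndarray:
    """MI of every column of ``codes`` with one code vector ``target``."""
    n, p = codes.shape
    out = np.empty(p)
    for j in range(p):
        out[j] = _mi_from_codes(codes[:, j], target, k_codes, k_target)
    return out


def _rank_mrmr(x: np.ndarray, y: np.ndarray, max_greedy: int,
               bins: int = 10) -> np.ndarray:
    n, p = x.shape
    constant = x.std(axis=0) == 0
    codes = _discretize(x, bins)
    ycodes = y.astype(np.int64)
    relevance = _mi_matrix_vs(codes, ycodes, bins + 1, 2)
    k = min(max_greedy, p)
    selected: list[int] = []
    red_sum = np.zeros(p)
    avail = np.where(~constant)[0].tolist() or list(range(p))
    score0 = relevance.copy()
    first = max(avail, key=lambda j: (score0[j], -j))
    selected.append(first)
    while len(selected) < k:
        last = selected[-1]
        red_sum += _mi_matrix_vs(codes, codes[:, last], bins + 1, bins + 1)
        best, best_val = -1, -np.inf
        for j in avail:
            if j in selected:
                continue
            val = relevance[j] - red_sum[j] / len(selected)
            if val > best_val:
                best, best_val = j, val
        if best < 0:
            break
        selected.append(best)
    return _scores_to_ranks(relevance, prefix_order=selected, constant=constant)


def _rank_relief(x: np.ndarray, y: np.ndarray, max_greedy: int,
                 k: int = 10, rng: np.random.Generator | None = None
                 ) -> np.ndarray:
    n, p = x.shape
    constant = x.std(axis=0) == 0
    scale = np.ptp(x, axis=0)
    scale[scale == 0] = 1.0
    xs = x / scale
    # squared euclidean distances
    sq = (xs**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * xs @ xs.T
    np.fill_diagonal(d2, np.inf)
    w = np.zeros(p)
    for cls in (0, 1):
        idx_same = np.where(y == cls)[0]
        idx_other = np.where(y != cls)[0]
        if len(idx_same) < 2 or len(idx_other) < 1:
            continue
        for i in idx_same:
            kh = min(k, len(idx_same) - 1)
            km = min(k, len(idx_other))
            hits = idx_same[np.argsort(d2[i, idx_same])[:kh]]
            misses = idx_other[np.argsort(d2[i, idx_other])[:km]]
            w -= np.abs(xs[i] - xs[hits]).mean(axis=0)
            w += np.abs(xs[i] - xs[misses]).mean(axis=0)
    return _scores_to_ranks(w / n, constant=constant)


def _rank_gso(x: np.ndarray, y: np.ndarray, max_greedy: int) -> np.ndarray:
    n, p = x.shape
    constant = x.std(axis=0) == 0
    yy = np.where(y > 0, 1.0, -1.0)
    yy = yy - yy.mean()
    r = x.copy()
    selected: list[int] = []
    final_score = np.zeros(p)
    k = min(max_greedy, p)
    for _ in range(k):
        norms = np.linalg.norm(r, axis=0)
        ok = norms > 1e-10
        scores = np.zeros(p)
        scores[ok] = np.abs(r[:, ok].T @ yy) / (norms[ok] * np.linalg.norm(yy))
        scores[constant] = -np.inf
        for j in selected:
            scores[j] = -np.inf
        best = int(np.argmax(scores))
        if not np.isfinite(scores[best]) or scores[best] <= 0:
            break
        if not selected:
            final_score[:] = np.where(np.isfinite(scores), scores, 0.0)
        selected.append(best)
        u = r[:, best] / norms[best]
        r = r - np.outer(u, u @ r)
    # remaining features scored by current residual correlation
    norms = np.linalg.norm(r, axis=0)
    ok = norms > 1e-10
    rest_score = np.zeros(p)
    rest_score[ok] = np.abs(r[:, ok].T @ yy) / (norms[ok] * np.linalg.norm(yy))
    return _scores_to_ranks(rest_score, prefix_order=selected, constant=constant)


def _rank_llbfs(x: np.ndarray, y: np.ndarray, max_greedy: int,
                n_iter: int = 4, lam: float = 1.0) -> np.ndarray:
    """Local-learning margin weights with multiplicative L1 shrinkage."""
    n, p = x.shape
    constant = x.std(axis=0) == 0
    w = np.ones(p)
    for _ in range(n_iter):
        xw = x * w
        sq = (xw**2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2 * xw @ xw.T
        np.fill_diagonal(d2, np.inf)
        z = np.zeros(p)
        for i in range(n):
            same = np.where(y == y[i])[0]
            other = np.where(y != y[i])[0]
            same = same[same != i]
            if len(same) == 0 or len(other) == 0:
                continue
            nh = same[np.argmin(d2[i, same])]
            nm = other[np.argmin(d2[i, other])]
            z += np.abs(x[i] - x[nm]) - np.abs(x[i] - x[nh])
        z /= n
        # gradient of logistic margin objective wrt w (w >= 0)
        margin = float(w @ z)
        sig = 1.0 / (1.0 + np.exp(np.clip(margin, -30, 30)))
        grad = sig * z - lam / max(p, 1)
        w = np.maximum(w + 0.5 * grad, 0.0)
        if w.sum() == 0:
            w = np.ones(p)
            break
    return _scores_to_ranks(w, constant=constant)


_RANKERS = {"lasso": _rank_lasso, "mrmr": _rank_mrmr, "relief": _rank_relief,
            "gso": _rank_gso, "llbfs": _rank_llbfs}


def majority_vote(rank_vectors: np.ndarray) -> np.ndarray:
    """Unified permutation from an (n_algorithms, p) rank array.

    Order by median rank; ties by mean rank, then best single rank,
    then column order.
    """
    ranks = np.asarray(rank_vectors)
    if ranks.ndim != 2:
        raise ValueError("expected a 2-D (n_algorithms, p) rank array")
    p = ranks.shape[1]
    for row in ranks:
        if sorted(row) != list(range(1, p + 1)):
            raise ValueError("each rank vector must be a permutation of 1..p")
    med = np.median(ranks, axis=0)
    mean = ranks.mean(axis=0)
    best = ranks.min(axis=0)
    order = sorted(range(p), key=lambda j: (med[j], mean[j], best[j], j))
    unified = np.empty(p, dtype=int)
    unified[order] = np.arange(1, p + 1)
    return unified


def rank_features(x: np.ndarray, y: np.ndarray, feature_names: list[str],
                  contrast: str = "", max_greedy: int = 60,
                  seed: int = 0) -> RankingResult:
    """Run all 5 algorithms on standardized training data + majority vote.

    ``x``: (n, p) imputed training features (standardized internally);
    ``y``: binary labels (0/1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    xs = standardize(x)
    ranks: dict[str, np.ndarray] = {}
    for algo in ALGORITHMS:
        ranks[algo] = _RANKERS[algo](xs, y, max_greedy)
    unified = majority_vote(np.vstack([ranks[a] for a in ALGORITHMS]))
    return RankingResult(feature_names=list(feature_names), ranks=ranks,
                         unified=unified, contrast=contrast)
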