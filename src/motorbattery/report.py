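"""Summary artifacts: task-salience breakdowns, accuracy-vs-feature-count
curve tables and plain-text run reports.

All numbers are re-derivations of the tidy iteration-level CSVs (no
recomputation of the underlying models), so re-rendering is
byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .classify import CVResult
from .extract import PREFIX_TO_TASK
from .selection import RankingResult

#: display order of the 7 tasks in salience tables
TASK_DISPLAY = ("voice", "balance", "gait", "tapping", "reaction",
                "rest_tremor", "postural_tremor")
_PREFIX_FOR_TASK = {"voice": "voice", "balance": "balance", "gait": "gait",
                    "tapping": "tap", "reaction": "rt",
                    "rest_tremor": "rest", "postural_tremor": "postural"}


def task_salience(ranking: RankingResult, k: int = 30) -> dict[str, float]:
    """Percentage of the top-k unified features drawn from each task.

    The 7 percentages sum to 100. Unknown feature prefixes raise (guards
    against catalog drift).
    """
    if k > len(ranking.feature_names):
        raise ValueError(f"k={k} exceeds feature count {len(ranking.feature_names)}")
    counts = dict.fromkeys(TASK_DISPLAY, 0)
    for name in ranking.top(k):
        prefix = name.split(".", 1)[0]
        if prefix not in PREFIX_TO_TASK:
            raise ValueError(f"unknown feature prefix {prefix!r} in {name!r}")
        counts[PREFIX_TO_TASK[prefix]] += 1
    return {t: 100.0 * counts[t] / k for t in TASK_DISPLAY}


def salience_frame(saliences: dict[tuple[str, str], dict[str, float]]
                   ) -> pd.DataFrame:
    """Tidy frame from {(contrast, sex_filter): task->pct} maps."""
    rows = []
    for (contrast, sex), pcts in sorted(saliences.items()):
        row = {"contrast": contrast, "sex_filter": sex}
        row.update({t: pcts[t] for t in TASK_DISPLAY})
        rows.append(row)
    return pd.DataFrame(rows)


def curve_frame(results: list[CVResult]) -> pd.DataFrame:
    """Mean +- SD sensitivity/specificity vs n_features per config."""
    rows = []
    for res in results:
        s = res.summary()
        cfg = res.config
        rows.append({"contrast": cfg.contrast, "scheme": cfg.scheme,
                     "sex_filter": cfg.sex_filter,
                     "n_features": cfg.n_features, **s})
    return pd.DataFrame(rows)


def render_report(curves: pd.DataFrame | None,
                  saliences: pd.DataFrame | None,
                  out_dir: str | Path,
                  mismatch: dict | None = None,
                  make_figures: bool = False) -> list[Path]:
    """Write curve/salience CSVs and a Markdown summary; returns paths.

    Deterministic: identical inputs produce identical files.
    """
    if (curves is None or len(curves) == 0) and (saliences is None or len(saliences) == 0):
        raise ValueError("nothing to report: empty results")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    lines = ["# Motor-battery validation report", ""]

    if curves is not None and len(curves):
        p = out / "accuracy_curves.csv"
        curves.sort_values(["contrast", "scheme", "sex_filter", "n_features"],
                           key=_sortkey).to_csv(p, index=False)
        written.append(p)
        lines += ["## Accuracy vs number of features", ""]
        for _, r in curves.iterrows():
            lines.append(
                f"- {r['contrast']} / {r['scheme']} / {r['sex_filter']} / "
                f"k={r['n_features']}: sens {r['sens_mean']:.3f} "
                f"(SD {r['sens_sd']:.3f}), spec {r['spec_mean']:.3f} "
                f"(SD {r['spec_sd']:.3f})")
        lines.append("")

    if saliences is not None and len(saliences):
        p = out / "task_salience.csv"
        saliences.to_csv(p, index=False)
        written.append(p)
        lines += ["## Task salience (top-feature share per task, %)", ""]
        for _, r in saliences.iterrows():
            parts = ", ".join(f"{t} {r[t]:.1f}" for t in TASK_DISPLAY)
            lines.append(f"- {r['contrast']} / {r['sex_filter']}: {parts}")
        lines.append("")

    if mismatch is not None:
        lines += ["## Train/validation mismatch", ""]
        for scheme, diag in sorted(mismatch.items()):
            flag = " (UNRELIABLE VALIDATION)" if diag.get("unreliable_validation") else ""
            lines.append(f"- {scheme}: mean mismatch {diag['mean_pct']:.2f}%{flag}")
        lines.append("")

    if make_figures and curves is not None and len(curves):
        written += _figures(curves, out)

    summary = out / "report.md"
    summary.write_text("\n".join(lines))
    written.append(summary)
    return written


def _sortkey(col: pd.Series) -> pd.Series:
    if col.name == "n_features":
        return col.map(lambda v: 10**9 if v == "all" else int(v))
    return col


def _figures(curves: pd.DataFrame, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    numeric = curves[curves["n_features"] != "all"].copy()
    numeric["n_features"] = numeric["n_features"].astype(int)
    for (contrast, scheme, sex), grp in numeric.groupby(
            ["contrast", "scheme", "sex_filter"]):
        grp = grp.sort_values("n_features")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.errorbar(grp["n_features"], grp["sens_mean"], yerr=grp["sens_sd"],
                    marker="o", label="sensitivity")
        ax.errorbar(grp["n_features"], grp["spec_mean"], yerr=grp["spec_sd"],
                    marker="s", label="specificity")
        ax.set_xlabel("number of features")
        ax.set_ylabel("rate")
        ax.set_ylim(0, 1.05)
        ax.set_title(f"{contrast} / {scheme} / {sex}")
        ax.legend()
        fig.tight_layout()
        p = out / f"curve_{contrast}_{scheme}_{sex}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
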