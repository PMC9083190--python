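"""Optional figures: ROC curve and total-score box plot for a scored cohort."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cohort import ScoredCohort
from .stats import auc_roc


def roc_plot(cohort: ScoredCohort, path: str | Path) -> Path:
    """Empirical ROC curve of the total score with the AUC in the legend."""
    scores = np.asarray(cohort.total_scores(), dtype=float)
    labels = np.asarray(cohort.outcomes(), dtype=int)
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(scores))[::-1]])
    npos = max(int((labels == 1).sum()), 1)
    nneg = max(int((labels == 0).sum()), 1)
    tpr = [float(((scores >= t) & (labels == 1)).sum()) / npos for t in thresholds]
    fpr = [float(((scores >= t) & (labels == 0)).sum()) / nneg for t in thresholds]
    res = auc_roc(scores, labels)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, tpr, drawstyle="steps-post",
            label=f"AUC = {res.auc * 100:.1f}% "
                  f"({res.ci_low * 100:.1f}–{res.ci_high * 100:.1f}%)")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=1)
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC, total score — {cohort.name}")
    ax.legend(loc="lower right")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def score_boxplot(cohort: ScoredCohort, path: str | Path) -> Path:
    """Box plot of the total score by outcome group."""
    scores = np.asarray(cohort.total_scores(), dtype=float)
    labels = np.asarray(cohort.outcomes(), dtype=int)
    groups = [scores[labels == 0], scores[labels == 1]]
    fig, ax = plt.subplots(figsize=(4, 5))
    ax.boxplot(groups, tick_labels=["outcome=0", "outcome=1"])
    ax.set_ylabel("total score")
    ax.set_title(f"Total score by outcome — {cohort.name}")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
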