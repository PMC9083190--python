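"""Diagnostic-accuracy evaluation of a scored cohort.

Implements the validation statistics used to assess a screening score
against a binary outcome (1 = immune-mediated outcome, 0 = not):

* group summaries of the total score (mean / median / min / max),
* a two-sided Wilcoxon rank-sum (Mann–Whitney) comparison of the two
  outcome groups — exact when both groups are small and tie-free,
  otherwise a tie-corrected normal approximation with continuity
  correction,
* AUC-ROC of the total score, computed from midranks (equal to the
  trapezoidal area under the empirical ROC curve, ties counted 1/2), with
  a 95% DeLong confidence interval,
* per-threshold 2×2 tables with sensitivity and specificity and exact
  Clopper–Pearson binomial confidence intervals.

Percent renderings round half away from zero to integer percent
(e.g. 14/21 -> 67%, 1/21 -> 5%).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import ScoredCohort
from .exceptions import EvaluationError

logger = logging.getLogger(__name__)

_Z = {0.95: sps.norm.ppf(0.975)}


def percent(fraction: float) -> int:
    """Render a fraction as integer percent, rounding half away from zero."""
    x = fraction * 100.0
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


# ---------------------------------------------------------------------------
# score summaries


@dataclass(frozen=True)
class ScoreSummary:
    group: str
    n: int
    mean: float
    median: float
    min: int
    max: int


def summarize_scores(cohort: ScoredCohort) -> list[ScoreSummary]:
    """Summaries of the total score for all / outcome=1 / outcome=0.

    The median of an even-sized group is the midpoint of the two central
    values. A group with no members is omitted with a logged note.
    """
    scores = np.asarray(cohort.total_scores())
    outcomes = np.asarray(cohort.outcomes())
    out = []
    for label, mask in [
        ("all", np.ones(len(scores), dtype=bool)),
        ("outcome=1", outcomes == 1),
        ("outcome=0", outcomes == 0),
    ]:
        grp = scores[mask]
        if grp.size == 0:
            logger.warning(
                "cohort %s: group %s is empty; summary omitted", cohort.name, label
            )
            continue
        out.append(
            ScoreSummary(
                group=label,
                n=int(grp.size),
                mean=float(grp.mean()),
                median=float(np.median(grp)),
                min=int(grp.min()),
                max=int(grp.max()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


@dataclass(frozen=True)
class WilcoxonResult:
    u: float
    pvalue: float
    method: str  # "exact" | "normal_approx"
    degenerate: bool = False


def wilcoxon_rank_sum(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test of equal distributions.

    ``u`` is the Mann–Whitney U statistic of the first sample. Exact
    enumeration is used when n1 + n2 <= 20 and there are no ties; otherwise
    the normal approximation with tie-corrected variance and continuity
    correction. If every value in both samples is identical the comparison
    is degenerate: U = n1*n2/2 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EvaluationError("wilcoxon_rank_sum requires two nonempty samples")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return WilcoxonResult(
            u=x.size * y.size / 2.0, pvalue=1.0, method="normal_approx", degenerate=True
        )
    has_ties = np.unique(combined).size < combined.size
    if x.size + y.size <= 20 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal_approx"
    return WilcoxonResult(
        u=float(res.statistic), pvalue=float(min(res.pvalue, 1.0)), method=method
    )


# ---------------------------------------------------------------------------
# AUC-ROC with DeLong CI


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    level: float = 0.95


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as concordance probability via midranks (ties count 1/2)."""
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    m = pos.size
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * neg.size))


def auc_roc(scores, labels, level: float = 0.95) -> AUCResult:
    """AUC-ROC of ``scores`` against binary ``labels`` with a DeLong CI.

    The point estimate is the Mann–Whitney concordance probability
    (concordant pairs + half the tied pairs, over all positive–negative
    pairs), identical to trapezoidal integration of the empirical ROC
    curve. The confidence interval uses the DeLong variance estimator on
    the per-observation structural components, truncated to [0, 1]; with
    perfect separation the variance collapses and the interval degenerates
    to the point estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError(
            "AUC is undefined: both outcome classes must be present"
        )
    m, n = pos.size, neg.size
    combined_ranks = sps.rankdata(np.concatenate([pos, neg]))
    tx, ty = combined_ranks[:m], combined_ranks[m:]
    tx_within = sps.rankdata(pos)
    ty_within = sps.rankdata(neg)
    auc = float((tx.sum() - m * (m + 1) / 2.0) / (m * n))
    # DeLong structural components
    v10 = (tx - tx_within) / n          # one per positive
    v01 = 1.0 - (ty - ty_within) / m    # one per negative
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = _Z.get(level, sps.norm.ppf(0.5 + level / 2.0))
    half = z * math.sqrt(max(var, 0.0))
    return AUCResult(
        auc=auc,
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        level=level,
    )


# ---------------------------------------------------------------------------
# threshold accuracy


@dataclass(frozen=True)
class ConfusionTable2x2:
    """Counts at one triage threshold: outcome x passed."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise EvaluationError(f"confusion count {name} must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion_at_threshold(cohort: ScoredCohort, level: int) -> ConfusionTable2x2:
    """Cross-tabulate outcome against passing threshold ``level`` (1 or 2)."""
    if level not in (1, 2):
        raise EvaluationError(f"threshold level must be 1 or 2, got {level}")
    attr = "passed_t1" if level == 1 else "passed_t2"
    tp = fn = fp = tn = 0
    for p in cohort.participants:
        passed = getattr(p, attr)
        if p.outcome == 1:
            tp, fn = (tp + 1, fn) if passed else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if passed else (fp, tn + 1)
    return ConfusionTable2x2(tp=tp, fn=fn, fp=fp, tn=tn)


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) two-sided binomial confidence interval.

    Endpoints come from beta-distribution quantiles, with the conventional
    exact bounds 0 at ``successes == 0`` and 1 at ``successes == n``.
    """
    if n < 1:
        raise EvaluationError("clopper_pearson requires n >= 1")
    if not 0 <= successes <= n:
        raise EvaluationError(f"successes must be in [0, {n}], got {successes}")
    alpha = 1.0 - level
    low = 0.0 if successes == 0 else float(
        sps.beta.ppf(alpha / 2.0, successes, n - successes + 1)
    )
    high = 1.0 if successes == n else float(
        sps.beta.ppf(1.0 - alpha / 2.0, successes + 1, n - successes)
    )
    return low, high


@dataclass(frozen=True)
class DiagnosticAccuracy:
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    level: float = 0.95

    @property
    def sens_pct(self) -> int:
        return percent(self.sensitivity)

    @property
    def spec_pct(self) -> int:
        return percent(self.specificity)

    @property
    def sens_ci_pct(self) -> tuple[int, int]:
        return (percent(self.sens_ci[0]), percent(self.sens_ci[1]))

    @property
    def spec_ci_pct(self) -> tuple[int, int]:
        return (percent(self.spec_ci[0]), percent(self.spec_ci[1]))

    def render_sensitivity(self) -> str:
        lo, hi = self.sens_ci_pct
        return f"{self.sens_pct}% ({lo}–{hi}%)"

    def render_specificity(self) -> str:
        lo, hi = self.spec_ci_pct
        return f"{self.spec_pct}% ({lo}–{hi}%)"


def diagnostic_accuracy(
    table: ConfusionTable2x2, level: float = 0.95
) -> DiagnosticAccuracy:
    """Sensitivity, specificity and their exact binomial CIs from a 2×2."""
    npos = table.tp + table.fn
    nneg = table.fp + table.tn
    if npos < 1:
        raise EvaluationError(
            "sensitivity undefined: no outcome-positive participants (tp+fn = 0)"
        )
    if nneg < 1:
        raise EvaluationError(
            "specificity undefined: no outcome-negative participants (fp+tn = 0)"
        )
    return DiagnosticAccuracy(
        sensitivity=table.tp / npos,
        specificity=table.tn / nneg,
        sens_ci=clopper_pearson(table.tp, npos, level),
        spec_ci=clopper_pearson(table.tn, nneg, level),
        level=level,
    )


# ---------------------------------------------------------------------------
# full report


@dataclass
class EvaluationReport:
    cohort_name: str
    n: int
    summaries: list[ScoreSummary]
    wilcoxon: WilcoxonResult | None
    auc: AUCResult | None
    thresholds: dict[int, tuple[ConfusionTable2x2, DiagnosticAccuracy]]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": s.group,
                    "n": s.n,
                    "mean_score": s.mean,
                    "median": s.median,
                    "min": s.min,
                    "max": s.max,
                }
                for s in self.summaries
            ]
        )

    def accuracy_frame(self) -> pd.DataFrame:
        rows = []
        for level, (table, acc) in sorted(self.thresholds.items()):
            rows.append(
                {
                    "threshold": level,
                    "tp": table.tp,
                    "fn": table.fn,
                    "fp": table.fp,
                    "tn": table.tn,
                    "sensitivity": acc.sensitivity,
                    "sens_ci_low": acc.sens_ci[0],
                    "sens_ci_high": acc.sens_ci[1],
                    "specificity": acc.specificity,
                    "spec_ci_low": acc.spec_ci[0],
                    "spec_ci_high": acc.spec_ci[1],
                    "sensitivity_pct": acc.render_sensitivity(),
                    "specificity_pct": acc.render_specificity(),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        d: dict = {
            "cohort": self.cohort_name,
            "n": self.n,
            "score_summaries": [
                {
                    "group": s.group,
                    "n": s.n,
                    "mean": s.mean,
                    "median": s.median,
                    "min": s.min,
                    "max": s.max,
                }
                for s in self.summaries
            ],
        }
        if self.wilcoxon is not None:
            d["wilcoxon"] = {
                "U": self.wilcoxon.u,
                "pvalue": self.wilcoxon.pvalue,
                "method": self.wilcoxon.method,
                "degenerate": self.wilcoxon.degenerate,
            }
        if self.auc is not None:
            d["auc_roc"] = {
                "auc": self.auc.auc,
                "ci_low": self.auc.ci_low,
                "ci_high": self.auc.ci_high,
                "level": self.auc.level,
            }
        d["thresholds"] = {
            str(level): {
                "tp": t.tp,
                "fn": t.fn,
                "fp": t.fp,
                "tn": t.tn,
                "sensitivity": a.sensitivity,
                "sens_ci": list(a.sens_ci),
                "specificity": a.specificity,
                "spec_ci": list(a.spec_ci),
            }
            for level, (t, a) in sorted(self.thresholds.items())
        }
        return d

    def render_text(self) -> str:
        lines = [f"Evaluation report: {self.cohort_name} (n={self.n})", ""]
        lines.append("Total score by group")
        lines.append(f"{'group':<12}{'n':>5}{'mean':>9}{'median':>9}{'min':>6}{'max':>6}")
        for s in self.summaries:
            lines.append(
                f"{s.group:<12}{s.n:>5}{s.mean:>9.1f}{s.median:>9.1f}"
                f"{s.min:>6}{s.max:>6}"
            )
        if self.wilcoxon is not None:
            w = self.wilcoxon
            ptxt = "<0.0001" if w.pvalue < 1e-4 else f"{w.pvalue:.4g}"
            lines.append(
                f"\nWilcoxon rank-sum (outcome=1 vs outcome=0): "
                f"U={w.u:.1f}, P={ptxt} [{w.method}]"
            )
        if self.auc is not None:
            a = self.auc
            lines.append(
                f"AUC-ROC: {a.auc * 100:.1f}% "
                f"({a.ci_low * 100:.1f}–{a.ci_high * 100:.1f}%)"
            )
        for level, (table, acc) in sorted(self.thresholds.items()):
            lines.append(f"\nThreshold {level}")
            lines.append(f"  not passing: {table.fn} outcome=1, {table.tn} outcome=0")
            lines.append(f"  passing:     {table.tp} outcome=1, {table.fp} outcome=0")
            lines.append(f"  sensitivity: {acc.render_sensitivity()}")
            lines.append(f"  specificity: {acc.render_specificity()}")
        return "\n".join(lines) + "\n"


def evaluate_cohort(cohort: ScoredCohort) -> EvaluationReport:
    """Assemble the full evaluation of a scored cohort.

    With both outcome classes present this produces score summaries, the
    Wilcoxon comparison and AUC of the total score, and the 2×2 table with
    sensitivity/specificity at each triage threshold. A single-class cohort
    yields a partial report (summaries only) with a logged warning.
    """
    scores = np.asarray(cohort.total_scores(), dtype=float)
    outcomes = np.asarray(cohort.outcomes(), dtype=int)
    summaries = summarize_scores(cohort)
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    if pos.size == 0 or neg.size == 0:
        logger.warning(
            "cohort %s has a single outcome class; comparative statistics omitted",
            cohort.name,
        )
        return EvaluationReport(
            cohort_name=cohort.name,
            n=cohort.n,
            summaries=summaries,
            wilcoxon=None,
            auc=None,
            thresholds={},
        )
    wil = wilcoxon_rank_sum(pos, neg)
    auc = auc_roc(scores, outcomes)
    thresholds = {}
    for level in (1, 2):
        table = confusion_at_threshold(cohort, level)
        thresholds[level] = (table, diagnostic_accuracy(table))
    return EvaluationReport(
        cohort_name=cohort.name,
        n=cohort.n,
        summaries=summaries,
        wilcoxon=wil,
        auc=auc,
        thresholds=thresholds,
    )


def write_report(report: EvaluationReport, outdir: str | Path, fmt: str = "both") -> list[Path]:
    """Write report artifacts (summary.csv, accuracy.csv, report.json, report.txt)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if fmt in ("csv", "both"):
        p = outdir / "summary.csv"
        report.summary_frame().to_csv(p, index=False)
        written.append(p)
        if report.thresholds:
            p = outdir / "accuracy.csv"
            report.accuracy_frame().to_csv(p, index=False)
            written.append(p)
        p = outdir / "report.json"
        p.write_text(
            json.dumps(report.to_dict(), indent=1, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        written.append(p)
    if fmt in ("text", "both"):
        p = outdir / "report.txt"
        p.write_text(report.render_text(), encoding="utf-8")
        written.append(p)
    return written
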