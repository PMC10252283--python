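"""Clinical interpretation and diagnostic-performance evaluation.

Scores are mapped to calls at two cut-offs: 0.49 separates normal-leaning
from pathological (screening use) and 0.77 confirms HSIL with high
specificity (surgery-decision use).  A score equal to the cut-off is called
POSITIVE — the convention favouring sensitivity at the screening threshold —
and is flippable via configuration.

HSIL is the condition-positive class throughout.  All rates are percentages
of the usual confusion-matrix ratios; zero-denominator rates are reported
as None (undefined), never as 0.  Rank statistics (Mann–Whitney,
Kruskal–Wallis) and the ROC sweep are delegated to scipy/scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .config import InterpretConfig
from .data import Diagnosis, HPVStatus, ScoreResult

__all__ = [
    "ConfusionCounts",
    "DiagnosticReport",
    "classify",
    "categorize",
    "confusion",
    "metrics",
    "roc_auc",
    "mann_whitney",
    "kruskal_wallis",
    "evaluate_scores",
]

#: Interpretation bands (color ramp green→yellow→red in the kit's read-out).
CATEGORY_NORMAL = "normal-leaning"
CATEGORY_ELEVATED = "elevated"
CATEGORY_CONFIRM = "HSIL-confirming"


def classify(score: float, cutoff: float, positive_at_cutoff: bool = True) -> str:
    """Binary call at a cut-off: 'POSITIVE' or 'NEGATIVE'."""
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"score {score} outside [0, 1]")
    positive = score >= cutoff if positive_at_cutoff else score > cutoff
    return "POSITIVE" if positive else "NEGATIVE"


def categorize(score: float, config: InterpretConfig | None = None) -> str:
    """Three-band clinical category for one score."""
    config = config or InterpretConfig()
    if classify(score, config.confirm_cutoff, config.positive_at_cutoff) == "POSITIVE":
        return CATEGORY_CONFIRM
    if classify(score, config.screen_cutoff, config.positive_at_cutoff) == "POSITIVE":
        return CATEGORY_ELEVATED
    return CATEGORY_NORMAL


@dataclass
class ConfusionCounts:
    """2×2 confusion counts with HSIL as the condition-positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion counts must be positive in total")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    results: Sequence[ScoreResult],
    cutoff: float,
    positive_at_cutoff: bool = True,
) -> ConfusionCounts:
    """Confusion counts of the score calls against morphological diagnosis."""
    tp = fp = tn = fn = 0
    for r in results:
        if r.diagnosis == Diagnosis.UNKNOWN:
            raise ValueError(f"sample {r.sample_id!r} has UNKNOWN diagnosis")
        positive = classify(r.mir_cervix, cutoff, positive_at_cutoff) == "POSITIVE"
        if r.diagnosis == Diagnosis.HSIL:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _rate(numerator: int, denominator: int) -> float | None:
    return None if denominator == 0 else 100.0 * numerator / denominator


def metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Standard diagnostic rates, as percentages.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN), accuracy = (TP+TN)/total; precision is PPV by
    definition.  A zero denominator yields None (undefined), not 0.
    """
    out = {
        "sensitivity": _rate(counts.tp, counts.tp + counts.fn),
        "specificity": _rate(counts.tn, counts.tn + counts.fp),
        "ppv": _rate(counts.tp, counts.tp + counts.fp),
        "npv": _rate(counts.tn, counts.tn + counts.fn),
        "accuracy": _rate(counts.tp + counts.tn, counts.total),
    }
    out["precision"] = out["ppv"]
    return out


def roc_auc(
    scores: Sequence[float], labels: Sequence
) -> tuple[list[tuple[float, float, float]], float]:
    """ROC swept over all distinct thresholds (plus sentinels) and its AUC.

    ``labels`` may be Diagnosis enums, 'NILM'/'HSIL' strings, or 0/1 with 1
    = HSIL.  Returns ([(threshold, tpr, fpr), ...], auc); AUC is the
    trapezoidal integral of the curve, equal to the concordance probability
    with ties counted half.
    """
    y = np.asarray(
        [1 if (l == Diagnosis.HSIL or l == "HSIL" or l == 1) else 0 for l in labels]
    )
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, thresholds = _sk_roc_curve(y, s, drop_intermediate=False)
    curve = [(float(t), float(tp), float(fp)) for t, tp, fp in zip(thresholds, tpr, fpr)]
    return curve, float(_trapezoid_auc(fpr, tpr))


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test of two score samples.

    U is computed from rank sums with midranks for ties; the p-value is
    exact (full enumeration) when the smaller sample has <= 8 observations
    and there are no ties, otherwise a tie-corrected normal approximation
    with continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float, list[float]]:
    """Kruskal–Wallis H (tie-corrected), chi-squared p, and per-group means."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    means = [float(g.mean()) for g in arrays]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):  # scipy rejects all-identical data
        return 0.0, 1.0, means
    h, p = stats.kruskal(*arrays)
    return float(h), float(p), means


@dataclass
class DiagnosticReport:
    """Complete evaluation of a scored cohort against morphology labels."""

    n_enrolled: int
    n_excluded: int
    n_scored: int
    exclusion_reasons: dict[str, int]
    counts_screen: ConfusionCounts
    counts_confirm: ConfusionCounts
    metrics_screen: dict[str, float | None]
    metrics_confirm: dict[str, float | None]
    roc: list[tuple[float, float, float]]
    auc: float
    mann_whitney: tuple[float, float]
    group_means: dict[str, float | None]
    kruskal_wallis: tuple[float, float, list[float]] | None
    cutoffs: tuple[float, float] = (0.49, 0.77)

    def to_dict(self) -> dict:
        def cc(c: ConfusionCounts) -> dict:
            return {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn, "total": c.total}

        return {
            "n_enrolled": self.n_enrolled,
            "n_excluded": self.n_excluded,
            "n_scored": self.n_scored,
            "eligibility_pct": round(100.0 * self.n_scored / self.n_enrolled, 2)
            if self.n_enrolled
            else None,
            "exclusion_reasons": self.exclusion_reasons,
            "cutoffs": {"screen": self.cutoffs[0], "confirm": self.cutoffs[1]},
            "confusion": {"screen": cc(self.counts_screen), "confirm": cc(self.counts_confirm)},
            "metrics": {
                "screen": {k: None if v is None else round(v, 2) for k, v in self.metrics_screen.items()},
                "confirm": {k: None if v is None else round(v, 2) for k, v in self.metrics_confirm.items()},
            },
            "auc": self.auc,
            "mann_whitney": {"U": self.mann_whitney[0], "p": self.mann_whitney[1]},
            "group_means": self.group_means,
            "kruskal_wallis": None
            if self.kruskal_wallis is None
            else {
                "H": self.kruskal_wallis[0],
                "p": self.kruskal_wallis[1],
                "group_means": self.kruskal_wallis[2],
            },
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def roc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.roc, columns=["threshold", "tpr", "fpr"])


def evaluate_scores(
    results: Sequence[ScoreResult],
    config: InterpretConfig | None = None,
    n_enrolled: int | None = None,
    exclusion_reasons: dict[str, int] | None = None,
) -> DiagnosticReport:
    """Build the full diagnostic report from labeled score results.

    Group means are reported for NILM and HSIL overall; when HPV status is
    available the three-group comparison NILM/HPV(−), HSIL/HPV(−),
    HSIL/HPV(+) is tested with Kruskal–Wallis.
    """
    config = config or InterpretConfig()
    if not results:
        raise ValueError("no score results to evaluate")
    labeled = [r for r in results if r.diagnosis != Diagnosis.UNKNOWN]
    if not labeled:
        raise ValueError("no labeled samples to evaluate")

    nilm = [r.mir_cervix for r in labeled if r.diagnosis == Diagnosis.NILM]
    hsil = [r.mir_cervix for r in labeled if r.diagnosis == Diagnosis.HSIL]
    if not nilm or not hsil:
        raise ValueError("both NILM and HSIL must be present after QC")

    counts_screen = confusion(labeled, config.screen_cutoff, config.positive_at_cutoff)
    counts_confirm = confusion(labeled, config.confirm_cutoff, config.positive_at_cutoff)
    roc, auc_value = roc_auc(
        [r.mir_cervix for r in labeled], [r.diagnosis for r in labeled]
    )

    group_means: dict[str, float | None] = {
        "NILM": float(np.mean(nilm)),
        "HSIL": float(np.mean(hsil)),
    }
    kw = None
    nilm_neg = [
        r.mir_cervix
        for r in labeled
        if r.diagnosis == Diagnosis.NILM and r.hpv_status == HPVStatus.NEG
    ]
    hsil_neg = [
        r.mir_cervix
        for r in labeled
        if r.diagnosis == Diagnosis.HSIL and r.hpv_status == HPVStatus.NEG
    ]
    hsil_pos = [
        r.mir_cervix
        for r in labeled
        if r.diagnosis == Diagnosis.HSIL and r.hpv_status == HPVStatus.POS
    ]
    group_means["HSIL/HPV-"] = float(np.mean(hsil_neg)) if hsil_neg else None
    group_means["HSIL/HPV+"] = float(np.mean(hsil_pos)) if hsil_pos else None
    if nilm_neg and hsil_neg and hsil_pos:
        kw = kruskal_wallis([nilm_neg, hsil_neg, hsil_pos])

    n_scored = len(labeled)
    n_enrolled = n_enrolled if n_enrolled is not None else len(results)
    return DiagnosticReport(
        n_enrolled=n_enrolled,
        n_excluded=n_enrolled - len(results),
        n_scored=n_scored,
        exclusion_reasons=exclusion_reasons or {},
        counts_screen=counts_screen,
        counts_confirm=counts_confirm,
        metrics_screen=metrics(counts_screen),
        metrics_confirm=metrics(counts_confirm),
        roc=roc,
        auc=auc_value,
        mann_whitney=mann_whitney(hsil, nilm),
        group_means=group_means,
        kruskal_wallis=kw,
        cutoffs=(config.screen_cutoff, config.confirm_cutoff),
    )
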