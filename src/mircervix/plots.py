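"""Optional figures: ranked score bars with a diagnosis color strip, and
the ROC curve.  Matplotlib with the Agg backend; every function returns the
Figure so callers can save or embed it."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .data import Diagnosis, ScoreResult  # noqa: E402
from .evaluate import DiagnosticReport  # noqa: E402

__all__ = ["plot_ranked_scores", "plot_roc"]

_DIAG_COLORS = {Diagnosis.NILM: "#2ca02c", Diagnosis.HSIL: "#d62728", Diagnosis.UNKNOWN: "#7f7f7f"}


def plot_ranked_scores(
    scores: Sequence[ScoreResult], path: str | Path | None = None
) -> plt.Figure:
    """Samples in ascending score order: black bars, diagnosis strip below."""
    ordered = sorted(scores, key=lambda r: (r.mir_cervix, r.sample_id))
    values = [r.mir_cervix for r in ordered]
    colors = [_DIAG_COLORS[r.diagnosis] for r in ordered]
    fig, (ax, strip) = plt.subplots(
        2, 1, figsize=(10, 4), gridspec_kw={"height_ratios": [10, 1]}, sharex=True
    )
    ax.bar(range(len(values)), values, color="black", width=0.9)
    ax.set_ylabel("miR-CERVIX")
    ax.set_ylim(0, 1)
    strip.bar(range(len(colors)), [1] * len(colors), color=colors, width=1.0)
    strip.set_yticks([])
    strip.set_xlabel("samples (ascending score)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_roc(report: DiagnosticReport, path: str | Path | None = None) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    frame = report.roc_frame()
    ax.plot(frame["fpr"], frame["tpr"], color="black")
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {report.auc:.2f}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
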