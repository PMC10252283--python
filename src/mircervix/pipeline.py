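"""End-to-end pipeline: QC gate → χ predictors → cross-validated ensemble
score → clinical interpretation and diagnostic report.

The stage ordering is fixed — no sample failing QC ever reaches the
predictor or scoring stage — and the whole run is deterministic given the
cohort, configuration and seed.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np

from .config import PipelineConfig
from .data import Cohort, Diagnosis, ScoreResult
from .evaluate import DiagnosticReport, categorize, evaluate_scores
from .forest import crossval_scores
from .predictors import CHI_NAMES, predictor_matrix
from .qc import QCResult, apply_qc

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger("mircervix")


class PipelineResult:
    """Bundle of everything a run produces."""

    def __init__(
        self,
        report: DiagnosticReport,
        scores: list[ScoreResult],
        qc_results: list[QCResult],
        config: PipelineConfig,
    ):
        self.report = report
        self.scores = scores
        self.qc_results = qc_results
        self.config = config


def run_pipeline(cohort: Cohort, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on a labeled cohort.

    Requires at least ``2 * k`` labeled samples with both classes
    represented after QC; raises otherwise.
    """
    config = config or PipelineConfig()
    n_enrolled = len(cohort)
    logger.info("enrolled: %d samples", n_enrolled)

    passing, qc_results = apply_qc(cohort, config.qc)
    reason_counts = Counter(
        reason.value for r in qc_results if not r.passed for reason in r.reasons
    )
    n_excluded = n_enrolled - len(passing)
    logger.info("QC: %d passed, %d excluded (%s)", len(passing), n_excluded, dict(reason_counts))

    labeled = Cohort(
        samples=[s for s in passing if s.diagnosis != Diagnosis.UNKNOWN],
        provenance=dict(passing.provenance),
    )
    chi = predictor_matrix(labeled)
    X = chi[list(CHI_NAMES)].to_numpy()
    y = (chi["diagnosis"] == Diagnosis.HSIL.value).to_numpy().astype(int)

    if len(np.unique(y)) < 2:
        raise ValueError("fewer than two diagnosis classes remain after QC")
    if config.cv.k > len(y):
        raise ValueError(
            f"cv.k={config.cv.k} exceeds the {len(y)} labeled QC-passing samples"
        )

    cv = crossval_scores(X, y, config, seed=config.seed)
    logger.info("scored %d samples out-of-fold (k=%d)", len(y), config.cv.k)

    scores = []
    for sample, score, fold in zip(labeled, cv.scores, cv.folds):
        scores.append(
            ScoreResult(
                sample_id=sample.sample_id,
                mir_cervix=float(score),
                fold=int(fold),
                category=categorize(float(score), config.interpret),
                diagnosis=sample.diagnosis,
                hpv_status=sample.hpv_status,
            )
        )

    report = evaluate_scores(
        scores,
        config.interpret,
        n_enrolled=n_enrolled,
        exclusion_reasons=dict(reason_counts),
    )
    return PipelineResult(report=report, scores=scores, qc_results=qc_results, config=config)
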