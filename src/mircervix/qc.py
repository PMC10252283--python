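"""Control-reaction quality gating.

A sample is analyzable only when both control reactions succeeded and all
six marker Cts are present:

* ``Ct(ACTB) <= 34`` — material quantity/quality control; exclusion is
  strictly above 34.
* ``Ct(cel-miR-39) < 18.5`` — spike-in enzymatic-efficiency control; the
  bound is strict, so 18.5 itself fails.  Note the two bounds have opposite
  inclusivity.

Missing marker Cts exclude the sample rather than being imputed: the
predictor stage needs all six values and a cap-style imputation would bias
the ratios.  When ``enforce_wetlab_fields`` is on, the spectrophotometric
criteria (RNA >= 100 ng/µL, A260/280 >= 1.7) are additionally applied.
QC never hard-fails — it partitions the cohort and records machine-readable
reasons for every exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .config import QCConfig
from .data import Cohort, SampleAssay

__all__ = ["QCReason", "QCResult", "apply_qc", "qc_results_frame"]


class QCReason(str, Enum):
    ACTB_HIGH = "ACTB_HIGH"
    SPIKEIN_HIGH = "SPIKEIN_HIGH"
    MISSING_CONTROL = "MISSING_CONTROL"
    MISSING_MARKER = "MISSING_MARKER"
    LOW_RNA = "LOW_RNA"
    LOW_PURITY = "LOW_PURITY"


@dataclass
class QCResult:
    """Pass/fail verdict for one sample; ``passed`` iff ``reasons`` empty."""

    sample_id: str
    passed: bool
    reasons: frozenset[QCReason] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.reasons = frozenset(self.reasons)
        if self.passed != (not self.reasons):
            raise ValueError("passed must be equivalent to an empty reason set")


def _check_sample(sample: SampleAssay, config: QCConfig) -> frozenset[QCReason]:
    reasons: set[QCReason] = set()
    if math.isnan(sample.ct_actb):
        reasons.add(QCReason.MISSING_CONTROL)
    elif sample.ct_actb > config.actb_max_ct:
        reasons.add(QCReason.ACTB_HIGH)
    if math.isnan(sample.ct_celmir39):
        reasons.add(QCReason.MISSING_CONTROL)
    elif sample.ct_celmir39 >= config.spikein_max_ct:
        reasons.add(QCReason.SPIKEIN_HIGH)
    if not sample.has_all_markers():
        reasons.add(QCReason.MISSING_MARKER)
    if config.enforce_wetlab_fields:
        if sample.rna_conc is None or sample.rna_conc < config.min_rna_conc:
            reasons.add(QCReason.LOW_RNA)
        if sample.a260_280 is None or sample.a260_280 < config.min_a260_280:
            reasons.add(QCReason.LOW_PURITY)
    return frozenset(reasons)


def apply_qc(cohort: Cohort, config: QCConfig | None = None) -> tuple[Cohort, list[QCResult]]:
    """Partition a cohort into QC-passing samples and per-sample verdicts.

    Returns the passing sub-cohort (input order preserved) and one
    :class:`QCResult` per input sample.  Every excluded sample carries all
    applicable reasons.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    config = config or QCConfig()
    results = []
    passing = []
    for sample in cohort:
        reasons = _check_sample(sample, config)
        results.append(QCResult(sample.sample_id, passed=not reasons, reasons=reasons))
        if not reasons:
            passing.append(sample)
    passing_cohort = Cohort(samples=passing, provenance=dict(cohort.provenance))
    return passing_cohort, results


def qc_results_frame(results: list[QCResult]) -> pd.DataFrame:
    """Tabular QC export: sample_id, passed, reasons joined by ';'."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "passed": [r.passed for r in results],
            "reasons": [";".join(sorted(x.value for x in r.reasons)) for r in results],
        }
    )
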