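"""Reciprocal-pair predictors χ1…χ9.

Each QC-passing sample's six marker Cts are reduced to nine ratios

    χ = 2^(Ct_marker − Ct_reference)

pairing each miRNA expected to be up-regulated in HSIL (miR-145, miR-1246,
miR-1290) with each stable/down-regulated reference (miR-21, miR-29b,
miR-451a).  Because Ct is a log2 scale, the exponent of a Ct difference is
an amplification ratio; since both members share the sample's input
quantity, χ is exactly invariant to any constant shift of that sample's
Cts — a reference-free normalization.

Orientation convention: the HSIL-marker Ct sits first in the exponent, so
up-regulation in HSIL (lower marker Ct) *decreases* χ.  The classifier is
orientation-agnostic; the convention is fixed so importances are
reproducible.  Ordering is marker-major: χ1=(miR-145, miR-21),
χ2=(miR-145, miR-29b), χ3=(miR-145, miR-451a), χ4..χ6 likewise for
miR-1246, χ7..χ9 for miR-1290.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array

from .data import Cohort, SampleAssay

__all__ = [
    "PAIR_LABELS",
    "CHI_NAMES",
    "PredictorVector",
    "pair_ratio",
    "predictor_vector",
    "predictor_matrix",
    "ReciprocalPairs",
]

_UP_MARKERS = ("ct_mir145", "ct_mir1246", "ct_mir1290")
_REFERENCES = ("ct_mir21", "ct_mir29b", "ct_mir451a")

#: Fixed (marker, reference) ordering of χ1…χ9, marker-major.
PAIR_LABELS: tuple[tuple[str, str], ...] = tuple(
    (marker, ref) for marker in _UP_MARKERS for ref in _REFERENCES
)
CHI_NAMES: tuple[str, ...] = tuple(f"chi{i}" for i in range(1, 10))


def pair_ratio(ct_x: float, ct_y: float) -> float:
    """Amplification ratio 2^(ct_x − ct_y) for one reciprocal pair."""
    if math.isnan(ct_x) or math.isnan(ct_y):
        raise ValueError("pair_ratio requires both Ct values present")
    return float(2.0 ** (ct_x - ct_y))


@dataclass
class PredictorVector:
    """One sample's nine χ ratios in the fixed marker-major ordering."""

    sample_id: str
    chi: np.ndarray
    pair_labels: tuple[tuple[str, str], ...] = PAIR_LABELS

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        if self.chi.shape != (9,):
            raise ValueError(f"chi must have shape (9,); got {self.chi.shape}")
        if not np.all(self.chi > 0):
            raise ValueError("all χ must be positive")


def predictor_vector(sample: SampleAssay) -> PredictorVector:
    """Compute χ1…χ9 for one sample; errors name any missing miRNA."""
    missing = [f for f in (*_UP_MARKERS, *_REFERENCES) if math.isnan(getattr(sample, f))]
    if missing:
        raise ValueError(
            f"sample {sample.sample_id!r} is missing marker Ct(s): {missing}"
        )
    chi = np.array(
        [pair_ratio(getattr(sample, m), getattr(sample, r)) for m, r in PAIR_LABELS]
    )
    return PredictorVector(sample_id=sample.sample_id, chi=chi)


def predictor_matrix(cohort: Cohort) -> pd.DataFrame:
    """n×9 predictor table with diagnosis/HPV metadata, indexed by sample."""
    rows = []
    for sample in cohort:
        vec = predictor_vector(sample)
        row = dict(zip(CHI_NAMES, vec.chi))
        row["sample_id"] = sample.sample_id
        row["diagnosis"] = sample.diagnosis.value
        row["hpv_status"] = sample.hpv_status.value
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["sample_id", *CHI_NAMES, "diagnosis", "hpv_status"])
    return frame.set_index("sample_id")


class ReciprocalPairs(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping n×6 marker Cts to n×9 χ ratios.

    Input column order must be the assay order (miR-21, miR-29b, miR-145,
    miR-451a, miR-1246, miR-1290).  ``log2=True`` returns Ct differences
    instead of ratios (often better conditioned for linear models; the tree
    ensemble is invariant to this monotone rescaling).
    """

    _CT_ORDER = ("ct_mir21", "ct_mir29b", "ct_mir145", "ct_mir451a", "ct_mir1246", "ct_mir1290")

    def __init__(self, log2: bool = False):
        self.log2 = log2

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=6)
        if X.shape[1] != 6:
            raise ValueError(f"expected 6 marker Ct columns, got {X.shape[1]}")
        self.n_features_in_ = 6
        return self

    def transform(self, X):
        X = check_array(X)
        if X.shape[1] != 6:
            raise ValueError(f"expected 6 marker Ct columns, got {X.shape[1]}")
        col = {name: i for i, name in enumerate(self._CT_ORDER)}
        diffs = np.column_stack(
            [X[:, col[m]] - X[:, col[r]] for m, r in PAIR_LABELS]
        )
        return diffs if self.log2 else 2.0**diffs

    def get_feature_names_out(self, input_features=None):
        return np.asarray(CHI_NAMES, dtype=object)
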