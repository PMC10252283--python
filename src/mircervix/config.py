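"""Pipeline configuration: QC cut-offs, forest hyperparameters, CV and
interpretation thresholds, and the master seed.

Defaults follow the published assay protocol: ACTB control accepted up to
Ct 34 (exclusion is strictly above), cel-miR-39 spike-in accepted strictly
under Ct 18.5, 20-fold stratified cross-validation, and the two clinical
cut-offs 0.49 (screening) and 0.77 (HSIL confirmation).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = [
    "QCConfig",
    "ForestConfig",
    "CVConfig",
    "InterpretConfig",
    "PipelineConfig",
]

N_PREDICTORS = 9


@dataclass
class QCConfig:
    actb_max_ct: float = 34.0        # pass iff Ct(ACTB) <= this
    spikein_max_ct: float = 18.5     # pass iff Ct(cel-miR-39) < this (strict)
    min_rna_conc: float = 100.0      # ng/µL, only when enforce_wetlab_fields
    min_a260_280: float = 1.7
    enforce_wetlab_fields: bool = False


@dataclass
class ForestConfig:
    n_trees: int = 100
    features_per_split: int = 3      # floor(sqrt(9))
    max_depth: int | None = None     # None = unlimited
    min_leaf: int = 1
    hard_voting: bool = False        # majority vote instead of mean leaf probability

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 1 <= self.features_per_split <= N_PREDICTORS:
            raise ValueError(f"features_per_split must be in [1, {N_PREDICTORS}]")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")


@dataclass
class CVConfig:
    k: int = 20
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class InterpretConfig:
    screen_cutoff: float = 0.49
    confirm_cutoff: float = 0.77
    positive_at_cutoff: bool = True  # score == cutoff counts as POSITIVE

    def __post_init__(self) -> None:
        if not (0.0 < self.screen_cutoff <= self.confirm_cutoff < 1.0):
            raise ValueError(
                "cutoffs must satisfy 0 < screen_cutoff <= confirm_cutoff < 1; "
                f"got {self.screen_cutoff}, {self.confirm_cutoff}"
            )


@dataclass
class PipelineConfig:
    qc: QCConfig = field(default_factory=QCConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    interpret: InterpretConfig = field(default_factory=InterpretConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        known = {"qc", "forest", "cv", "interpret", "seed"}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            qc=QCConfig(**payload.get("qc", {})),
            forest=ForestConfig(**payload.get("forest", {})),
            cv=CVConfig(**payload.get("cv", {})),
            interpret=InterpretConfig(**payload.get("interpret", {})),
            seed=int(payload.get("seed", 0)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
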