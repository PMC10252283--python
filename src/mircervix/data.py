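"""Core data model and cohort file I/O.

A cohort is a collection of :class:`SampleAssay` records, one per cervical
smear.  Each record carries eight Ct values — six marker miRNAs plus two
control reactions (an ACTB genomic-region amplification and a cel-miR-39
spike-in) — alongside the morphological diagnosis (Bethesda NILM/HSIL) and
the high-risk-HPV screen call.

Two CSV dialects are supported.  The canonical *long* form is tidy
(``sample_id, target, ct`` plus optional metadata columns); the *wide* form
has one row per sample with fixed column names.  Ct values absent from the
file are recorded as missing (NaN) and dealt with downstream by QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Diagnosis",
    "HPVStatus",
    "SampleAssay",
    "Cohort",
    "ScoreResult",
    "CT_FIELDS",
    "MARKER_CT_FIELDS",
    "MISSING",
    "read_cohort",
    "write_cohort",
    "write_scores",
    "read_scores",
]

#: Sentinel for an absent Ct value (qPCR reaction that never crossed threshold
#: or was not run).  NaN so that pandas round-trips are natural.
MISSING = math.nan

#: Valid Ct window, cycles.  qPCR protocols run at most 45 cycles; a Ct of 0
#: is physically meaningless.
CT_MIN, CT_MAX = 0.0, 45.0


class Diagnosis(str, Enum):
    """Morphological (Bethesda) diagnosis used as the reference standard."""

    NILM = "NILM"
    HSIL = "HSIL"
    UNKNOWN = "UNKNOWN"


class HPVStatus(str, Enum):
    """High-risk HPV screen call (14 carcinogenic types, undifferentiated)."""

    POS = "POS"
    NEG = "NEG"
    UNKNOWN = "UNKNOWN"


#: Ct field names, assay order: six markers then the two controls.
MARKER_CT_FIELDS: tuple[str, ...] = (
    "ct_mir21",
    "ct_mir29b",
    "ct_mir145",
    "ct_mir451a",
    "ct_mir1246",
    "ct_mir1290",
)
CONTROL_CT_FIELDS: tuple[str, ...] = ("ct_actb", "ct_celmir39")
CT_FIELDS: tuple[str, ...] = MARKER_CT_FIELDS + CONTROL_CT_FIELDS


def _normalise_target(name: str) -> str:
    return "".join(ch for ch in str(name).lower() if ch.isalnum())


def _alias_table() -> dict[str, str]:
    """Map normalised target spellings to canonical Ct field names."""
    table: dict[str, str] = {}
    variants = {
        "ct_mir21": ["miR-21", "miR-21-5p", "hsa-miR-21", "hsa-miR-21-5p"],
        "ct_mir29b": ["miR-29b", "miR-29b-3p", "hsa-miR-29b", "hsa-miR-29b-3p"],
        "ct_mir145": ["miR-145", "miR-145-5p", "hsa-miR-145", "hsa-miR-145-5p"],
        "ct_mir451a": [
            "miR-451",
            "miR-451a",
            "miR-451a-5p",
            "hsa-miR-451a",
            "hsa-miR-451a-5p",
        ],
        "ct_mir1246": ["miR-1246", "miR-1246-5p", "hsa-miR-1246", "hsa-miR-1246-5p"],
        "ct_mir1290": ["miR-1290", "miR-1290-3p", "hsa-miR-1290", "hsa-miR-1290-3p"],
        "ct_actb": ["ACTB", "actin", "b-actin", "beta-actin"],
        "ct_celmir39": [
            "cel-miR-39",
            "cel-miR-39-3p",
            "cel-miR-39-5p",
            "spike-in",
            "spikein",
        ],
    }
    for canon, names in variants.items():
        table[_normalise_target(canon)] = canon
        for name in names:
            table[_normalise_target(name)] = canon
    return table


_TARGET_ALIASES = _alias_table()


def _canonical_target(name: str) -> str:
    key = _normalise_target(name)
    if key not in _TARGET_ALIASES:
        accepted = sorted(set(_TARGET_ALIASES.values()))
        raise ValueError(
            f"unknown assay target {name!r}; accepted targets (canonical field "
            f"names, case-insensitive aliases like 'miR-21' or 'hsa-miR-21-5p' "
            f"also work): {accepted}"
        )
    return _TARGET_ALIASES[key]


def _coerce_enum(value, enum_cls):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return enum_cls.UNKNOWN
    if isinstance(value, enum_cls):
        return value
    text = str(value).strip().upper()
    synonyms = {"+": "POS", "-": "NEG", "POSITIVE": "POS", "NEGATIVE": "NEG", "": "UNKNOWN"}
    text = synonyms.get(text, text)
    try:
        return enum_cls(text)
    except ValueError as exc:
        raise ValueError(f"cannot interpret {value!r} as {enum_cls.__name__}") from exc


@dataclass
class SampleAssay:
    """One sample's eight Ct values plus clinical metadata.

    Ct values are positive reals in ``(0, 45]`` or NaN when the reaction
    failed or was not run.  ``rna_conc`` (ng/µL) and ``a260_280`` are the
    optional spectrophotometric wet-lab QC fields.
    """

    sample_id: str
    diagnosis: Diagnosis = Diagnosis.UNKNOWN
    hpv_status: HPVStatus = HPVStatus.UNKNOWN
    ct_mir21: float = MISSING
    ct_mir29b: float = MISSING
    ct_mir145: float = MISSING
    ct_mir451a: float = MISSING
    ct_mir1246: float = MISSING
    ct_mir1290: float = MISSING
    ct_actb: float = MISSING
    ct_celmir39: float = MISSING
    rna_conc: float | None = None
    a260_280: float | None = None

    def __post_init__(self) -> None:
        if not str(self.sample_id):
            raise ValueError("sample_id must be non-empty")
        self.sample_id = str(self.sample_id)
        self.diagnosis = _coerce_enum(self.diagnosis, Diagnosis)
        self.hpv_status = _coerce_enum(self.hpv_status, HPVStatus)
        for name in CT_FIELDS:
            value = getattr(self, name)
            if value is None:
                setattr(self, name, MISSING)
                continue
            value = float(value)
            if not math.isnan(value) and not (CT_MIN < value <= CT_MAX):
                raise ValueError(
                    f"sample {self.sample_id!r}: {name}={value} outside "
                    f"({CT_MIN}, {CT_MAX}]"
                )
            setattr(self, name, value)

    def marker_cts(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MARKER_CT_FIELDS}

    def has_all_markers(self) -> bool:
        return not any(math.isnan(getattr(self, f)) for f in MARKER_CT_FIELDS)


@dataclass
class Cohort:
    """Ordered collection of assays with pairwise-distinct sample ids."""

    samples: list[SampleAssay] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_ids in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        """Wide-format view, one row per sample, stable ordering."""
        rows = []
        for s in self.samples:
            row = {
                "sample_id": s.sample_id,
                "diagnosis": s.diagnosis.value,
                "hpv_status": s.hpv_status.value,
            }
            row.update({f: getattr(s, f) for f in CT_FIELDS})
            row["rna_conc"] = s.rna_conc
            row["a260_280"] = s.a260_280
            rows.append(row)
        columns = ["sample_id", "diagnosis", "hpv_status", *CT_FIELDS, "rna_conc", "a260_280"]
        return pd.DataFrame(rows, columns=columns)

    def subset(self, sample_ids: Iterable[str]) -> "Cohort":
        """Sub-cohort restricted to ``sample_ids``, preserving cohort order."""
        keep = set(sample_ids)
        return Cohort(
            samples=[s for s in self.samples if s.sample_id in keep],
            provenance=dict(self.provenance),
        )


@dataclass
class ScoreResult:
    """Per-sample miR-CERVIX score with fold assignment and clinical band."""

    sample_id: str
    mir_cervix: float
    fold: int | None = None
    category: str = ""
    diagnosis: Diagnosis = Diagnosis.UNKNOWN
    hpv_status: HPVStatus = HPVStatus.UNKNOWN

    def __post_init__(self) -> None:
        if not 0.0 <= self.mir_cervix <= 1.0:
            raise ValueError(
                f"mir_cervix {self.mir_cervix} outside [0, 1] for {self.sample_id!r}"
            )
        self.diagnosis = _coerce_enum(self.diagnosis, Diagnosis)
        self.hpv_status = _coerce_enum(self.hpv_status, HPVStatus)


# ---------------------------------------------------------------------------
# Readers / writers


def _parse_ct(value, where: str):
    """Missing/non-numeric -> NaN; out-of-window numeric -> hard error."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING
    text = str(value).strip()
    if text == "" or text.lower() in {"na", "nan", "none", "undetermined", "undet"}:
        return MISSING
    try:
        ct = float(text)
    except ValueError:
        return MISSING
    if not (CT_MIN < ct <= CT_MAX):
        raise ValueError(f"Ct value {ct} outside ({CT_MIN}, {CT_MAX}] at {where}")
    return ct


def _read_long(frame: pd.DataFrame) -> list[SampleAssay]:
    required = {"sample_id", "target", "ct"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"long dialect requires columns {sorted(required)}; got {list(frame.columns)}"
        )
    order: list[str] = []
    per_sample: dict[str, dict] = {}
    seen_pairs: set[tuple[str, str]] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # header is line 1
        sid = str(row.sample_id)
        target = _canonical_target(row.target)
        if (sid, target) in seen_pairs:
            raise ValueError(
                f"duplicate (sample_id, target) pair ({sid!r}, {row.target!r}) at line {i}"
            )
        seen_pairs.add((sid, target))
        if sid not in per_sample:
            per_sample[sid] = {"sample_id": sid}
            order.append(sid)
        per_sample[sid][target] = _parse_ct(row.ct, f"line {i}")
        for meta in ("diagnosis", "hpv_status", "rna_conc", "a260_280"):
            if hasattr(row, meta):
                value = getattr(row, meta)
                if value is not None and not (isinstance(value, float) and math.isnan(value)):
                    per_sample[sid].setdefault(meta, value)
    return [SampleAssay(**per_sample[sid]) for sid in order]


def _read_wide(frame: pd.DataFrame) -> list[SampleAssay]:
    if "sample_id" not in frame.columns:
        raise ValueError("wide dialect requires a 'sample_id' column")
    known_meta = {"sample_id", "diagnosis", "hpv_status", "rna_conc", "a260_280"}
    rename: dict[str, str] = {}
    for col in frame.columns:
        if col in known_meta:
            continue
        rename[col] = _canonical_target(col)  # raises for unknown columns
    seen: set[str] = set()
    samples = []
    for i, record in enumerate(frame.to_dict("records"), start=2):
        kwargs: dict = {"sample_id": str(record["sample_id"])}
        if kwargs["sample_id"] in seen:
            raise ValueError(f"duplicate sample_id {kwargs['sample_id']!r} at line {i}")
        seen.add(kwargs["sample_id"])
        for meta in ("diagnosis", "hpv_status"):
            if meta in record:
                kwargs[meta] = record[meta]
        for meta in ("rna_conc", "a260_280"):
            if meta in record and record[meta] is not None:
                value = record[meta]
                if not (isinstance(value, float) and math.isnan(value)):
                    kwargs[meta] = float(value)
        for col, canon in rename.items():
            kwargs[canon] = _parse_ct(record[col], f"line {i}, column {col!r}")
        samples.append(SampleAssay(**kwargs))
    return samples


def read_cohort(path: str | Path, dialect: str = "long") -> Cohort:
    """Read a cohort CSV.

    Parameters
    ----------
    path:
        CSV file.  Long dialect: tidy rows ``sample_id, target, ct`` with
        optional ``diagnosis``/``hpv_status``/``rna_conc``/``a260_280``
        columns.  Wide dialect: one row per sample, Ct columns named by any
        accepted target alias (``miR-21``, ``hsa-miR-21-5p``, ``ct_mir21``…).
    dialect:
        ``"long"`` (canonical) or ``"wide"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype={"sample_id": str})
    if dialect == "long":
        samples = _read_long(frame)
    elif dialect == "wide":
        samples = _read_wide(frame)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")
    return Cohort(samples=samples, provenance={"source": str(path), "dialect": dialect})


def write_cohort(cohort: Cohort, path: str | Path, dialect: str = "long") -> Path:
    """Write a cohort CSV in the requested dialect (inverse of read_cohort)."""
    path = Path(path)
    if dialect == "wide":
        cohort.to_frame().to_csv(path, index=False)
        return path
    if dialect != "long":
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    for s in cohort.samples:
        for target in CT_FIELDS:
            ct = getattr(s, target)
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "target": target,
                    "ct": "" if math.isnan(ct) else repr(ct),
                    "diagnosis": s.diagnosis.value,
                    "hpv_status": s.hpv_status.value,
                    "rna_conc": s.rna_conc,
                    "a260_280": s.a260_280,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


SCORE_COLUMNS = ["sample_id", "mir_cervix", "fold", "category", "diagnosis", "hpv_status"]


def write_scores(results: Sequence[ScoreResult], path: str | Path) -> Path:
    """Write per-sample scores as CSV; scores serialised at 6 decimal places."""
    if not results:
        raise ValueError("cannot write an empty score collection")
    path = Path(path)
    rows = [
        {
            "sample_id": r.sample_id,
            "mir_cervix": f"{r.mir_cervix:.6f}",
            "fold": "" if r.fold is None else int(r.fold),
            "category": r.category,
            "diagnosis": r.diagnosis.value,
            "hpv_status": r.hpv_status.value,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, index=False)
    return path


def read_scores(path: str | Path) -> list[ScoreResult]:
    frame = pd.read_csv(path, dtype={"sample_id": str, "category": str})
    results = []
    for row in frame.itertuples(index=False):
        fold = row.fold
        fold = None if (fold is None or (isinstance(fold, float) and math.isnan(fold))) else int(fold)
        category = "" if (isinstance(row.category, float) and math.isnan(row.category)) else str(row.category)
        results.append(
            ScoreResult(
                sample_id=row.sample_id,
                mir_cervix=float(row.mir_cervix),
                fold=fold,
                category=category,
                diagnosis=row.diagnosis,
                hpv_status=row.hpv_status,
            )
        )
    return results
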