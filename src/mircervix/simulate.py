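"""Synthetic Ct-level cohort generator.

No patient-level data are deposited with the assay, so every downstream
stage is exercised on simulated cohorts that reproduce the study's
statistical structure: two morphological groups (114 NILM / 112 HSIL
enrolled), an HPV(+)/HPV(−) substructure within HSIL (72/101 positive; one
of 87 NILM positive), three marker miRNAs up-regulated in HSIL
(miR-145, miR-1246, miR-1290 — lower Ct), two down-regulated (miR-29b,
miR-451a — higher Ct), miR-21 stable, and a ~17% control-reaction failure
rate (38 of 226).

The noise model is two-level Normal: a per-sample offset shared by all
eight reactions (input-quantity variation — exactly what reciprocal-pair
normalization removes) plus independent per-reaction noise.  HSIL/HPV(−)
samples receive attenuated effects, mirroring their intermediate group
mean.  QC failures are injected through the control reactions only,
split evenly between an inflated ACTB Ct and an inflated spike-in Ct.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import Cohort, Diagnosis, HPVStatus, MARKER_CT_FIELDS, SampleAssay

__all__ = ["SimulationParams", "default_params", "simulate_cohort"]

#: Baseline NILM-state Ct per marker, cycles.  Plausible qPCR magnitudes for
#: an abundant-to-moderate miRNA panel; arbitrary, documented as such.
_DEFAULT_BASELINE = {
    "ct_mir21": 24.0,
    "ct_mir29b": 26.0,
    "ct_mir145": 25.0,
    "ct_mir451a": 23.0,
    "ct_mir1246": 27.0,
    "ct_mir1290": 29.0,
}

#: HSIL ΔCt shifts, cycles; negative = up-regulated (more template, lower Ct).
_DEFAULT_EFFECT = {
    "ct_mir21": 0.0,     # normalizer, stable
    "ct_mir29b": +0.8,   # down-regulated
    "ct_mir145": -1.2,   # up-regulated
    "ct_mir451a": +1.0,  # down-regulated
    "ct_mir1246": -1.0,  # up-regulated
    "ct_mir1290": -0.8,  # up-regulated
}


@dataclass
class SimulationParams:
    """Generator parameters; defaults emulate the study conditions."""

    n_nilm: int = 114
    n_hsil: int = 112
    baseline_ct: dict = field(default_factory=lambda: dict(_DEFAULT_BASELINE))
    effect_hsil: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECT))
    hpv_frac_hsil: float = 72 / 101
    hpv_frac_nilm: float = 1 / 87
    effect_hpvneg_scale: float = 0.6
    sample_offset_sd: float = 1.5    # cycles, shared across a sample's reactions
    reaction_noise_sd: float = 1.25  # cycles, independent per reaction
    qc_fail_rate: float = 38 / 226
    actb_mean: float = 28.0
    spikein_mean: float = 17.5
    control_noise_sd: float = 0.3    # cycles; control assays are robust
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nilm < 1 or self.n_hsil < 1:
            raise ValueError("group sizes must be >= 1")
        for name in ("hpv_frac_hsil", "hpv_frac_nilm", "qc_fail_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if not 0.0 <= self.effect_hpvneg_scale <= 1.0:
            raise ValueError("effect_hpvneg_scale must be in [0, 1]")
        for name in ("sample_offset_sd", "reaction_noise_sd", "control_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        missing = set(MARKER_CT_FIELDS) - set(self.baseline_ct)
        if missing:
            raise ValueError(f"baseline_ct missing markers: {sorted(missing)}")
        missing = set(MARKER_CT_FIELDS) - set(self.effect_hsil)
        if missing:
            raise ValueError(f"effect_hsil missing markers: {sorted(missing)}")

    def replace(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


def default_params(seed: int = 0, **overrides) -> SimulationParams:
    """Documented default parameter set (study-shaped cohort).

    Effect sizes are calibrated once so that the default pipeline shows a
    clear but imperfect separation between groups — overlapping score
    distributions, not a perfect classifier.
    """
    return SimulationParams(seed=seed, **overrides)


def _simulate_sample(
    rng: np.random.Generator,
    sample_id: str,
    diagnosis: Diagnosis,
    hpv: HPVStatus,
    params: SimulationParams,
) -> SampleAssay:
    offset = rng.normal(0.0, params.sample_offset_sd) if params.sample_offset_sd else 0.0
    if diagnosis == Diagnosis.HSIL:
        scale = 1.0 if hpv == HPVStatus.POS else params.effect_hpvneg_scale
    else:
        scale = 0.0
    cts = {}
    for marker in MARKER_CT_FIELDS:
        noise = rng.normal(0.0, params.reaction_noise_sd) if params.reaction_noise_sd else 0.0
        cts[marker] = params.baseline_ct[marker] + scale * params.effect_hsil[marker] + offset + noise
    control_noise = (
        lambda: rng.normal(0.0, params.control_noise_sd) if params.control_noise_sd else 0.0
    )
    # ACTB tracks material quantity (shares the offset); the spike-in is added
    # at fixed concentration after isolation, so it does not.
    actb = params.actb_mean + offset + control_noise()
    spikein = params.spikein_mean + control_noise()
    # control-reaction failure injection, split evenly between the two controls
    if rng.random() < params.qc_fail_rate:
        if rng.random() < 0.5:
            actb = 34.0 + rng.uniform(0.5, 4.0)
        else:
            spikein = 18.5 + rng.uniform(0.5, 4.0)
    clip = lambda ct: float(np.clip(ct, 1.0, 45.0))
    return SampleAssay(
        sample_id=sample_id,
        diagnosis=diagnosis,
        hpv_status=hpv,
        ct_actb=clip(actb),
        ct_celmir39=clip(spikein),
        **{marker: clip(ct) for marker, ct in cts.items()},
    )


def simulate_cohort(params: SimulationParams | None = None) -> Cohort:
    """Generate a labeled Ct-level cohort; deterministic given the seed."""
    params = params or default_params()
    rng = np.random.default_rng(params.seed)
    samples = []
    for i in range(params.n_nilm):
        hpv = HPVStatus.POS if rng.random() < params.hpv_frac_nilm else HPVStatus.NEG
        samples.append(
            _simulate_sample(rng, f"NILM-{i + 1:04d}", Diagnosis.NILM, hpv, params)
        )
    for i in range(params.n_hsil):
        hpv = HPVStatus.POS if rng.random() < params.hpv_frac_hsil else HPVStatus.NEG
        samples.append(
            _simulate_sample(rng, f"HSIL-{i + 1:04d}", Diagnosis.HSIL, hpv, params)
        )
    return Cohort(
        samples=samples,
        provenance={"source": "synthetic", "generator_seed": params.seed},
    )
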