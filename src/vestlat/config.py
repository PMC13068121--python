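"""Configuration models (validated with pydantic).

``SyntheticConfig`` parameterizes the synthetic cohort generator; its
defaults define the simulated study conditions (effect sizes, recording
bias, missingness, flip rate).  ``RunConfig`` drives the end-to-end
pipeline.  All models are JSON-(de)serializable.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

from pydantic import BaseModel, Field, ValidationError, model_validator

from .exceptions import ConfigurationError

__all__ = [
    "GainDeficit",
    "DeficitConfig",
    "VhitBias",
    "MissingRates",
    "NoiseConfig",
    "BaselineConfig",
    "SyntheticConfig",
    "RunConfig",
    "validated",
]


def validated(model_cls, **kwargs):
    """Construct a config model, converting pydantic errors into
    :class:`ConfigurationError` naming the offending field."""
    try:
        return model_cls(**kwargs)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or model_cls.__name__
        raise ConfigurationError(f"invalid configuration field '{loc}': {first['msg']}") from exc


class GainDeficit(BaseModel):
    """Normal distributions of affected vs unaffected VOR gains for one
    canal type (gains are truncated below at 0.05)."""

    affected_mean: float = Field(ge=0)
    affected_sd: float = Field(ge=0)
    unaffected_mean: float = Field(ge=0)
    unaffected_sd: float = Field(ge=0)


class DeficitConfig(BaseModel):
    """Per-test lateralized effect sizes of the simulated tumor."""

    # Lateral-canal gains: affected side clearly hypofunctional.
    lateral: GainDeficit = GainDeficit(
        affected_mean=0.60, affected_sd=0.10, unaffected_mean=0.95, unaffected_sd=0.05
    )
    # Vertical (anterior/posterior) canals, slightly lower baseline.
    vertical: GainDeficit = GainDeficit(
        affected_mean=0.55, affected_sd=0.10, unaffected_mean=0.90, unaffected_sd=0.05
    )
    # Multiplicative amplitude reduction on the affected-side pathway.
    cvemp_factor: float = Field(default=0.4, ge=0)
    ovemp_factor: float = Field(default=0.6, ge=0)
    # Multiplicative slow-phase-velocity reduction of the affected ear.
    caloric_factor: float = Field(default=0.35, ge=0)
    # Mean verticality tilt toward the affected side, degrees.
    svv_tilt: float = Field(default=3.0, ge=0)

    @classmethod
    def null(cls) -> "DeficitConfig":
        """A deficit-free configuration: both sides drawn identically."""
        sym_lat = GainDeficit(
            affected_mean=0.95, affected_sd=0.05, unaffected_mean=0.95, unaffected_sd=0.05
        )
        sym_ver = GainDeficit(
            affected_mean=0.90, affected_sd=0.05, unaffected_mean=0.90, unaffected_sd=0.05
        )
        return cls(
            lateral=sym_lat,
            vertical=sym_ver,
            cvemp_factor=1.0,
            ovemp_factor=1.0,
            caloric_factor=1.0,
            svv_tilt=0.0,
        )


class VhitBias(BaseModel):
    """Systematic left-minus-right gain offset of monocular (right-eye)
    vHIT recording, by canal type.  Negative values mean the right gain
    is inflated.  Applied identically to patients and controls."""

    lateral: float = -0.06
    anterior: float = -0.01
    posterior: float = -0.03

    @classmethod
    def null(cls) -> "VhitBias":
        return cls(lateral=0.0, anterior=0.0, posterior=0.0)


class MissingRates(BaseModel):
    """Per-test-block probability that a subject's block is absent."""

    vhit: float = Field(default=0.0, ge=0, le=1)
    cvemp: float = Field(default=0.0, ge=0, le=1)
    ovemp: float = Field(default=0.044, ge=0, le=1)
    svv: float = Field(default=0.058, ge=0, le=1)
    caloric: float = Field(default=0.073, ge=0, le=1)

    @classmethod
    def null(cls) -> "MissingRates":
        return cls(vhit=0, cvemp=0, ovemp=0, svv=0, caloric=0)


class NoiseConfig(BaseModel):
    """Measurement / subject-level noise.

    VEMP amplitudes and caloric SPVs carry multiplicative log-normal
    noise (sigma on the log scale).  SVV has a per-subject idiosyncratic
    verticality bias (``svv_subject_sd``, degrees) on top of per-trial
    noise; the subject-level term dominates the mean tumor tilt, which
    keeps the simulated SVV weakly lateralizing (clinically: central
    compensation often restores verticality perception).
    """

    vemp_sigma: float = Field(default=0.2, ge=0)
    caloric_sigma: float = Field(default=0.2, ge=0)
    svv_subject_sd: float = Field(default=6.0, ge=0)
    svv_trial_sd: float = Field(default=1.5, ge=0)


class BaselineConfig(BaseModel):
    """Healthy-side baseline levels of the amplitude/SPV tests."""

    cvemp_mean: float = Field(default=160.0, gt=0)  # µV, pre-tension corrected
    cvemp_sd: float = Field(default=40.0, ge=0)
    ovemp_mean: float = Field(default=12.0, gt=0)  # µV
    ovemp_sd: float = Field(default=4.0, ge=0)
    caloric_shape: float = Field(default=8.0, gt=0)  # Gamma shape of base SPV
    caloric_scale: float = Field(default=2.5, gt=0)  # Gamma scale, °/s


class SyntheticConfig(BaseModel):
    """Full specification of a simulated patient + comparison cohort."""

    n_patients: int = Field(default=68, ge=1)
    n_controls: int = Field(default=33, ge=1)
    p_right: float = Field(default=0.5, ge=0, le=1)
    deficit: DeficitConfig = DeficitConfig()
    baseline: BaselineConfig = BaselineConfig()
    vhit_bias: VhitBias = VhitBias()
    missing_rates: MissingRates = MissingRates()
    outlier_rate: float = Field(default=0.02, ge=0, le=1)
    p_flip: float = Field(default=0.05, ge=0, le=1)
    noise: NoiseConfig = NoiseConfig()
    seed: int = 0

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        return validated(cls, **json.loads(text))

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True)


#: Canonical sign orientation per metric: +1 keeps the as-printed sign,
#: -1 negates it, so that positive always means "right side affected"
#: (equivalently, better left-side function).
ORIENTATION = {
    "rlll": 1,
    "ralp": 1,
    "larp": 1,
    "cmp_ap": 1,
    "ovemp_ar": -1,
    "cvemp_ar": -1,
    "caloric_cp": -1,
    "svv_shift": 1,
}

#: Pathological thresholds, applied strictly (boundary values are normal).
THRESHOLDS = {
    "lateral_gain": 0.8,
    "vertical_gain": 0.7,
    "caloric_cp": 25.0,
    "svv_shift": 2.2,
}


class RunConfig(BaseModel):
    """End-to-end pipeline configuration.

    Either ``simulate`` (a SyntheticConfig) or ``patients_csv`` (plus
    optionally ``controls_csv``) must be given.
    """

    simulate: Optional[SyntheticConfig] = None
    patients_csv: Optional[str] = None
    controls_csv: Optional[str] = None
    classifier: str = "logistic"
    correct_bias: bool = True
    offset_side: str = "left"  # which gain absorbs the offset: "left" | "split"
    n_boot: int = Field(default=2000, ge=1)
    seed: int = 0
    out_dir: str = "vestlat_report"

    @model_validator(mode="after")
    def _check_inputs(self):
        if self.simulate is None and self.patients_csv is None:
            raise ValueError("either 'simulate' or 'patients_csv' is required")
        if self.classifier not in {"logistic", "naive_bayes", "linear_svm"}:
            raise ValueError(f"unknown classifier '{self.classifier}'")
        if self.offset_side not in {"left", "split"}:
            raise ValueError("offset_side must be 'left' or 'split'")
        return self

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return validated(cls, **json.loads(text))

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True)

    def hash(self) -> str:
        # the output location does not affect what is computed
        payload = self.model_dump()
        payload.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]
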