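"""Run configuration: a single serializable object drives the whole pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .preprocess import RejectionCriteria
from .synth import ArtifactSpec, ConditionEffectProfile, default_profiles


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs.

    One master ``seed`` deterministically derives every stage's seed, so two
    runs with equal configs produce byte-identical outputs.
    """

    # cohort
    n_participants: int = 15
    fs: float = 256.0
    duration: float = 300.0
    participant_sigma: float = 0.2
    noise_rms: float = 4.0
    effect_profiles: dict = field(default_factory=dict)  # condition -> profile dict
    artifacts: dict = field(default_factory=dict)  # ArtifactSpec overrides
    # preprocessing
    band_low_hz: float = 0.5
    band_high_hz: float = 70.0
    epoch_length: float = 2.0
    rejection: dict = field(default_factory=dict)  # RejectionCriteria overrides
    use_ica: bool = False
    ica_threshold: float = 0.8
    # selection
    top_k: int = 20
    # modeling
    n_folds: int = 5
    classifier_overrides: dict = field(default_factory=dict)  # kind -> hp dict
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not (0 < self.band_low_hz < self.band_high_hz < self.fs / 2):
            raise ConfigurationError("need 0 < band_low < band_high < fs/2")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")

    # --- materialized domain objects -------------------------------------

    def profiles(self) -> dict[str, ConditionEffectProfile]:
        profs = default_profiles()
        for cond, spec in self.effect_profiles.items():
            profs[cond] = ConditionEffectProfile(
                band_multipliers=dict(spec.get("band_multipliers", {})),
                asymmetry_offsets={
                    tuple(k.split(":")): v
                    for k, v in spec.get("asymmetry_offsets", {}).items()
                },
            )
        return profs

    def artifact_spec(self) -> ArtifactSpec:
        base = ArtifactSpec()
        fields = {**asdict(base), **self.artifacts}
        fields["muscle_band"] = tuple(fields["muscle_band"])
        return ArtifactSpec(**fields)

    def rejection_criteria(self) -> RejectionCriteria:
        return RejectionCriteria(**{**asdict(RejectionCriteria()), **self.rejection})

    # --- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
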