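"""Run configuration: serialisable defaults reproducing the reference
study design and parameter set, with YAML round-trip and CLI overrides."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model_core import (
    DEFAULT_MIU_TO_UG,
    PDParameters,
    PKParameters,
    default_pd_parameters,
    default_pk_parameters,
)
from .synthetic import (
    RandomEffectsSpec,
    ResidualErrorSpec,
    StudyDesign,
    default_pd_error,
    default_pk_error,
    default_random_effects,
)

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    groups: list[list[float]] = field(
        default_factory=lambda: [[9.0, 6], [18.0, 6], [27.0, 6], [36.0, 6]]
    )
    pk_times: list[float] | None = None   # None -> design default
    pd_times: list[float] | None = None
    miu_to_ug: float = DEFAULT_MIU_TO_UG
    pk_theta: dict = field(default_factory=lambda: dataclasses.asdict(default_pk_parameters()))
    pd_theta: dict = field(default_factory=lambda: dataclasses.asdict(default_pd_parameters()))
    pk_omega: dict = field(default_factory=lambda: dict(default_random_effects()[0].omega))
    pd_omega: dict = field(default_factory=lambda: dict(default_random_effects()[1].omega))
    pk_sigma: dict = field(default_factory=lambda: dataclasses.asdict(default_pk_error()))
    pd_sigma: dict = field(default_factory=lambda: dataclasses.asdict(default_pd_error()))
    seed: int = 1
    n_bootstrap: int = 1000
    n_vpc: int = 1000
    fit_maxfev: int = 4000
    recovery_tolerance: float = 0.20
    outdir: str = "results"

    def validate(self) -> None:
        for dose, n in self.groups:
            if dose <= 0:
                raise ValueError(f"group dose must be > 0, got {dose}")
            if int(n) <= 0:
                raise ValueError(f"group size must be > 0, got {n}")
        if self.n_bootstrap < 1 or self.n_vpc < 1:
            raise ValueError("replicate counts must be >= 1")
        # constructing the model objects runs their invariant checks
        self.design()
        self.pk_parameters()
        self.pd_parameters()
        self.pk_error()
        self.pd_error()

    # -- model-object accessors -------------------------------------------
    def design(self) -> StudyDesign:
        kwargs: dict = {
            "groups": tuple((float(d), int(n)) for d, n in self.groups),
            "miu_to_ug": self.miu_to_ug,
        }
        if self.pk_times is not None:
            kwargs["pk_times"] = tuple(self.pk_times)
        if self.pd_times is not None:
            kwargs["pd_times"] = tuple(self.pd_times)
        return StudyDesign(**kwargs)

    def pk_parameters(self) -> PKParameters:
        return PKParameters(**self.pk_theta)

    def pd_parameters(self) -> PDParameters:
        return PDParameters(**self.pd_theta)

    def pk_iiv(self) -> RandomEffectsSpec:
        return RandomEffectsSpec(self.pk_omega)

    def pd_iiv(self) -> RandomEffectsSpec:
        return RandomEffectsSpec(self.pd_omega)

    def pk_error(self) -> ResidualErrorSpec:
        return ResidualErrorSpec(**self.pk_sigma)

    def pd_error(self) -> ResidualErrorSpec:
        return ResidualErrorSpec(**self.pd_sigma)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the full configuration for provenance records."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
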