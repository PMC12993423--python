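"""Run configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .errors import ConfigError

DEFAULT_STRUCTURES = ("body", "bladder", "rectum", "prostate")


@dataclass
class RunConfig:
    """Knobs of the evaluation pipeline.

    ``structures`` are the organs evaluated per fraction; the planning
    target surrogate (``<prostate_name>+1cm``) is always added, built by
    uniform expansion of the prostate by ``margin_mm``.  Deviations of a
    dose-volume metric beyond ``deviation_threshold_pct`` percent of the
    planned value are flagged as relevant.  Geometry and DVH metrics are
    evaluated on the dose grid resampled to ``geometry_spacing_mm``
    isotropic.
    """

    structures: tuple[str, ...] = DEFAULT_STRUCTURES
    prostate_name: str = "prostate"
    margin_mm: float = 10.0
    deviation_threshold_pct: float = 2.0
    bin_width_gy: float = 0.1
    fine_bin_width_gy: float = 0.01
    supersample: int = 4
    geometry_spacing_mm: float = 1.0
    max_outside_fraction: float = 0.05
    strict: bool = False
    seed: int = 0
    output_formats: tuple[str, ...] = ("json", "csv")
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.deviation_threshold_pct <= 0:
            raise ConfigError("deviation threshold must be > 0")
        if self.margin_mm <= 0:
            raise ConfigError("margin must be > 0")
        if self.bin_width_gy <= 0 or self.fine_bin_width_gy <= 0:
            raise ConfigError("bin widths must be > 0")
        if self.supersample < 1:
            raise ConfigError("supersample must be >= 1")
        if self.geometry_spacing_mm <= 0:
            raise ConfigError("geometry spacing must be > 0")
        self.structures = tuple(self.structures)

    @property
    def target_name(self) -> str:
        return f"{self.prostate_name}+1cm"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)
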