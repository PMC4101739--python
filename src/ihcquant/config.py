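"""Run configuration: one YAML/JSON file driving simulate -> quantify -> compare."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import SyntheticConfig

__all__ = ["RunConfig", "CohortSpec", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort layout: tissues x (n_normal + n_tumor) samples.

    Defaults mirror the montage being emulated: 12 tissues, one normal and
    three tumor samples each, with high stromal DAB in normal tissue
    (fraction 0.4) and low in tumors (0.1).
    """

    tissues: tuple[str, ...] = (
        "bladder", "breast", "cervix", "colon", "kidney", "ovary",
        "pancreas", "prostate", "rectum", "skin", "stomach", "testis",
    )
    n_normal: int = 1
    n_tumor: int = 3
    normal: SyntheticConfig = field(
        default_factory=lambda: SyntheticConfig(dab_target_fraction=0.4, noise_sd=5.0)
    )
    tumor: SyntheticConfig = field(
        default_factory=lambda: SyntheticConfig(dab_target_fraction=0.1, noise_sd=5.0)
    )


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration."""

    out_dir: str = "ihcquant_run"
    seed: int = 0
    stain_matrix_csv: str | None = None
    threshold_mode: str = "otsu"  # otsu | triangle | fixed
    fixed_threshold: float | None = None
    min_threshold: float = 0.05
    min_particle_size: int = 4
    connectivity: int = 8
    tissue_od_threshold: float = 0.06
    comparison_metric: str = "dab_area_fraction"
    plot_format: str = "png"
    log_level: str = "INFO"
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def __post_init__(self) -> None:
        if self.min_particle_size < 0:
            raise ConfigError("min_particle_size must be >= 0")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")
        if self.threshold_mode not in ("otsu", "triangle", "fixed"):
            raise ConfigError("threshold_mode must be otsu, triangle, or fixed")
        if self.threshold_mode == "fixed" and self.fixed_threshold is None:
            raise ConfigError("fixed threshold mode requires fixed_threshold")
        if self.tissue_od_threshold < 0:
            raise ConfigError("tissue_od_threshold must be >= 0")
        if self.plot_format not in ("png", "svg"):
            raise ConfigError("plot_format must be png or svg")
        if self.stain_matrix_csv is not None and not Path(self.stain_matrix_csv).exists():
            raise ConfigError(f"stain matrix CSV not found: {self.stain_matrix_csv}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the scientific configuration.

        Output location and logging verbosity do not affect results, so they
        are excluded: the same analysis run into two directories hashes
        identically.
        """
        payload = {k: v for k, v in self.to_dict().items()
                   if k not in ("out_dir", "log_level")}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)} in {path}")
    return cls(**data)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML or JSON."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping: {path}")
    cohort_raw = raw.pop("cohort", None)
    cohort = CohortSpec()
    if cohort_raw is not None:
        for key in ("normal", "tumor"):
            if key in cohort_raw:
                cohort_raw[key] = _build(SyntheticConfig, cohort_raw[key], str(path))
        if "tissues" in cohort_raw:
            cohort_raw["tissues"] = tuple(cohort_raw["tissues"])
        cohort = _build(CohortSpec, cohort_raw, str(path))
    return _build(RunConfig, {**raw, "cohort": cohort}, str(path))
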