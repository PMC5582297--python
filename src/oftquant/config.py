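"""Run configuration: one YAML record of every threshold the pipeline applies."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class Thresholds:
    """Every cutoff applied anywhere in the pipeline, with study defaults."""

    mass_error_ppm_max: float = 20.0
    reporter_floor: float = 500.0
    intensity_floor: float = 4000.0
    input_p_max: float = 0.1
    q_cutoff: float = 0.1
    z_threshold: float = 2.0
    pathway_p_max: float = 0.05
    window_width_deg: float = 20.0
    gap_nm: float = 200.0
    top_k: int = 3

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ConfigError(f"threshold {name} must be positive, got {value}")


@dataclass
class SampleSpec:
    sample_id: str
    group: str  # "control" | "banded"
    volume_tiff: str
    volume_yaml: str
    annotations_tsv: str


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    samples: list[SampleSpec] = field(default_factory=list)
    psm_tsv: str | None = None
    pathways_tsv: str | None = None
    diameters_tsv: str | None = None
    normalize_channels: bool = True

    def __post_init__(self) -> None:
        groups = {s.group for s in self.samples}
        bad = groups - {"control", "banded"}
        if bad:
            raise ConfigError(f"unknown sample group(s): {sorted(bad)}")


def load_config(path: str | Path) -> RunConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        thresholds = Thresholds(**raw.get("thresholds", {}))
        samples = [SampleSpec(**s) for s in raw.get("samples", [])]
        return RunConfig(
            out_dir=raw["out_dir"],
            seed=int(raw.get("seed", 0)),
            thresholds=thresholds,
            samples=samples,
            psm_tsv=raw.get("psm_tsv"),
            pathways_tsv=raw.get("pathways_tsv"),
            diameters_tsv=raw.get("diameters_tsv"),
            normalize_channels=bool(raw.get("normalize_channels", True)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
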