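"""YAML-backed pipeline configuration with strict validation.

Every threshold defaults to the study value where one exists (QC and
consensus-call strata, the 3-cell and 10-bp site filters, alpha = 0.002,
beta = 0.2, FDR 0.05, |log2FC| > 1, SIFT 0.05, PolyPhen 0.85). Unknown keys
are rejected with their full path, so typos never silently fall back to a
default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .lineage import ErrorModel
from .scgeno import FilterConfig
from .sim import SimConfig

__all__ = ["PipelineConfig", "ConcordanceConfig", "ClonesConfig",
           "GenesConfig", "validate_config", "config_from_dict"]


@dataclass
class ConcordanceConfig:
    low_maf_min_support: int = 2
    low_maf_ceiling: float = 0.05
    caller_min_vaf: float = 0.05        # emulated caller sensitivity on sim bulk
    caller_min_alt: int = 4
    min_bulk_depth: int = 10

    def validate(self) -> None:
        if not 0.0 < self.low_maf_ceiling <= 1.0:
            raise ValueError("concordance.low_maf_ceiling must be in (0, 1]")
        if self.low_maf_min_support < 1:
            raise ValueError("concordance.low_maf_min_support must be >= 1")


@dataclass
class ClonesConfig:
    k: int | str = "auto"
    snv_k: int | str = "auto"
    min_support: int = 10
    mds_dims: int = 2

    def validate(self) -> None:
        for name in ("k", "snv_k"):
            v = getattr(self, name)
            if v != "auto" and (not isinstance(v, int) or v < 1):
                raise ValueError(f"clones.{name} must be 'auto' or a positive int")
        if self.min_support < 1:
            raise ValueError("clones.min_support must be >= 1")


@dataclass
class LineageConfig:
    alpha: float = 0.002
    beta: float = 0.2

    def validate(self) -> None:
        try:
            self.error_model()
        except ValueError as exc:
            raise ValueError(f"lineage.{exc}") from None

    def error_model(self) -> ErrorModel:
        return ErrorModel(alpha=self.alpha, beta=self.beta)


@dataclass
class GenesConfig:
    fdr_threshold: float = 0.05
    lfc_threshold: float = 1.0
    sift_threshold: float = 0.05
    polyphen_threshold: float = 0.85
    min_cells_mutated: int = 3

    def validate(self) -> None:
        for name in ("fdr_threshold", "sift_threshold", "polyphen_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"genes.{name} must be in (0, 1), got {v}")
        if self.lfc_threshold < 0:
            raise ValueError("genes.lfc_threshold must be >= 0")


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    concordance: ConcordanceConfig = field(default_factory=ConcordanceConfig)
    clones: ClonesConfig = field(default_factory=ClonesConfig)
    lineage: LineageConfig = field(default_factory=LineageConfig)
    genes: GenesConfig = field(default_factory=GenesConfig)
    seed: int = 42
    out_dir: str = "scwes_run"
    log_level: str = "INFO"

    def validate(self) -> None:
        self.sim.seed = int(self.seed)      # one seed fans out to every stage
        self.sim.validate()
        self.filter.validate()
        self.concordance.validate()
        self.clones.validate()
        self.lineage.validate()
        self.genes.validate()


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s): "
                         f"{', '.join(sorted(f'{path}{k}' for k in unknown))}")
    return cls(**data)


_SECTIONS = {"sim": SimConfig, "filter": FilterConfig,
             "concordance": ConcordanceConfig, "clones": ClonesConfig,
             "lineage": LineageConfig, "genes": GenesConfig}


def config_from_dict(data: dict | None) -> PipelineConfig:
    data = dict(data or {})
    unknown = set(data) - set(_SECTIONS) - {"seed", "out_dir", "log_level"}
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data.pop(name)
            if not isinstance(section, dict):
                raise ValueError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build(cls, section, f"{name}.")
    kwargs.update(data)
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def validate_config(path: str | None) -> PipelineConfig:
    """Parse, default and range-check a YAML config (empty file = defaults)."""
    if path is None:
        return config_from_dict({})
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return config_from_dict(data)
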