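"""Pipeline configuration: YAML-backed per-stage parameter blocks.

Every stage block is present with defaults; a YAML file overrides fields
selectively. The global seed is threaded into every stage and recorded in
all outputs via the provenance header.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .diffabund import DAParams
from .ml import ResampleParams
from .preprocess import FilterParams, ImputeParams
from .signature import TierParams
from .synthetic import SyntheticConfig


@dataclass(frozen=True)
class ValidationParams:
    m: int = 6  # Bonferroni denominator: number of panel proteins tested
    equal_var: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    simulate: SyntheticConfig = field(default_factory=SyntheticConfig)
    filter: FilterParams = field(default_factory=FilterParams)
    impute: ImputeParams = field(default_factory=ImputeParams)
    da: DAParams = field(default_factory=DAParams)
    resampling: ResampleParams = field(default_factory=ResampleParams)
    tiering: TierParams = field(default_factory=TierParams)
    validation: ValidationParams = field(default_factory=ValidationParams)
    seed: int = 0
    out_dir: str = "results"

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Propagate one global seed into every seeded stage block."""
        return replace(
            self,
            seed=seed,
            simulate=replace(self.simulate, seed=seed),
            impute=replace(self.impute, seed=seed),
            da=replace(self.da, seed=seed),
            resampling=replace(self.resampling, seed=seed),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulate"]["signal_proteins"] = [list(p) for p in self.simulate.signal_proteins]
        return d


_BLOCKS = {
    "simulate": SyntheticConfig,
    "filter": FilterParams,
    "impute": ImputeParams,
    "da": DAParams,
    "resampling": ResampleParams,
    "tiering": TierParams,
    "validation": ValidationParams,
}


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus programmatic overrides."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for k, v in overrides.items():
            raw.setdefault(k, {}) if isinstance(v, dict) else None
            if isinstance(v, dict):
                raw[k] = {**raw.get(k, {}), **v}
            else:
                raw[k] = v
    kwargs = {}
    for name, cls in _BLOCKS.items():
        block = raw.get(name, {})
        if name == "simulate" and "signal_proteins" in block:
            block = {**block, "signal_proteins": tuple(tuple(p) for p in block["signal_proteins"])}
        if name == "simulate" and "base_log2_mean_range" in block:
            block = {**block, "base_log2_mean_range": tuple(block["base_log2_mean_range"])}
        kwargs[name] = cls(**block)
    cfg = PipelineConfig(
        **kwargs, seed=int(raw.get("seed", 0)), out_dir=str(raw.get("out_dir", "results"))
    )
    return cfg.with_seed(cfg.seed)
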