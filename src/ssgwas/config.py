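"""Pipeline configuration: one structured text file (YAML or JSON dialect)
drives every stage with validated, documented defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .qc import QcThresholds
from .traits import TRAIT_NAMES

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # input paths
    pedigree: str = ""
    genotypes: str = ""
    genotype_map: str = ""
    phenotypes: str = ""  # trait table TSV (one row per sow)
    sow_records: str = ""  # alternative raw litter records
    herd_days: str = ""
    gene_annotation: str = ""
    gene_annotation_format: str = "bed"
    output_dir: str = "ssgwas_out"
    # analysis options
    traits: tuple = TRAIT_NAMES
    fixed_effects: tuple = (
        "farm",
        "last_parity",
        "last_farrow_month",
        "last_farrow_year",
    )
    qc: QcThresholds = field(default_factory=QcThresholds)
    iterations: int = 2
    window_size: int = 5
    threshold_pct: float = 1.0
    denominator: str = "reml"
    blend_tau: float = 0.05
    tune_diagonal: bool = True
    flank_bp: int = 2_000_000
    reml_max_rounds: int = 200
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.threshold_pct <= 100.0:
            raise ValueError("threshold_pct must be in [0, 100]")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if not 0.0 <= self.blend_tau < 1.0:
            raise ValueError("blend_tau must be in [0, 1)")
        if self.denominator not in ("reml", "empirical"):
            raise ValueError("denominator must be 'reml' or 'empirical'")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")

    def check_paths(self) -> None:
        for name in ("pedigree", "genotypes", "gene_annotation"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["traits"] = list(self.traits)
        d["fixed_effects"] = list(self.fixed_effects)
        return d


def load_config(path) -> PipelineConfig:
    """Read a YAML (or JSON, a YAML subset) config file; unknown keys are
    rejected so typos fail loudly before any stage runs."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    qc_raw = raw.pop("qc", {})
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if qc_raw:
        cfg.qc = QcThresholds(**qc_raw)
    if isinstance(cfg.traits, list):
        cfg.traits = tuple(cfg.traits)
    if isinstance(cfg.fixed_effects, list):
        cfg.fixed_effects = tuple(cfg.fixed_effects)
    cfg.validate()
    return cfg
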