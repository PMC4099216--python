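"""Run configuration: every filter threshold of the pipeline in one namespace.

Defaults are the analysis settings the method is defined with (call rates 99%/98%, HWE p<1e-6,
cDNA contamination >40%, expression >=1000 fluorescence units, >=3 informative
SNPs per window, +/-250 kb candidate window, association p<1e-6 with |slope|
>=0.05 and >=4 samples per allele combination, 2-of-4 replicate peaks with >50%
overlap at peak p<=1e-5, +/-2.5 kb enhancer flanks, 10% FDR for co-expression,
r^2>=0.8 LD proxies).  The config serializes to a flat dotted-key YAML file so
any threshold can be overridden for sensitivity analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class QcConfig:
    snp_call_rate: float = 0.99
    sample_call_rate: float = 0.98
    hwe_p: float = 1e-6
    cdna_contamination_call_rate: float = 0.40


@dataclass
class NormConfig:
    n_bins: int = 100


@dataclass
class AseConfig:
    min_informative_snps: int = 3
    expression_threshold: float = 1000.0


@dataclass
class AssocConfig:
    window_bp: int = 250_000
    p_thresh: float = 1e-6
    slope_thresh: float = 0.05
    min_per_class: int = 4


@dataclass
class EnrichConfig:
    min_support: int = 2
    min_overlap: float = 0.5
    peak_p_thresh: float = 1e-5
    flank_bp: int = 2500
    nonsig_p: float = 0.5


@dataclass
class CoexprConfig:
    fdr_q: float = 0.10
    ase_p_thresh: float = 1e-6


@dataclass
class GwasConfig:
    r2_thresh: float = 0.8


@dataclass
class PipelineConfig:
    """Aggregate of all stage configurations."""

    qc: QcConfig = field(default_factory=QcConfig)
    norm: NormConfig = field(default_factory=NormConfig)
    ase: AseConfig = field(default_factory=AseConfig)
    assoc: AssocConfig = field(default_factory=AssocConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    coexpr: CoexprConfig = field(default_factory=CoexprConfig)
    gwas: GwasConfig = field(default_factory=GwasConfig)

    def to_flat_dict(self) -> dict:
        out = {}
        for sect in dataclasses.fields(self):
            sub = getattr(self, sect.name)
            for f in dataclasses.fields(sub):
                out[f"{sect.name}.{f.name}"] = getattr(sub, f.name)
        return out

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "PipelineConfig":
        cfg = cls()
        known = cfg.to_flat_dict()
        for key, value in flat.items():
            if key not in known:
                raise KeyError(f"unknown config key: {key!r}")
            sect, name = key.split(".", 1)
            sub = getattr(cfg, sect)
            current = getattr(sub, name)
            setattr(sub, name, type(current)(value))
        return cfg

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            flat = yaml.safe_load(fh) or {}
        return cls.from_flat_dict(flat)
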