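"""Run-time thresholds of the haplotype-aware pipeline.

Every default traces to a published analysis rule (mutant-tag counts for
point-mutation phasing, supporting-read fractions for SV phasing, the
Bonferroni level and count/fraction floors of the biased-region scan,
junction-validation coverage/identity, CNV copy-number cut-offs). They are
overridable from a YAML mapping, but unknown keys are rejected so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # windowing
    window_size_bp: int = 100_000          # mutation-cluster scan tiles
    methylation_window_bp: int = 50_000    # methylation profile tiles
    # enrichment scan
    bonferroni_alpha: float = 0.1
    # point-mutation haplotype rule
    min_mutant_reads: int = 3              # >=3 mutant reads with one tag
    max_opposite_reads: int = 1            # <=1 mutant read with the other tag
    # SV haplotype rule
    sv_min_assigned_reads: int = 3
    sv_haplotype_fraction: float = 0.70
    # supplementary-alignment read haplotyping from phased SNPs
    snp_support_min: int = 2
    snp_haplotype_fraction: float = 0.70
    # biased-region extraction
    phased_fraction_min: float = 0.50
    min_phased_mutations: int = 4
    bias_fraction: float = 0.80
    # junction validation
    junction_flank_bp: int = 500
    junction_min_coverage: float = 0.90
    junction_min_identity: float = 0.90
    # CNV classification
    cnv_gain_min: int = 4
    cnv_loss_max: int = 1
    # VAF stratum boundary for phasing summaries
    vaf_stratum: float = 0.2
    # mutation-pair universe for ordering
    pair_max_distance_bp: int = 10_000
    max_inconsistent_reads: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"configuration file {path} must contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
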