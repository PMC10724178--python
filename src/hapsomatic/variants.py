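"""Somatic variant records: point mutations and structural variants."""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_BASES = frozenset("ACGTN")


def mutation_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical mutation identifier; ``pos`` is 0-based internally but the
    identifier shows the 1-based coordinate so it matches VCF output."""
    return f"{chrom}:{pos + 1}:{ref}>{alt}"


@dataclass(frozen=True)
class SomaticMutation:
    """A somatic point mutation (SNV or small indel) with its caller VAF.

    ``pos`` is 0-based. ``is_snv`` distinguishes single-base substitutions,
    the only class entering the 96-channel spectrum.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - VALID_BASES:
                raise ValueError(f"invalid allele {allele!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")

    @property
    def id(self) -> str:
        return mutation_id(self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    pos: int              # 0-based position of the junction edge
    orientation: str      # '+' keeps the reference strand, '-' flips it

    def __post_init__(self) -> None:
        if self.orientation not in {"+", "-"}:
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")
        if self.pos < 0:
            raise ValueError(f"negative breakpoint position {self.pos}")


SV_TYPES = ("deletion", "duplication", "inversion", "translocation", "insertion")


@dataclass(frozen=True)
class SVRecord:
    """A structural variant as a breakpoint pair plus any inserted sequence."""

    sv_id: str
    type: str
    breakpoint1: Breakpoint
    breakpoint2: Breakpoint
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.type!r}")
        if set(self.inserted_seq) - VALID_BASES:
            raise ValueError("inserted sequence contains non-ACGTN characters")


@dataclass
class PhasedSNP:
    """A phased germline heterozygous SNP: which allele sits on which
    haplotype within its phased block."""

    chrom: str
    pos: int
    hp1_allele: str
    hp2_allele: str
    block_id: str = ""

    def __post_init__(self) -> None:
        if self.hp1_allele == self.hp2_allele:
            raise ValueError("phased SNP alleles must differ between haplotypes")
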