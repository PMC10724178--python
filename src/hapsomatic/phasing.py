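"""Haplotype assignment of somatic mutations and SVs from tagged long reads.

A somatic point mutation is "phased" to haplotype HP1 when at least
``min_mutant_reads`` (default 3) mutant reads carry the HP1 tag and at most
``max_opposite_reads`` (default 1) mutant reads carry the HP2 tag
(symmetrically for HP2). Untagged mutant reads carry no vote. SVs are phased
from their supporting reads: a haplotype is called when at least
``sv_min_assigned_reads`` (default 3) haplotype-resolved supporting reads
vote for it and that vote is at least ``sv_haplotype_fraction`` (default
70%) of the resolved supporting reads. Reads whose haplotype is known only
through phased germline SNPs (supplementary alignments) are resolved when at
least ``snp_support_min`` (default 2) informative SNPs are observed and at
least ``snp_haplotype_fraction`` (default 70%) of them match one haplotype's
alleles.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import RunConfig
from .variants import PhasedSNP, SomaticMutation

logger = logging.getLogger(__name__)

HP1 = "HP1"
HP2 = "HP2"
UNASSIGNED = "unassigned"


@dataclass
class MutantReadSupport:
    """Tagged-read tallies for one somatic mutation."""

    mutation_id: str
    n_hp1: int
    n_hp2: int
    n_untagged: int = 0
    n_ref_reads: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hp1", "n_hp2", "n_untagged", "n_ref_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_mutant(self) -> int:
        return self.n_hp1 + self.n_hp2 + self.n_untagged

    @property
    def observed_vaf(self) -> float | None:
        total = self.n_mutant + self.n_ref_reads
        return self.n_mutant / total if total else None


@dataclass
class HaplotypeCall:
    subject_id: str
    call: str                      # HP1 | HP2 | unassigned
    evidence: dict = field(default_factory=dict)

    @property
    def assigned(self) -> bool:
        return self.call != UNASSIGNED


def assign_snv_haplotype(support: MutantReadSupport, cfg: RunConfig | None = None) -> HaplotypeCall:
    """Apply the tagged-mutant-read rule to one point mutation."""
    cfg = cfg or RunConfig()
    lo, hi = cfg.max_opposite_reads, cfg.min_mutant_reads
    evidence = {"n_hp1": support.n_hp1, "n_hp2": support.n_hp2,
                "n_untagged": support.n_untagged}
    hp1_ok = support.n_hp1 >= hi and support.n_hp2 <= lo
    hp2_ok = support.n_hp2 >= hi and support.n_hp1 <= lo
    if hp1_ok and not hp2_ok:
        call = HP1
    elif hp2_ok and not hp1_ok:
        call = HP2
    else:
        # both directions can only co-fire with pathological thresholds
        call = UNASSIGNED
    return HaplotypeCall(support.mutation_id, call, evidence)


def assign_read_haplotype_by_snps(
    observations: Iterable[tuple[str, int, str]],
    phased_snps: Mapping[tuple[str, str | int], PhasedSNP]
    | Mapping[tuple[str, int], PhasedSNP],
    cfg: RunConfig | None = None,
) -> str:
    """Resolve one read's haplotype from its phased-SNP observations.

    ``observations`` yields ``(chrom, pos, base)`` tuples; ``phased_snps``
    maps ``(chrom, pos)`` to the phased germline SNP there. Observations at
    non-phased sites are ignored (logged at debug level); third alleles
    matching neither haplotype are ignored too.

    Returns ``"HP1"``, ``"HP2"`` or ``"none"``.
    """
    cfg = cfg or RunConfig()
    votes = Counter()
    for chrom, pos, base in observations:
        snp = phased_snps.get((chrom, pos))
        if snp is None:
            logger.debug("observation at non-phased site %s:%d ignored", chrom, pos + 1)
            continue
        if base == snp.hp1_allele:
            votes[HP1] += 1
        elif base == snp.hp2_allele:
            votes[HP2] += 1
    n_informative = votes[HP1] + votes[HP2]
    if n_informative < cfg.snp_support_min:
        return "none"
    for hp in (HP1, HP2):
        if votes[hp] / n_informative >= cfg.snp_haplotype_fraction and votes[hp] > votes[HP2 if hp == HP1 else HP1]:
            return hp
    return "none"


@dataclass
class SVSupport:
    """Per-read haplotype votes for one SV's supporting reads.

    ``read_votes`` holds one entry per supporting read: ``"HP1"``, ``"HP2"``
    or ``"none"`` (haplotype unresolved). Each read contributes at most one
    vote; resolve supplementary alignments with
    :func:`assign_read_haplotype_by_snps` beforehand.
    """

    sv_id: str
    read_votes: Sequence[str]

    def __post_init__(self) -> None:
        bad = set(self.read_votes) - {HP1, HP2, "none"}
        if bad:
            raise ValueError(f"invalid haplotype votes {sorted(bad)}")


def assign_sv_haplotype(support: SVSupport, cfg: RunConfig | None = None) -> HaplotypeCall:
    """Apply the supporting-read rule to one SV.

    The fraction denominator counts only haplotype-resolved supporting
    reads; reads voting ``none`` are excluded.
    """
    cfg = cfg or RunConfig()
    votes = Counter(v for v in support.read_votes if v != "none")
    n_resolved = votes[HP1] + votes[HP2]
    evidence = {"n_hp1": votes[HP1], "n_hp2": votes[HP2],
                "n_supporting": len(support.read_votes)}
    call = UNASSIGNED
    if n_resolved:
        for hp in (HP1, HP2):
            if (votes[hp] >= cfg.sv_min_assigned_reads
                    and votes[hp] / n_resolved >= cfg.sv_haplotype_fraction):
                call = hp
                break
    return HaplotypeCall(support.sv_id, call, evidence)


# ------------------------------------------------------------------
# building support tallies from an observation table


def support_from_observations(
    observations: pd.DataFrame, mutations: Sequence[SomaticMutation]
) -> dict[str, MutantReadSupport]:
    """Tally tagged mutant/reference reads per mutation from the
    observation table ('N' observations are excluded from both counts)."""
    supports: dict[str, MutantReadSupport] = {}
    by_site = {(m.chrom, m.pos): m for m in mutations}
    counts: dict[str, Counter] = {m.id: Counter() for m in mutations}
    sub = observations[observations["allele"] != "N"]
    for row in sub.itertuples(index=False):
        mut = by_site.get((row.chrom, row.pos))
        if mut is None:
            continue
        c = counts[mut.id]
        if row.allele == "A":
            if row.haplotype_tag == "1":
                c["hp1"] += 1
            elif row.haplotype_tag == "2":
                c["hp2"] += 1
            else:
                c["untagged"] += 1
        else:
            c["ref"] += 1
    for mut in mutations:
        c = counts[mut.id]
        supports[mut.id] = MutantReadSupport(
            mutation_id=mut.id, n_hp1=c["hp1"], n_hp2=c["hp2"],
            n_untagged=c["untagged"], n_ref_reads=c["ref"],
        )
    return supports


def assign_all_snvs(
    observations: pd.DataFrame,
    mutations: Sequence[SomaticMutation],
    cfg: RunConfig | None = None,
) -> dict[str, HaplotypeCall]:
    cfg = cfg or RunConfig()
    supports = support_from_observations(observations, mutations)
    return {mid: assign_snv_haplotype(sup, cfg) for mid, sup in supports.items()}


def summarize_phasing(
    calls: Mapping[str, HaplotypeCall],
    mutations: Sequence[SomaticMutation],
    cfg: RunConfig | None = None,
    sv_calls: Mapping[str, HaplotypeCall] | None = None,
) -> dict:
    """Phased fractions overall, within the high-VAF stratum, and for SVs.

    Empty denominators yield ``None`` fractions with their count reported.
    """
    cfg = cfg or RunConfig()

    def frac(subset: Sequence[SomaticMutation]) -> tuple[float | None, int]:
        n = len(subset)
        if n == 0:
            return None, 0
        phased = sum(1 for m in subset if calls.get(m.id) and calls[m.id].assigned)
        return phased / n, n

    overall, n_total = frac(mutations)
    high, n_high = frac([m for m in mutations if m.vaf >= cfg.vaf_stratum])
    summary = {
        "fraction_phased": overall,
        "n_mutations": n_total,
        "fraction_phased_vaf_ge_stratum": high,
        "n_mutations_vaf_ge_stratum": n_high,
        "vaf_stratum": cfg.vaf_stratum,
    }
    if sv_calls is not None:
        n_sv = len(sv_calls)
        summary["n_svs"] = n_sv
        summary["fraction_svs_phased"] = (
            sum(1 for c in sv_calls.values() if c.assigned) / n_sv if n_sv else None
        )
    return summary
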