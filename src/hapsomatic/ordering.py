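"""Mutation-occurrence ordering from long reads spanning mutation pairs.

For two nearby somatic mutations, long reads covering both sites are
partitioned into double-mutant reads (both alternate alleles), single-mutant
reads for either mutation alone, and wild-type reads. Under a nested-clone
model the mutation with the higher VAF occurred first: its mutant reads are
a superset of the other's. The order is called resolved when at least 3
single-mutant reads carry only the higher-VAF mutation, at least 3
double-mutant reads exist, and no read carries only the lower-VAF mutation
(an inconsistency with nesting). Resolved pairs imply co-location on one
haplotype.

Cross-checking against clone assignments: a resolved pair whose mutations
sit in different clones is *consistent* when the first-occurring mutation's
clone has strictly higher cellular prevalence, *discrepant* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .config import RunConfig
from .variants import SomaticMutation


@dataclass
class PairReadClassification:
    mut_high: SomaticMutation      # higher caller VAF
    mut_low: SomaticMutation
    n_double: int
    n_single_high: int
    n_single_low: int              # inconsistent with nesting
    n_wild: int

    def __post_init__(self) -> None:
        if min(self.n_double, self.n_single_high, self.n_single_low, self.n_wild) < 0:
            raise ValueError("read counts must be non-negative")


@dataclass
class OrderCall:
    classification: PairReadClassification
    resolved: bool
    first: str | None              # mutation_id of the earlier mutation

    @property
    def pair_ids(self) -> tuple[str, str]:
        return (self.classification.mut_high.id, self.classification.mut_low.id)


class EqualVAFError(ValueError):
    """The pair has no VAF ordering; it is skipped rather than broken
    arbitrarily."""


def classify_pair_reads(
    mut_a: SomaticMutation,
    mut_b: SomaticMutation,
    observations: pd.DataFrame,
) -> PairReadClassification:
    """Tally reads that directly cover both mutation positions.

    Only reads with a non-missing ('R' or 'A') observation at *both* sites
    are classified; the partition over those reads is exhaustive and
    disjoint. Raises :class:`EqualVAFError` for ties in caller VAF.
    """
    if mut_a.chrom != mut_b.chrom:
        raise ValueError("mutations of a pair must share a chromosome")
    if mut_a.vaf == mut_b.vaf:
        raise EqualVAFError(f"no VAF ordering for {mut_a.id} / {mut_b.id}")
    mut_high, mut_low = (mut_a, mut_b) if mut_a.vaf > mut_b.vaf else (mut_b, mut_a)

    sub = observations[
        (observations["chrom"] == mut_high.chrom)
        & (observations["pos"].isin([mut_high.pos, mut_low.pos]))
        & (observations["allele"].isin(["R", "A"]))
    ]
    per_read = sub.pivot_table(index="read_id", columns="pos", values="allele",
                               aggfunc="first")
    n_double = n_single_high = n_single_low = n_wild = 0
    if mut_high.pos in per_read.columns and mut_low.pos in per_read.columns:
        both = per_read.dropna(subset=[mut_high.pos, mut_low.pos])
        for hi, lo in zip(both[mut_high.pos], both[mut_low.pos]):
            if hi == "A" and lo == "A":
                n_double += 1
            elif hi == "A":
                n_single_high += 1
            elif lo == "A":
                n_single_low += 1
            else:
                n_wild += 1
    return PairReadClassification(mut_high, mut_low, n_double,
                                  n_single_high, n_single_low, n_wild)


def resolve_order(
    classification: PairReadClassification, cfg: RunConfig | None = None
) -> OrderCall:
    """The order is resolved iff >=3 single-high reads, >=3 double-mutant
    reads and zero inconsistent (single-low) reads; then the higher-VAF
    mutation occurred first."""
    cfg = cfg or RunConfig()
    resolved = (
        classification.n_single_high >= 3
        and classification.n_double >= 3
        and classification.n_single_low <= cfg.max_inconsistent_reads
    )
    return OrderCall(classification, resolved,
                     classification.mut_high.id if resolved else None)


def candidate_pairs(
    mutations: Sequence[SomaticMutation],
    observations: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> list[tuple[SomaticMutation, SomaticMutation]]:
    """All same-chromosome mutation pairs within the configured genomic
    distance that share at least one read with observations at both sites."""
    cfg = cfg or RunConfig()
    sub = observations[observations["allele"].isin(["R", "A"])]
    site_reads = {
        (chrom, pos): set(group["read_id"])
        for (chrom, pos), group in sub.groupby(["chrom", "pos"], sort=False)
    }
    pairs = []
    for a, b in combinations(sorted(mutations, key=lambda m: (m.chrom, m.pos)), 2):
        if a.chrom != b.chrom or abs(a.pos - b.pos) > cfg.pair_max_distance_bp:
            continue
        reads_a = site_reads.get((a.chrom, a.pos), set())
        reads_b = site_reads.get((b.chrom, b.pos), set())
        if reads_a & reads_b:
            pairs.append((a, b))
    return pairs


def order_all_pairs(
    mutations: Sequence[SomaticMutation],
    observations: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> list[OrderCall]:
    """Classify and resolve every candidate pair; equal-VAF pairs are
    skipped."""
    cfg = cfg or RunConfig()
    calls = []
    for a, b in candidate_pairs(mutations, observations, cfg):
        try:
            classification = classify_pair_reads(a, b, observations)
        except EqualVAFError:
            continue
        calls.append(resolve_order(classification, cfg))
    return calls


SAME_CLONE = "same_clone"
CONSISTENT = "cross_clone_consistent"
DISCREPANT = "cross_clone_discrepant"


def clone_consistency(
    order_calls: Sequence[OrderCall],
    clone_table: pd.DataFrame,
) -> tuple[list[dict], dict]:
    """Compare resolved orders with clone assignments.

    ``clone_table`` columns: ``mutation_id``, ``clone_id``, ``ccf``. Pairs
    with a mutation missing from the table are dropped. Equal cellular
    prevalences across different clones cannot support the resolved order
    and count as discrepant (flagged ambiguous).
    """
    clones = clone_table.set_index("mutation_id")
    rows: list[dict] = []
    summary = {SAME_CLONE: 0, CONSISTENT: 0, DISCREPANT: 0, "dropped": 0,
               "unresolved": 0}
    for call in order_calls:
        if not call.resolved:
            summary["unresolved"] += 1
            continue
        hi_id, lo_id = call.pair_ids
        if hi_id not in clones.index or lo_id not in clones.index:
            summary["dropped"] += 1
            continue
        hi, lo = clones.loc[hi_id], clones.loc[lo_id]
        ambiguous = False
        if hi["clone_id"] == lo["clone_id"]:
            status = SAME_CLONE
        elif hi["ccf"] > lo["ccf"]:
            status = CONSISTENT
        else:
            status = DISCREPANT
            ambiguous = hi["ccf"] == lo["ccf"]
        summary[status] += 1
        rows.append({
            "first": hi_id, "second": lo_id,
            "first_clone": hi["clone_id"], "second_clone": lo["clone_id"],
            "first_ccf": float(hi["ccf"]), "second_ccf": float(lo["ccf"]),
            "status": status, "ambiguous": ambiguous,
        })
    return rows, summary
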