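"""Scan for mutation-enriched and haplotype-biased regions.

The four-step procedure:

1. tile the analyzed genome into 100-kb windows;
2. test each window's mutation count with an upper-tail hypergeometric
   probability (population = analyzed genome bp, successes = window bp,
   draws = total somatic point mutations) and keep windows with a
   Bonferroni-adjusted p below 0.1 as *mutation-enriched windows*;
3. intersect enriched windows with phased blocks and keep overlap regions
   where at least 50% of the somatic mutations are phased and at least 4
   phased mutations lie, as *mutation-enriched regions*;
4. call a region *haplotype-biased* when at least 80% of its phased
   mutations sit on one haplotype.

Bonferroni counts all tiled windows genome-wide, including empty ones —
deterministic and conservative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import hypergeom

from .config import RunConfig
from .intervals import GenomicInterval, tile_windows
from .phasing import HP1, HP2, HaplotypeCall
from .variants import SomaticMutation

ENRICHED = "enriched"
ENRICHED_PHASED = "enriched+phased"
BIASED = "enriched+phased+biased"


@dataclass
class EnrichmentTest:
    window: GenomicInterval
    k: int              # mutations in window
    M: int              # mutations genome-wide
    w: int              # window length (bp)
    G: int              # analyzed genome length (bp)
    p_raw: float
    p_adj: float
    n_tests: int
    flagged: bool


@dataclass
class BiasedRegion:
    region: GenomicInterval      # window ∩ phased block
    window: GenomicInterval
    n_mutations: int
    n_phased: int
    n_hp1: int
    n_hp2: int
    status: str

    @property
    def phased_fraction(self) -> float | None:
        return self.n_phased / self.n_mutations if self.n_mutations else None

    @property
    def bias_fraction(self) -> float | None:
        return max(self.n_hp1, self.n_hp2) / self.n_phased if self.n_phased else None


def hypergeom_upper_tail(k: int, M: int, w: int, G: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population G, successes w, draws M).

    The probability that at least ``k`` of ``M`` uniformly-placed mutations
    land inside a window of ``w`` of the genome's ``G`` base pairs. Computed
    via log-space survival functions, stable up to genome scale.
    """
    if not (0 <= k <= M <= G):
        raise ValueError(f"require 0 <= k <= M <= G, got k={k}, M={M}, G={G}")
    if not (0 < w <= G):
        raise ValueError(f"require 0 < w <= G, got w={w}, G={G}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, G, w, M))


def scan_enriched_windows(
    mutations: Sequence[SomaticMutation],
    windows: Sequence[GenomicInterval],
    alpha: float = 0.1,
    genome_length: int | None = None,
) -> list[EnrichmentTest]:
    """Hypergeometric enrichment test for every window, Bonferroni-adjusted
    over all tiled windows; a window is flagged iff p_adj < alpha strictly.

    ``genome_length`` defaults to the summed window lengths (the analyzed
    genome). Output order follows window order and is independent of
    mutation input order.
    """
    n_tests = len(windows)
    G = genome_length if genome_length is not None else sum(w.length for w in windows)
    M = len(mutations)
    counts = [0] * n_tests
    for mut in mutations:
        for i, win in enumerate(windows):
            if win.contains(mut.chrom, mut.pos):
                counts[i] += 1
                break
    results = []
    for win, k in zip(windows, counts):
        p_raw = hypergeom_upper_tail(k, M, win.length, G) if M else 1.0
        p_adj = min(1.0, p_raw * n_tests)
        results.append(
            EnrichmentTest(win, k, M, win.length, G, p_raw, p_adj, n_tests,
                           flagged=p_adj < alpha)
        )
    return results


def extract_biased_regions(
    enriched: Sequence[EnrichmentTest],
    phased_blocks: Sequence[GenomicInterval],
    mutations: Sequence[SomaticMutation],
    haplotype_calls: Mapping[str, HaplotypeCall],
    cfg: RunConfig | None = None,
) -> list[BiasedRegion]:
    """Steps 3-4: intersect flagged windows with phased blocks, count
    mutations within each overlap, and grade the region's status."""
    cfg = cfg or RunConfig()
    regions: list[BiasedRegion] = []
    for test in enriched:
        if not test.flagged:
            continue
        for block in phased_blocks:
            overlap = test.window.intersect(block)
            if overlap is None:
                continue
            in_region = [m for m in mutations if overlap.contains(m.chrom, m.pos)]
            n_hp1 = n_hp2 = 0
            for m in in_region:
                call = haplotype_calls.get(m.id)
                if call is None:
                    continue
                if call.call == HP1:
                    n_hp1 += 1
                elif call.call == HP2:
                    n_hp2 += 1
            n_phased = n_hp1 + n_hp2
            n_mut = len(in_region)
            status = ENRICHED
            if (n_mut and n_phased / n_mut >= cfg.phased_fraction_min
                    and n_phased >= cfg.min_phased_mutations):
                status = ENRICHED_PHASED
                if max(n_hp1, n_hp2) / n_phased >= cfg.bias_fraction:
                    status = BIASED
            regions.append(
                BiasedRegion(overlap, test.window, n_mut, n_phased, n_hp1, n_hp2, status)
            )
    return regions


def scan_genome(
    mutations: Sequence[SomaticMutation],
    chrom_lengths: dict[str, int],
    phased_blocks: Sequence[GenomicInterval],
    haplotype_calls: Mapping[str, HaplotypeCall],
    cfg: RunConfig | None = None,
) -> tuple[list[EnrichmentTest], list[BiasedRegion]]:
    """Run the full four-step scan over a genome."""
    cfg = cfg or RunConfig()
    windows = tile_windows(chrom_lengths, cfg.window_size_bp)
    tests = scan_enriched_windows(mutations, windows, cfg.bonferroni_alpha)
    regions = extract_biased_regions(tests, phased_blocks, mutations,
                                     haplotype_calls, cfg)
    return tests, regions
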