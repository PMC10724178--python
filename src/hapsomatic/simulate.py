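"""Synthetic diploid tumor cohort with known haplotype/clone ground truth.

The generator emulates, at a scaled-down genome (default 2 chromosomes x
10 Mb), the substrate every downstream rule consumes:

* a random reference sequence with heterozygous germline SNPs grouped into
  phased blocks (block lengths exponential around a configurable N50);
* clonal somatic SNVs on a linear clone tree (founder CCF 1.0), VAF =
  purity x CCF / 2 for copy-number-neutral heterozygous sites;
* optionally one planted mutation cluster inside a chosen 100-kb window,
  all on one haplotype, with a TpC-context C>G/C>T spectrum;
* haplotype-tagged long-read allele observations at somatic sites, with
  configurable tag dropout (tag becomes untagged), tag error (tag flips)
  and allele error (R/A flips);
* structural variants with haplotype-tagged supporting reads and
  junction-spanning read sequences;
* per-read CpG methylation calls with window-specific rates.

Reads are emitted as an abstract observation table (read id, haplotype
tag, per-site allele), not as aligned sequences: every downstream rule
consumes only these observations. A read from a tumor cell of clone ``j``
carries exactly the mutations of clones 1..j (its lineage) that sit on the
read's haplotype of origin — the nested-clone model that underlies
mutation ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .variants import Breakpoint, PhasedSNP, SomaticMutation, SVRecord, mutation_id

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# length-weighted median of an exponential is ~1.6783 x its mean
_EXP_N50_FACTOR = 1.6783


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedCluster:
    """One mutation cluster planted into a single scan window."""

    window_index: int          # 100-kb tile index on the cluster chromosome
    n_mutations: int
    haplotype: str = "HP1"     # haplotype of origin of every cluster mutation
    spectrum_name: str = "tpc_cg"   # TpC-context C>G/C>T substitutions
    chrom_index: int = 0


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the scaled-down conditions the downstream rules are
    exercised under: a 2 x 10 Mb diploid genome, ~1 het SNP per kb, phased
    blocks with ~500 kb N50, a three-clone linear tree at 60% purity,
    3 somatic SNVs per Mb, 24x long reads of ~5 kb, and a genome-wide
    baseline methylation rate of 78.7%.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 10_000_000
    het_snp_rate: float = 1e-3
    phased_block_n50_bp: int = 500_000
    clone_ccfs: tuple[float, ...] = (1.0, 0.5, 0.25)
    tumor_purity: float = 0.6
    mutation_rate_per_mb: float = 3.0
    planted_cluster: PlantedCluster | None = None
    read_depth: float = 24.0
    read_length_bp: int = 5_000
    allele_error_rate: float = 0.0
    tag_dropout_rate: float = 0.2
    tag_error_rate: float = 0.0
    methylation_rate: float = 0.787
    methylation_profile: tuple[tuple[int, float], ...] = ()
    methylation_window_bp: int = 50_000
    cpg_spacing_bp: int = 1_000
    methylation_depth: float = 20.0
    n_svs: int = 6
    scan_window_bp: int = 100_000
    seed: int = 0

    @property
    def n_clones(self) -> int:
        return len(self.clone_ccfs)

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if self.chrom_length_bp < self.scan_window_bp:
            raise ConfigError("chrom_length_bp must be >= scan_window_bp")
        for name in ("het_snp_rate", "tumor_purity", "allele_error_rate",
                     "tag_dropout_rate", "tag_error_rate", "methylation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.mutation_rate_per_mb < 0:
            raise ConfigError("mutation_rate_per_mb must be non-negative")
        if not self.clone_ccfs:
            raise ConfigError("clone_ccfs must be non-empty")
        if self.clone_ccfs[0] != 1.0:
            raise ConfigError("clone_ccfs: founder clone CCF must be 1.0")
        for ccf in self.clone_ccfs:
            if not (0.0 < ccf <= 1.0):
                raise ConfigError(f"clone_ccfs: CCF {ccf} outside (0, 1]")
        if list(self.clone_ccfs) != sorted(self.clone_ccfs, reverse=True):
            raise ConfigError("clone_ccfs must be sorted descending")
        if self.planted_cluster is not None:
            pc = self.planted_cluster
            n_windows = self.chrom_length_bp // self.scan_window_bp
            if not (0 <= pc.window_index < n_windows):
                raise ConfigError(
                    f"planted_cluster.window_index {pc.window_index} outside "
                    f"[0, {n_windows})"
                )
            if pc.haplotype not in ("HP1", "HP2"):
                raise ConfigError("planted_cluster.haplotype must be HP1 or HP2")
            if pc.n_mutations < 1:
                raise ConfigError("planted_cluster.n_mutations must be >= 1")
        for idx, rate in self.methylation_profile:
            if not (0.0 <= rate <= 1.0):
                raise ConfigError(f"methylation_profile rate {rate} outside [0, 1]")


@dataclass
class MutationTruth:
    haplotype: str
    clone_id: str
    order_index: int
    true_vaf: float
    in_planted_cluster: bool = False


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated case."""

    mutations: dict[str, MutationTruth] = field(default_factory=dict)
    sv_haplotypes: dict[str, str] = field(default_factory=dict)
    window_methylation: dict[tuple[str, int], float] = field(default_factory=dict)
    clone_ccfs: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulatedCase:
    """Everything simulate_cohort emits for one tumor/normal case."""

    config: SimConfig
    reference: dict[str, str]
    chrom_lengths: dict[str, int]
    mutations: list[SomaticMutation]
    observations: pd.DataFrame
    svs: list[SVRecord]
    sv_read_votes: dict[str, list[str]]
    sv_reads: dict[str, list[str]]
    methylation_calls: pd.DataFrame
    phased_blocks: list[GenomicInterval]
    phased_snps: dict[tuple[str, int], PhasedSNP]
    truth: SyntheticTruth

    @property
    def clone_table(self) -> pd.DataFrame:
        rows = [
            {"mutation_id": mid, "clone_id": t.clone_id,
             "ccf": self.truth.clone_ccfs[t.clone_id]}
            for mid, t in self.truth.mutations.items()
        ]
        return pd.DataFrame(rows, columns=["mutation_id", "clone_id", "ccf"])


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length, dtype=np.uint8)]


def _draw_blocks(rng: np.random.Generator, chrom: str, length: int,
                 n50: int) -> list[GenomicInterval]:
    mean = max(1_000, int(n50 / _EXP_N50_FACTOR))
    blocks, start = [], 0
    while start < length:
        size = max(1_000, int(rng.exponential(mean)))
        end = min(start + size, length)
        blocks.append(GenomicInterval(chrom, start, end))
        start = end
    return blocks


def _mutate_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[rng.integers(0, 3)]


def simulate_cohort(config: SimConfig) -> SimulatedCase:
    """Generate one synthetic tumor/normal case with full ground truth.

    Identical config and seed give byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chrom_length_bp for c in chroms}

    ref_arrays = {c: _random_sequence(rng, config.chrom_length_bp) for c in chroms}

    # ---- germline het SNPs and phased blocks
    phased_blocks: list[GenomicInterval] = []
    phased_snps: dict[tuple[str, int], PhasedSNP] = {}
    for chrom in chroms:
        blocks = _draw_blocks(rng, chrom, config.chrom_length_bp,
                              config.phased_block_n50_bp)
        phased_blocks.extend(blocks)
        n_snps = rng.poisson(config.het_snp_rate * config.chrom_length_bp)
        positions = np.sort(rng.choice(config.chrom_length_bp, size=n_snps,
                                       replace=False))
        block_starts = np.array([b.start for b in blocks])
        for pos in positions:
            ref_base = chr(ref_arrays[chrom][pos])
            alt_base = _mutate_base(rng, ref_base)
            alt_on_hp1 = bool(rng.integers(0, 2))
            block = blocks[int(np.searchsorted(block_starts, pos, side="right")) - 1]
            phased_snps[(chrom, int(pos))] = PhasedSNP(
                chrom, int(pos),
                hp1_allele=alt_base if alt_on_hp1 else ref_base,
                hp2_allele=ref_base if alt_on_hp1 else alt_base,
                block_id=f"{chrom}_b{block.start}",
            )

    # ---- clone tree (linear chain, founder first)
    clone_ids = [f"clone_{i + 1}" for i in range(config.n_clones)]
    ccfs = dict(zip(clone_ids, config.clone_ccfs))
    # fraction of tumor cells whose *deepest* clone is i
    terminal = np.diff(-np.array(list(config.clone_ccfs) + [0.0]))

    # ---- somatic point mutations
    truth = SyntheticTruth(clone_ccfs=ccfs)
    used: set[tuple[str, int]] = set(phased_snps)
    planted_specs: list[tuple[str, int, str, str, str]] = []  # chrom,pos,hap,clone,kind

    if config.planted_cluster is not None:
        pc = config.planted_cluster
        chrom = chroms[pc.chrom_index]
        lo = pc.window_index * config.scan_window_bp
        hi = lo + config.scan_window_bp
        positions = set()
        while len(positions) < pc.n_mutations:
            pos = int(rng.integers(lo + 1, hi - 1))
            if (chrom, pos) not in used:
                positions.add(pos)
                used.add((chrom, pos))
        for pos in sorted(positions):
            # plant the APOBEC target motif TpC at the site
            ref_arrays[chrom][pos - 1] = ord("T")
            ref_arrays[chrom][pos] = ord("C")
            planted_specs.append((chrom, pos, pc.haplotype, clone_ids[0], "cluster"))

    n_background = rng.poisson(
        config.mutation_rate_per_mb * config.n_chromosomes
        * config.chrom_length_bp / 1e6
    )
    background_specs: list[tuple[str, int, str, str, str]] = []
    while len(background_specs) < n_background:
        chrom = chroms[int(rng.integers(0, config.n_chromosomes))]
        pos = int(rng.integers(1, config.chrom_length_bp - 1))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        hap = "HP1" if rng.integers(0, 2) else "HP2"
        clone = clone_ids[int(rng.integers(0, config.n_clones))]
        background_specs.append((chrom, pos, hap, clone, "background"))

    mutations: list[SomaticMutation] = []
    mut_attrs: dict[str, tuple[str, int]] = {}  # id -> (haplotype, clone index)
    order_counters = {"HP1": 0, "HP2": 0}
    all_specs = planted_specs + background_specs
    # order of occurrence follows the clone lineage: ancestors first
    all_specs.sort(key=lambda s: (clone_ids.index(s[3]), s[0], s[1]))
    for chrom, pos, hap, clone, kind in all_specs:
        ref_base = chr(ref_arrays[chrom][pos])
        if kind == "cluster":
            alt_base = "G" if rng.random() < 0.7 else "T"
        else:
            alt_base = _mutate_base(rng, ref_base)
        vaf = config.tumor_purity * ccfs[clone] / 2.0
        mut = SomaticMutation(chrom, pos, ref_base, alt_base, vaf)
        mutations.append(mut)
        order_counters[hap] += 1
        truth.mutations[mut.id] = MutationTruth(
            haplotype=hap, clone_id=clone, order_index=order_counters[hap],
            true_vaf=vaf, in_planted_cluster=(kind == "cluster"),
        )
        mut_attrs[mut.id] = (hap, clone_ids.index(clone))
    mutations.sort(key=lambda m: (m.chrom, m.pos))

    # ---- long-read allele observations at somatic sites
    observations = _simulate_observations(
        rng, config, chroms, mutations, mut_attrs, terminal
    )

    # ---- structural variants
    svs, sv_read_votes, sv_reads = _simulate_svs(rng, config, chroms, ref_arrays, truth)

    # ---- methylation calls
    methylation_calls = _simulate_methylation(rng, config, chroms, truth)

    reference = {c: arr.tobytes().decode("ascii") for c, arr in ref_arrays.items()}
    return SimulatedCase(
        config=config, reference=reference, chrom_lengths=chrom_lengths,
        mutations=mutations, observations=observations, svs=svs,
        sv_read_votes=sv_read_votes, sv_reads=sv_reads,
        methylation_calls=methylation_calls, phased_blocks=phased_blocks,
        phased_snps=phased_snps, truth=truth,
    )


def _simulate_observations(
    rng: np.random.Generator,
    config: SimConfig,
    chroms: Sequence[str],
    mutations: Sequence[SomaticMutation],
    mut_attrs: dict[str, tuple[str, int]],
    terminal: np.ndarray,
) -> pd.DataFrame:
    """Draw reads and record their alleles at somatic sites.

    Read starts are uniform, lengths exponential around the configured
    mean. Only reads covering at least one somatic site produce rows.
    """
    rows: list[tuple[str, str, str, int, str]] = []
    n_clones = len(terminal)
    for chrom in chroms:
        sites = np.array([m.pos for m in mutations if m.chrom == chrom], dtype=int)
        site_muts = [m for m in mutations if m.chrom == chrom]
        n_reads = int(round(config.read_depth * config.chrom_length_bp
                            / config.read_length_bp))
        starts = rng.integers(0, config.chrom_length_bp, size=n_reads)
        lengths = np.maximum(200, rng.exponential(config.read_length_bp,
                                                  size=n_reads).astype(int))
        ends = np.minimum(starts + lengths, config.chrom_length_bp)
        is_tumor = rng.random(n_reads) < config.tumor_purity
        deepest = rng.choice(n_clones, size=n_reads, p=terminal / terminal.sum())
        hap = rng.integers(1, 3, size=n_reads)        # haplotype of origin
        drop = rng.random(n_reads) < config.tag_dropout_rate
        flip = rng.random(n_reads) < config.tag_error_rate

        if len(sites) == 0:
            continue
        lo = np.searchsorted(sites, starts, side="left")
        hi = np.searchsorted(sites, ends, side="left")
        covering = np.nonzero(hi > lo)[0]
        for i in covering:
            read_id = f"{chrom}_r{i}"
            if drop[i]:
                tag = "."
            elif flip[i]:
                tag = "2" if hap[i] == 1 else "1"
            else:
                tag = str(hap[i])
            for j in range(lo[i], hi[i]):
                mut = site_muts[j]
                m_hap, m_clone_idx = mut_attrs[mut.id]
                carries = (
                    is_tumor[i]
                    and hap[i] == (1 if m_hap == "HP1" else 2)
                    and m_clone_idx <= deepest[i]
                )
                allele = "A" if carries else "R"
                if rng.random() < config.allele_error_rate:
                    allele = "R" if allele == "A" else "A"
                rows.append((read_id, tag, chrom, mut.pos, allele))
    return pd.DataFrame(rows, columns=["read_id", "haplotype_tag", "chrom",
                                       "pos", "allele"])


_SV_CYCLE = ("deletion", "deletion", "duplication", "inversion",
             "translocation", "insertion")


def _simulate_svs(
    rng: np.random.Generator,
    config: SimConfig,
    chroms: Sequence[str],
    ref_arrays: dict[str, np.ndarray],
    truth: SyntheticTruth,
) -> tuple[list[SVRecord], dict[str, list[str]], dict[str, list[str]]]:
    """Plant SVs with haplotype-tagged supporting-read votes and
    junction-spanning read sequences (error-free copies of the junction)."""
    from .sv import build_junction

    svs: list[SVRecord] = []
    votes: dict[str, list[str]] = {}
    reads: dict[str, list[str]] = {}
    L = config.chrom_length_bp
    margin = 2_000
    reference = {c: arr.tobytes().decode("ascii") for c, arr in ref_arrays.items()}
    for i in range(config.n_svs):
        sv_type = _SV_CYCLE[i % len(_SV_CYCLE)]
        sv_id = f"sv_{i + 1}"
        chrom1 = chroms[int(rng.integers(0, len(chroms)))]
        pos1 = int(rng.integers(margin, L - margin))
        insert = ""
        if sv_type == "deletion":
            bp1 = Breakpoint(chrom1, pos1, "+")
            bp2 = Breakpoint(chrom1, min(L - margin, pos1 + int(rng.integers(1_000, 50_000))), "+")
        elif sv_type == "duplication":
            bp1 = Breakpoint(chrom1, min(L - margin, pos1 + int(rng.integers(1_000, 50_000))), "+")
            bp2 = Breakpoint(chrom1, pos1, "+")
        elif sv_type == "inversion":
            bp1 = Breakpoint(chrom1, pos1, "+")
            bp2 = Breakpoint(chrom1, min(L - margin, pos1 + int(rng.integers(1_000, 50_000))), "-")
        elif sv_type == "translocation":
            chrom2 = chroms[(chroms.index(chrom1) + 1) % len(chroms)]
            bp1 = Breakpoint(chrom1, pos1, "+")
            bp2 = Breakpoint(chrom2, int(rng.integers(margin, L - margin)), "+")
        else:  # insertion
            bp1 = Breakpoint(chrom1, pos1, "+")
            bp2 = Breakpoint(chrom1, pos1, "+")
            insert = "".join("ACGT"[b] for b in rng.integers(0, 4, size=300))
        sv = SVRecord(sv_id, sv_type, bp1, bp2, insert)
        svs.append(sv)

        hap = "HP1" if rng.integers(0, 2) else "HP2"
        truth.sv_haplotypes[sv_id] = hap
        n_support = max(3, int(rng.poisson(config.read_depth * config.tumor_purity / 2)))
        sv_votes = []
        for _ in range(n_support):
            if rng.random() < config.tag_dropout_rate:
                sv_votes.append("none")
            elif rng.random() < config.tag_error_rate:
                sv_votes.append("HP2" if hap == "HP1" else "HP1")
            else:
                sv_votes.append(hap)
        votes[sv_id] = sv_votes

        junction = build_junction(sv, reference, 500)
        reads[sv_id] = [junction.sequence for _ in range(min(n_support, 3))]
    return svs, votes, reads


def _simulate_methylation(
    rng: np.random.Generator,
    config: SimConfig,
    chroms: Sequence[str],
    truth: SyntheticTruth,
) -> pd.DataFrame:
    """Per-read CpG calls: sites every ``cpg_spacing_bp``, per-site call
    depth Poisson, methylated count binomial at the window's true rate."""
    profile = dict(config.methylation_profile)
    frames = []
    counter = 0
    for chrom in chroms:
        positions = np.arange(config.cpg_spacing_bp // 2, config.chrom_length_bp,
                              config.cpg_spacing_bp)
        window_idx = positions // config.methylation_window_bp
        rates = np.array([profile.get(int(w), config.methylation_rate)
                          for w in window_idx])
        n_windows = -(-config.chrom_length_bp // config.methylation_window_bp)
        for w in range(n_windows):
            truth.window_methylation[(chrom, w)] = profile.get(w, config.methylation_rate)
        depths = rng.poisson(config.methylation_depth, size=len(positions))
        n_meth = rng.binomial(depths, rates)
        total = int(depths.sum())
        pos_rep = np.repeat(positions, depths)
        state = np.empty(total, dtype="U1")
        # first n_meth[i] calls of site i are methylated — read identity
        # carries no signal here, so the order within a site is immaterial
        offset = 0
        for d, m in zip(depths, n_meth):
            state[offset : offset + m] = "M"
            state[offset + m : offset + d] = "U"
            offset += d
        frames.append(pd.DataFrame({
            "read_id": [f"m{counter + k}" for k in range(total)],
            "chrom": chrom,
            "pos": pos_rep,
            "state": state,
        }))
        counter += total
    if not frames:
        return pd.DataFrame(columns=["read_id", "chrom", "pos", "state"])
    return pd.concat(frames, ignore_index=True)


def simulate_nested_clone_pair(
    vaf_high: float,
    vaf_low: float,
    depth: int,
    seed: int,
    allele_error_rate: float = 0.0,
    chrom: str = "chr1",
    pos_high: int = 1_000,
    pos_low: int = 2_000,
) -> pd.DataFrame:
    """Observation table for one nested mutation pair on one haplotype.

    Every read covers both sites. Before error injection, reads carrying
    the low-VAF mutation are a strict subset of reads carrying the
    high-VAF one (the nested-clone model). Raises ``ValueError`` unless
    ``vaf_high > vaf_low``.
    """
    if not (0.0 <= vaf_low < vaf_high <= 1.0):
        raise ValueError(
            f"require 0 <= vaf_low < vaf_high <= 1, got high={vaf_high}, low={vaf_low}"
        )
    rng = np.random.default_rng(seed)
    u = rng.random(depth)
    carries_high = u < vaf_high
    carries_low = u < vaf_low          # subset of carries_high by construction
    rows = []
    for i in range(depth):
        for pos, carries in ((pos_high, carries_high[i]), (pos_low, carries_low[i])):
            allele = "A" if carries else "R"
            if rng.random() < allele_error_rate:
                allele = "R" if allele == "A" else "A"
            rows.append((f"r{i}", "1", chrom, pos, allele))
    return pd.DataFrame(rows, columns=["read_id", "haplotype_tag", "chrom",
                                       "pos", "allele"])


def tpc_spectrum_template(cg_weight: float = 0.7) -> np.ndarray:
    """A 96-channel template concentrated on TpC-context C>G and C>T
    channels, mirroring the planted cluster's generator: C>G with weight
    ``cg_weight`` and C>T with the remainder, uniform over 3' bases."""
    from .signatures import CHANNELS

    weights = np.zeros(len(CHANNELS))
    for i, ch in enumerate(CHANNELS):
        if ch.startswith("T[C>G]"):
            weights[i] = cg_weight / 4
        elif ch.startswith("T[C>T]"):
            weights[i] = (1 - cg_weight) / 4
    return weights
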