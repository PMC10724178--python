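# Methods

This note documents the statistical model behind each component of
`hapsomatic`, the parameters with their defaults and rationale, what the
synthetic-data generator does and does not emulate, and the numerical
choices made along the way. Coordinates are 0-based half-open internally
and 1-based inclusive in every report and on-disk position column;
round-trips through `GenomicInterval.report()`/`from_report()` are exact.

## Haplotype phasing of somatic SNVs

Each read observation at a somatic site carries a haplotype tag
(`1`, `2`, or `.` for untagged) and an allele (`R` reference, `A`
alternate, `N` unresolved). A mutation is assigned to haplotype *h* when
at least `min_mutant_reads` (default **3**) of its mutant (`A`) reads
carry tag *h* and at most `max_opposite_reads` (default **1**) carry the
opposite tag. Untagged reads are uninformative and never count against an
assignment. The two thresholds trade sensitivity against switch errors:
three concordant reads make a random triple-tag error vanishingly rare at
20–30× depth, while tolerating one opposite read absorbs a single tagging
mistake without discarding the site.

Supplementary alignments lack tags; their haplotype is recovered from
phased germline SNPs covered by the read: `snp_support_min` (default
**2**) informative SNPs with at least `snp_haplotype_fraction` (default
**0.70**) agreeing on one haplotype.

Structural variants are phased from their supporting reads: at least
`sv_min_assigned_reads` (default **3**) haplotype-resolved reads, of
which at least `sv_haplotype_fraction` (default **0.70**) on one
haplotype; unresolved reads are excluded from the denominator.

Phasing summaries report the assigned fraction overall and within the
VAF ≥ `vaf_stratum` (default **0.2**) stratum, since low-VAF subclonal
mutations have few mutant reads and phase at a much lower rate.

## Hotspot scan (four steps)

1. **Tile** the genome into `window_size_bp` (default **100 000**)
   windows; terminal tiles keep their true (shorter) length.
2. **Test** each window for mutation enrichment with the hypergeometric
   upper tail: for a genome of G bp with M mutations and a window of
   w bp holding k of them, `P(X ≥ k)` with
   `X ~ Hypergeom(G, w, M)`, i.e. the chance a uniformly mutated genome
   puts that many in the window. `k = 0` returns 1 exactly.
3. **Correct** with Bonferroni over *all* tested windows (not only those
   containing mutations) and flag windows with adjusted
   `p < bonferroni_alpha` (default **0.1**, strict inequality).
4. **Check bias** inside each flagged window's overlap with a phased
   block: the overlap qualifies when ≥ `phased_fraction_min` (default
   **0.50**) of its mutations are phased and at least
   `min_phased_mutations` (default **4**) are phased; it is *biased*
   when ≥ `bias_fraction` (default **0.80**) of the phased mutations sit
   on one haplotype. Statuses are `enriched`, `enriched+phased`,
   `enriched+phased+biased`.

The hypergeometric tail is computed by `scipy.stats.hypergeom.sf(k−1, G,
w, M)`, which stays accurate at genome scale (a 3-Gb genome with a
~10⁻¹⁵ tail does not underflow to zero). The test suite verifies it
against an exact integer-arithmetic enumeration for every parameter
combination with G ≤ 60.

## Mutational spectra

SNVs are mapped to the 96 trinucleotide channels in lexicographic order
(`A[C>A]A` … `T[T>G]T`); purine reference bases are reverse-complemented
to the pyrimidine frame. The TpC fraction is the spectrum mass on the 12
channels with a 5′ T next to a mutated C (the APOBEC target motif), and
spectra are compared by cosine similarity (undefined, and an error, for
all-zero spectra). Mutations at contig edges, whose trinucleotide context
is incomplete, are skipped and logged.

## Mutation ordering

For two same-chromosome mutations within `pair_max_distance_bp` (default
**10 000**) sharing at least one read with non-missing alleles at both
sites, reads covering both sites are partitioned into double-mutant,
single-high (only the higher-VAF site mutant), single-low, and wild-type.
Under a nested-clone model the higher-VAF mutation occurred first and its
mutant reads are a superset of the other's, so single-low reads are
inconsistencies. The order is *resolved* when `n_single_high ≥ 3`,
`n_double ≥ 3` and `n_single_low ≤ max_inconsistent_reads` (default
**0**). Equal-VAF pairs admit no ordering and are skipped rather than
broken arbitrarily.

Resolved orders are cross-checked against clone assignments: same clone,
*consistent* (first mutation's clone has strictly higher CCF), or
*discrepant* (equal CCFs across different clones are discrepant and
flagged ambiguous).

At the study defaults (24× depth, 5-kb reads) genome-wide pairs rarely
resolve — few reads span both sites of a 10-kb pair — which is why the
worked example adds a 60× nested-pair positive control.

## Methylation

Per-read CpG calls (state `M`/`U`, strand-collapsed to the forward-strand
C) are averaged in two stages: a per-CpG fraction first, then the
unweighted mean of site fractions per `methylation_window_bp` (default
**50 000**) window. Two-stage averaging prevents deep sites from
dominating a window. The genome-wide summary is the *median* over windows
with ≥ 1 covered CpG (robust to a tail of aberrant windows); uncovered
windows carry nulls rather than zeros. Tumor−normal deltas require
identical tilings; annotation-class rates count each CpG once per class
even under overlapping features.

## SV junction validation

Each SV's junction contig is `left flank + inserted sequence + right
flank` with `junction_flank_bp` (default **500**) reference flanks,
orientation-resolved: a `+` breakpoint contributes the forward-strand
sequence on its side of the junction, a `−` breakpoint the
reverse-complement of the other side. Flanks truncated by contig ends are
flagged. A read supports the junction when its best local alignment
(match +1, mismatch −1, gap −2, `Bio.Align.PairwiseAligner`) reaches
both `junction_min_coverage` and `junction_min_identity` (defaults
**0.90**/**0.90**), where coverage is the aligned span on the junction
over junction length and identity is matches over alignment columns;
both read orientations are tried. An SV is *validated* with ≥ 1
supporting read. Per-type validation rates are reported with their
denominators.

## Cohort statistics

Two-sided Fisher's exact tests use the point-probability method (sum of
all tables with the observed margins whose probability does not exceed
the observed table's), via `scipy.stats.fisher_exact`; the test suite
verifies it against a direct margin enumeration for every table with
total ≤ 40. Degenerate tables (an empty row or column) return p = 1 with
a warning. CNV calls are *gain* at total copy number ≥ `cnv_gain_min`
(default **4**), *loss* at ≤ `cnv_loss_max` (default **1**), otherwise
neutral. Percentages are displayed by rounding half-up after guarding
against binary-float artifacts (`round(fraction × 100, 9)` before the
decimal half-up step), so 62.5% displays as 63.

## Synthetic-data generator

`simulate_cohort(SimConfig)` builds one tumor/normal case with full
ground truth; identical config + seed give byte-identical outputs
(single `numpy.random.default_rng` stream).

What it emulates:

* a uniform-random diploid reference (default **2 × 10 Mb**) with
  heterozygous germline SNPs at `het_snp_rate` (default **10⁻³**/bp)
  grouped into phased blocks whose lengths are i.i.d. exponential with
  mean `phased_block_n50_bp / 1.6783` (the length-weighted median of an
  exponential is ≈ 1.6783 × its mean, so the realized N50 matches the
  configured **500 kb** on average);
* a linear clone chain with CCFs `clone_ccfs` (default
  **1.0, 0.5, 0.25**; founder first) at `tumor_purity` (default
  **0.6**); copy-number-neutral heterozygous sites give
  VAF = purity × CCF / 2;
* background SNVs at `mutation_rate_per_mb` (default **3**) and
  optionally one planted cluster: `n_mutations` founder-clone mutations
  in one scan window, all on one haplotype, with a TpC motif planted at
  each site and alt allele G with probability 0.7, else T (a
  C>G/C>T-at-TpC, APOBEC-like spectrum);
* haplotype-tagged read observations at somatic sites: read starts
  uniform, lengths exponential (mean `read_length_bp`, default
  **5 000**) at `read_depth` (default **24×**); a tumor read from clone
  *j* carries exactly the mutations of clones 1..j on its haplotype of
  origin (the nested-clone model); tags drop out at `tag_dropout_rate`
  (default **0.2**), flip at `tag_error_rate` (default **0**), and
  alleles flip at `allele_error_rate` (default **0**);
* structural variants (`n_svs`, default **6**, cycling deletion ×2,
  duplication, inversion, translocation, insertion) with
  haplotype-tagged supporting-read votes and verbatim junction-spanning
  read sequences;
* per-read CpG methylation calls on a site grid every `cpg_spacing_bp`
  (default **1 000**), Poisson call depth (`methylation_depth`, default
  **20**), binomial methylated counts at the window's true rate
  (`methylation_rate` baseline, default **0.787**, with per-window
  overrides via `methylation_profile`).

What it does not emulate: sequence-context-dependent error profiles,
alignment and mapping artifacts, copy-number alterations (all somatic
sites are copy-neutral, so VAF = purity × CCF / 2 exactly), branching
clone topologies, kataegis strand coordination beyond the planted
cluster, CpG-island spatial structure, and SV-read sequencing errors
(junction reads are verbatim copies; degraded reads are constructed
explicitly in tests). Observation rows are emitted only for reads
covering ≥ 1 somatic site — other reads carry no information for any
rule here.

## Numerical choices

* Hypergeometric and Fisher tails come from scipy (routine, well-tested
  statistics); both are cross-checked against independent exact
  enumerations in the test suite.
* `hypergeom.sf` keeps ~10⁻¹⁵ tails representable at 3-Gb scale;
  Bonferroni caps adjusted p at 1.
* Percent display rounds half-up through `decimal.Decimal` after a
  9-digit pre-round, avoiding `0.615 × 100 = 61.4999…` artifacts.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; derived seeds stay below 2³¹.
* Pipeline reruns on identical inputs write byte-identical
  `summary.json`; stage timings go to `pipeline.log` only.

## Limitations

* The phasing rule assumes tag errors are rare and independent; switch
  errors inside a phased block are not modeled or detected.
* The hotspot scan assumes a uniform background mutation rate;
  replication timing and chromatin covariates that modulate real
  mutation density are out of scope, so enrichment p-values are
  optimistic for real genomes.
* Ordering requires reads spanning both sites: at 24× with 5-kb reads,
  most 10-kb pairs are unresolved; conclusions should be drawn only from
  the resolved subset, which is biased toward close pairs.
* Junction validation with verbatim flanks cannot distinguish an SV from
  a reference-matching read when breakpoints are near-homologous; the
  ≥90%/≥90% thresholds were fixed a priori and are not tuned.
* The two-stage methylation average weights every covered CpG equally
  within a window regardless of depth; single-call sites contribute
  full-weight noisy fractions.
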