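"""Scan 100-kb windows for mutation enrichment and haplotype bias.

Hypergeometric upper tail per window, Bonferroni over all windows, then
the phasing and >=80%-one-haplotype bias checks inside window/phased-block
overlaps. Writes the flagged windows and candidate regions.
"""

from pathlib import Path

import pandas as pd

from hapsomatic import io as hio
from hapsomatic.config import RunConfig
from hapsomatic.hotspot import scan_genome
from hapsomatic.phasing import assign_all_snvs

RESULTS = Path(__file__).resolve().parents[1] / "results"
CASE_DIR = RESULTS / "case"


def main() -> None:
    cfg = RunConfig()
    mutations = hio.read_vcf(CASE_DIR / "mutations.vcf")
    observations = hio.read_observations(CASE_DIR / "observations.tsv")
    blocks = hio.read_bed(CASE_DIR / "phased_blocks.bed")
    chrom_lengths = {c: max(b.end for b in blocks if b.chrom == c)
                     for c in {b.chrom for b in blocks}}
    calls = assign_all_snvs(observations, mutations, cfg)
    tests, regions = scan_genome(mutations, chrom_lengths, blocks, calls, cfg)

    pd.DataFrame(
        [{"window": t.window.report(), "k": t.k, "p_raw": t.p_raw,
          "p_adj": t.p_adj, "flagged": t.flagged}
         for t in tests if t.k > 0]
    ).to_csv(RESULTS / "enriched_windows.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"region": r.region.report(), "n_mutations": r.n_mutations,
          "n_phased": r.n_phased, "n_hp1": r.n_hp1, "n_hp2": r.n_hp2,
          "status": r.status} for r in regions]
    ).to_csv(RESULTS / "biased_regions.tsv", sep="\t", index=False)
    print(f"{sum(t.flagged for t in tests)} enriched window(s), "
          f"{sum(r.status.endswith('biased') for r in regions)} biased region(s)")
    for r in regions:
        print(f"  {r.region.report()}  status={r.status}  "
              f"hp1={r.n_hp1} hp2={r.n_hp2} of {r.n_mutations}")


if __name__ == "__main__":
    main()
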