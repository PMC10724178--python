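"""Simulate the worked-example case and write its input tables.

One synthetic tumor/normal case on a 2 x 2 Mb diploid genome with a
10-mutation single-haplotype cluster planted in the sixth 100-kb window of
chr1, six structural variants with junction-spanning reads, and per-read
CpG methylation calls with three windows departing from the 78.7%
baseline. All downstream analysis steps read from ``results/case``.
"""

from pathlib import Path

import pandas as pd

from hapsomatic import io as hio
from hapsomatic.simulate import PlantedCluster, SimConfig, simulate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
CASE_DIR = RESULTS / "case"

CONFIG = SimConfig(
    seed=7,
    n_chromosomes=2,
    chrom_length_bp=2_000_000,
    mutation_rate_per_mb=8.0,
    planted_cluster=PlantedCluster(window_index=5, n_mutations=10,
                                   haplotype="HP1"),
    cpg_spacing_bp=500,
    methylation_profile=((2, 0.30), (10, 0.90), (25, 0.50)),
    n_svs=6,
)


def main() -> None:
    case = simulate_cohort(CONFIG)
    CASE_DIR.mkdir(parents=True, exist_ok=True)
    hio.write_vcf(case.mutations, CASE_DIR / "mutations.vcf", case.chrom_lengths)
    hio.write_bed(case.phased_blocks, CASE_DIR / "phased_blocks.bed")
    hio.write_observations(case.observations, CASE_DIR / "observations.tsv")
    hio.write_methylation_calls(case.methylation_calls,
                                CASE_DIR / "methylation_calls.tsv")
    hio.write_clone_table(case.clone_table, CASE_DIR / "clone_table.tsv")
    hio.write_fasta(case.reference, CASE_DIR / "reference.fa")
    hio.write_sv_table(case.svs, CASE_DIR / "svs.tsv")
    hio.write_fasta(
        {f"{sv_id}_{i}": seq
         for sv_id, seqs in case.sv_reads.items()
         for i, seq in enumerate(seqs)},
        CASE_DIR / "sv_reads.fa",
    )
    truth = pd.DataFrame(
        [{"mutation_id": mid, "haplotype": t.haplotype, "clone_id": t.clone_id,
          "order_index": t.order_index, "true_vaf": t.true_vaf,
          "in_planted_cluster": t.in_planted_cluster}
         for mid, t in case.truth.mutations.items()]
    )
    truth.to_csv(CASE_DIR / "truth.tsv", sep="\t", index=False)
    print(f"wrote {len(case.mutations)} mutations, {len(case.svs)} SVs, "
          f"{len(case.methylation_calls)} methylation calls to {CASE_DIR}")


if __name__ == "__main__":
    main()
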