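"""Aggregate per-read CpG calls into 50-kb window methylation rates.

Two-stage averaging (per-CpG fraction, then unweighted window mean) and
the genome-wide median over covered windows.
"""

import json
from pathlib import Path

import pandas as pd

from hapsomatic import io as hio
from hapsomatic.methylation import genome_median, site_rates, window_rates

RESULTS = Path(__file__).resolve().parents[1] / "results"
CASE_DIR = RESULTS / "case"


def main() -> None:
    calls = hio.read_methylation_calls(CASE_DIR / "methylation_calls.tsv")
    blocks = hio.read_bed(CASE_DIR / "phased_blocks.bed")
    chrom_lengths = {c: max(b.end for b in blocks if b.chrom == c)
                     for c in {b.chrom for b in blocks}}
    wins = window_rates(site_rates(calls), chrom_lengths, 50_000)
    pd.DataFrame(
        [{"window": w.window.report(), "n_cpgs": w.n_cpgs_covered,
          "mean_rate": w.mean_rate} for w in wins]
    ).to_csv(RESULTS / "methylation_windows.tsv", sep="\t", index=False)
    print(json.dumps({
        "n_windows": len(wins),
        "genome_median": genome_median(wins),
    }, indent=2))


if __name__ == "__main__":
    main()
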