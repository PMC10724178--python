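"""Validate SV junctions against junction-spanning long reads.

Builds each SV's 500-bp-flank junction contig and checks for at least one
read aligning locally with >=90% junction coverage and >=90% identity
(both orientations tried).
"""

import json
from pathlib import Path

import pandas as pd

from hapsomatic import io as hio
from hapsomatic.config import RunConfig
from hapsomatic.sv import cohort_validation_rate

RESULTS = Path(__file__).resolve().parents[1] / "results"
CASE_DIR = RESULTS / "case"


def main() -> None:
    cfg = RunConfig()
    svs = hio.read_sv_table(CASE_DIR / "svs.tsv")
    reference = hio.read_fasta(CASE_DIR / "reference.fa")
    reads_by_sv: dict[str, list[str]] = {}
    for name, seq in hio.read_fasta(CASE_DIR / "sv_reads.fa").items():
        reads_by_sv.setdefault(name.rsplit("_", 1)[0], []).append(seq)
    result = cohort_validation_rate(svs, reads_by_sv, reference, cfg)
    pd.DataFrame(
        [{"sv_id": r.sv_id, "validated": r.validated,
          "best_coverage": round(r.best_coverage, 4),
          "best_identity": round(r.best_identity, 4),
          "n_supporting": r.n_supporting} for r in result["results"]]
    ).to_csv(RESULTS / "sv_validation.tsv", sep="\t", index=False)
    print(json.dumps({k: v for k, v in result.items() if k != "results"},
                     indent=2))


if __name__ == "__main__":
    main()
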