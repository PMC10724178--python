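"""Readers and writers for the pipeline's on-disk formats.

Formats
-------
* somatic mutations: minimal VCF 4.2 with an ``INFO/VAF`` field (pysam)
* intervals (phased blocks, windows, annotations): 3+ column BED,
  0-based half-open as BED prescribes
* read observations: TSV with header
  ``read_id  haplotype_tag  chrom  pos  allele`` where ``haplotype_tag`` is
  ``1``, ``2`` or ``.`` (untagged), ``pos`` is 1-based in the file, and
  ``allele`` is ``R`` (reference), ``A`` (alternate) or ``N`` (unresolved)
* methylation calls: TSV ``read_id  chrom  pos  state`` with state ``M``/``U``
  and ``pos`` the 1-based forward-strand C of the CpG
* clone assignments: TSV ``mutation_id  clone_id  ccf``

Positions are converted to the package-internal 0-based convention on read
and back on write, so round-trips are exact.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .intervals import GenomicInterval
from .variants import SomaticMutation


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- VCF

def read_vcf(path: str | Path) -> list[SomaticMutation]:
    """Read somatic point mutations from a single-sample VCF.

    VAF is taken from ``INFO/VAF``; records without it get VAF 0.0.
    Positions become 0-based internally.
    """
    mutations: list[SomaticMutation] = []
    try:
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                if rec.alts is None:
                    continue
                vaf = rec.info.get("VAF", 0.0)
                if isinstance(vaf, tuple):
                    vaf = vaf[0]
                for alt in rec.alts:
                    mutations.append(
                        SomaticMutation(rec.chrom, rec.pos - 1, rec.ref, alt, float(vaf))
                    )
    except (ValueError, OSError) as exc:
        raise ParseError(f"failed to parse VCF {path}: {exc}") from exc
    return mutations


def write_vcf(
    mutations: Iterable[SomaticMutation],
    path: str | Path,
    contig_lengths: dict[str, int],
) -> None:
    """Write mutations as minimal VCF 4.2 with ``INFO/VAF``."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">')
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for mut in sorted(mutations, key=lambda m: (m.chrom, m.pos, m.ref, m.alt)):
            rec = out.new_record(
                contig=mut.chrom, start=mut.pos, alleles=(mut.ref, mut.alt)
            )
            rec.info["VAF"] = mut.vaf
            out.write(rec)


# ---------------------------------------------------------------- BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3+ column BED file into 0-based half-open intervals."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                interval = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(interval)
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ------------------------------------------------- read observations

OBS_COLUMNS = ["read_id", "haplotype_tag", "chrom", "pos", "allele"]


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read a per-read allele-observation table (positions become 0-based)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"read_id": str, "haplotype_tag": str, "chrom": str,
                               "pos": int, "allele": str}
    )
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing observation columns {sorted(missing)}")
    bad = set(df["allele"].unique()) - {"R", "A", "N"}
    if bad:
        raise ParseError(f"{path}: invalid allele codes {sorted(bad)}")
    df = df.copy()
    df["pos"] -= 1
    return df[OBS_COLUMNS]


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    out = df[OBS_COLUMNS].copy()
    out["pos"] += 1
    out.to_csv(path, sep="\t", index=False)


# ------------------------------------------------- methylation calls

METH_COLUMNS = ["read_id", "chrom", "pos", "state"]


def read_methylation_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "chrom": str,
                                            "pos": int, "state": str})
    missing = set(METH_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing methylation columns {sorted(missing)}")
    bad = set(df["state"].unique()) - {"M", "U"}
    if bad:
        raise ParseError(f"{path}: invalid methylation states {sorted(bad)}")
    df = df.copy()
    df["pos"] -= 1
    return df[METH_COLUMNS]


def write_methylation_calls(df: pd.DataFrame, path: str | Path) -> None:
    out = df[METH_COLUMNS].copy()
    out["pos"] += 1
    out.to_csv(path, sep="\t", index=False)


# ------------------------------------------------- clone assignments

def read_clone_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mutation_id": str, "clone_id": str})
    missing = {"mutation_id", "clone_id", "ccf"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing clone-table columns {sorted(missing)}")
    return df


def write_clone_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["mutation_id", "clone_id", "ccf"]].to_csv(path, sep="\t", index=False)


# ------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a reference FASTA into a chrom -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------- SV tables (BEDPE-like)

SV_COLUMNS = ["sv_id", "chrom1", "pos1", "strand1", "chrom2", "pos2",
              "strand2", "type", "insert"]


def read_sv_table(path: str | Path) -> list:
    from .variants import Breakpoint, SVRecord

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(SV_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing SV columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SVRecord(
                sv_id=row.sv_id,
                type=row.type,
                breakpoint1=Breakpoint(row.chrom1, int(row.pos1) - 1, row.strand1),
                breakpoint2=Breakpoint(row.chrom2, int(row.pos2) - 1, row.strand2),
                inserted_seq=row.insert,
            )
        )
    return records


def write_sv_table(svs: Sequence, path: str | Path) -> None:
    rows = [
        {
            "sv_id": sv.sv_id,
            "chrom1": sv.breakpoint1.chrom,
            "pos1": sv.breakpoint1.pos + 1,
            "strand1": sv.breakpoint1.orientation,
            "chrom2": sv.breakpoint2.chrom,
            "pos2": sv.breakpoint2.pos + 1,
            "strand2": sv.breakpoint2.orientation,
            "type": sv.type,
            "insert": sv.inserted_seq,
        }
        for sv in svs
    ]
    pd.DataFrame(rows, columns=SV_COLUMNS).to_csv(path, sep="\t", index=False)
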