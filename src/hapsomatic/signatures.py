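"""96-channel single-base-substitution spectra and cosine similarity.

Channels follow the standard pyrimidine-centred trinucleotide convention:
six substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) in each of the 16
flanking-base contexts. Mutations with a purine reference are
reverse-complemented onto the pyrimidine strand before lookup. The channel
order is the full lexicographic sort of the channel strings,
``A[C>A]A`` ... ``T[T>G]T``, and is written into output headers.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .variants import SomaticMutation

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: the fixed 96-channel order (lexicographic on the channel string)
CHANNELS: tuple[str, ...] = tuple(sorted(
    f"{five}[{sub}]{three}"
    for sub in PYRIMIDINE_SUBS
    for five in "ACGT"
    for three in "ACGT"
))
_CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}

#: channels whose context is TpC (5' T next to a mutated C) — the
#: APOBEC-family target motif
TPC_CHANNELS: tuple[str, ...] = tuple(
    c for c in CHANNELS if c.startswith("T[C>")
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def trinucleotide_channel(
    chrom: str, pos: int, ref: str, alt: str,
    reference_sequence: Mapping[str, str],
) -> int:
    """Channel index of a single-base substitution at 0-based ``pos``.

    Raises ``ValueError`` on a reference mismatch; raises ``IndexError``
    when a flanking base is missing (contig edge) — callers skip and log.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    seq = reference_sequence[chrom]
    if seq[pos] != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos + 1}: expected {ref}, found {seq[pos]}"
        )
    if pos == 0 or pos + 1 >= len(seq):
        raise IndexError(f"no flanking base at {chrom}:{pos + 1}")
    context = seq[pos - 1 : pos + 2]
    if ref in "AG":  # purine reference: flip to the pyrimidine strand
        context = reverse_complement(context)
        alt = alt.translate(_COMPLEMENT)
    channel = f"{context[0]}[{context[1]}>{alt}]{context[2]}"
    try:
        return _CHANNEL_INDEX[channel]
    except KeyError as exc:
        raise ValueError(f"non-ACGT context {channel}") from exc


def spectrum(
    mutations: Iterable[SomaticMutation],
    reference_sequence: Mapping[str, str],
) -> np.ndarray:
    """96-channel substitution counts of a mutation set.

    Indels are excluded; SNVs at contig edges or with ambiguous context are
    skipped with a log message. Counts sum to the number of usable SNVs.
    """
    counts = np.zeros(len(CHANNELS), dtype=float)
    for mut in mutations:
        if not mut.is_snv:
            continue
        try:
            idx = trinucleotide_channel(mut.chrom, mut.pos, mut.ref, mut.alt,
                                        reference_sequence)
        except IndexError:
            logger.warning("skipping %s: no trinucleotide context", mut.id)
            continue
        counts[idx] += 1
    return counts


def normalize(spec: Sequence[float]) -> np.ndarray:
    arr = np.asarray(spec, dtype=float)
    total = arr.sum()
    return arr / total if total > 0 else arr


def tpc_fraction(spec: Sequence[float]) -> float:
    """Fraction of spectrum mass on TpC-context C-mutation channels."""
    arr = np.asarray(spec, dtype=float)
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero spectrum")
    idx = [_CHANNEL_INDEX[c] for c in TPC_CHANNELS]
    return float(arr[idx].sum() / total)


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """Cosine similarity of two non-negative spectra, in [0, 1]."""
    va, vb = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("spectra have different lengths")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for an all-zero spectrum")
    return float(np.dot(va, vb) / (na * nb))


def write_spectrum_tsv(spec: Sequence[float], path) -> None:
    arr = np.asarray(spec, dtype=float)
    frac = normalize(arr)
    with open(path, "w") as fh:
        fh.write("channel\tcount\tfraction\n")
        for name, c, f in zip(CHANNELS, arr, frac):
            fh.write(f"{name}\t{c:g}\t{f:.6g}\n")
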