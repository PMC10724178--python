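"""Aggregate per-read CpG methylation calls into window-level profiles.

Per-read calls (one methylated/unmethylated state per read and CpG site,
strand-collapsed to the forward-strand C) are averaged in two stages: first
a per-CpG methylation fraction, then the unweighted mean of site fractions
within each 50-kb window. Two-stage averaging keeps deep sites from
dominating a window. The genome-wide summary is the median over windows
with at least one covered CpG. Tumour-minus-normal deltas and
annotation-class means (repeat families, CpG islands/shores, promoters,
enhancers) reuse the same site fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, tile_windows


@dataclass
class WindowMethylation:
    window: GenomicInterval
    n_cpgs_covered: int
    mean_rate: float | None
    delta_vs_normal: float | None = None


def site_rates(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG methylation fraction from a call table.

    Input columns: ``read_id, chrom, pos, state`` with state 'M'/'U'.
    Output columns: ``chrom, pos, n_calls, rate``; uncovered sites are
    simply absent.
    """
    if calls.empty:
        return pd.DataFrame(columns=["chrom", "pos", "n_calls", "rate"])
    grouped = calls.groupby(["chrom", "pos"], sort=True)["state"].agg(
        n_calls="size", n_meth=lambda s: (s == "M").sum()
    )
    out = grouped.reset_index()
    out["rate"] = out["n_meth"] / out["n_calls"]
    return out[["chrom", "pos", "n_calls", "rate"]]


def window_rates(
    rates: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_size: int = 50_000,
) -> list[WindowMethylation]:
    """Unweighted mean of per-CpG fractions per fixed-size tile; windows
    with no covered CpG carry a null rate."""
    windows = tile_windows(chrom_lengths, window_size)
    results = []
    for win in windows:
        sub = rates[
            (rates["chrom"] == win.chrom)
            & (rates["pos"] >= win.start)
            & (rates["pos"] < win.end)
        ]
        n = len(sub)
        results.append(
            WindowMethylation(win, n, float(sub["rate"].mean()) if n else None)
        )
    return results


def genome_median(windows: Sequence[WindowMethylation]) -> float | None:
    """Median of per-window mean rates over covered windows (null when no
    window is covered)."""
    values = [w.mean_rate for w in windows if w.mean_rate is not None]
    return float(np.median(values)) if values else None


def tumor_normal_delta(
    tumor: Sequence[WindowMethylation],
    normal: Sequence[WindowMethylation],
) -> list[WindowMethylation]:
    """Per-window tumour-minus-normal difference; null when either side is
    uncovered. Window lists must tile the same genome."""
    if [w.window for w in tumor] != [w.window for w in normal]:
        raise ValueError("tumor and normal window tilings differ")
    out = []
    for t, n in zip(tumor, normal):
        delta = (
            t.mean_rate - n.mean_rate
            if t.mean_rate is not None and n.mean_rate is not None
            else None
        )
        out.append(WindowMethylation(t.window, t.n_cpgs_covered, t.mean_rate, delta))
    return out


def annotation_rates(
    rates: pd.DataFrame,
    annotations: Mapping[str, Sequence[GenomicInterval]],
) -> dict[str, float | None]:
    """Mean site methylation per annotation class.

    A CpG contributes to every class with an interval containing it
    (overlapping features within a class count the site once). Classes with
    no covered CpG report null.
    """
    out: dict[str, float | None] = {}
    for name, intervals in annotations.items():
        mask = np.zeros(len(rates), dtype=bool)
        for iv in intervals:
            mask |= (
                (rates["chrom"] == iv.chrom).to_numpy()
                & (rates["pos"].to_numpy() >= iv.start)
                & (rates["pos"].to_numpy() < iv.end)
            )
        out[name] = float(rates.loc[mask, "rate"].mean()) if mask.any() else None
    return out
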