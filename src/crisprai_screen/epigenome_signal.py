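"""Regulatory-element signal aggregation and TF-occupancy classification.

Tracks are bedGraph-style interval tables (chrom, start, end, value) in
0-based half-open BED coordinates. The mean signal over a regulatory
element is the base-pair-weighted average of overlapping track values;
bases not covered by the track count as signal 0 by default. A gene is
classified as bound by a factor when at least one of its elements —
the promoter window (TSS +/- 1 kb) or an annotated enhancer — has
log2(signal + 0.01) strictly above 5 (fold-change-over-control units).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "promoter_window",
    "aggregate_interval_signal",
    "log2_signal",
    "classify_bound_genes",
    "atac_normalize",
    "track_total",
]


def promoter_window(tss: int, flank: int = 1000) -> tuple[int, int]:
    """TSS +/- flank as a 0-based half-open interval, clipped at 0."""
    return max(0, tss - flank), tss + flank


def aggregate_interval_signal(
    track: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    uncovered_as_zero: bool = True,
) -> float:
    """Base-pair-weighted mean track value over [start, end).

    ``uncovered_as_zero=False`` averages over covered bases only (NaN if
    none are covered).
    """
    if start >= end or start < 0:
        raise ValueError(f"malformed interval [{start}, {end})")
    sub = track[track["chrom"] == chrom]
    ov_start = np.maximum(sub["start"].to_numpy(), start)
    ov_end = np.minimum(sub["end"].to_numpy(), end)
    width = np.clip(ov_end - ov_start, 0, None)
    total = float((width * sub["value"].to_numpy()).sum())
    covered = int(width.sum())
    if uncovered_as_zero:
        return total / (end - start)
    return total / covered if covered else float("nan")


def log2_signal(mean_signal, pseudocount: float = 0.01):
    """log2(signal + pseudocount); signal must be nonnegative."""
    arr = np.asarray(mean_signal, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative signal value")
    out = np.log2(arr + pseudocount)
    return float(out) if np.isscalar(mean_signal) else out


def classify_bound_genes(
    element_signal: pd.DataFrame,
    threshold: float = 5.0,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-gene TF-occupancy call from element-level mean signal.

    ``element_signal`` has one row per (gene, element) with columns
    ``gene, element, mean_signal`` (fold-change-over-control). A gene is
    bound iff any element's log2(signal + pseudocount) exceeds ``threshold``
    strictly. Returns (gene, n_elements, max_log2_signal, bound).
    """
    if len(element_signal) == 0:
        return pd.DataFrame(columns=["gene", "n_elements", "max_log2_signal", "bound"])
    df = element_signal.copy()
    df["log2_signal"] = log2_signal(df["mean_signal"].to_numpy(), pseudocount)
    agg = df.groupby("gene").agg(
        n_elements=("element", "count"), max_log2_signal=("log2_signal", "max")
    )
    agg["bound"] = agg["max_log2_signal"] > threshold
    return agg.reset_index()


def atac_normalize(
    values,
    chrom_total: float,
    pseudocount: float = 1e-4,
    scale: float = 1e6,
):
    """Per-chromosome depth normalization of ATAC track values.

    value -> (raw + pseudocount) / chrom_total * scale, where ``chrom_total``
    is the per-sample total signal on the normalization chromosome (sum of
    value x interval width). Cross-sample comparisons use these units.
    """
    if chrom_total <= 0:
        raise ValueError("chromosome total must be positive")
    arr = np.asarray(values, dtype=float)
    out = (arr + pseudocount) / chrom_total * scale
    return float(out) if np.isscalar(values) else out


def track_total(track: pd.DataFrame, chrom: str) -> float:
    """Total signal on one chromosome: sum of value x interval width."""
    sub = track[track["chrom"] == chrom]
    return float(
        ((sub["end"] - sub["start"]) * sub["value"]).sum()
    )
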