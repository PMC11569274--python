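"""Cell QC, per-cell guide calling, and guide-detection error-rate estimation.

A cell passes QC only if every filter holds with a strict inequality:
genes detected > min_genes and < max_genes, transcriptome UMIs < max_umis,
percent mitochondrial reads < max_pct_mito, guides with nonzero reads >
min_guides_detected, and guide UMIs > min_guide_umis. Guide calling uses a
fraction-of-total-reads rule: a guide is called when its share of the cell's
guide reads reaches 20% (single-capture cells) or 10% (double-capture
cells). Detection FNR is the fraction of double-capture cells called single;
FPR the fraction of single-capture cells called double.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "MisassignmentEstimate",
    "qc_filter_cells",
    "assign_guides",
    "estimate_misassignment",
    "normalize_guide_counts",
]

QC_COLUMNS = [
    "n_genes_detected",
    "total_transcript_umis",
    "pct_mito",
    "n_guides_detected",
    "guide_umis",
]


@dataclass
class QCThresholds:
    """Cell-level QC cutoffs (all comparisons strict).

    max_genes / max_umis defaults sit at the midpoints of the per-capture
    ranges used in practice (5,500-8,300 genes; 27,000-75,000 UMIs); tune
    per capture.
    """

    min_genes: int = 200
    max_genes: int = 6_900
    max_umis: int = 51_000
    max_pct_mito: float = 10.0
    min_guides_detected: int = 20
    min_guide_umis: int = 50


# first-failing filter order for the removal tally
_FILTER_ORDER = [
    ("min_genes", lambda df, t: df["n_genes_detected"] > t.min_genes),
    ("max_genes", lambda df, t: df["n_genes_detected"] < t.max_genes),
    ("max_umis", lambda df, t: df["total_transcript_umis"] < t.max_umis),
    ("max_pct_mito", lambda df, t: df["pct_mito"] < t.max_pct_mito),
    (
        "min_guides_detected",
        lambda df, t: df["n_guides_detected"] > t.min_guides_detected,
    ),
    ("min_guide_umis", lambda df, t: df["guide_umis"] > t.min_guide_umis),
]


def qc_filter_cells(
    qc: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[pd.Index, pd.Series]:
    """Apply the strict QC filters.

    Parameters
    ----------
    qc
        One row per cell (index = cell id) with columns
        ``n_genes_detected, total_transcript_umis, pct_mito,
        n_guides_detected, guide_umis``.

    Returns
    -------
    (retained cell index, per-filter removal tally). Each removed cell is
    tallied under the first filter it fails, in the documented order
    min_genes, max_genes, max_umis, max_pct_mito, min_guides_detected,
    min_guide_umis.
    """
    if len(qc) == 0:
        raise ValueError("empty QC table")
    missing = [c for c in QC_COLUMNS if c not in qc.columns]
    if missing:
        raise KeyError(f"QC table is missing column(s): {', '.join(missing)}")
    t = thresholds or QCThresholds()
    keep = pd.Series(True, index=qc.index)
    failed_by = pd.Series("", index=qc.index)
    for name, rule in _FILTER_ORDER:
        ok = rule(qc, t)
        newly_failed = keep & ~ok
        failed_by[newly_failed] = name
        keep &= ok
    tally = pd.Series(
        {name: int((failed_by == name).sum()) for name, _ in _FILTER_ORDER},
        name="n_removed",
    )
    return qc.index[keep], tally


def assign_guides(
    guide_counts: pd.DataFrame,
    capture_multiplicity: pd.Series,
    fraction_single: float = 0.20,
    fraction_double: float = 0.10,
) -> pd.DataFrame:
    """Call guides per cell by their fraction of total guide reads.

    A guide is called when ``reads / total_guide_reads >= fraction`` with the
    capture-appropriate fraction (20% single, 10% double). Cells with zero
    guide reads, zero calls, or more than two calls are flagged
    not-assignable rather than erroring.

    Returns a table indexed by cell with columns ``assigned_guides`` (tuple),
    ``n_guides``, ``genotype`` ('|'-joined sorted guide ids), ``assignable``.
    """
    counts = guide_counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    guides = np.asarray(guide_counts.columns)
    mult = capture_multiplicity.reindex(guide_counts.index)
    rows = []
    for c, cell in enumerate(guide_counts.index):
        if totals[c] <= 0:
            rows.append((cell, (), 0, "", False))
            continue
        frac = counts[c] / totals[c]
        thr = fraction_double if mult.iloc[c] == 2 else fraction_single
        called = tuple(sorted(guides[frac >= thr]))
        assignable = 1 <= len(called) <= 2
        genotype = "|".join(called) if assignable else ""
        rows.append((cell, called, len(called), genotype, assignable))
    return pd.DataFrame(
        rows,
        columns=["cell_id", "assigned_guides", "n_guides", "genotype", "assignable"],
    ).set_index("cell_id")


@dataclass
class MisassignmentEstimate:
    fnr: float
    fpr: float
    n_double_capture: int
    n_single_capture: int

    def as_dict(self) -> dict:
        return asdict(self)


def estimate_misassignment(
    assignments: pd.DataFrame, capture_multiplicity: pd.Series
) -> MisassignmentEstimate:
    """Estimate guide-detection FNR and FPR from called guide numbers.

    FNR = fraction of double-capture cells with exactly one called guide;
    FPR = fraction of single-capture cells with two called guides.
    Denominators count only assignable cells (1 or 2 calls): cells with zero
    guide reads or >2 calls carry no evidence about single-vs-double
    detection and are excluded. An empty denominator yields NaN for that
    rate.
    """
    mult = capture_multiplicity.reindex(assignments.index)
    ok = assignments["assignable"]
    dbl = ok & (mult == 2)
    sgl = ok & (mult == 1)
    n_dbl, n_sgl = int(dbl.sum()), int(sgl.sum())
    fnr = (
        float((assignments.loc[dbl, "n_guides"] == 1).mean()) if n_dbl else float("nan")
    )
    fpr = (
        float((assignments.loc[sgl, "n_guides"] == 2).mean()) if n_sgl else float("nan")
    )
    return MisassignmentEstimate(fnr=fnr, fpr=fpr, n_double_capture=n_dbl,
                                 n_single_capture=n_sgl)


def normalize_guide_counts(
    guide_counts: pd.DataFrame, scale: float = 100.0
) -> pd.DataFrame:
    """Relative guide counts: reads / cell total x scale (rows sum to scale).

    Cells with zero total guide reads come back as all-NaN rows (flagged
    downstream, not an exception).
    """
    totals = guide_counts.sum(axis=1).astype(float)
    rel = guide_counts.div(totals.where(totals > 0), axis=0) * scale
    return rel
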