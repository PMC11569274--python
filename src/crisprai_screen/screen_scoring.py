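"""Pooled FACS sort-screen gRNA-enrichment scoring.

Raw guide-pair read counts per sorted population and replicate flow through
a fixed sequence: (1) pairs with <= 300 total reads across the populations
of a replicate are dropped; (2) counts are CPM-normalized per sample and
log2-transformed with a pseudocount of 1; (3) log2 fold change is taken
against the cytokine-negative (NEG) population; (4) each pair's log2FC is
converted to a z-score by centering and scaling with the mean and sample
standard deviation of the non-targeting control (NTC) pairs, independently
per replicate (and per screen). These "log2FC z-scores" are the unit of all
downstream interaction analysis.

Perturbation strength re-normalizations (relative to the promoter/TSS
perturbation, or to the average NTC), directional guide concordance, and
qPCR ddCt relative expression live here too.

Expected long-format input columns:
``pair_id, guide1, guide2, is_ntc, population, replicate, reads`` (element /
direction columns are carried through when present).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "filter_pairs",
    "cpm_log2",
    "log2fc_vs_reference",
    "zscore_vs_ntc",
    "score_screen",
    "normalize_strength",
    "guide_concordance",
    "delta_delta_ct",
    "StrengthRecord",
]


def filter_pairs(
    counts: pd.DataFrame, min_total: int = 300, exclude_populations: tuple = ()
) -> pd.DataFrame:
    """Keep pairs whose raw reads summed over populations exceed ``min_total``.

    The sum runs over all populations present (including any unsorted
    sample, unless listed in ``exclude_populations``) within each replicate;
    the comparison is strict (> min_total).
    """
    sub = counts[~counts["population"].isin(exclude_populations)]
    totals = sub.groupby(["replicate", "pair_id"])["reads"].sum()
    keep = totals[totals > min_total].index
    idx = pd.MultiIndex.from_frame(counts[["replicate", "pair_id"]])
    return counts[idx.isin(keep)].copy()


def cpm_log2(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(pseudocount + CPM) per sample (population x replicate).

    The pseudocount is applied after CPM scaling: log2(1 + reads/total*1e6).
    """
    out = counts.copy()
    totals = out.groupby(["replicate", "population"])["reads"].transform("sum")
    if (totals <= 0).any():
        bad = out.loc[totals <= 0, ["replicate", "population"]].drop_duplicates()
        raise ValueError(f"zero-total sample(s): {bad.to_dict('records')}")
    out["norm_log2"] = np.log2(pseudocount + out["reads"] / totals * 1e6)
    return out


def log2fc_vs_reference(
    normalized: pd.DataFrame, population: str, reference: str = "NEG"
) -> pd.DataFrame:
    """Per-pair log2FC: norm_log2(population) - norm_log2(reference).

    Computed per replicate; returns one row per pair x replicate with column
    ``lfc``.
    """
    pops = set(normalized["population"])
    for p in (population, reference):
        if p not in pops:
            raise ValueError(f"population {p!r} absent (have {sorted(pops)})")
    wide = normalized.pivot_table(
        index=["replicate", "pair_id"], columns="population", values="norm_log2"
    )
    meta_cols = [
        c
        for c in (
            "guide1",
            "guide2",
            "element1",
            "direction1",
            "element2",
            "direction2",
            "is_ntc",
            "pair_type",
        )
        if c in normalized.columns
    ]
    meta = normalized.drop_duplicates(["replicate", "pair_id"]).set_index(
        ["replicate", "pair_id"]
    )[meta_cols]
    out = meta.join(wide[[population, reference]].dropna())
    out["lfc"] = out[population] - out[reference]
    return out.drop(columns=[population, reference]).dropna(subset=["lfc"]).reset_index()


def zscore_vs_ntc(lfc: pd.DataFrame) -> pd.DataFrame:
    """NTC-referenced z-score of log2FC, independently per replicate.

    z = (lfc - mean(NTC lfc)) / sd(NTC lfc) with sample sd (n-1). Requires
    at least two NTC pairs with finite lfc per replicate and nonzero spread.
    """
    out = lfc.copy()
    out["z"] = np.nan
    for rep, sub in out.groupby("replicate"):
        ntc = sub.loc[sub["is_ntc"], "lfc"].dropna()
        if len(ntc) < 2:
            raise ValueError(f"replicate {rep}: need >= 2 NTC pairs, have {len(ntc)}")
        sd = ntc.std(ddof=1)
        if sd == 0:
            raise ValueError(f"replicate {rep}: NTC lfc standard deviation is zero")
        out.loc[sub.index, "z"] = (sub["lfc"] - ntc.mean()) / sd
    return out


def score_screen(
    counts: pd.DataFrame,
    population: str = "POS",
    reference: str = "NEG",
    min_total: int = 300,
    pseudocount: float = 1.0,
    exclude_guides: tuple = (),
) -> pd.DataFrame:
    """Full scoring pipeline: filter -> CPM/log2 -> log2FC vs NEG -> NTC z.

    ``exclude_guides`` drops any pair containing a listed guide id before
    scoring (user-supplied outlier-guide removal; never automatic).
    """
    sub = counts
    if exclude_guides:
        bad = sub["guide1"].isin(exclude_guides) | sub["guide2"].isin(exclude_guides)
        sub = sub[~bad]
    sub = filter_pairs(sub, min_total=min_total)
    sub = cpm_log2(sub, pseudocount=pseudocount)
    lfc = log2fc_vs_reference(sub, population=population, reference=reference)
    return zscore_vs_ntc(lfc)


@dataclass
class StrengthRecord:
    element: str
    direction: str
    strength_diff: float  # element lfc - TSS lfc (log2 units)
    strength_pct: float  # element lfc / TSS lfc x 100
    ntc_corrected_lfc: float  # element lfc - mean NTC lfc


def normalize_strength(
    element_lfc: float,
    tss_lfc: float,
    ntc_mean_lfc: float = 0.0,
    element: str = "",
    direction: str = "",
) -> StrengthRecord:
    """Perturbation strength of an element relative to the TSS and NTCs.

    strength_pct is NaN-flagged when the TSS log2FC is zero.
    """
    pct = element_lfc / tss_lfc * 100.0 if tss_lfc != 0 else float("nan")
    return StrengthRecord(
        element=element,
        direction=direction,
        strength_diff=element_lfc - tss_lfc,
        strength_pct=pct,
        ntc_corrected_lfc=element_lfc - ntc_mean_lfc,
    )


def guide_concordance(z_values, min_abs_z: float = 0.0) -> tuple[int, int, int]:
    """Directional concordance of guides targeting one element/direction.

    Majority sign is the sign of the median z. Returns
    (n_concordant, n_total, majority_sign) where a guide is concordant when
    its z sign equals the majority sign and |z| exceeds ``min_abs_z``.
    """
    z = np.asarray(list(z_values), dtype=float)
    if len(z) == 0:
        raise ValueError("need at least one guide z-score")
    majority = int(np.sign(np.median(z)))
    conc = int(np.sum((np.sign(z) == majority) & (np.abs(z) > min_abs_z)))
    return conc, len(z), majority


def delta_delta_ct(
    ct: pd.DataFrame,
    target: str,
    housekeeping: str = "ACTB",
    reference_sample: str = "NTC",
) -> pd.DataFrame:
    """Relative expression by the ddCt method.

    ``ct`` is long format (sample, gene, ct); technical replicates are
    averaged. dCt = Ct(target) - Ct(housekeeping); ddCt = dCt(sample) -
    dCt(reference); rel_expr = 2^(-ddCt). Samples missing either Ct come
    back with NaN and ``defined=False``.
    """
    mean_ct = ct.groupby(["sample", "gene"])["ct"].mean().unstack()
    for gene in (target, housekeeping):
        if gene not in mean_ct.columns:
            raise KeyError(f"gene {gene!r} absent from Ct table")
    if reference_sample not in mean_ct.index:
        raise KeyError(f"reference sample {reference_sample!r} absent from Ct table")
    dct = mean_ct[target] - mean_ct[housekeeping]
    ddct = dct - dct[reference_sample]
    out = pd.DataFrame(
        {
            "sample": mean_ct.index,
            "ct_target": mean_ct[target],
            "ct_housekeeping": mean_ct[housekeeping],
            "delta_ct": dct,
            "delta_delta_ct": ddct,
            "rel_expr": 2.0 ** (-ddct),
        }
    ).reset_index(drop=True)
    out["defined"] = out["delta_delta_ct"].notna()
    return out
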