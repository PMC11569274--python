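"""Normalized expression, differential expression, module scores, and
regulatory-mode classification for dual-perturbation perturb-seq.

The additive model predicts that the log2 fold change of a downstream gene
under a double perturbation equals the sum of the two single-perturbation
log2 fold changes. Genes whose observed double effect departs from that
expectation are classified as under *synergistic* regulation (difference
above 0.1 with greater magnitude than expected, or an effect of opposite
sign) or *buffering* regulation (difference above 0.7 with lower magnitude
than expected); the rest are *additive*.

Differential expression follows the logistic-regression convention for
single-cell data: per gene, a model predicting group membership from the
gene's normalized expression plus batch indicator covariates is compared to
the covariate-only null by a likelihood-ratio test (chi-square, 1 df). A
tiny L2 ridge (default 1e-6) keeps fits finite under complete separation;
such genes are flagged. P values are Benjamini-Hochberg adjusted across
tested genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

__all__ = [
    "log_normalize",
    "de_test_lr",
    "significant_de",
    "classify_mode",
    "classify_modes",
    "module_score",
    "overlap_de_sets",
    "select_comparison_sets",
]


def log_normalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """ln(1 + count / cell_total * scale), per cell (row).

    Raises on zero-total cells: they should have been removed by QC.
    """
    totals = counts.sum(axis=1).astype(float)
    if (totals <= 0).any():
        bad = counts.index[totals <= 0][:5].tolist()
        raise ValueError(f"cells with zero total counts (should fail QC): {bad}")
    return np.log1p(counts.div(totals, axis=0) * scale)


def _loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float) -> tuple[float, float]:
    """Fit ridge-stabilized logistic regression; return (llf, max |coef|)."""
    if X.shape[1] == 0:
        p = y.mean()
        return _loglik(y, np.full_like(y, p, dtype=float)), 0.0
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=500, tol=1e-8)
    clf.fit(X, y)
    return _loglik(y, clf.predict_proba(X)[:, 1]), float(np.abs(clf.coef_).max())


def de_test_lr(
    norm: pd.DataFrame,
    cells_a,
    cells_b,
    batch: pd.Series | None = None,
    ridge: float = 1e-6,
) -> pd.DataFrame:
    """Likelihood-ratio DE between two cell groups on normalized expression.

    Parameters
    ----------
    norm
        Cell x gene log-normalized expression.
    cells_a, cells_b
        Index labels of the two groups (A is the perturbed/of-interest
        group, B the reference, typically NTC cells).
    batch
        Optional per-cell batch labels entering both models as indicator
        covariates.

    Returns
    -------
    DataFrame (gene, log2fc, p_value, p_adj, flagged) sorted by gene order
    of ``norm``. log2fc = log2 of the ratio of (mean back-transformed
    expression + 1) between groups, the usual single-cell convention.
    """
    cells_a = pd.Index(cells_a)
    cells_b = pd.Index(cells_b)
    if len(cells_a) == 0 or len(cells_b) == 0:
        raise ValueError("both cell groups must be nonempty")
    cells = cells_a.append(cells_b)
    y = np.concatenate([np.ones(len(cells_a)), np.zeros(len(cells_b))])
    sub = norm.loc[cells]
    if batch is not None:
        cov = pd.get_dummies(batch.reindex(cells), drop_first=True, dtype=float)
        cov = cov.loc[:, cov.std(axis=0) > 0].to_numpy()
    else:
        cov = np.empty((len(cells), 0))

    llf_null, _ = _fit_logistic(cov, y, ridge)

    xa = np.expm1(sub.loc[cells_a].to_numpy())
    xb = np.expm1(sub.loc[cells_b].to_numpy())
    log2fc = np.log2((xa.mean(axis=0) + 1.0) / (xb.mean(axis=0) + 1.0))

    expr = sub.to_numpy()
    pvals = np.empty(norm.shape[1])
    flagged = np.zeros(norm.shape[1], dtype=bool)
    for j in range(norm.shape[1]):
        col = expr[:, j]
        if col.std() == 0:
            pvals[j] = 1.0
            continue
        X = np.column_stack([col, cov]) if cov.shape[1] else col[:, None]
        llf_full, cmax = _fit_logistic(X, y, ridge)
        lr = max(0.0, 2.0 * (llf_full - llf_null))
        pvals[j] = stats.chi2.sf(lr, df=1)
        flagged[j] = cmax > 15.0  # near-separation: ridge-dominated fit
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": norm.columns,
            "log2fc": log2fc,
            "p_value": pvals,
            "p_adj": p_adj,
            "flagged": flagged,
        }
    )


def significant_de(
    results: pd.DataFrame, min_abs_lfc: float = 0.5, max_padj: float = 0.05
) -> set:
    """DE gene set: p_adj < max_padj AND |log2fc| > min_abs_lfc (both strict)."""
    if len(results) == 0:
        return set()
    keep = (results["p_adj"] < max_padj) & (results["log2fc"].abs() > min_abs_lfc)
    return set(results.loc[keep, "gene"])


def classify_mode(
    observed: float, expected: float, thr_syn: float = 0.1, thr_buf: float = 0.7
) -> str:
    """Regulatory mode of one gene from observed/expected double log2FC.

    With d = observed - expected:
      synergy  if |d| > thr_syn and (|observed| > |expected| or opposite sign),
      buffer   if |d| > thr_buf and |observed| < |expected|,
      additive otherwise.
    A zero value is treated as matching either sign.
    """
    if thr_syn >= thr_buf:
        raise ValueError("synergy threshold must be below buffer threshold")
    d = observed - expected
    opposite = observed * expected < 0
    if abs(d) > thr_syn and (abs(observed) > abs(expected) or opposite):
        return "synergy"
    if abs(d) > thr_buf and abs(observed) < abs(expected):
        return "buffer"
    return "additive"


@dataclass
class ModeSummary:
    records: pd.DataFrame
    proportions: pd.Series
    synergy_buffer_ratio: float  # NaN when no buffer genes


def classify_modes(
    de_single_a: pd.DataFrame,
    de_single_i: pd.DataFrame,
    de_double: pd.DataFrame,
    thr_syn: float = 0.1,
    thr_buf: float = 0.7,
    restrict_to_significant: bool = True,
) -> ModeSummary:
    """Classify genes into synergy / buffer / additive regulatory modes.

    Expected double log2FC is the sum of the two single log2FCs. Only genes
    present in all three DE tables are classified; by default they are
    further restricted to genes significant (p_adj < 0.05, |log2fc| > 0.5)
    in at least one of the three sets.
    """
    tabs = {}
    for name, df in (("a", de_single_a), ("i", de_single_i), ("d", de_double)):
        tabs[name] = df.set_index("gene")
    genes = tabs["a"].index.intersection(tabs["i"].index).intersection(tabs["d"].index)
    if restrict_to_significant:
        sig = (
            significant_de(de_single_a)
            | significant_de(de_single_i)
            | significant_de(de_double)
        )
        genes = genes[genes.isin(sig)]
    recs = pd.DataFrame(
        {
            "gene": genes,
            "lfc_single_a": tabs["a"].loc[genes, "log2fc"].to_numpy(),
            "lfc_single_i": tabs["i"].loc[genes, "log2fc"].to_numpy(),
            "lfc_double_observed": tabs["d"].loc[genes, "log2fc"].to_numpy(),
        }
    )
    recs["lfc_double_expected"] = recs["lfc_single_a"] + recs["lfc_single_i"]
    recs["difference"] = recs["lfc_double_observed"] - recs["lfc_double_expected"]
    recs["mode"] = [
        classify_mode(o, e, thr_syn, thr_buf)
        for o, e in zip(recs["lfc_double_observed"], recs["lfc_double_expected"])
    ]
    props = (
        recs["mode"].value_counts(normalize=True)
        .reindex(["additive", "synergy", "buffer"])
        .fillna(0.0)
    )
    n_syn = int((recs["mode"] == "synergy").sum())
    n_buf = int((recs["mode"] == "buffer").sum())
    ratio = n_syn / n_buf if n_buf else float("nan")
    return ModeSummary(records=recs, proportions=props, synergy_buffer_ratio=ratio)


def module_score(
    norm: pd.DataFrame,
    gene_set,
    n_bins: int = 25,
    n_controls: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-bin-matched module score per cell.

    Genes are binned by dataset-average expression into ``n_bins`` bins; for
    each set gene, up to ``n_controls`` control genes are drawn from its bin
    (excluding set genes, without replacement within a draw — a bin smaller
    than ``n_controls`` contributes all of its non-set genes). The score is
    mean(set expression) - mean(control expression) per cell, controls
    counted with multiplicity across set genes.
    """
    gene_set = [g for g in gene_set]
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    missing = set(gene_set) - set(norm.columns)
    if missing:
        raise KeyError(f"gene set members not in matrix: {sorted(missing)[:5]}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    avg = norm.mean(axis=0)
    # rank-based cut mirrors binning on average expression with stable ties
    bins = pd.qcut(avg.rank(method="first"), q=n_bins, labels=False)
    in_set = norm.columns.isin(gene_set)
    controls: list[str] = []
    for g in gene_set:
        pool = norm.columns[(bins == bins[g]) & ~in_set]
        if len(pool) == 0:
            continue
        take = min(n_controls, len(pool))
        controls.extend(rng.choice(pool, size=take, replace=False))
    if not controls:
        raise ValueError("no control genes available outside the gene set")
    score = norm[gene_set].mean(axis=1) - norm[controls].mean(axis=1)
    score.name = "module_score"
    return score


def overlap_de_sets(set_a: set, set_i: set, set_double: set) -> dict:
    """Three-way partition of DE gene sets.

    Returns the 7 exclusive region counts plus ``double_specific``, the gene
    set unique to the double perturbation.
    """
    a, i, d = set(set_a), set(set_i), set(set_double)
    return {
        "a_only": len(a - i - d),
        "i_only": len(i - a - d),
        "double_only": len(d - a - i),
        "a_and_i": len((a & i) - d),
        "a_and_double": len((a & d) - i),
        "i_and_double": len((i & d) - a),
        "all_three": len(a & i & d),
        "double_specific": d - a - i,
    }


def select_comparison_sets(
    mode_records: pd.DataFrame,
    detected_genes,
    excluded_sets,
    n_top_additive: int = 50,
    n_random: int = 300,
    seed: int = 0,
) -> tuple[list, list]:
    """Comparison gene sets for occupancy analysis.

    top-additive: the ``n_top_additive`` classified genes with smallest
    |observed - expected| (ties broken by gene id). random: ``n_random``
    genes sampled (without replacement, seeded) from detected genes
    excluding every set in ``excluded_sets``.
    """
    ranked = mode_records.assign(absdiff=mode_records["difference"].abs()).sort_values(
        ["absdiff", "gene"]
    )
    if len(ranked) < n_top_additive:
        raise ValueError(
            f"only {len(ranked)} classified genes for top-{n_top_additive} additive"
        )
    top = ranked["gene"].head(n_top_additive).tolist()
    excluded = set().union(*excluded_sets) if excluded_sets else set()
    pool = sorted(set(detected_genes) - excluded)
    if len(pool) < n_random:
        raise ValueError(
            f"only {len(pool)} candidate genes for a random set of {n_random}"
        )
    rng = np.random.default_rng(seed)
    rand = sorted(rng.choice(pool, size=n_random, replace=False))
    return top, rand
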