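"""Genetic-interaction (GI) scoring for bidirectional perturbation pairs.

The additive null model for a double perturbation's log2FC z-score is the
sum of the two corresponding single-perturbation z-scores. Per replicate,
observed double z is regressed on expected z (ordinary least squares) and
the GI score of a pair is its residual from that line. Two significance
procedures are applied:

* method 1 — flag pairs whose residual lies outside 1 s.d. from the mean of
  residuals, and require the flag in *all* replicates;
* method 2 — center/scale residuals to residual z-scores, check normality
  (Shapiro-Wilk, advisory), and flag pairs with two-sided normal-tail
  p < 0.05, uncorrected.

Consensus hits are pairs significant by both methods (method-2 flag required
in every replicate by default; an any-replicate mode is available).

Gatekeeper detection formalizes the hierarchy readout: an element whose
single-perturbation strength is a substantial fraction of the promoter's and
whose bidirectional pairs follow the element's own sign against opposing
partners is called a gatekeeper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FitSummary",
    "expected_pair_z",
    "build_gi_table",
    "fit_observed_expected",
    "gi_method1",
    "gi_method2",
    "gi_consensus",
    "score_interactions",
    "detect_gatekeepers",
]


def expected_pair_z(z_single_1: float, z_single_2: float) -> float:
    """Additive expectation: sum of the two single-perturbation z-scores."""
    return z_single_1 + z_single_2


def _single_z(scored: pd.DataFrame) -> pd.DataFrame:
    """Single-perturbation z per (replicate, element, direction).

    Singles are pairs whose second guide is an NTC partner (pair_type
    'single' when present, otherwise direction2 == 'ntc'). Multiple guides
    per element/direction are averaged.
    """
    if "pair_type" in scored.columns:
        singles = scored[scored["pair_type"] == "single"]
    else:
        singles = scored[(scored["direction2"] == "ntc") & ~scored["is_ntc"]]
    return (
        singles.groupby(["replicate", "element1", "direction1"])["z"]
        .mean()
        .rename("z_single")
        .reset_index()
    )


def build_gi_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Join observed double-pair z with the additive expected z.

    Input is the scored screen table (one row per pair x replicate with
    ``z``). Doubles missing either single in a replicate are dropped (the
    count is recorded in the ``attrs['n_excluded']`` of the result).
    """
    singles = _single_z(scored)
    if "pair_type" in scored.columns:
        doubles = scored[scored["pair_type"] == "double"].copy()
    else:
        doubles = scored[
            (scored["direction1"] != "ntc") & (scored["direction2"] != "ntc")
        ].copy()
    n0 = len(doubles)
    for side in ("1", "2"):
        doubles = doubles.merge(
            singles.rename(
                columns={
                    "element1": f"element{side}",
                    "direction1": f"direction{side}",
                    "z_single": f"z_single_{side}",
                }
            ),
            on=["replicate", f"element{side}", f"direction{side}"],
            how="inner",
        )
    doubles["z_observed"] = doubles["z"]
    doubles["z_expected"] = doubles["z_single_1"] + doubles["z_single_2"]
    doubles.attrs["n_excluded"] = n0 - len(doubles)
    return doubles


@dataclass
class FitSummary:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    replicate: int | None = None


def fit_observed_expected(
    expected, observed, replicate: int | None = None
) -> tuple[FitSummary, np.ndarray]:
    """OLS line of best fit of observed on expected z; returns residuals.

    residual = observed - (slope * expected + intercept).
    """
    x = np.asarray(expected, dtype=float)
    y = np.asarray(observed, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs to fit")
    if np.var(x) == 0:
        raise ValueError("expected z has zero variance; line of best fit undefined")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    return (
        FitSummary(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r_squared=float(fit.rvalue**2),
            n_points=len(x),
            replicate=replicate,
        ),
        resid,
    )


def gi_method1(residuals: pd.DataFrame, k: float = 1.0) -> tuple[pd.Series, pd.DataFrame]:
    """Mean +/- k.s.d. outlier rule, required in every replicate.

    ``residuals`` is wide (index = pair, one column per replicate). Returns
    (per-pair method-1 hit flag, per-replicate flag table). A replicate with
    zero residual spread yields no flags (with a warning).
    """
    flags = pd.DataFrame(False, index=residuals.index, columns=residuals.columns)
    for rep in residuals.columns:
        r = residuals[rep]
        sd = r.std(ddof=1)
        if not sd > 0:
            warnings.warn(f"replicate {rep}: residual sd is 0; no method-1 flags")
            continue
        flags[rep] = (r - r.mean()).abs() > k * sd
    return flags.all(axis=1), flags


def gi_method2(
    residuals: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Normal-tail p-values on residual z-scores, uncorrected.

    Per replicate: residual_z = (r - mean) / sd (sample sd); Shapiro-Wilk
    normality p is reported (advisory — a warning below 0.05, analysis
    proceeds); per-pair p = 2 * (1 - Phi(|residual_z|)); flag iff p < alpha.
    A zero-spread replicate gives residual_z = 0 and p = 1 throughout.

    Returns (normality p per replicate, residual_z, p, flags).
    """
    zs = pd.DataFrame(index=residuals.index, columns=residuals.columns, dtype=float)
    normality = pd.Series(index=residuals.columns, dtype=float, name="shapiro_p")
    for rep in residuals.columns:
        r = residuals[rep]
        sd = r.std(ddof=1)
        zs[rep] = 0.0 if not sd > 0 else (r - r.mean()) / sd
        if 3 <= len(r) <= 5000 and sd > 0:
            normality[rep] = stats.shapiro(r).pvalue
            if normality[rep] < 0.05:
                warnings.warn(
                    f"replicate {rep}: residuals fail Shapiro-Wilk normality "
                    f"(p={normality[rep]:.3g}); method-2 p-values are approximate"
                )
        else:
            normality[rep] = float("nan")
    pvals = 2.0 * stats.norm.sf(zs.abs())
    pvals = pd.DataFrame(pvals, index=zs.index, columns=zs.columns)
    return normality, zs, pvals, pvals < alpha


def gi_consensus(
    method1_hits: pd.Series, method2_flags: pd.DataFrame, require: str = "all"
) -> pd.Series:
    """Pairs significant by both methods.

    ``require`` controls how method-2 per-replicate flags aggregate:
    'all' (default, the stringent reading) or 'any'.
    """
    if not method1_hits.index.equals(method2_flags.index):
        raise ValueError("method 1 and method 2 were run on different pair sets")
    if require == "all":
        m2 = method2_flags.all(axis=1)
    elif require == "any":
        m2 = method2_flags.any(axis=1)
    else:
        raise ValueError("require must be 'all' or 'any'")
    return method1_hits & m2


def score_interactions(
    scored: pd.DataFrame,
    k: float = 1.0,
    alpha: float = 0.05,
    require: str = "all",
) -> dict:
    """End-to-end GI scoring on a scored screen table.

    Returns a dict with the per-replicate fit summaries, wide residual /
    residual-z / p tables, method flags, and consensus hits.
    """
    gi = build_gi_table(scored)
    fits, resid_cols = [], {}
    for rep, sub in gi.groupby("replicate"):
        sub = sub.set_index("pair_id")
        fit, resid = fit_observed_expected(
            sub["z_expected"], sub["z_observed"], replicate=rep
        )
        fits.append(fit)
        resid_cols[rep] = pd.Series(resid, index=sub.index)
    residuals = pd.DataFrame(resid_cols).dropna()
    m1_hits, m1_flags = gi_method1(residuals, k=k)
    normality, resid_z, pvals, m2_flags = gi_method2(residuals, alpha=alpha)
    consensus = gi_consensus(m1_hits, m2_flags, require=require)
    return {
        "table": gi,
        "fits": fits,
        "residuals": residuals,
        "residual_z": resid_z,
        "normality_p": normality,
        "p_method2": pvals,
        "method1_flags": m1_flags,
        "method1_hits": m1_hits,
        "method2_flags": m2_flags,
        "consensus_hits": consensus,
    }


def detect_gatekeepers(
    scored: pd.DataFrame,
    tss_element: str = "TSS",
    min_strength_pct: float = 50.0,
    min_override_frac: float = 0.5,
) -> pd.DataFrame:
    """Call gatekeeper elements from single and bidirectional z-scores.

    Per (element, direction), averaging z over replicates: the element is a
    gatekeeper when (a) its single-perturbation strength is at least
    ``min_strength_pct`` percent of the same-direction TSS single z, and
    (b) among its bidirectional pairs whose partner's single z opposes the
    element's single z, the fraction of pairs whose pair z follows the
    element's sign is at least ``min_override_frac``. The TSS itself is not
    scored (hierarchy over enhancers is its expected behavior). Elements
    with no opposing partners get ``override_frac`` NaN and no call.
    """
    singles = (
        _single_z(scored)
        .groupby(["element1", "direction1"])["z_single"]
        .mean()
    )
    gi = build_gi_table(scored)
    pair_z = gi.groupby(
        ["element1", "direction1", "element2", "direction2"]
    )[["z_observed", "z_single_1", "z_single_2"]].mean()

    rows = []
    for (el, dr), z_el in singles.items():
        if el == tss_element:
            continue
        tss_key = (tss_element, dr)
        z_tss = singles.get(tss_key, float("nan"))
        pct = z_el / z_tss * 100.0 if pd.notna(z_tss) and z_tss != 0 else float("nan")
        n_opp = n_override = 0
        for (e1, d1, e2, d2), row in pair_z.iterrows():
            if (e1, d1) == (el, dr):
                partner_z = row["z_single_2"]
            elif (e2, d2) == (el, dr):
                partner_z = row["z_single_1"]
            else:
                continue
            if np.sign(partner_z) == np.sign(z_el) or partner_z == 0:
                continue  # not an opposing partner
            n_opp += 1
            if np.sign(row["z_observed"]) == np.sign(z_el):
                n_override += 1
        frac = n_override / n_opp if n_opp else float("nan")
        rows.append(
            {
                "element": el,
                "direction": dr,
                "strength_pct": pct,
                "n_opposing_pairs": n_opp,
                "override_frac": frac,
                "is_gatekeeper": bool(
                    n_opp > 0
                    and pd.notna(pct)
                    and abs(pct) >= min_strength_pct
                    and frac >= min_override_frac
                ),
            }
        )
    return pd.DataFrame(rows)
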