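"""Ground-truth simulators for every stage of the dual-perturbation pipeline.

The generators plant known effects so the analysis stages can be tested
end-to-end without external data:

* :func:`simulate_perturbseq` — negative-binomial single-cell counts with
  per-genotype planted log2 fold changes (additive / synergy / buffer doubles),
  log-normal library-size variation, batch factors, and a guide-capture
  matrix with ambient background reads.
* :func:`simulate_sort_screen` — multinomial read counts per FACS population
  for a pool of guide pairs, driven by a latent-expression model
  ``x = sum(beta) + epsilon + N(0,1)`` with a hard sorting gate.
* :func:`simulate_signal_tracks` — piecewise-constant bedGraph tracks with
  planted bound/unbound regulatory elements.
* :func:`simulate_guide_dropout` — degrades a guide-count matrix with
  controlled detection false-negative / false-positive rates.

Child seeds are derived from the master seed by fixed arithmetic
(``child_k = (seed * 1_000_003 + k) mod 2**31``), so adding a replicate or
matrix does not perturb streams already drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PerturbTruth",
    "ScreenTruth",
    "SignalTruth",
    "GuideNoise",
    "make_guide_library",
    "build_screen_design",
    "example_perturb_truth",
    "example_screen_truth",
    "example_signal_layout",
    "simulate_perturbseq",
    "simulate_sort_screen",
    "simulate_signal_tracks",
    "simulate_guide_dropout",
    "child_seed",
]

GENOTYPE_SEP = "|"


def child_seed(seed: int, k: int) -> int:
    """Deterministic child seed ``(seed * 1_000_003 + k) mod 2**31``."""
    return (int(seed) * 1_000_003 + int(k)) % (2**31)


# ---------------------------------------------------------------------------
# guide library


def make_guide_library(
    elements: Sequence[str],
    guides_per_element: int = 1,
    n_ntc: int = 4,
    scaffolds: tuple[str, str] = ("Sp", "Sa"),
) -> pd.DataFrame:
    """Build a guide registry: one row per guide.

    Each targeting element gets ``guides_per_element`` guides per direction;
    CRISPRa guides ride one dCas9 scaffold species and CRISPRi guides the
    other (orthogonal recruitment), NTCs exist for both.

    Columns: guide, element, direction ('a'/'i'/'ntc'), scaffold, is_ntc.
    """
    rows = []
    for element in elements:
        for direction, scaffold in zip(("a", "i"), scaffolds):
            for g in range(1, guides_per_element + 1):
                rows.append(
                    {
                        "guide": f"{element}.{direction}{g}",
                        "element": element,
                        "direction": direction,
                        "scaffold": scaffold,
                        "is_ntc": False,
                    }
                )
    for j in range(1, n_ntc + 1):
        scaffold = scaffolds[(j - 1) % 2]
        rows.append(
            {
                "guide": f"NTC.{j}",
                "element": "NTC",
                "direction": "ntc",
                "scaffold": scaffold,
                "is_ntc": True,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# perturb-seq


@dataclass
class GuideNoise:
    """Guide-capture noise model.

    depth: mean total guide UMIs per cell (Poisson).
    ambient_frac: fraction of a cell's guide reads drawn from the ambient
        pool over all library guides (Dirichlet-multinomial). The real
        ambient level is not characterized; 2% is a stand-in default and a
        visible knob.
    split_alpha: Dirichlet concentration for splitting reads between the two
        true guides of a dual cassette (higher = more even).
    dirichlet_alpha: concentration of the ambient pool composition.
    """

    depth: float = 500.0
    ambient_frac: float = 0.02
    split_alpha: float = 10.0
    dirichlet_alpha: float = 1.0


@dataclass
class PerturbTruth:
    """Planted truth for the perturb-seq simulator.

    gene_effects maps (genotype, gene) -> true log2 fold change vs baseline.
    Genotype strings are '|'-joined sorted guide ids (e.g. 'GATA1.a1|SPI1.i1').
    mode_labels carries the planted regulatory-mode label per gene for the
    double genotype. baseline_means / dispersion parameterize the negative
    binomial (variance = mu + mu^2 * dispersion). batch_effects are
    multiplicative factors on the mean.
    """

    genotypes: list[str]
    gene_effects: Mapping[tuple[str, str], float]
    baseline_means: pd.Series
    dispersion: float | pd.Series = 0.3
    mode_labels: Mapping[str, str] = field(default_factory=dict)
    batch_effects: Mapping[str, float] = field(default_factory=lambda: {"b1": 1.0})
    library: pd.DataFrame | None = None
    libsize_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.baseline_means <= 0).any():
            raise ValueError("all baseline means must be > 0")
        disp = (
            self.dispersion
            if np.isscalar(self.dispersion)
            else np.asarray(self.dispersion)
        )
        if np.any(np.asarray(disp) <= 0):
            raise ValueError("dispersion must be > 0")
        for geno, gene in self.gene_effects:
            if geno not in self.genotypes:
                raise ValueError(f"unknown genotype in gene_effects: {geno!r}")
            if gene not in self.baseline_means.index:
                raise ValueError(f"unknown gene in gene_effects: {gene!r}")
        if self.library is not None:
            known = set(self.library["guide"])
            for geno in self.genotypes:
                for g in geno.split(GENOTYPE_SEP):
                    if g not in known:
                        raise ValueError(
                            f"genotype {geno!r} references guide {g!r} "
                            "absent from the library"
                        )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    # NB with variance mu + mu^2 * disp: shape n = 1/disp, p = n/(n+mu)
    n = 1.0 / disp
    p = n / (n + mu)
    return rng.negative_binomial(np.broadcast_to(n, mu.shape), p)


def simulate_perturbseq(
    truth: PerturbTruth,
    n_cells_per_genotype: int,
    guide_noise: GuideNoise | None = None,
) -> tuple[ad.AnnData, ad.AnnData, pd.DataFrame, PerturbTruth]:
    """Simulate expression and guide-capture count matrices.

    Returns (expression AnnData, guide-counts AnnData, cell metadata, truth).
    Expression counts are negative binomial with mean
    ``baseline * 2**lfc * batch_factor * size_factor``; guide counts hold the
    cell's true guides at high abundance plus ambient reads on all guides.
    """
    if n_cells_per_genotype < 1:
        raise ValueError("n_cells_per_genotype must be >= 1")
    noise = guide_noise or GuideNoise()
    if noise.depth <= 0:
        raise ValueError("guide capture depth must be positive")
    genes = truth.baseline_means.index.to_numpy()
    disp = (
        np.full(len(genes), float(truth.dispersion))
        if np.isscalar(truth.dispersion)
        else np.asarray(truth.dispersion, dtype=float)
    )
    if truth.library is not None:
        lib_guides = truth.library["guide"].to_numpy()
    else:
        lib_guides = np.array(
            sorted({g for geno in truth.genotypes for g in geno.split(GENOTYPE_SEP)})
        )
    guide_index = {g: j for j, g in enumerate(lib_guides)}
    batches = list(truth.batch_effects)

    expr_blocks, guide_blocks, meta_rows = [], [], []
    for k, geno in enumerate(truth.genotypes):
        rng = np.random.default_rng(child_seed(truth.seed, k))
        lfc = np.zeros(len(genes))
        for j, gene in enumerate(genes):
            lfc[j] = truth.gene_effects.get((geno, gene), 0.0)
        guides = geno.split(GENOTYPE_SEP)
        capture = "double" if len(guides) == 2 else "single"
        batch_labels = [batches[c % len(batches)] for c in range(n_cells_per_genotype)]
        bfac = np.array([truth.batch_effects[b] for b in batch_labels])
        size = np.exp(rng.normal(0.0, truth.libsize_sd, n_cells_per_genotype))
        mu = (
            truth.baseline_means.to_numpy()[None, :]
            * 2.0 ** lfc[None, :]
            * (bfac * size)[:, None]
        )
        expr_blocks.append(_nb_draw(rng, mu, disp[None, :]))

        # guide matrix: true guides split Dirichlet, ambient over all guides
        gcounts = np.zeros((n_cells_per_genotype, len(lib_guides)), dtype=np.int64)
        totals = rng.poisson(noise.depth, n_cells_per_genotype) + 1
        n_ambient = rng.binomial(totals, noise.ambient_frac)
        for c in range(n_cells_per_genotype):
            n_true = totals[c] - n_ambient[c]
            if len(guides) == 2:
                frac = rng.dirichlet([noise.split_alpha] * 2)
                split = rng.multinomial(n_true, frac)
            else:
                split = np.array([n_true])
            for g, cnt in zip(guides, split):
                gcounts[c, guide_index[g]] += cnt
            if n_ambient[c] > 0:
                w = rng.dirichlet([noise.dirichlet_alpha] * len(lib_guides))
                gcounts[c] += rng.multinomial(n_ambient[c], w)
        guide_blocks.append(gcounts)

        for c in range(n_cells_per_genotype):
            meta_rows.append(
                {
                    "cell_id": f"cell_{k}_{c}",
                    "genotype": geno,
                    "batch": batch_labels[c],
                    "capture": capture,
                    "capture_multiplicity": len(guides),
                }
            )

    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    adata = ad.AnnData(
        X=np.vstack(expr_blocks), obs=meta.copy(), var=pd.DataFrame(index=genes)
    )
    gdata = ad.AnnData(
        X=np.vstack(guide_blocks),
        obs=meta.copy(),
        var=pd.DataFrame(index=lib_guides),
    )
    return adata, gdata, meta, truth


# ---------------------------------------------------------------------------
# sort screen


@dataclass
class ScreenTruth:
    """Planted truth for the FACS sort-screen simulator.

    pairs: design table with columns guide1, guide2, element1, direction1,
        element2, direction2, is_ntc. Singles carry an NTC partner.
    element_effects: (element, direction) -> latent sort effect beta in
        z-units of the latent expression; NTC implicitly 0.
    interaction_effects: frozenset({(e1,d1),(e2,d2)}) -> epsilon, default 0.
    sort_threshold: latent cutoff of the positive gate.
    read_depth: per-population sequencing depth.
    """

    pairs: pd.DataFrame
    element_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    interaction_effects: Mapping[frozenset, float] = field(default_factory=dict)
    sort_threshold: float = 1.0
    pool_fractions: np.ndarray | None = None
    read_depth: Mapping[str, int] = field(
        default_factory=lambda: {"POS": 1_000_000, "NEG": 1_000_000}
    )
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pairs) == 0:
            raise ValueError("empty guide-pair pool")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any(d <= 0 for d in self.read_depth.values()):
            raise ValueError("read_depth must be positive")
        for (el, dr) in self.element_effects:
            hit = (
                ((self.pairs["element1"] == el) & (self.pairs["direction1"] == dr))
                | ((self.pairs["element2"] == el) & (self.pairs["direction2"] == dr))
            )
            if not hit.any():
                raise ValueError(f"element effect ({el},{dr}) not in the pair pool")
        if self.pool_fractions is not None:
            f = np.asarray(self.pool_fractions, dtype=float)
            if len(f) != len(self.pairs) or not np.isclose(f.sum(), 1.0):
                raise ValueError("pool_fractions must sum to 1 over the pool")


def build_screen_design(
    n_elements: int = 13,
    n_ntc_pairs: int = 18,
    tss_name: str = "TSS",
) -> pd.DataFrame:
    """Standard pool layout: promoter + enhancers, a/i singles, all
    bidirectional a x i doubles across distinct elements, plus NTC|NTC pairs.

    With 13 elements and 18 NTC pairs this yields 26 + 156 + 18 = 200 pairs.
    """
    elements = [tss_name] + [f"E{j}" for j in range(1, n_elements)]
    rows = []
    for el in elements:
        for dr in ("a", "i"):
            rows.append(
                {
                    "guide1": f"{el}.{dr}",
                    "guide2": "NTC",
                    "element1": el,
                    "direction1": dr,
                    "element2": "NTC",
                    "direction2": "ntc",
                    "is_ntc": False,
                    "pair_type": "single",
                }
            )
    for el1 in elements:
        for el2 in elements:
            if el1 == el2:
                continue
            rows.append(
                {
                    "guide1": f"{el1}.a",
                    "guide2": f"{el2}.i",
                    "element1": el1,
                    "direction1": "a",
                    "element2": el2,
                    "direction2": "i",
                    "is_ntc": False,
                    "pair_type": "double",
                }
            )
    for j in range(1, n_ntc_pairs + 1):
        rows.append(
            {
                "guide1": f"NTC.{j}",
                "guide2": "NTC",
                "element1": "NTC",
                "direction1": "ntc",
                "element2": "NTC",
                "direction2": "ntc",
                "is_ntc": True,
                "pair_type": "ntc",
            }
        )
    df = pd.DataFrame(rows)
    df["pair_id"] = df["guide1"] + GENOTYPE_SEP + df["guide2"]
    return df


def latent_means(truth: ScreenTruth) -> np.ndarray:
    """Expected latent expression per pair: sum of betas plus epsilon."""
    beta = truth.element_effects
    eps = truth.interaction_effects
    mus = np.zeros(len(truth.pairs))
    for i, row in enumerate(truth.pairs.itertuples(index=False)):
        mu = beta.get((row.element1, row.direction1), 0.0)
        mu += beta.get((row.element2, row.direction2), 0.0)
        mu += eps.get(
            frozenset(
                {(row.element1, row.direction1), (row.element2, row.direction2)}
            ),
            0.0,
        )
        mus[i] = mu
    return mus


def simulate_sort_screen(truth: ScreenTruth) -> tuple[pd.DataFrame, ScreenTruth]:
    """Simulate raw read counts per guide pair x population x replicate.

    The positive-gate probability of a pair is ``P(x > threshold)`` for
    ``x ~ N(sum(beta) + epsilon, 1)``; population counts are multinomial over
    pairs with probabilities proportional to pool_fraction x gate probability
    (POS) or pool_fraction x (1 - gate probability) (NEG). An 'UN' population,
    if given a depth, samples the unsorted pool directly.
    """
    mus = latent_means(truth)
    q_pos = stats.norm.sf(truth.sort_threshold - mus)
    frac = (
        np.full(len(truth.pairs), 1.0 / len(truth.pairs))
        if truth.pool_fractions is None
        else np.asarray(truth.pool_fractions, dtype=float)
    )
    records = []
    for r in range(1, truth.n_replicates + 1):
        rng = np.random.default_rng(child_seed(truth.seed, r))
        for pop, depth in truth.read_depth.items():
            if pop == "POS" or pop == "DP":
                w = frac * q_pos
            elif pop == "NEG":
                w = frac * (1.0 - q_pos)
            else:  # unsorted
                w = frac.copy()
            if w.sum() <= 0:
                raise ValueError(f"population {pop!r} has zero sampling mass")
            counts = rng.multinomial(int(depth), w / w.sum())
            block = truth.pairs[
                [
                    "pair_id",
                    "guide1",
                    "guide2",
                    "element1",
                    "direction1",
                    "element2",
                    "direction2",
                    "is_ntc",
                    "pair_type",
                ]
            ].copy()
            block["population"] = pop
            block["replicate"] = r
            block["reads"] = counts
            records.append(block)
    return pd.concat(records, ignore_index=True), truth


# ---------------------------------------------------------------------------
# signal tracks


@dataclass
class SignalTruth:
    """Planted TF occupancy for signal-track simulation.

    bound_elements: set of (factor, element_name) pairs that carry signal.
    bound_level / unbound_level: fold-change-over-control track values.
    """

    bound_elements: set
    bound_level: float = 40.0
    unbound_level: float = 0.5
    track_bin_size: int = 50
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bound_level <= self.unbound_level:
            raise ValueError("bound level must exceed unbound level")
        if self.track_bin_size <= 0:
            raise ValueError("track bin size must be positive")


def simulate_signal_tracks(
    truth: SignalTruth, elements: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Build a bedGraph-style track per factor over the element layout.

    Track value inside a bound element is ``bound_level`` (+ optional
    Gaussian noise per bin, clipped at 0); everywhere else it is
    ``unbound_level``. Tracks tile each chromosome from 0 to the last
    element end plus one bin.
    """
    factors = sorted({f for f, _ in truth.bound_elements}) or []
    tracks: dict[str, pd.DataFrame] = {}
    rng = np.random.default_rng(child_seed(truth.seed, 0))
    for factor in factors:
        rows = []
        if len(elements) == 0:
            tracks[factor] = pd.DataFrame(columns=["chrom", "start", "end", "value"])
            continue
        for chrom, sub in elements.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            cursor = 0
            chrom_end = int(sub["end"].max()) + truth.track_bin_size
            for row in sub.itertuples(index=False):
                start, end = int(row.start), int(row.end)
                if start > cursor:
                    rows.append((chrom, cursor, start, truth.unbound_level))
                level = (
                    truth.bound_level
                    if (factor, row.name) in truth.bound_elements
                    else truth.unbound_level
                )
                for b0 in range(start, end, truth.track_bin_size):
                    b1 = min(b0 + truth.track_bin_size, end)
                    v = level
                    if truth.noise_sd > 0:
                        v = max(0.0, v + rng.normal(0.0, truth.noise_sd))
                    rows.append((chrom, b0, b1, v))
                cursor = end
            rows.append((chrom, cursor, chrom_end, truth.unbound_level))
        tracks[factor] = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return tracks


# ---------------------------------------------------------------------------
# canonical planted-truth study conditions


def example_perturb_truth(
    seed: int = 0,
    n_background_genes: int = 80,
    n_per_mode: int = 5,
) -> PerturbTruth:
    """Perturb-seq truth with planted additive / synergy / buffer genes.

    Four genotypes: an NTC cell population, one activating single, one
    repressing single, and their bidirectional double. Per mode,
    ``n_per_mode`` downstream genes are planted at baseline mean 20 counts
    (well-detected targets):

    * additive — singles +0.8 / -0.6, double = their sum;
    * synergy  — singles +0.5 / +0.2, double 1.4 (difference +0.7);
    * buffer   — singles +1.0 / +1.0, double 0.9 (difference -1.1).

    Background genes draw log-normal baseline means around ~2 counts.
    """
    rng = np.random.default_rng(child_seed(seed, 997))
    genes = (
        [f"ADD{j}" for j in range(n_per_mode)]
        + [f"SYN{j}" for j in range(n_per_mode)]
        + [f"BUF{j}" for j in range(n_per_mode)]
        + [f"BG{j}" for j in range(n_background_genes)]
    )
    means = pd.Series(20.0, index=genes)
    means[[f"BG{j}" for j in range(n_background_genes)]] = np.exp(
        rng.normal(np.log(2.0), 1.0, n_background_genes)
    )
    library = make_guide_library(["GA", "GB"], guides_per_element=1, n_ntc=2)
    g_a, g_i, ntc = "GA.a1", "GB.i1", "NTC.1"
    double = GENOTYPE_SEP.join(sorted([g_a, g_i]))
    genotypes = [ntc, g_a, g_i, double]
    effects: dict[tuple[str, str], float] = {}
    modes: dict[str, str] = {}
    plan = {
        "ADD": (0.8, -0.6, None, "additive"),
        "SYN": (0.5, 0.2, 1.4, "synergy"),
        "BUF": (1.0, 1.0, 0.9, "buffer"),
    }
    for prefix, (ea, ei, ed, mode) in plan.items():
        for j in range(n_per_mode):
            gene = f"{prefix}{j}"
            effects[(g_a, gene)] = ea
            effects[(g_i, gene)] = ei
            effects[(double, gene)] = ed if ed is not None else ea + ei
            modes[gene] = mode
    return PerturbTruth(
        genotypes=genotypes,
        gene_effects=effects,
        baseline_means=means,
        mode_labels=modes,
        batch_effects={"b1": 1.0, "b2": 1.1},
        library=library,
        seed=seed,
    )


def example_screen_truth(
    seed: int = 0,
    n_elements: int = 13,
    n_ntc_pairs: int = 18,
    element_effects: Mapping[tuple[str, str], float] | None = None,
    interaction_effects: Mapping[frozenset, float] | None = None,
    n_replicates: int = 3,
    read_depth: int = 1_000_000,
) -> ScreenTruth:
    """Sort-screen truth over the standard 200-pair pool.

    With no effects supplied this is the null screen (all beta = epsilon =
    0) used for calibration; pass ``element_effects`` /
    ``interaction_effects`` to plant perturbations and interactions.
    """
    design = build_screen_design(n_elements=n_elements, n_ntc_pairs=n_ntc_pairs)
    return ScreenTruth(
        pairs=design,
        element_effects=dict(element_effects or {}),
        interaction_effects=dict(interaction_effects or {}),
        n_replicates=n_replicates,
        read_depth={"POS": read_depth, "NEG": read_depth},
        seed=seed,
    )


def example_signal_layout(
    n_genes: int = 8,
    elements_per_gene: int = 2,
    element_width: int = 400,
    gap: int = 600,
    chrom: str = "chr4",
) -> pd.DataFrame:
    """Non-overlapping element layout: per gene, a promoter plus enhancers.

    Returns a BED-like frame (chrom, start, end, name, gene, element_class).
    """
    rows = []
    pos = 1000
    for g in range(n_genes):
        gene = f"G{g}"
        for e in range(elements_per_gene):
            cls = "promoter" if e == 0 else "enhancer"
            name = f"{gene}_{cls}{e}"
            rows.append(
                {
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + element_width,
                    "name": name,
                    "gene": gene,
                    "element_class": cls,
                }
            )
            pos += element_width + gap
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# guide dropout


def simulate_guide_dropout(
    gdata: ad.AnnData,
    fnr_sim: float,
    fpr_sim: float,
    seed: int = 0,
    suppressed_fraction: float = 0.04,
    inflated_fraction: float = 0.30,
) -> ad.AnnData:
    """Degrade guide counts to emulate detection failure modes.

    In double-capture cells, with probability ``fnr_sim`` one of the two true
    guides is suppressed to ``suppressed_fraction`` of the cell's guide reads
    (below the 10% double-capture calling threshold). In single-capture
    cells, with probability ``fpr_sim`` a random second guide is inflated to
    ``inflated_fraction`` of reads (above the 20% single-capture threshold).
    Requires obs columns 'capture' and 'genotype'.
    """
    if not (0.0 <= fnr_sim <= 1.0 and 0.0 <= fpr_sim <= 1.0):
        raise ValueError("fnr_sim and fpr_sim must lie in [0, 1]")
    out = gdata.copy()
    x = np.asarray(out.X, dtype=np.int64).copy()
    rng = np.random.default_rng(seed)
    guide_index = {g: j for j, g in enumerate(out.var_names)}
    for c, (cap, geno) in enumerate(zip(out.obs["capture"], out.obs["genotype"])):
        guides = geno.split(GENOTYPE_SEP)
        total = x[c].sum()
        if total == 0:
            continue
        if cap == "double" and len(guides) == 2 and rng.random() < fnr_sim:
            victim = guide_index[guides[rng.integers(2)]]
            rest = total - x[c, victim]
            x[c, victim] = int(
                suppressed_fraction * rest / (1.0 - suppressed_fraction)
            )
        elif cap == "single" and rng.random() < fpr_sim:
            others = [j for g, j in guide_index.items() if g not in guides]
            if others:
                j = others[rng.integers(len(others))]
                x[c, j] = int(
                    np.ceil(inflated_fraction * total / (1.0 - inflated_fraction))
                )
    out.X = x
    return out
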