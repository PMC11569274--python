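"""End-to-end orchestration of the screen analysis stages.

Stages run in dependency order: simulate -> assign -> de -> modes ->
screen-score -> gi -> occupancy. Every output table carries a '#'-prefixed
header with the package version, master seed, and a hash of the effective
configuration, so a rerun with the same config is byte-identical for the
deterministic stages.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from . import __version__, io
from .config import RunConfig, config_hash, dump_config
from . import epigenome_signal as es
from . import guide_assignment as ga
from . import interaction_scores as gi_mod
from . import perturbseq_modes as pm
from . import screen_scoring as ss
from . import synthetic_data as sd

log = logging.getLogger("crisprai_screen")

STAGES = ["simulate", "assign", "de", "modes", "screen-score", "gi", "occupancy"]


class MissingArtifactError(FileNotFoundError):
    """A stage dependency was not produced by an earlier stage."""


def _header(cfg: RunConfig) -> str:
    return (
        f"crisprai-screen v{__version__}\n"
        f"seed: {cfg.seed}\n"
        f"config: {config_hash(cfg)}"
    )


def _need(path: str, stage: str) -> str:
    if not os.path.exists(path):
        raise MissingArtifactError(
            f"stage {stage!r} requires missing artifact {path!r}; "
            "run the producing stage first"
        )
    return path


def run_pipeline(cfg: RunConfig) -> str:
    """Run the configured stages; returns the artifact directory."""
    out = cfg.outdir
    os.makedirs(out, exist_ok=True)
    dump_config(cfg, os.path.join(out, "effective_config.yaml"))
    for stage in STAGES:
        if stage in cfg.stages:
            log.info("stage %s", stage)
            _RUNNERS[stage](cfg)
    return out


# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig) -> None:
    out = cfg.outdir
    truth = sd.example_perturb_truth(seed=cfg.seed)
    noise = sd.GuideNoise(depth=cfg.guide_depth, ambient_frac=cfg.ambient_frac)
    adata, gdata, meta, _ = sd.simulate_perturbseq(
        truth, cfg.n_cells_per_genotype, guide_noise=noise
    )
    io.write_mtx(adata, os.path.join(out, "expression_"))
    io.write_mtx(gdata, os.path.join(out, "guides_"))
    io.write_table(
        meta.reset_index(), os.path.join(out, "cells.tsv"), _header(cfg)
    )
    log.info("simulated %d cells x %d genes", *adata.shape)

    screen_truth = sd.example_screen_truth(
        seed=cfg.seed,
        n_elements=cfg.n_screen_elements,
        n_ntc_pairs=cfg.n_ntc_pairs,
        element_effects={("TSS", "a"): 1.5, ("TSS", "i"): -2.0, ("E4", "a"): 1.6},
        n_replicates=cfg.n_replicates,
        read_depth=cfg.read_depth,
    )
    counts, _ = sd.simulate_sort_screen(screen_truth)
    io.write_table(counts, os.path.join(out, "screen_counts.tsv"), _header(cfg))

    elements = sd.example_signal_layout()
    # bind a subset of elements (mix of promoters and enhancers) so the
    # occupancy stage has both bound and unbound genes to classify
    bound = {("FACTOR1", n) for n in elements["name"].iloc[::3]}
    tracks = sd.simulate_signal_tracks(
        sd.SignalTruth(bound_elements=bound, seed=cfg.seed), elements
    )
    io.write_bed6(elements, os.path.join(out, "elements.bed"))
    elements.to_csv(os.path.join(out, "elements.tsv"), sep="\t", index=False)
    for factor, track in tracks.items():
        io.write_bedgraph(track, os.path.join(out, f"track_{factor}.bedGraph"))
    with open(os.path.join(out, "signal_truth.tsv"), "w") as fh:
        fh.write("factor\telement\n")
        for factor, name in sorted(bound):
            fh.write(f"{factor}\t{name}\n")


def stage_assign(cfg: RunConfig) -> None:
    out = cfg.outdir
    prefix = os.path.join(out, "guides_")
    _need(prefix + "matrix.mtx", "assign")
    gdata = io.read_mtx(prefix)
    meta = io.read_table(_need(os.path.join(out, "cells.tsv"), "assign")).set_index(
        "cell_id"
    )
    counts = pd.DataFrame(
        np.asarray(gdata.X.todense() if hasattr(gdata.X, "todense") else gdata.X),
        index=gdata.obs_names,
        columns=gdata.var_names,
    )
    assigned = ga.assign_guides(
        counts,
        meta["capture_multiplicity"],
        fraction_single=cfg.fraction_single,
        fraction_double=cfg.fraction_double,
    )
    est = ga.estimate_misassignment(assigned, meta["capture_multiplicity"])
    log.info("estimated FNR %.3f FPR %.3f", est.fnr, est.fpr)
    table = assigned.drop(columns=["assigned_guides"]).reset_index()
    table["true_genotype"] = meta["genotype"].to_numpy()
    io.write_table(table, os.path.join(out, "assignment.tsv"), _header(cfg))


def _load_expression(cfg: RunConfig, stage: str):
    out = cfg.outdir
    prefix = os.path.join(out, "expression_")
    _need(prefix + "matrix.mtx", stage)
    adata = io.read_mtx(prefix)
    meta = io.read_table(_need(os.path.join(out, "cells.tsv"), stage)).set_index(
        "cell_id"
    )
    counts = pd.DataFrame(
        np.asarray(adata.X.todense() if hasattr(adata.X, "todense") else adata.X),
        index=adata.obs_names,
        columns=adata.var_names,
    )
    return counts, meta


def stage_de(cfg: RunConfig) -> None:
    out = cfg.outdir
    counts, meta = _load_expression(cfg, "de")
    norm = pm.log_normalize(counts, scale=cfg.norm_scale)
    genotypes = [g for g in meta["genotype"].unique()]
    ntc = [g for g in genotypes if g.startswith(cfg.ntc_label)]
    if not ntc:
        raise MissingArtifactError("no NTC genotype among simulated cells")
    ntc_cells = meta.index[meta["genotype"] == ntc[0]]
    for geno in genotypes:
        if geno == ntc[0]:
            continue
        cells = meta.index[meta["genotype"] == geno]
        if len(cells) < cfg.min_cells_per_genotype:
            log.info("skipping %s (n=%d < %d)", geno, len(cells),
                     cfg.min_cells_per_genotype)
            continue
        res = pm.de_test_lr(norm, cells, ntc_cells, batch=meta["batch"],
                            ridge=cfg.de_ridge)
        safe = geno.replace("|", "_")
        io.write_table(res, os.path.join(out, f"de_{safe}.tsv"), _header(cfg))


def stage_modes(cfg: RunConfig) -> None:
    out = cfg.outdir
    truth = sd.example_perturb_truth(seed=cfg.seed)
    single_a, single_i, double = truth.genotypes[1], truth.genotypes[2], truth.genotypes[3]
    tables = {}
    for geno in (single_a, single_i, double):
        path = os.path.join(out, f"de_{geno.replace('|', '_')}.tsv")
        tables[geno] = io.read_table(_need(path, "modes"))
    summary = pm.classify_modes(
        tables[single_a], tables[single_i], tables[double],
        thr_syn=cfg.thr_syn, thr_buf=cfg.thr_buf,
    )
    io.write_table(summary.records, os.path.join(out, "modes.tsv"), _header(cfg))
    props = summary.proportions.rename_axis("mode").reset_index(name="proportion")
    props["synergy_buffer_ratio"] = summary.synergy_buffer_ratio
    io.write_table(props, os.path.join(out, "mode_proportions.tsv"), _header(cfg))


def stage_screen_score(cfg: RunConfig) -> None:
    out = cfg.outdir
    counts = io.read_table(_need(os.path.join(out, "screen_counts.tsv"), "screen-score"))
    scored = ss.score_screen(
        counts,
        population=cfg.population,
        reference=cfg.reference_population,
        min_total=cfg.min_total_reads,
        pseudocount=cfg.cpm_pseudocount,
        exclude_guides=tuple(cfg.exclude_guides),
    )
    io.write_table(scored, os.path.join(out, "screen_scored.tsv"), _header(cfg))


def stage_gi(cfg: RunConfig) -> None:
    out = cfg.outdir
    scored = io.read_table(_need(os.path.join(out, "screen_scored.tsv"), "gi"))
    res = gi_mod.score_interactions(
        scored, k=cfg.gi_k, alpha=cfg.gi_alpha, require=cfg.gi_require
    )
    fits = pd.DataFrame([vars(f) for f in res["fits"]])
    io.write_table(fits, os.path.join(out, "gi_fits.tsv"), _header(cfg))
    wide = res["residuals"].copy()
    wide.columns = [f"residual_rep{r}" for r in wide.columns]
    for r in res["p_method2"].columns:
        wide[f"p_rep{r}"] = res["p_method2"][r]
    wide["hit_method1"] = res["method1_hits"]
    wide["hit_method2_all"] = res["method2_flags"].all(axis=1)
    wide["hit_consensus"] = res["consensus_hits"]
    io.write_table(
        wide.rename_axis("pair_id").reset_index(),
        os.path.join(out, "gi_hits.tsv"),
        _header(cfg),
    )
    gates = gi_mod.detect_gatekeepers(
        scored,
        tss_element=cfg.tss_element,
        min_strength_pct=cfg.min_strength_pct,
        min_override_frac=cfg.min_override_frac,
    )
    io.write_table(gates, os.path.join(out, "gatekeepers.tsv"), _header(cfg))
    log.info("%d consensus GI hits", int(res["consensus_hits"].sum()))


def stage_occupancy(cfg: RunConfig) -> None:
    out = cfg.outdir
    elements = io.read_table(_need(os.path.join(out, "elements.tsv"), "occupancy"))
    tracks = sorted(
        f for f in os.listdir(out) if f.startswith("track_") and f.endswith(".bedGraph")
    )
    if not tracks:
        raise MissingArtifactError("occupancy requires track_*.bedGraph from simulate")
    records = []
    for fname in tracks:
        factor = fname[len("track_"): -len(".bedGraph")]
        track = io.read_bedgraph(os.path.join(out, fname))
        sig = pd.DataFrame(
            {
                "gene": elements["gene"],
                "element": elements["name"],
                "mean_signal": [
                    es.aggregate_interval_signal(track, row.chrom, row.start, row.end)
                    for row in elements.itertuples(index=False)
                ],
            }
        )
        calls = es.classify_bound_genes(
            sig, threshold=cfg.bound_threshold, pseudocount=cfg.signal_pseudocount
        )
        calls.insert(0, "factor", factor)
        records.append(calls)
    io.write_table(
        pd.concat(records, ignore_index=True),
        os.path.join(out, "occupancy.tsv"),
        _header(cfg),
    )


_RUNNERS = {
    "simulate": stage_simulate,
    "assign": stage_assign,
    "de": stage_de,
    "modes": stage_modes,
    "screen-score": stage_screen_score,
    "gi": stage_gi,
    "occupancy": stage_occupancy,
}
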