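"""Run configuration: a flat YAML-backed schema with validated defaults.

Every numeric threshold used anywhere in the pipeline is named here, so a
run log can echo the full effective configuration and every default is
overridable from one file. Unknown keys are rejected (catches typos), and
values are type-checked against the schema.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "load_validate_config", "dump_config", "config_hash"]


@dataclass
class RunConfig:
    # global
    seed: int = 0
    outdir: str = "crisprai_run"
    stages: list = field(
        default_factory=lambda: [
            "simulate",
            "assign",
            "de",
            "modes",
            "screen-score",
            "gi",
            "occupancy",
        ]
    )
    ntc_label: str = "NTC"
    # populations
    population: str = "POS"
    reference_population: str = "NEG"
    # guide_assignment
    min_genes: int = 200
    max_genes: int = 6_900
    max_umis: int = 51_000
    max_pct_mito: float = 10.0
    min_guides_detected: int = 20
    min_guide_umis: int = 50
    fraction_single: float = 0.20
    fraction_double: float = 0.10
    min_cells_per_genotype: int = 20
    guide_scale: float = 100.0
    # perturbseq_modes
    norm_scale: float = 1e4
    de_ridge: float = 1e-6
    min_abs_lfc: float = 0.5
    max_padj: float = 0.05
    thr_syn: float = 0.1
    thr_buf: float = 0.7
    module_n_bins: int = 25
    module_n_controls: int = 100
    n_top_additive: int = 50
    n_random_genes: int = 300
    # screen_scoring
    min_total_reads: int = 300
    cpm_pseudocount: float = 1.0
    exclude_unsorted_in_filter: bool = False
    exclude_guides: list = field(default_factory=list)
    # interaction_scores
    gi_k: float = 1.0
    gi_alpha: float = 0.05
    gi_require: str = "all"
    min_strength_pct: float = 50.0
    min_override_frac: float = 0.5
    tss_element: str = "TSS"
    # epigenome_signal
    promoter_flank: int = 1000
    signal_pseudocount: float = 0.01
    bound_threshold: float = 5.0
    atac_pseudocount: float = 1e-4
    atac_scale: float = 1e6
    atac_chrom: str = "chr4"
    # synthetic_data
    n_cells_per_genotype: int = 200
    ambient_frac: float = 0.02
    guide_depth: float = 500.0
    libsize_sd: float = 0.3
    n_replicates: int = 3
    read_depth: int = 1_000_000
    sort_threshold: float = 1.0
    n_screen_elements: int = 13
    n_ntc_pairs: int = 18


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def _check_types(cfg: RunConfig) -> None:
    for name, f in _FIELDS.items():
        val = getattr(cfg, name)
        # field types arrive as strings under `from __future__ import annotations`
        tname = f.type if isinstance(f.type, str) else f.type.__name__
        ok = {
            "int": lambda v: isinstance(v, int) and not isinstance(v, bool),
            "float": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
            "str": lambda v: isinstance(v, str),
            "bool": lambda v: isinstance(v, bool),
            "list": lambda v: isinstance(v, list),
        }.get(tname)
        if ok is not None and not ok(val):
            raise TypeError(f"config key {name!r}: expected {tname}, got {val!r}")
    if cfg.thr_syn >= cfg.thr_buf:
        raise ValueError("thr_syn must be below thr_buf")
    if cfg.gi_require not in ("all", "any"):
        raise ValueError("gi_require must be 'all' or 'any'")


def load_validate_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Load YAML config, fill defaults, reject unknown keys, type-check.

    ``overrides`` (e.g. from CLI flags) are applied on top of the file.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        data = loaded or {}
        if not isinstance(data, dict):
            raise TypeError("config file must contain a mapping")
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(data) - set(_FIELDS)
    if unknown:
        raise KeyError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    cfg = RunConfig(**data)
    _check_types(cfg)
    return cfg


def dump_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the effective configuration."""
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
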