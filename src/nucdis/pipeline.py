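"""End-to-end pipeline wiring: simulate -> quantify -> metagene ->
classify -> model -> report, with a manifest for exact reruns.

Stage outputs are plain files under ``outdir`` so later stages can run in a
separate invocation; the synthetic path round-trips through the written
GFF3 / bedGraph / TSV files deliberately, exercising the same I/O code the
real-data path uses.  Output is byte-stable for a fixed config and seed
(no timestamps in any artifact).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, NucdisError
from .genesets import (
    dependence_summary,
    hypergeometric_overlap,
    kmeans_cluster,
    select_extreme_cluster,
    threshold_gene_set,
    write_gene_set,
)
from .metagene import (
    MetageneConfig,
    mean_profile,
    plot_profile,
    scale_regions_matrix,
    write_matrix_tsv,
    write_profile_tsv,
)
from .model import (
    DisassemblyObservables,
    default_grid,
    estimate_contribution,
    fun30_disassembly_levels,
    plot_contribution_curve,
)
from .occupancy import (
    GeneOccupancyTable,
    gene_level_occupancy,
    read_chrom_sizes,
    read_coverage_bedgraph,
    read_gene_annotation,
    read_gene_table,
    write_gene_table,
)
from .simulate import GeneratorConfig, generate_cohort, truth_summary, write_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "metagene", "classify", "model", "report")


@dataclass
class PipelineConfig:
    """Declarative run description; every block has config-file overrides."""

    outdir: Path = Path("nucdis_run")
    seed: int = 0
    mode: str = "synthetic"  # or "real"
    generator: dict = field(default_factory=dict)
    quantify: dict = field(default_factory=lambda: {"pseudocount": 0.01})
    metagene: dict = field(default_factory=dict)
    classify: dict = field(default_factory=lambda: {"k": 3, "n_init": 10})
    sets: dict = field(
        default_factory=lambda: {"column": "dpol_fft3", "cutoff": -0.1, "direction": "le"}
    )
    model: dict = field(
        default_factory=lambda: {"grid_step": 0.01, "flatness_tol": 1e-3}
    )
    # real-data inputs
    annotation_path: str | None = None
    annotation_format: str = "gff3"
    ip_track_path: str | None = None
    control_track_path: str | None = None
    chrom_sizes_path: str | None = None
    gene_table_path: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.outdir = Path(cfg.outdir)
        if cfg.mode not in ("synthetic", "real"):
            raise ConfigError(f"mode must be 'synthetic' or 'real', got {cfg.mode!r}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        return d

    def validate_inputs(self) -> None:
        if self.mode == "real":
            required = {
                "annotation_path": self.annotation_path,
                "gene_table_path": self.gene_table_path,
            }
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise ConfigError(f"real-data mode requires {missing}")
            for key in ("annotation_path", "ip_track_path", "control_track_path",
                        "chrom_sizes_path", "gene_table_path"):
                value = getattr(self, key)
                if value is not None and not Path(value).exists():
                    raise ConfigError(f"{key} does not exist: {value}")


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _manifest(config: PipelineConfig, stages: list[str]) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True)
    return {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "stages": stages,
        "nucdis_version": __version__,
    }


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the selected stages (default: all) and return the report.

    A stage failure aborts with the stage name; artifacts written by earlier
    stages remain on disk under ``config.outdir``.
    """
    stages = list(stages or STAGES)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    config.validate_inputs()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    _write_json(_manifest(config, stages), outdir / "manifest.json")

    report: dict = {"seed": config.seed, "mode": config.mode, "stages_run": stages}
    state: dict = {}
    for stage in stages:
        try:
            _STAGE_FN[stage](config, state, report)
        except NucdisError:
            raise
        except Exception as exc:  # annotate with the failing stage
            raise NucdisError(
                f"stage {stage!r} failed: {exc}; partial outputs in {outdir}"
            ) from exc
    _write_json(report, outdir / "report.json")
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, state: dict, report: dict) -> None:
    if config.mode != "synthetic":
        logger.info("simulate: skipped in real-data mode")
        return
    gen = GeneratorConfig(seed=config.seed, **config.generator)
    cohort = generate_cohort(gen)
    write_cohort(cohort, config.outdir)
    state["cohort"] = cohort
    report["generator"] = dataclasses.asdict(gen)
    report["truth_summary"] = truth_summary(cohort.truth)


def _load_annotation(config: PipelineConfig, state: dict) -> pd.DataFrame:
    if "annotation" not in state:
        if config.mode == "synthetic":
            path, fmt = config.outdir / "annotation.gff3", "gff3"
        else:
            path, fmt = Path(config.annotation_path), config.annotation_format
        state["annotation"] = read_gene_annotation(path, format=fmt)
    return state["annotation"]


def _load_tracks(config: PipelineConfig, state: dict) -> None:
    if "ip_track" in state:
        return
    if config.mode == "synthetic":
        sizes = read_chrom_sizes(config.outdir / "chrom.sizes")
        step = int(config.generator.get("track_bin_bp", 10))
        state["ip_track"] = read_coverage_bedgraph(
            config.outdir / "tracks" / "pol_wt.bedgraph", sizes, step
        )
        state["control_track"] = read_coverage_bedgraph(
            config.outdir / "tracks" / "control.bedgraph", sizes, step
        )
    else:
        if not (config.ip_track_path and config.control_track_path and config.chrom_sizes_path):
            raise ConfigError("real-data metagene/quantify stages need track paths")
        sizes = read_chrom_sizes(config.chrom_sizes_path)
        step = int(config.quantify.get("step_bp", 10))
        state["ip_track"] = read_coverage_bedgraph(config.ip_track_path, sizes, step)
        state["control_track"] = read_coverage_bedgraph(config.control_track_path, sizes, step)


def _stage_quantify(config: PipelineConfig, state: dict, report: dict) -> None:
    annotation = _load_annotation(config, state)
    _load_tracks(config, state)
    table, exclusions = gene_level_occupancy(
        state["ip_track"], state["control_track"], annotation,
        pseudocount=float(config.quantify.get("pseudocount", 0.01)),
        column="pol_occupancy",
    )
    write_gene_table(table, config.outdir / "occupancy.tsv")
    exclusions.to_csv(config.outdir / "occupancy_exclusions.tsv", sep="\t", index=False)
    state["occupancy"] = table
    report["quantify"] = {
        "n_genes": int(len(table.values)),
        "n_excluded": int(len(exclusions)),
    }


def _stage_metagene(config: PipelineConfig, state: dict, report: dict) -> None:
    annotation = _load_annotation(config, state)
    _load_tracks(config, state)
    mg = MetageneConfig(**config.metagene)
    matrix = scale_regions_matrix(state["ip_track"], annotation, mg)
    profile = mean_profile(matrix)
    write_matrix_tsv(matrix, config.outdir / "metagene_matrix.tsv")
    write_profile_tsv(profile, matrix, config.outdir / "metagene_profile.tsv")
    plot_profile(profile, matrix, config.outdir / "metagene_profile.png")
    state["metagene_matrix"] = matrix
    report["metagene"] = {
        "n_genes": int(matrix.values.shape[0]),
        "n_bins": int(matrix.values.shape[1]),
        "n_dropped": len(matrix.dropped),
    }


def _stage_classify(config: PipelineConfig, state: dict, report: dict) -> None:
    if "metagene_matrix" not in state:
        _stage_metagene(config, state, report)
    matrix = state["metagene_matrix"]
    k = int(config.classify.get("k", 3))
    clusters = kmeans_cluster(
        matrix.values.dropna(), k=k,
        seed=config.seed, n_init=int(config.classify.get("n_init", 10)),
    )
    high = select_extreme_cluster(clusters, "highest")
    write_gene_set(high, config.outdir / "high_occupancy_genes.txt")

    table = _gene_table(config, state)
    change_set = threshold_gene_set(
        table.column(config.sets["column"]),
        cutoff=float(config.sets["cutoff"]),
        direction=config.sets.get("direction", "le"),
    )
    write_gene_set(change_set, config.outdir / "threshold_genes.txt")
    overlap = hypergeometric_overlap(high, change_set)
    state["clusters"] = clusters
    report["classify"] = {
        "k": k,
        "cluster_sizes": {int(c): int(s) for c, s in clusters.cluster_sizes().items()},
        "degenerate": clusters.degenerate,
        "high_occupancy_set_size": len(high),
        "threshold_set": {
            "column": config.sets["column"],
            "cutoff": config.sets["cutoff"],
            "size": len(change_set),
        },
        "overlap": dataclasses.asdict(overlap),
    }


def _gene_table(config: PipelineConfig, state: dict) -> GeneOccupancyTable:
    if "gene_table" not in state:
        if config.mode == "synthetic":
            state["gene_table"] = read_gene_table(config.outdir / "gene_table.tsv")
        else:
            state["gene_table"] = read_gene_table(config.gene_table_path)
    return state["gene_table"]


def _stage_model(config: PipelineConfig, state: dict, report: dict) -> None:
    table = _gene_table(config, state)
    obs = DisassemblyObservables.from_table(table)
    grid = default_grid(float(config.model.get("grid_step", 0.01)))
    estimate = estimate_contribution(
        obs, grid=grid, flatness_tol=float(config.model.get("flatness_tol", 1e-3))
    )
    estimate.to_json(config.outdir / "contribution_estimate.json")
    levels = fun30_disassembly_levels(estimate)
    levels.rename_axis("gene_id").to_csv(config.outdir / "disassembly_levels.tsv", sep="\t")
    plot_contribution_curve(estimate, config.outdir / "contribution_curve.png")
    state["estimate"] = estimate
    state["levels"] = levels
    report["model"] = {
        "x_hat": estimate.x_hat,
        "r_max": estimate.r_max,
        "flatness": estimate.flatness,
        "identifiable": estimate.identifiable,
        "n_genes_used": estimate.n_genes_used,
    }


def _stage_report(config: PipelineConfig, state: dict, report: dict) -> None:
    if "estimate" not in state:
        _stage_model(config, state, report)
    table = _gene_table(config, state)
    levels: pd.Series = state["levels"]
    pol = table.column("pol_wt")
    correlations = {
        "h3_loss_vs_pol": dependence_summary(pol, table.column("dH3_fft3")),
        "disassembly_vs_pol": dependence_summary(pol, levels),
    }
    if "dpol_fft3" in table.values.columns:
        correlations["disassembly_vs_pol_change"] = dependence_summary(
            table.column("dpol_fft3"), levels
        )
    if "exchange" in table.values.columns:
        correlations["h3_loss_vs_exchange"] = dependence_summary(
            table.column("exchange"), table.column("dH3_fft3")
        )
    report["correlations"] = correlations
    if config.mode == "synthetic":
        report["note"] = (
            "synthetic cohort: noise scales and effect sizes are generator "
            "calibrations, not measured values"
        )


_STAGE_FN = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "metagene": _stage_metagene,
    "classify": _stage_classify,
    "model": _stage_model,
    "report": _stage_report,
}
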