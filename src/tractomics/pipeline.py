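"""Config-driven orchestration: simulate -> track -> map expression ->
network -> report.

A single master seed drives every stage through named substreams, so a
rerun with the same config is byte-identical.  Each stage writes its
outputs before the next starts; tasks that retain no streamline still
appear in the pathway table with zeros.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import expression as expr
from . import network as net
from .phantom import (
    PlantedEffect,
    SyntheticBundle,
    default_phantom_config,
    generate_bundle,
    write_bundle,
)
from .tracking import (
    PathwayResult,
    TrackingParams,
    enumerate_pathway_tasks,
    track_pathway,
)
logger = logging.getLogger("tractomics")

TARGET_STRUCTURES = (
    "amygdala",
    "caudate_nucleus",
    "globus_pallidus",
    "putamen",
    "thalamus",
    "nucleus_accumbens",
)


@dataclass
class PipelineConfig:
    """Everything one run needs; ``seed`` is the master seed."""

    seed: int = 0
    # synthetic-data stage
    n_samples: int = 200
    forced_per_tract: int = 12
    n_genes: int = 40
    probes_per_gene: int = 2
    noise_sd: float = 0.5
    # tracking stage
    seed_structure: str = "hippocampus"
    target_structures: tuple[str, ...] = TARGET_STRUCTURES
    step_size: float = 0.5
    curvature_deg: float = 80.0
    samples_per_voxel: int = 100
    max_steps: int = 2000
    min_fraction: float = 0.05
    mask_threshold: int = 1
    # expression stage
    sd_ddof: int = 0
    # network stage
    min_ppi_count: int = 10
    tier3_rule: str = "at_least"

    def tracking_params(self) -> TrackingParams:
        return TrackingParams(
            step_size=self.step_size,
            curvature_deg=self.curvature_deg,
            samples_per_voxel=self.samples_per_voxel,
            max_steps=self.max_steps,
            min_fraction=self.min_fraction,
            mask_threshold=self.mask_threshold,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "target_structures" in raw:
            raw["target_structures"] = tuple(raw["target_structures"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["target_structures"] = list(data["target_structures"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def validate_config(config: PipelineConfig) -> list[tuple[str, str]]:
    """Return (level, message) findings; empty means runnable."""
    findings: list[tuple[str, str]] = []

    def err(msg: str) -> None:
        findings.append(("error", msg))

    def warn(msg: str) -> None:
        findings.append(("warning", msg))

    if config.step_size <= 0:
        err("step_size must be positive")
    if not 0 < config.curvature_deg <= 180:
        err("curvature_deg must be in (0, 180]")
    elif config.curvature_deg >= 90:
        warn("curvature_deg >= 90 allows near-reversals within a step")
    if not 0 <= config.min_fraction <= 1:
        err("min_fraction must be in [0, 1]")
    if config.samples_per_voxel < 1:
        err("samples_per_voxel must be >= 1")
    if config.mask_threshold < 1:
        err("mask_threshold must be >= 1")
    if config.n_samples < 1:
        err("n_samples must be >= 1")
    if config.noise_sd < 0:
        err("noise_sd must be >= 0")
    if config.min_ppi_count < 0:
        err("min_ppi_count must be >= 0")
    if config.tier3_rule not in ("at_least", "exactly"):
        err("tier3_rule must be 'at_least' or 'exactly'")
    if config.sd_ddof not in (0, 1):
        err("sd_ddof must be 0 (population) or 1 (sample)")
    return findings


@dataclass
class ReportBundle:
    """Machine-readable outputs of one full run."""

    pathway_table: pd.DataFrame  # seed, target, n_voxels, n_samples, n_retained
    gene_count_table: pd.DataFrame  # gene, protein, n_ppi
    filtered_genes: list[str]
    pathway_gene_z: pd.DataFrame  # long: pathway, gene, average_z, n
    tier_table: pd.DataFrame  # protein, tier
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pathway_table.to_csv(
            outdir / "pathway_table.tsv", sep="\t", index=False
        )
        self.gene_count_table.to_csv(
            outdir / "gene_ppi_counts.tsv", sep="\t", index=False
        )
        pd.DataFrame({"gene": self.filtered_genes}).to_csv(
            outdir / "filtered_genes.tsv", sep="\t", index=False
        )
        self.pathway_gene_z.to_csv(
            outdir / "pathway_gene_z.tsv", sep="\t", index=False
        )
        self.tier_table.to_csv(outdir / "tier_table.tsv", sep="\t", index=False)
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=True)


def run_tracking(
    bundle: SyntheticBundle, config: PipelineConfig
) -> list[PathwayResult]:
    """Run every hemisphere-matched seed->target task on the bundle."""
    registry = bundle.phantom.labels.registry
    tasks = enumerate_pathway_tasks(
        registry, config.seed_structure, list(config.target_structures)
    )
    params = config.tracking_params()
    results = []
    for task_key, (seed_name, target_name) in enumerate(tasks):
        seed_label = registry.by_name(seed_name).label
        target_label = registry.by_name(target_name).label
        seed_voxels = bundle.phantom.labels.roi_voxels(seed_label)
        target_mask = bundle.phantom.labels.roi_mask(target_label)
        logger.info("tracking %s -> %s", seed_name, target_name)
        results.append(
            track_pathway(
                bundle.phantom.field,
                seed_voxels,
                target_mask,
                params,
                seed_name=seed_name,
                target_name=target_name,
                task_key=task_key,
            )
        )
    return results


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    planted: Sequence[PlantedEffect] | None = None,
) -> ReportBundle:
    """Execute the full chain on the default synthetic bundle."""
    findings = validate_config(config)
    errors = [m for lvl, m in findings if lvl == "error"]
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    warnings: dict[str, object] = {
        "config_warnings": [m for lvl, m in findings if lvl == "warning"]
    }

    logger.info("stage 1/4: synthetic bundle (seed %d)", config.seed)
    bundle = generate_bundle(
        seed=config.seed,
        n_samples=config.n_samples,
        forced_per_tract=config.forced_per_tract,
        n_genes=config.n_genes,
        probes_per_gene=config.probes_per_gene,
        noise_sd=config.noise_sd,
        planted=planted,
    )
    if outdir is not None:
        write_bundle(bundle, Path(outdir) / "bundle")

    logger.info("stage 2/4: tractography")
    results = run_tracking(bundle, config)

    logger.info("stage 3/4: expression mapping")
    z, stats = expr.probe_zscores(bundle.expression, ddof=config.sd_ddof)
    warnings["n_sigma_zero_probes"] = stats.attrs["n_sigma_zero"]
    gene_z = expr.gene_zscores(z, bundle.probe_gene, bundle.genes)
    affine = bundle.phantom.affine
    pathway_rows = []
    long_tables = []
    n_oob_total = 0
    for r in results:
        sel = expr.samples_in_pathway(bundle.samples, r.mask, affine)
        n_oob_total += sel.n_out_of_bounds
        pathway_rows.append(
            {
                "seed_region": r.seed_name,
                "target_region": r.target_name,
                "n_voxels": r.voxel_count,
                "n_samples": len(sel),
                "n_retained": r.retained,
            }
        )
        name = f"{r.seed_name}__{r.target_name}"
        long_tables.append(expr.pathway_average(gene_z, sel.sample_ids, name))
    pathway_table = pd.DataFrame(pathway_rows)
    nonempty_tables = [t for t in long_tables if len(t)]
    pathway_gene_z = (
        pd.concat(nonempty_tables, ignore_index=True)
        if nonempty_tables
        else expr.pathway_average(gene_z, [], "")
    )
    warnings["n_out_of_bounds_samples"] = n_oob_total

    logger.info("stage 4/4: interaction network")
    graph, report = net.build_graph(bundle.ppi_edges)
    warnings["n_self_loops"] = report.n_self_loops
    warnings["n_duplicate_edges"] = report.n_duplicates
    count_table, unmapped = net.interaction_counts(
        graph, bundle.disease_genes, bundle.gene_protein
    )
    warnings["unmapped_genes"] = unmapped
    filtered = net.filter_by_degree(count_table, config.min_ppi_count)
    related = net.seed_related_set(
        graph, bundle.seed_protein, set(bundle.tier_design.related)
    )
    tiers = net.classify_nodes(
        graph, bundle.seed_protein, related, tier3_rule=config.tier3_rule
    )
    tier_table = tiers.to_frame()

    manifest = {
        "config": {
            **asdict(config),
            "target_structures": list(config.target_structures),
        },
        "bundle": bundle.manifest,
        "warnings": warnings,
        "n_tasks": len(results),
        "n_nonempty_pathways": int(sum(r.retained > 0 for r in results)),
    }
    out = ReportBundle(
        pathway_table=pathway_table,
        gene_count_table=count_table,
        filtered_genes=filtered,
        pathway_gene_z=pathway_gene_z,
        tier_table=tier_table,
        manifest=manifest,
    )
    if outdir is not None:
        out.write(outdir)
    return out
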