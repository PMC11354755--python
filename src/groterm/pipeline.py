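"""Pipeline orchestration: stages, run configuration, artifact manifest.

Stages run in dependency order (filter -> rti -> diff; filter ->
metagene; rti -> heatmap). Every output TSV carries a comment header
recording the exact parameter values used, so any printed number is
auditable; the log records the filter funnel and per-stage gene counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import annotation as ann
from . import coverage as cov
from .filtering import FilterConfig, apply_filters
from .metagene import heatmap_matrix, metagene_profile, plot_heatmap, plot_metagene
from .readthrough import (
    compute_rti_table,
    differential_readthrough,
    differential_to_frame,
    rti_records_to_frame,
    summarize_rti,
    volcano_frame,
    write_summary_json,
)

logger = logging.getLogger(__name__)

STAGES = ("filter", "rti", "diff", "metagene", "heatmap")
_DEPS = {"rti": ("filter",), "diff": ("rti",), "metagene": ("filter",), "heatmap": ("rti",)}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    annotation: str
    sample_sheet: str
    chrom_sizes: str
    outdir: str
    input_dir: str = "."
    annotation_format: str | None = None
    polya_override: str | None = None
    wt_label: str = "WT"
    mut_label: str = "mut"
    # filters
    min_neighbor_distance_nt: int = 500
    min_length_nt: int = 500
    min_expression_reads_per_nt: float = 1.0
    min_replicates_passing: int = 3
    # RTI windows
    exclusion_nt: int = 50
    window_nt: int = 450
    # differential testing
    alpha: float = 0.05
    log2_fc_threshold: float = 1.0
    min_total_replicates: int = 5
    min_per_group: int = 2
    # metagene
    metagene_window_nt: int = 200
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            min_neighbor_distance_nt=self.min_neighbor_distance_nt,
            min_length_nt=self.min_length_nt,
            min_expression_reads_per_nt=self.min_expression_reads_per_nt,
            min_replicates_passing=self.min_replicates_passing,
        )


def _write_tsv(df: pd.DataFrame, path: Path, params: Mapping[str, object]) -> None:
    with open(path, "w") as fh:
        for key, value in params.items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(
    config: RunConfig, stages: Sequence[str] = STAGES
) -> dict[str, str]:
    """Run the requested stages; returns a manifest of output files.

    A requested stage whose dependency is neither requested nor already
    materialized raises a :class:`PipelineError` naming the stage to run
    first.
    """
    stages = list(stages)
    for s in stages:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}; choose from {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in stages:
        for dep in _DEPS.get(s, ()):
            if dep not in stages:
                raise PipelineError(
                    f"stage {s!r} requires stage {dep!r}; run {dep!r} first "
                    "or include it in the requested stages"
                )

    base = Path(config.input_dir)
    genes = ann.load_annotation(
        base / config.annotation,
        fmt=config.annotation_format,
        polya_override=(base / config.polya_override) if config.polya_override else None,
    )
    chrom_sizes = cov.load_chrom_sizes(base / config.chrom_sizes)
    sheet = cov.load_sample_sheet(base / config.sample_sheet)
    tracks = cov.load_tracks_from_sheet(sheet, chrom_sizes, base_dir=base)
    logger.info("loaded %d genes, %d tracks", len(genes), len(tracks))

    manifest: dict[str, str] = {}
    # record analysis parameters, not run-specific locations, so reruns on
    # identical inputs produce byte-identical numeric outputs
    params = {
        k: v for k, v in asdict(config).items() if k not in ("outdir", "input_dir")
    }

    distances = ann.neighbor_distances(genes)
    passed = genes
    if "filter" in stages:
        report = apply_filters(genes, distances, tracks, config.filter_config())
        logger.info("filter funnel: %s", report.funnel)
        _write_tsv(report.per_gene, outdir / "filter_per_gene.tsv", params)
        pd.DataFrame(
            {"filter": list(report.funnel), "surviving": list(report.funnel.values())}
        ).to_csv(outdir / "filter_funnel.tsv", sep="\t", index=False)
        gene_by_id = {g.gene_id: g for g in genes}
        passed = [gene_by_id[gid] for gid in report.passed_genes]
        ann.write_gene_table(
            passed,
            [d for d in distances if d.gene_id in set(report.passed_genes)],
            outdir / "analyzed_genes.tsv",
        )
        manifest.update(
            filter_per_gene="filter_per_gene.tsv",
            filter_funnel="filter_funnel.tsv",
            analyzed_genes="analyzed_genes.tsv",
        )

    rti_records = None
    if "rti" in stages:
        rti_records = compute_rti_table(
            tracks, passed, exclusion_nt=config.exclusion_nt, window_nt=config.window_nt
        )
        _write_tsv(rti_records_to_frame(rti_records), outdir / "rti_per_replicate.tsv", params)
        manifest["rti"] = "rti_per_replicate.tsv"
        logger.info("computed RTI for %d genes x %d samples", len(passed), len(tracks))

    diff_records = None
    if "diff" in stages:
        wt = [r for r in rti_records if r.genotype == config.wt_label]
        mut = [r for r in rti_records if r.genotype == config.mut_label]
        diff_records = differential_readthrough(
            wt, mut,
            alpha=config.alpha,
            log2_fc_threshold=config.log2_fc_threshold,
            min_total=config.min_total_replicates,
            min_per_group=config.min_per_group,
        )
        _write_tsv(differential_to_frame(diff_records), outdir / "differential.tsv", params)
        _write_tsv(volcano_frame(diff_records), outdir / "volcano.tsv", params)
        summary = summarize_rti(diff_records)
        write_summary_json(summary, outdir / "rti_summary.json")
        manifest.update(
            differential="differential.tsv",
            volcano="volcano.tsv",
            summary="rti_summary.json",
        )
        logger.info(
            "differential: %d genes, %.1f%% significant",
            summary.n_genes, 100 * summary.fraction_significant,
        )

    window = (-config.metagene_window_nt, config.metagene_window_nt)
    if "metagene" in stages:
        frames = []
        profiles = {}
        for label in (config.wt_label, config.mut_label):
            geno_tracks = [t for t in tracks if t.genotype == label]
            if not geno_tracks:
                continue
            prof = metagene_profile(geno_tracks, passed, window=window)
            profiles[label] = prof
            f = prof.to_frame()
            f.insert(0, "genotype", label)
            frames.append(f)
        _write_tsv(pd.concat(frames, ignore_index=True), outdir / "metagene.tsv", params)
        manifest["metagene"] = "metagene.tsv"
        if config.make_plots:
            plot_metagene(profiles, outdir / "metagene.png")
            manifest["metagene_plot"] = "metagene.png"

    if "heatmap" in stages:
        mut_rti: dict[str, list[float]] = {}
        for r in rti_records:
            if r.genotype == config.mut_label and r.rti is not None:
                mut_rti.setdefault(r.gene_id, []).append(r.rti)
        order_key = {gid: sum(v) / len(v) for gid, v in mut_rti.items()}
        matrices = heatmap_matrix(tracks, passed, order_key, window=window)
        for sample_id, mat in matrices.items():
            name = f"heatmap_{sample_id}.tsv"
            mat.to_csv(outdir / name, sep="\t")
            manifest[f"heatmap_{sample_id}"] = name
            if config.make_plots:
                plot_heatmap(mat, outdir / f"heatmap_{sample_id}.png")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["manifest"] = "manifest.json"
    return manifest
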