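"""End-to-end orchestration with a single config and a run manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    Z_CUTOFF,
    activation_z,
    differential_direction,
    fisher_right_tail,
    group_overlap_table,
    hit_count_matrix,
)
from .expression_filter import make_calls, select_analysis_genes
from .factor_clustering import (
    assign_temporal_groups,
    fit_factor_model,
    horn_parallel_analysis,
)
from .io_tables import (
    AgeDesign,
    read_expression_table,
    read_gene_annotation,
    read_gtf,
    read_regulator_network,
)
from .isoform_analysis import (
    classify_splice_event,
    filter_novel_isoforms,
    variant_usage_report,
)
from .regulator_modules import find_modules, summarize_modules
from .temporal_stats import age_summaries, type_profiles

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run.

    Optional inputs switch their stages off when absent.  The config is
    serialized into ``manifest.json`` next to the outputs so any run can
    be reproduced exactly.
    """

    expression_path: str
    out_dir: str
    transcript_expression_path: str | None = None
    annotation_path: str | None = None
    network_path: str | None = None
    novel_gtf_path: str | None = None
    reference_gtf_path: str | None = None
    ages: tuple[float, ...] | None = None
    replicates_per_age: int = 3
    theta_fpkm: float = 1.0
    min_replicates: int = 2
    alpha: float = 0.05
    n_factors: int | None = None          # None -> Horn's parallel analysis
    assignment_cutoff: float = 0.7
    horn_quantile: float = 0.95
    horn_n_sim: int = 200
    icc_cutoff: float = 0.6
    min_targets: int = 5
    z_cutoff: float = Z_CUTOFF
    n_perm: int = 999
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.expression_path).exists():
            raise ValueError(f"expression table not found: "
                             f"{self.expression_path}")
        if self.theta_fpkm < 0:
            raise ValueError("theta_fpkm must be >= 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.assignment_cutoff <= 1:
            raise ValueError("assignment cutoff must be in (0, 1]")
        if not 0 < self.icc_cutoff <= 1:
            raise ValueError("icc_cutoff must be in (0, 1]")
        if not 0.5 < self.horn_quantile < 1:
            raise ValueError("horn_quantile must be in (0.5, 1)")
        if self.min_targets < 1:
            raise ValueError("min_targets must be >= 1")
        if self.n_perm < 999:
            raise ValueError("n_perm must be >= 999")
        if self.z_cutoff <= 0:
            raise ValueError("z_cutoff must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        if "ages" in cfg and cfg["ages"] is not None:
            cfg["ages"] = tuple(cfg["ages"])
        return cls(**cfg)

    def design(self) -> AgeDesign:
        if self.ages is None:
            return AgeDesign.default()
        return AgeDesign(tuple(self.ages), self.replicates_per_age)


def _write(df: pd.DataFrame, out_dir: Path, name: str,
           manifest: dict) -> None:
    path = out_dir / name
    df.to_csv(path, sep="\t", float_format="%.10g")
    manifest["outputs"].append(name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute filter -> stats -> clustering -> enrichment -> modules ->
    isoforms, writing TSVs plus ``manifest.json``.

    Returns a dict of the in-memory results per stage.  The first hard
    error aborts the run with the stage name attached.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = config.design()
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "outputs": [],
    }
    results: dict = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("filter")
        matrix = read_expression_table(config.expression_path, design)
        calls = make_calls(matrix, config.theta_fpkm, config.min_replicates,
                           config.alpha)
        analysis_genes = select_analysis_genes(calls)
        _write(calls.to_frame(design.ages), out_dir, "calls.tsv", manifest)
        manifest["n_analysis_genes"] = len(analysis_genes)
        results["calls"] = calls
        results["analysis_genes"] = analysis_genes
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("filter", exc) from exc

    try:
        stage("temporal_stats")
        summaries = age_summaries(matrix, calls, restrict="analysis")
        _write(summaries, out_dir, "age_summaries.tsv", manifest)
        results["age_summaries"] = summaries
        if config.annotation_path:
            annotation = read_gene_annotation(config.annotation_path)
            profiles = type_profiles(matrix.subset(analysis_genes),
                                     annotation)
            _write(profiles, out_dir, "type_profiles.tsv", manifest)
            results["type_profiles"] = profiles
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("temporal_stats", exc) from exc

    try:
        stage("factor_clustering")
        sub = matrix.subset(analysis_genes)
        from .factor_clustering import standardize_series
        std = standardize_series(sub.log2_age_means())
        usable = ~np.isnan(std).any(axis=1)
        if config.n_factors is None:
            k, _, _ = horn_parallel_analysis(
                std[usable], n_sim=config.horn_n_sim,
                quantile=config.horn_quantile, seed=config.seed)
            k = max(k, 1)
        else:
            k = config.n_factors
        model = fit_factor_model(std[usable], k, ages=design.ages)
        assignment = assign_temporal_groups(
            sub, model, cutoff=config.assignment_cutoff)
        _write(model.to_frame(), out_dir, "loadings.tsv", manifest)
        _write(assignment.table, out_dir, "assignments.tsv", manifest)
        manifest["n_factors"] = k
        manifest["n_assigned"] = assignment.n_assigned
        results["model"] = model
        results["assignment"] = assignment
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("factor_clustering", exc) from exc

    network = None
    if config.network_path:
        try:
            stage("enrichment")
            network = read_regulator_network(config.network_path)
            hits = hit_count_matrix(network, assignment)
            _write(hits, out_dir, "hit_counts.tsv", manifest)
            universe = set(network.regulators)
            groups = sorted(set(assignment.labels) - {"unassigned"})
            group_sets: dict[str, set[str]] = {}
            for g in groups:
                genes = set(assignment.genes_in_group(g))
                regs = set()
                for reg in universe:
                    res = fisher_right_tail(
                        genes & set(matrix.feature_ids),
                        network.targets_of(reg) & set(matrix.feature_ids),
                        set(matrix.feature_ids), term_id=reg)
                    if res.significant_association:
                        regs.add(reg)
                group_sets[g] = regs
            overlaps = group_overlap_table(group_sets, len(universe))
            _write(overlaps, out_dir, "group_overlaps.tsv", manifest)
            directions = differential_direction(matrix)
            dir_of = {g: directions[i]
                      for i, g in enumerate(matrix.feature_ids)}
            zrows = []
            for reg in sorted(universe):
                expected = {t: network.direction(reg, t)
                            for t in network.targets_of(reg)}
                for j, age in enumerate(design.ages):
                    observed = {t: int(dir_of[t][j]) for t in expected
                                if t in dir_of and dir_of[t][j] != 0}
                    known = {t: d for t, d in expected.items()
                             if d != 0 and t in observed}
                    if not known:
                        continue
                    z = activation_z(observed, known)
                    zrows.append({"regulator": reg, "age": age, "z": z,
                                  "significant": abs(z) >= config.z_cutoff})
            zdf = pd.DataFrame(zrows)
            if not zdf.empty:
                zdf = zdf.set_index(["regulator", "age"])
            _write(zdf, out_dir, "activation_z.tsv", manifest)
            results["hit_counts"] = hits
            results["group_regulators"] = group_sets
            results["group_overlaps"] = overlaps
            results["activation_z"] = zdf
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("enrichment", exc) from exc

        try:
            stage("regulator_modules")
            module_frames = []
            for g in groups:
                genes = set(assignment.genes_in_group(g))
                if not genes:
                    continue
                mods = find_modules(network, matrix, genes,
                                    icc_cutoff=config.icc_cutoff,
                                    min_targets=config.min_targets)
                if mods:
                    frame = summarize_modules(mods)
                    frame.insert(0, "group", g)
                    module_frames.append(frame)
            modules_df = (pd.concat(module_frames, ignore_index=True)
                          if module_frames else
                          pd.DataFrame(columns=["group", "regulators",
                                                "size", "n_targets", "icc",
                                                "sign"]))
            _write(modules_df.set_index(
                modules_df.index.rename("module")), out_dir,
                "modules.tsv", manifest)
            results["modules"] = modules_df
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("regulator_modules", exc) from exc

    if config.transcript_expression_path:
        try:
            stage("isoforms")
            tmatrix = read_expression_table(
                config.transcript_expression_path, design,
                feature_level="transcript")
            tcalls = make_calls(tmatrix, config.theta_fpkm,
                                config.min_replicates, config.alpha)
            gene_of: dict[str, str] = {}
            ref_models = []
            novel_models = []
            if config.reference_gtf_path:
                ref_models = read_gtf(config.reference_gtf_path)
                gene_of.update({m.transcript_id: m.gene_id
                                for m in ref_models})
            if config.novel_gtf_path:
                novel_models = read_gtf(config.novel_gtf_path)
                gene_of.update({m.transcript_id: m.gene_id
                                for m in novel_models})
            usage = variant_usage_report(tmatrix, gene_of)
            _write(usage, out_dir, "variant_usage.tsv", manifest)
            records = filter_novel_isoforms(
                tmatrix, tcalls, gene_of, alpha=config.alpha,
                n_perm=config.n_perm, seed=config.seed)
            iso_df = pd.DataFrame([{
                "transcript_id": r.transcript_id, "gene_id": r.gene_id,
                "dw": r.dw, "p_dw": r.p_dw, "q_dw": r.q_dw,
                "passes_filter": r.passes_filter,
            } for r in records]).set_index("transcript_id")
            _write(iso_df, out_dir, "novel_isoforms.tsv", manifest)
            events_rows = []
            by_gene: dict[str, list] = {}
            for m in ref_models:
                by_gene.setdefault(m.gene_id, []).append(m)
            for m in novel_models:
                evs = classify_splice_event(m, by_gene.get(m.gene_id, []))
                for ev in evs:
                    events_rows.append({
                        "transcript_id": m.transcript_id,
                        "gene_id": m.gene_id,
                        "event_type": ev.event_type,
                        "coordinates": ";".join(
                            f"{s}-{e}" for s, e in ev.coordinates),
                        "reference_id": ev.reference_id,
                    })
            events_df = pd.DataFrame(
                events_rows, columns=["transcript_id", "gene_id",
                                      "event_type", "coordinates",
                                      "reference_id"])
            _write(events_df.set_index("transcript_id"), out_dir,
                   "splice_events.tsv", manifest)
            results["variant_usage"] = usage
            results["isoform_records"] = records
            results["splice_events"] = events_df
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("isoforms", exc) from exc

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    return results
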