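"""End-to-end pipeline: simulate → harmonize → similarity → cluster/FGA/3p →
concordance tiers → expression classification → aggressiveness comparison.

The pipeline is configured by :class:`PipelineConfig` (loadable from YAML),
runs fully from a single seed, writes every stage's tables as TSV plus a
machine-readable ``summary.json``, and is byte-reproducible for a fixed
config and seed (timestamps excluded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggressiveness import compare_groups, split_by_coclustering, split_by_quartile
from .errors import InvalidArgumentError
from .genome import KIDNEY_PANEL
from .harmonize import (GeneMatrix, discretize_gistic, filter_mutations,
                        segments_to_genes, write_gct, write_seg)
from .similarity import (binarize_mutations, jaccard_matrix,
                         matched_vs_unmatched, profile_correlation)
from .subtyping import (arm_loss_report, assign_cell_line_subtype,
                        cluster_profiles, cut_and_summarize,
                        fraction_genome_altered, linkage_to_newick)
from .synthetic import (balanced_diploid_scenario, default_archetypes,
                        make_default_genome, masked_loss_scenario,
                        ploidy_relative_scenario, simulate_allele_specific,
                        simulate_clinical, simulate_cna_cohort,
                        simulate_expression, simulate_two_source_views)
from .tiers import build_tier_calls, reliability_report
from .expression import (calls_to_frame, classify_margin, combat_adjust,
                         train_nsc)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All free parameters of the pipeline; defaults are the analysis defaults."""

    seed: int = 0
    out_dir: str = "renalmatch_out"
    # synthetic cohort sizes
    n_per_group: int = 100
    n_cell_lines_per_group: int = 10
    segment_noise_sd: float = 0.1
    # thresholds
    fga_threshold: float = 0.2
    loss_threshold: float = -0.2
    cut_height: float = 0.9
    lost_cutoff: float = 0.8
    margin: float = 0.05
    min_depth: int = 15
    min_vaf: float = 0.15
    shallow_thresh: float = 0.2
    deep_thresh: float = 1.0
    min_tumours: int = 5
    # two-source discrepancy injection
    drop_rate: float = 0.05
    alter_rate: float = 0.05
    extent_shift_rate: float = 0.05
    # expression stage
    expr_n_per_class: int = 100
    expr_n_intermediate: int = 20
    expr_effect_size: float = 2.0
    expr_n_markers: int = 200
    expr_noise_sd: float = 0.5
    expr_batch_shift: float = 1.0
    expr_batch_scale: float = 1.0
    nsc_folds: int = 10
    # clinical link
    stage_logit_slope: float = 8.0
    grade_logit_slope: float = 8.0
    gene_panel: list[str] = field(default_factory=lambda: list(KIDNEY_PANEL))

    def validate(self) -> None:
        checks = [
            (self.fga_threshold > 0, "fga_threshold must be > 0"),
            (self.loss_threshold < 0, "loss_threshold must be < 0"),
            (0 <= self.cut_height, "cut_height must be >= 0"),
            (0 < self.lost_cutoff <= 1, "lost_cutoff must lie in (0, 1]"),
            (self.margin >= 0, "margin must be >= 0"),
            (self.min_depth >= 0, "min_depth must be >= 0"),
            (0 <= self.min_vaf <= 1, "min_vaf must lie in [0, 1]"),
            (0 < self.shallow_thresh < self.deep_thresh,
             "need 0 < shallow_thresh < deep_thresh"),
            (all(0 <= r <= 1 for r in
                 (self.drop_rate, self.alter_rate, self.extent_shift_rate)),
             "injection rates must lie in [0, 1]"),
            (self.n_per_group >= 1, "n_per_group must be >= 1"),
            (self.segment_noise_sd >= 0, "segment_noise_sd must be >= 0"),
            (bool(self.gene_panel), "gene_panel must be non-empty"),
        ]
        for ok, message in checks:
            if not ok:
                raise InvalidArgumentError(f"config: {message}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise InvalidArgumentError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic cohort and write the report bundle.

    Returns the summary dictionary that is also written to
    ``out_dir/summary.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed,
                     "parameters": asdict(config)}

    _stage("simulate")
    genome = make_default_genome(seed=config.seed)
    profiles, truth = simulate_cna_cohort(
        genome, default_archetypes(),
        n_per_group=config.n_per_group,
        n_cell_lines_per_group=config.n_cell_lines_per_group,
        segment_noise_sd=config.segment_noise_sd,
        seed=config.seed)
    write_seg(profiles, out / "cohort.seg")
    truth.to_json(out / "truth.json")

    _stage("harmonize")
    gene_matrix = segments_to_genes(profiles, genome)
    gistic = discretize_gistic(gene_matrix, config.shallow_thresh, config.deep_thresh)
    filtered, audit = filter_mutations(truth.mutation_records,
                                       config.min_depth, config.min_vaf)
    summary["mutation_filter_audit"] = dict(audit)

    _stage("two_source_views")
    views = simulate_two_source_views(
        filtered, gistic, drop=config.drop_rate, alter=config.alter_rate,
        extent_shift=config.extent_shift_rate, seed=config.seed)
    views.ledger.to_csv(out / "injection_ledger.tsv", sep="\t", index=False)

    _stage("similarity")
    cell_lines = truth.cell_line_ids
    universe = set(genome.genes["gene_id"])
    prof_a = binarize_mutations(views.mutations_a, universe)
    prof_b = binarize_mutations(views.mutations_b, universe)
    shared_cls = [c for c in cell_lines if c in prof_a and c in prof_b]
    jac = jaccard_matrix({c: prof_a[c] for c in shared_cls},
                         {c: prof_b[c] for c in shared_cls})
    jac.to_csv(out / "similarity_mutation_jaccard.tsv", sep="\t")
    cl_matrix_a = GeneMatrix(views.gistic_a.values[cell_lines], kind="gistic5")
    cl_matrix_b = GeneMatrix(views.gistic_b.values[cell_lines], kind="gistic5")
    cna_corr = profile_correlation(cl_matrix_a, cl_matrix_b, method="pearson")
    cna_corr.to_csv(out / "similarity_cna_pearson.tsv", sep="\t")
    matched = matched_vs_unmatched(cna_corr, [(c, c) for c in cell_lines])
    matched.to_csv(out / "matched_vs_unmatched.tsv", sep="\t", index=False)
    summary["similarity"] = {
        "fraction_matched_ranked_first": matched.attrs["fraction_ranked_first"],
        "median_matched_cna_correlation": float(matched["matched_similarity"].median()),
        "median_matched_jaccard": float(np.median([jac.at[c, c] for c in shared_cls]))
        if shared_cls else None,
    }

    _stage("fga")
    fga = {p.sample_id: fraction_genome_altered(p, config.fga_threshold)
           for p in profiles}
    fga_frame = pd.DataFrame(
        [(r.sample_id, r.fga, r.threshold) for r in fga.values()],
        columns=["sample_id", "fga", "threshold"])
    fga_frame.to_csv(out / "fga.tsv", sep="\t", index=False)
    is_cl = truth.samples.set_index("sample_id")["is_cell_line"]
    summary["fga"] = {
        "median_tumour": float(fga_frame.loc[~fga_frame["sample_id"].map(is_cl), "fga"].median()),
        "median_cell_line": float(fga_frame.loc[fga_frame["sample_id"].map(is_cl), "fga"].median()),
    }

    _stage("loh3p")
    scenarios = {"masked_loss_line": masked_loss_scenario(),
                 "balanced_line": balanced_diploid_scenario(),
                 "ploidy_relative_line": ploidy_relative_scenario()}
    allele_profiles = {p.sample_id: p
                       for p in simulate_allele_specific(genome, scenarios, seed=config.seed)}
    log2_by_id = {p.sample_id: p for p in profiles}
    loh = arm_loss_report(log2_by_id, allele_profiles, genome, arm="3p",
                          loss_thresh=config.loss_threshold,
                          lost_cutoff=config.lost_cutoff)
    loh_frame = pd.DataFrame([{
        "sample_id": r.sample_id, "arm": r.arm,
        "log2_loss_fraction": r.log2_loss_fraction,
        "zero_minor_fraction": r.zero_minor_fraction,
        "relative_loss_fraction": r.relative_loss_fraction,
        "sample_mean_total_cn": r.sample_mean_total_cn,
        "combined_call": r.combined_call} for r in loh])
    loh_frame.to_csv(out / "arm3p_loss.tsv", sep="\t", index=False)
    summary["loh3p"] = {
        "n_lost": int((loh_frame["combined_call"] == "lost").sum()),
        "n_negligible": int((loh_frame["combined_call"] == "negligible").sum()),
    }

    _stage("cluster")
    linkage, ordered = cluster_profiles(gene_matrix)
    groups = truth.group_of()
    cluster_result = cut_and_summarize(linkage, ordered, groups, config.cut_height)
    cluster_result.composition.to_csv(out / "cluster_composition.tsv", sep="\t")
    (out / "dendrogram.nwk").write_text(linkage_to_newick(linkage, ordered))
    tumour_subtypes = groups[~groups.index.map(is_cl)]
    calls = assign_cell_line_subtype(cluster_result, tumour_subtypes,
                                     cell_lines, config.min_tumours)
    calls.rename_axis("cell_line").to_frame().to_csv(out / "cell_line_subtypes.tsv", sep="\t")
    summary["clustering"] = {
        "n_clusters": int(cluster_result.labels.nunique()),
        "cut_height": config.cut_height,
        "cell_line_calls": calls.value_counts().to_dict(),
    }

    _stage("tiers")
    tier_calls = build_tier_calls(views.mutations_a, views.mutations_b,
                                  views.gistic_a, views.gistic_b,
                                  config.gene_panel, cell_lines)
    tier_calls.to_csv(out / "tier_calls.tsv", sep="\t", index=False)
    report = reliability_report(tier_calls, config.gene_panel, cell_lines)
    report.ranking.to_csv(out / "reliability_ranking.tsv", sep="\t", index=False)
    summary["tiers"] = {
        "tier_counts": tier_calls.groupby(["data_kind", "tier"]).size()
        .unstack(fill_value=0).to_dict(),
        "n_all_tier1_mutations": int(report.flags["all_tier1_mutations"].sum()),
        "n_all_tier1_cna": int(report.flags["all_tier1_cna"].sum()),
    }

    _stage("classify")
    expr, expr_truth = simulate_expression(
        list(genome.genes["gene_id"]),
        n_per_class=config.expr_n_per_class,
        n_intermediate=config.expr_n_intermediate,
        class_effect_size=config.expr_effect_size,
        n_marker_genes=config.expr_n_markers,
        batch_shift=config.expr_batch_shift,
        batch_scale=config.expr_batch_scale,
        noise_sd=config.expr_noise_sd,
        seed=config.seed)
    write_gct(expr, out / "expression.gct")
    adjusted, _ = combat_adjust(expr, expr_truth.batch)
    labelled = expr_truth.expression_class[expr_truth.expression_class != "intermediate"]
    train = GeneMatrix(adjusted.values[labelled.index], kind="expression")
    model, cv_table = train_nsc(train, labelled, folds=config.nsc_folds,
                                seed=config.seed)
    cv_table.to_csv(out / "nsc_cv.tsv", sep="\t", index=False)
    model.to_json(out / "nsc_model.json")
    expr_calls = classify_margin(model, adjusted, margin=config.margin)
    calls_frame = calls_to_frame(expr_calls)
    calls_frame.to_csv(out / "expression_calls.tsv", sep="\t", index=False)
    inter = expr_truth.expression_class[expr_truth.expression_class == "intermediate"].index
    inter_calls = calls_frame.set_index("sample_id").loc[inter, "call"]
    summary["expression"] = {
        "selected_delta": model.delta,
        "n_surviving_genes": len(model.surviving_genes),
        "call_counts": calls_frame["call"].value_counts().to_dict(),
        "fraction_intermediate_unclassified":
            float((inter_calls == "unclassified").mean()) if len(inter) else None,
    }

    _stage("aggressiveness")
    fga_values = {sid: r.fga for sid, r in fga.items()}
    clinical = simulate_clinical(truth, fga_values,
                                 stage_logit_slope=config.stage_logit_slope,
                                 grade_logit_slope=config.grade_logit_slope,
                                 seed=config.seed)
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    ccrcc_tumours = [s for s in truth.tumour_ids if groups[s] == "ccRCC"]
    try:
        with_group, away_group = split_by_coclustering(
            cluster_result, ccrcc_tumours, cell_lines)
        split_used = "coclustering"
        if not with_group or not away_group:
            raise InvalidArgumentError("co-clustering split is degenerate")
    except InvalidArgumentError:
        # all (or none) of the tumours share the cell-line cluster; fall back
        # to ranking tumours by mean correlation with the cell lines
        ccrcc_cls = [c for c in cell_lines if groups[c] == "ccRCC"]
        tum_matrix = GeneMatrix(gene_matrix.values[ccrcc_tumours], kind="log2")
        cl_matrix = GeneMatrix(gene_matrix.values[ccrcc_cls or cell_lines],
                               kind="log2")
        sim = profile_correlation(tum_matrix, cl_matrix, method="spearman")
        with_group, away_group = split_by_quartile(sim)
        split_used = "quartile"
    comparison = compare_groups(with_group, away_group, clinical,
                                truth.mutated_genes, fga, config.gene_panel)
    comparison.gene_tests.to_csv(out / "aggressiveness_gene_tests.tsv",
                                 sep="\t", index=False)
    summary["aggressiveness"] = {"split": split_used, **comparison.to_dict()}

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True, default=str))
    logger.info("wrote %s", summary_path)
    return summary
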