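"""End-to-end orchestration of the analysis stages.

Stage order mirrors the analysis narrative: normalize → per-organ
cell-means fits and contrasts → BH adjustment and threshold calls →
probe→gene collapse → genotype/organ partitions → priming-candidate
selection → GO enrichment (optional) → sample clustering → qPCR
concordance (optional). `run_core` works on in-memory objects (what the
tests and the acceptance analysis use); `run_pipeline` reads a RunConfig's
files, delegates, and writes every table plus a manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from droughtprime import io as dio
from droughtprime.clustering import cluster_samples, cut_tree, to_newick
from droughtprime.diffexpr import (
    DROUGHT_VS_CONTROL,
    TOLERANT_VS_SENSITIVE_CONTROL,
    ContrastSpec,
    collapse_probes_to_genes,
    deg_gene_sets,
    fit_cell_means,
    run_contrast,
)
from droughtprime.enrichment import enrich
from droughtprime.normalize import ORGANS, normalize_matrix, validate_sample_sheet
from droughtprime.partition import (
    discordant_shared,
    partition_by_genotype,
    partition_by_organ,
)
from droughtprime.priming import (
    calls_to_frame,
    classify_priming_by_organ,
    initial_difference_genes,
    overlap_with_tolerant_degs,
    select_primed,
)


@dataclass
class RunConfig:
    """Paths and thresholds for a file-driven run."""

    expression_path: str
    sample_sheet_path: str
    probe_map_path: str
    output_dir: str
    annotation_path: str | None = None
    obo_path: str | None = None
    qpcr_path: str | None = None
    tau_drought: float = 3.0
    tau_init: float = 2.0
    alpha: float = 0.05
    p_go: float = 0.01
    min_mapping: int = 5
    percentile: float = 75.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_drought < 1 or self.tau_init < 1:
            raise ValueError("fold-change thresholds must be ≥ 1")
        if self.tau_drought < 3.0:
            warnings.warn(
                f"tau_drought={self.tau_drought} is below the conventional FC ≥ 3",
                stacklevel=2,
            )
        if not 0 < self.alpha < 1 or not 0 < self.p_go < 1:
            raise ValueError("significance levels must be in (0, 1)")


@dataclass
class ReportBundle:
    """All per-stage outputs of one run."""

    normalized: pd.DataFrame
    shifts: pd.Series
    gene_tables: dict[str, pd.DataFrame]  # contrast name → collapsed gene table
    probe_tables: dict[str, pd.DataFrame]
    partitions: dict  # per-organ genotype partitions + organ partition counts
    priming: pd.DataFrame
    priming_summary: dict
    tree: pd.DataFrame
    newick: str
    cluster_labels: dict[int, pd.Series]
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def contrast_specs(
    organ: str, tau_drought: float = 3.0, tau_init: float = 2.0, alpha: float = 0.05
) -> dict[str, ContrastSpec]:
    return {
        "tolerant_drought": ContrastSpec(
            organ, DROUGHT_VS_CONTROL, genotype="tolerant",
            fc_threshold=tau_drought, q_threshold=alpha,
        ),
        "sensitive_drought": ContrastSpec(
            organ, DROUGHT_VS_CONTROL, genotype="sensitive",
            fc_threshold=tau_drought, q_threshold=alpha,
        ),
        "initial": ContrastSpec(
            organ, TOLERANT_VS_SENSITIVE_CONTROL,
            fc_threshold=tau_init, q_threshold=alpha,
        ),
    }


def run_core(
    raw: pd.DataFrame,
    samples: pd.DataFrame,
    probe_map: pd.DataFrame,
    annotations: dict[str, set[str]] | None = None,
    dag=None,
    tau_drought: float = 3.0,
    tau_init: float = 2.0,
    alpha: float = 0.05,
    p_go: float = 0.01,
    min_mapping: int = 5,
    percentile: float = 75.0,
    already_log2: bool = False,
) -> ReportBundle:
    """Run normalization through clustering on in-memory inputs."""
    sheet = validate_sample_sheet(samples, raw)
    if already_log2:
        from droughtprime.normalize import baseline_to_median, percentile_shift

        shifted, shifts = percentile_shift(raw, percentile=percentile)
        normalized = baseline_to_median(shifted)
    else:
        normalized, shifts = normalize_matrix(raw, percentile=percentile)

    probe_tables: dict[str, pd.DataFrame] = {}
    gene_tables: dict[str, pd.DataFrame] = {}
    for organ in ORGANS:
        fit = fit_cell_means(normalized, sheet, organ)
        for label, spec in contrast_specs(organ, tau_drought, tau_init, alpha).items():
            stats_df = run_contrast(fit, spec)
            probe_tables[f"{organ}_{label}"] = stats_df
            gene_tables[f"{organ}_{label}"] = collapse_probes_to_genes(stats_df, probe_map)

    # partitions
    partitions: dict = {}
    universes: dict[str, set[str]] = {}
    for organ in ORGANS:
        tol = deg_gene_sets(gene_tables[f"{organ}_tolerant_drought"])
        sen = deg_gene_sets(gene_tables[f"{organ}_sensitive_drought"])
        part = partition_by_genotype(tol["all"], sen["all"])
        tol_dirs = gene_tables[f"{organ}_tolerant_drought"]["direction"].to_dict()
        sen_dirs = gene_tables[f"{organ}_sensitive_drought"]["direction"].to_dict()
        partitions[organ] = {
            "partition": part,
            "counts": part.counts(),
            "discordant_shared": sorted(discordant_shared(part.shared, tol_dirs, sen_dirs)),
        }
        universes[organ] = tol["all"] | sen["all"]
    organ_part = partition_by_organ(universes["root"], universes["leaf"])
    partitions["organ"] = {"partition": organ_part, "counts": organ_part.counts()}

    # priming
    per_organ_calls = {}
    for organ in ORGANS:
        initial = initial_difference_genes(
            gene_tables[f"{organ}_initial"], tau_init=tau_init, alpha=alpha
        )
        per_organ_calls[organ] = select_primed(
            initial,
            gene_tables[f"{organ}_sensitive_drought"],
            gene_tables[f"{organ}_tolerant_drought"],
            organ,
            tau_drought=tau_drought,
            alpha=alpha,
        )
    classified = classify_priming_by_organ(per_organ_calls["root"], per_organ_calls["leaf"])
    priming = calls_to_frame(classified)
    priming_summary = {
        "organ_class_counts": {
            oc: len({c.gene_id for c in classified if c.organ_class == oc})
            for oc in ("root_only", "leaf_only", "both")
        },
        "tolerant_overlap": overlap_with_tolerant_degs(classified),
    }

    # enrichment
    enrichment: dict[str, pd.DataFrame] = {}
    if annotations is not None:
        background = sorted(set(probe_map["gene_id"]))
        input_lists = {
            "root_degs": universes["root"],
            "leaf_degs": universes["leaf"],
            "primed": set(priming["gene_id"]) if len(priming) else set(),
        }
        for name, input_genes in input_lists.items():
            if not input_genes:
                continue
            enrichment[name] = enrich(
                input_genes,
                background,
                annotations,
                dag=dag,
                p_threshold=p_go,
                min_mapping=min_mapping,
            )

    # clustering
    _, tree = cluster_samples(normalized)
    cluster_labels = {k: cut_tree(tree, k) for k in (2, 4)}

    manifest = {
        "thresholds": {
            "tau_drought": tau_drought,
            "tau_init": tau_init,
            "alpha": alpha,
            "p_go": p_go,
            "min_mapping": min_mapping,
            "percentile": percentile,
        },
        "n_probes": int(raw.shape[0]),
        "n_samples": int(raw.shape[1]),
        "partition_counts": {
            organ: partitions[organ]["counts"] for organ in ORGANS
        }
        | {"organ": partitions["organ"]["counts"]},
        "priming_summary": priming_summary,
    }
    return ReportBundle(
        normalized=normalized,
        shifts=shifts,
        gene_tables=gene_tables,
        probe_tables=probe_tables,
        partitions=partitions,
        priming=priming,
        priming_summary=priming_summary,
        tree=tree,
        newick=to_newick(tree),
        cluster_labels=cluster_labels,
        enrichment=enrichment,
        manifest=manifest,
    )


def score_against_truth(bundle: ReportBundle, truth) -> dict[str, float]:
    """Priming recovery metrics of a run against the generator's labels.

    Sensitivity: fraction of true primed (gene, organ) pairs called;
    FDP: fraction of calls with no matching truth label.
    """
    truth_table = truth.priming_table()
    true_pairs = {
        (r.gene_id, r.organ)
        for r in truth_table.itertuples()
        if r.primed_label != "none"
    }
    called_pairs = (
        {(r.gene_id, r.organ) for r in bundle.priming.itertuples()}
        if len(bundle.priming)
        else set()
    )
    tp = len(true_pairs & called_pairs)
    sensitivity = tp / len(true_pairs) if true_pairs else float("nan")
    fdp = (len(called_pairs) - tp) / len(called_pairs) if called_pairs else 0.0
    return {
        "sensitivity": sensitivity,
        "fdp": fdp,
        "n_true": len(true_pairs),
        "n_called": len(called_pairs),
    }


def run_pipeline(config: RunConfig) -> ReportBundle:
    """File-driven run: read inputs, execute the stages, write all tables
    plus a manifest under ``config.output_dir``."""
    raw = dio.read_expression(config.expression_path)
    samples = dio.read_sample_sheet(config.sample_sheet_path, raw)
    probe_map = dio.read_probe_map(config.probe_map_path)
    annotations = dag = None
    if config.annotation_path:
        annotations = dio.read_annotations(config.annotation_path)
        if config.obo_path:
            dag = dio.read_obo(config.obo_path)

    bundle = run_core(
        raw,
        samples,
        probe_map,
        annotations=annotations,
        dag=dag,
        tau_drought=config.tau_drought,
        tau_init=config.tau_init,
        alpha=config.alpha,
        p_go=config.p_go,
        min_mapping=config.min_mapping,
        percentile=config.percentile,
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dio.write_expression(bundle.normalized, out / "normalized.tsv")
    bundle.shifts.rename_axis("sample_id").to_frame().to_csv(out / "normalization_log.tsv", sep="\t")
    for name, table in bundle.probe_tables.items():
        table.to_csv(out / f"probes_{name}.tsv", sep="\t")
    for name, table in bundle.gene_tables.items():
        table.to_csv(out / f"genes_{name}.tsv", sep="\t")
    bundle.priming.to_csv(out / "priming_candidates.tsv", sep="\t", index=False)
    for name, table in bundle.enrichment.items():
        table.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
    bundle.tree.to_csv(out / "ward_merges.tsv", sep="\t", index=False)
    (out / "dendrogram.nwk").write_text(bundle.newick + "\n", encoding="utf-8")
    for k, labels in bundle.cluster_labels.items():
        labels.to_frame().to_csv(out / f"clusters_k{k}.tsv", sep="\t")

    manifest = dict(bundle.manifest)
    manifest["inputs"] = {
        "expression": dio.file_checksum(config.expression_path),
        "sample_sheet": dio.file_checksum(config.sample_sheet_path),
        "probe_map": dio.file_checksum(config.probe_map_path),
    }
    manifest["seed"] = config.seed
    dio.write_manifest(manifest, out / "manifest.json")
    bundle.manifest = manifest
    return bundle
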