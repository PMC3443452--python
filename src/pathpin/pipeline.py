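"""End-to-end orchestration: files in, marker list and network artifacts out."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as pio
from .activity import ActivityMatrix, compute_activity, map_genes_to_pathways
from .baselines import marker_gene_overlap, rank_genes_ttest
from .pin import build_pin
from .selection import EvaluationConfig, SelectionTrace, evaluate_feature_set, greedy_select, write_manifest

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for a full run; defaults match the method's

    canonical settings (DE filter p < 0.05, co-expression |r| > 0.8,
    five-fold CV repeated 100 times for the final score).
    """

    expression: str
    labels: str
    gmt: str
    ppi: str
    outdir: str
    probe_map: str | None = None
    alpha: float = 0.05
    rho_min: float = 0.8
    min_genes: int = 1
    missing: str = "error"
    uppercase_genes: bool = False
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)


@dataclass
class RunResult:
    activity: ActivityMatrix
    trace: SelectionTrace
    counts: dict[str, int]


def run_pipeline(config: RunConfig) -> RunResult:
    """Standardize, score pathways, build the PIN, select markers, write artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    expr = pio.load_expression(
        config.expression,
        probe_map=config.probe_map,
        missing=config.missing,
        uppercase_genes=config.uppercase_genes,
    )
    labels = pio.load_labels(config.labels)
    pio.check_labels(expr, labels)
    sets = pio.load_gmt(config.gmt)
    ppi = pio.load_ppi(config.ppi)

    n_genes_raw = expr.n_genes
    expr = pio.standardize(expr)
    mapped = map_genes_to_pathways(expr, sets, min_genes=config.min_genes)
    activity = compute_activity(expr, mapped)
    pin = build_pin(mapped, ppi, expr, labels, alpha=config.alpha, rho_min=config.rho_min)
    trace = greedy_select(activity, pin, labels, config.evaluation)

    counts = {
        "genes_loaded": n_genes_raw,
        "genes_standardized": expr.n_genes,
        "genes_in_pathways": len(mapped.gene_universe()),
        "pathways_input": len(sets),
        "pathways_kept": len(mapped),
        "ppi_edges": len(ppi),
        "pin_edges": len(pin.edges),
        "markers_selected": len(trace.final_set),
    }
    for key, value in counts.items():
        logger.info("%s: %d", key, value)

    activity.write(outdir / "activity.tsv", outdir / "loadings.tsv")
    pin.write_sif(outdir / "pin.sif")
    pin.write_evidence(outdir / "pin_evidence.tsv")
    trace.write_tsv(outdir / "selection_trace.tsv")
    trace.write_markers(outdir / "markers.tsv")
    write_manifest(
        outdir / "manifest.json",
        config.evaluation,
        extra={
            "inputs": {
                "expression": str(config.expression),
                "labels": str(config.labels),
                "gmt": str(config.gmt),
                "ppi": str(config.ppi),
                "probe_map": str(config.probe_map) if config.probe_map else None,
            },
            "alpha": config.alpha,
            "rho_min": config.rho_min,
            "counts": counts,
            "final_auc": trace.final_auc,
        },
    )
    return RunResult(activity=activity, trace=trace, counts=counts)


def evaluate_holdout(
    markers: list[str],
    expression_path: str,
    labels_path: str,
    gmt_path: str,
    cfg: EvaluationConfig,
    *,
    min_genes: int = 1,
) -> dict[str, float]:
    """Score previously selected markers on an independent dataset.

    No re-selection happens: the holdout data's own standardization and PCA
    produce activities for the marker pathways (loadings do not transfer
    across platforms), which are then scored by the usual repeated CV.
    """
    expr = pio.standardize(pio.load_expression(expression_path))
    labels = pio.load_labels(labels_path)
    pio.check_labels(expr, labels)
    sets = pio.load_gmt(gmt_path)
    keep = {m: sets.sets[m] for m in markers if m in sets.sets}
    missing = [m for m in markers if m not in keep]
    if missing:
        raise pio.InputError(f"markers absent from gene-set collection: {missing[:5]}")
    mapped = map_genes_to_pathways(expr, pio.GeneSetCollection(sets=keep), min_genes=min_genes)
    activity = compute_activity(expr, mapped)
    present = [m for m in markers if m in set(activity.pathway_ids)]
    return evaluate_feature_set(activity, present, labels, cfg)


def gene_baseline_report(
    expression_path: str,
    labels_path: str,
    k: int,
    cfg: EvaluationConfig,
    outdir: str,
    *,
    gmt_path: str | None = None,
    markers: list[str] | None = None,
) -> dict:
    """Rank genes by t-test, score the top-k as features, optional overlap report."""
    from .activity import activity_from_genes

    outdir_p = Path(outdir)
    outdir_p.mkdir(parents=True, exist_ok=True)
    expr = pio.standardize(pio.load_expression(expression_path))
    labels = pio.load_labels(labels_path)
    pio.check_labels(expr, labels)
    ranked = rank_genes_ttest(expr, labels)
    ranked.write_tsv(outdir_p / "ranked_genes.tsv")
    top = ranked.top(k)
    result = evaluate_feature_set(activity_from_genes(expr, top), top, labels, cfg)
    report: dict = {"k": k, "top_genes": top, **result}
    if gmt_path and markers:
        sets = map_genes_to_pathways(expr, pio.load_gmt(gmt_path))
        overlap = marker_gene_overlap(markers, sets, ranked)
        report["overlap"] = overlap
        with open(outdir_p / "overlap.tsv", "w") as fh:
            fh.write("n_pathway_genes\tn_overlap\tpercentage\n")
            fh.write(
                f"{overlap['n_pathway_genes']}\t{overlap['n_overlap']}"
                f"\t{overlap['percentage']:.1f}\n"
            )
    (outdir_p / "gene_baseline.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
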