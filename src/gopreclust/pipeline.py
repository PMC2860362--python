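"""End-to-end orchestration: read → filter → precluster → summarize → rank.

``run`` executes the whole analysis for one configuration and writes all
artifacts (catalogs, count tables, profile/PCA tables, biplots, rankings and
ROC tables) into the output directory.  ``mode="both"`` runs the preclustered
and unclustered branches side by side and additionally emits the ROC
comparison when a reference term list is supplied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import preclust, ranking, summarize
from .io_annotation import build_membership, read_annotation, read_expression
from .preclust import PreclustConfig

__all__ = ["RunConfig", "run"]

log = logging.getLogger("gopreclust")


@dataclass
class RunConfig:
    expression_path: str | Path
    annotation_path: str | Path
    out_dir: str | Path
    annotation_format: str = "tsv2col"
    reference_path: str | Path | None = None
    namespace: str | None = "biological_process"
    min_genes: int = 4
    missing_policy: str = "drop_gene"
    preclust: PreclustConfig = field(default_factory=PreclustConfig)
    icc_threshold: float = 0.2
    center: bool = True
    connect_loadings: bool = True
    highlight: list[str] = field(default_factory=list)
    mode: str = "preclustered"  # preclustered | unclustered | both

    def __post_init__(self) -> None:
        if self.mode not in ("preclustered", "unclustered", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for p in (self.expression_path, self.annotation_path, self.reference_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _run_branch(name, expression, membership, config, out_dir, reference):
    """One analysis branch (preclustered or unclustered); returns its summary."""
    if name == "preclustered":
        catalog = preclust.precluster_catalog(expression, membership, config.preclust)
    else:
        catalog = preclust.identity_catalog(expression, membership)
    log.info("%s branch: %s", name, catalog.counts)
    preclust.write_catalog(catalog, out_dir / f"{name}_catalog.tsv")
    preclust.write_counts(catalog, out_dir / f"{name}_counts.tsv")

    profiles = summarize.combine(expression, catalog)
    summarize.write_profiles(profiles, out_dir / f"{name}_profiles.tsv")
    model = summarize.pca(profiles, center=config.center)
    summarize.write_pca(model, out_dir, prefix=f"{name}_pca")
    summarize.biplot(
        model,
        icc_by_class=catalog.icc_by_label(),
        icc_threshold=config.icc_threshold,
        highlight=config.highlight,
        connect_loadings=config.connect_loadings,
        out_path=out_dir / f"{name}_biplot.png",
    )
    summary = {
        "counts": catalog.counts,
        "explained_variance_pc12": float(model.explained_variance_fraction[:2].sum()),
    }
    result = {"catalog": catalog, "model": model, "summary": summary}
    if reference is not None:
        ranked = ranking.mahalanobis_rank(model.scores[:, :2], model.class_labels)
        labels = ranking.label_classes(ranked.class_labels, reference)
        curve = ranking.roc_curve(ranked, labels)
        ranking.write_roc(curve, out_dir / f"{name}_roc.tsv")
        summary["auc"] = curve.auc
        result["roc"] = curve
    return result


def run(config: RunConfig) -> dict:
    """Execute the configured analysis; returns the in-memory results per branch."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    expression = read_expression(config.expression_path, missing_policy=config.missing_policy)
    log.info("expression: %d genes × %d conditions", expression.n_genes, expression.n_conditions)
    annotation = read_annotation(config.annotation_path, format=config.annotation_format)
    membership, expression = build_membership(
        annotation, expression, namespace=config.namespace, min_genes=config.min_genes
    )
    log.info(
        "membership: %d genes × %d GO classes (namespace=%s, min_genes=%d)",
        len(membership.gene_ids), membership.n_terms, config.namespace, config.min_genes,
    )
    reference = (
        ranking.read_reference_list(config.reference_path)
        if config.reference_path is not None
        else None
    )

    branches = ("preclustered", "unclustered") if config.mode == "both" else (config.mode,)
    results = {}
    for name in branches:
        results[name] = _run_branch(name, expression, membership, config, out_dir, reference)

    summary = {name: r["summary"] for name, r in results.items()}
    if config.mode == "both" and reference is not None:
        comparison = ranking.compare_rocs(
            results["preclustered"]["roc"], results["unclustered"]["roc"]
        )
        summary["comparison"] = comparison
        ranking.plot_rocs(
            results["preclustered"]["roc"], results["unclustered"]["roc"],
            out_path=out_dir / "roc_comparison.png",
        )
        with open(out_dir / "roc_comparison.tsv", "w", encoding="utf-8") as fh:
            fh.write("delta_auc\tdominates\n")
            fh.write(f"{comparison['delta_auc']}\t{comparison['dominates']}\n")
    with open(out_dir / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    results["summary"] = summary
    return results
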