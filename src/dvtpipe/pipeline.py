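"""End-to-end orchestration of the biomarker-prioritization workflow.

The workflow is a chain of set reductions — catalog rows → genome-wide
significant SNPs → LD-expanded SNPs → mapped genes → risk genes →
coagulation genes → disease-linked genes → blood biomarkers — and every
intermediate is materialized as a TSV so the chain is auditable. The
stage counts form the report's headline.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrich as enrich_mod
from . import expression as expr_mod
from . import io_gwas, ld_expand, network, scorecard

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass(slots=True)
class PipelineConfig:
    """All thresholds and input paths of one run.

    Defaults carry the workflow's standard constants: genome-wide
    significance 5e-8, top-40 SNP cut, LD r² > 0.8 in the ASN panel,
    minimum annotation score 3, FDR 0.05, blood detectability 1.0 TPM.
    """

    associations: Path
    ld_panel: Path
    variant_links: Path
    eqtl: Path
    go_bp: Path
    go_cc: Path
    go_mf: Path
    pid: Path
    network_edges: Path
    expression: Path
    tissue_map: Path
    out_dir: Path
    alpha: float = 5e-8
    top_n: int = 40
    r2_min: float = 0.8
    population: str = "ASN"
    min_score: int = 3
    fdr: float = 0.05
    min_overlap: int = 2
    tpm_min: float = 1.0
    term_labels: tuple[str, ...] = (
        "coagulation",
        "regulation of response to wounding",
        "wound healing",
    )
    disease_labels: tuple[str, ...] = ("deep vein thrombosis", "thrombophilia")

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.r2_min <= 1:
            raise ValueError("r2_min must be in [0, 1]")
        if not 0 <= self.min_score <= 7:
            raise ValueError("min_score must be in [0, 7]")
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr must be in (0, 1]")

    @classmethod
    def from_bundle(cls, bundle_dir: str | Path, out_dir: str | Path | None = None) -> "PipelineConfig":
        """Load the ``pipeline_config.yaml`` written into a bundle directory."""
        bundle = Path(bundle_dir)
        return cls.from_yaml(bundle / "pipeline_config.yaml", out_dir=out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path | None = None) -> "PipelineConfig":
        """Load a YAML config; relative input paths resolve against the YAML's directory."""
        path = Path(path)
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        base = path.parent
        inputs = {key: base / value for key, value in raw["inputs"].items()}
        kwargs = {k: v for k, v in raw.items() if k != "inputs"}
        if "term_labels" in kwargs:
            kwargs["term_labels"] = tuple(kwargs["term_labels"])
        if "disease_labels" in kwargs:
            kwargs["disease_labels"] = tuple(kwargs["disease_labels"])
        return cls(
            out_dir=Path(out_dir) if out_dir is not None else base / "out",
            **inputs,
            **kwargs,
        )


@dataclass(slots=True)
class StageReport:
    """Counts, artifacts and the final call of one pipeline run."""

    counts: dict[str, int] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)
    mapped_genes: list[str] = field(default_factory=list)
    top_genes: list[str] = field(default_factory=list)
    risk_genes: list[str] = field(default_factory=list)
    coag_genes: list[str] = field(default_factory=list)
    network_genes: list[str] = field(default_factory=list)
    selected_biomarkers: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=1, sort_keys=True)
            handle.write("\n")

    @property
    def stage_counts(self) -> list[int]:
        """The headline reduction chain, in workflow order."""
        keys = (
            "n_associations", "n_significant", "n_expanded", "n_genes",
            "n_risk_genes", "n_coag_genes", "n_network_genes", "n_selected",
        )
        return [self.counts[k] for k in keys]


def run(config: PipelineConfig) -> StageReport:
    """Execute every stage, write intermediates, and return the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = StageReport(
        config={
            k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        }
    )

    def stage(name: str, code: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(name, code, str(exc)) from exc

    def artifact(name: str, path: Path) -> None:
        report.artifacts[name] = str(path)

    # 1. ingest
    assocs = stage("ingest", "read_error", io_gwas.read_associations, config.associations)
    report.counts["n_associations"] = len(assocs)

    # 2. genome-wide significance filter
    significant = stage(
        "filter", "filter_error", io_gwas.filter_genomewide, assocs, config.alpha
    )
    report.counts["n_significant"] = len(significant)
    io_gwas.write_associations(significant, out / "significant_snps.tsv")
    artifact("significant_snps", out / "significant_snps.tsv")

    # 3. top-N cut and Manhattan coordinates
    top = stage("top", "select_error", io_gwas.select_top_snps, assocs, config.top_n)
    top_genes = sorted(io_gwas.top_mapped_genes(top))
    report.top_genes = top_genes
    report.counts["n_top_snps"] = len(top)
    io_gwas.write_associations(top, out / "top_snps.tsv")
    artifact("top_snps", out / "top_snps.tsv")
    points = io_gwas.manhattan_coordinates(assocs)
    pd.DataFrame(
        [{"rsid": p.rsid, "chrom": p.chrom, "cumulative_x": p.cumulative_x,
          "neglog10p": p.neglog10p} for p in points]
    ).to_csv(out / "manhattan.tsv", sep="\t", index=False)
    artifact("manhattan", out / "manhattan.tsv")

    # 4. LD expansion
    panel = stage("expand", "panel_error", ld_expand.read_ld_panel, config.ld_panel)
    seeds = {a.rsid for a in significant}
    expanded = stage(
        "expand", "expand_error",
        ld_expand.expand_snps, seeds, panel, config.r2_min, config.population,
    )
    report.counts["n_expanded"] = len(expanded)
    with open(out / "expanded_snps.txt", "w") as handle:
        for rsid in sorted(expanded):
            handle.write(rsid + "\n")
    artifact("expanded_snps", out / "expanded_snps.txt")

    # 5. gene mapping
    links = stage("map", "links_error", ld_expand.read_variant_links, config.variant_links)
    mapping = ld_expand.map_to_genes(expanded, links)
    genes = sorted(mapping.genes)
    report.mapped_genes = genes
    report.counts["n_genes"] = len(genes)
    report.counts["n_unmapped_snps"] = len(mapping.unmapped)
    pd.DataFrame(
        [{"gene": g, "n_snps": len(mapping.genes[g]),
          "snps": ",".join(sorted(mapping.genes[g]))} for g in genes]
    ).to_csv(out / "gene_map.tsv", sep="\t", index=False)
    artifact("gene_map", out / "gene_map.tsv")

    # 6. GO enrichment of the mapped gene set -> criterion flags 4-6
    go_flags: dict[str, set[str]] = {}
    collections: dict[str, list[enrich_mod.GeneSetTerm]] = {}
    for key, path in (("go_bp", config.go_bp), ("go_cc", config.go_cc), ("go_mf", config.go_mf)):
        namespace = key.split("_")[1].upper()
        terms = stage("enrich", "gmt_error", enrich_mod.read_gmt, path, namespace)
        collections[key] = terms
        results = stage(
            "enrich", "test_error",
            enrich_mod.enrich, genes, terms, None, config.fdr, config.min_overlap,
        )
        go_flags[key] = enrich_mod.flagged_genes(genes, results, terms, config.fdr)
        enrich_mod.results_to_table(results).to_csv(
            out / f"enrichment_{namespace.lower()}_mapped.tsv", sep="\t", index=False
        )

    # 7. scorecard
    missense = ld_expand.missense_genes(expanded, links)
    eqtl_genes = stage("score", "eqtl_error", scorecard.read_eqtl_genes, config.eqtl)
    pid = stage("score", "pid_error", scorecard.read_gene_list, config.pid)
    profiles = scorecard.build_profiles(
        genes, top_genes, missense, eqtl_genes, go_flags, pid
    )
    risk = scorecard.risk_genes(profiles, config.min_score)
    report.risk_genes = risk
    report.counts["n_risk_genes"] = len(risk)
    scorecard.write_scorecard(profiles, out / "scorecard.tsv")
    artifact("scorecard", out / "scorecard.tsv")

    # 8. enrichment of the risk set -> coagulation/wound-healing genes
    risk_results = stage(
        "coag", "test_error",
        enrich_mod.enrich, risk, collections["go_bp"], None, config.fdr, config.min_overlap,
    )
    enrich_mod.results_to_table(risk_results).to_csv(
        out / "enrichment_bp_risk.tsv", sep="\t", index=False
    )
    artifact("enrichment_bp_risk", out / "enrichment_bp_risk.tsv")
    coag = sorted(
        enrich_mod.genes_in_terms(
            risk, risk_results, collections["go_bp"],
            enrich_mod.name_filter(config.term_labels), config.fdr,
        )
    )
    report.coag_genes = coag
    report.counts["n_coag_genes"] = len(coag)
    with open(out / "coag_genes.txt", "w") as handle:
        handle.write("\n".join(coag) + ("\n" if coag else ""))
    artifact("coag_genes", out / "coag_genes.txt")

    # 9. disease-network filter
    graph = stage("network", "edges_error", network.read_edges, config.network_edges)
    linked = sorted(network.direct_disease_genes(graph, coag, config.disease_labels))
    report.network_genes = linked
    report.counts["n_network_genes"] = len(linked)
    with open(out / "network_genes.txt", "w") as handle:
        handle.write("\n".join(linked) + ("\n" if linked else ""))
    artifact("network_genes", out / "network_genes.txt")

    # 10. tissue expression + biomarker call
    matrix, tissues = stage(
        "biomarkers", "expression_error",
        expr_mod.read_expression, config.expression, config.tissue_map,
    )
    summaries: list[expr_mod.ExpressionSummary] = []
    for gene in linked:
        summaries.extend(
            stage("biomarkers", "summary_error", expr_mod.tissue_summary, matrix, tissues, gene)
        )
    calls = expr_mod.call_biomarkers(linked, summaries, eqtl_genes, config.tpm_min)
    selected = sorted(expr_mod.selected_genes(calls))
    report.selected_biomarkers = selected
    report.counts["n_selected"] = len(selected)
    expr_mod.calls_to_table(calls).to_csv(out / "biomarker_calls.tsv", sep="\t", index=False)
    artifact("biomarker_calls", out / "biomarker_calls.tsv")

    report.to_json(out / "report.json")
    artifact("report", out / "report.json")
    log.info("stage counts: %s", report.stage_counts)
    return report
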