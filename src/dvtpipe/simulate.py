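"""Synthetic input bundles with planted ground truth.

The live services behind a catalog-driven biomarker study (association
catalog, LD server, GO enrichment portal, knowledge graph, expression
portal) are replaced by one generator that writes all seven input files
in the formats the pipeline consumes, with a controllable planted
signal:

* planted biomarker genes receive the full evidence chain — a
  top-ranked SNP, a missense LD proxy at r² > 0.8, a whole-blood eQTL,
  membership in enriched coagulation GO terms, a direct disease edge,
  and blood-shifted expression — and are the genes the pipeline should
  select;
* liver-class genes mimic hepatocyte-made coagulation factors: disease-
  linked and top-ranked but without blood eQTLs and with low blood TPM;
* decoy genes carry strict subsets of evidence and must not survive.

P-values are drawn log-uniformly within bands (below/above the
significance threshold) rather than from a genetic model: the pipeline
consumes only ranks and thresholds, so band membership is the only
distributional property that matters. Everything derives from one
seeded generator, so a seed fully determines the bundle bytes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import enrich as enrich_mod
from . import io_gwas, ld_expand

COAG_TERM_NAMES: tuple[str, ...] = (
    "coagulation",
    "regulation of response to wounding",
    "wound healing",
)
DISEASE_LABELS: tuple[str, ...] = ("deep vein thrombosis", "thrombophilia")

#: Bundle file names (all plain text, written into the output directory).
FILES = {
    "associations": "associations.tsv",
    "ld_panel": "ld_panel.tsv",
    "variant_links": "variant_gene_links.tsv",
    "eqtl": "eqtl_blood.tsv",
    "go_bp": "go_bp.gmt",
    "go_cc": "go_cc.gmt",
    "go_mf": "go_mf.gmt",
    "pid": "pid_genes.txt",
    "network_edges": "disease_edges.tsv",
    "expression": "expression_tpm.tsv",
    "tissue_map": "tissue_map.tsv",
    "config": "pipeline_config.yaml",
    "ground_truth": "ground_truth.json",
}


@dataclass(slots=True)
class SimulationConfig:
    """Knobs of the synthetic bundle.

    The paper-scale preset mirrors the study's stage magnitudes
    (689 associations / 458 significant / 4430 LD-expanded / 334 genes);
    the mini preset keeps the same structure at sub-second size.
    """

    seed: int = 42
    n_snps: int = 689
    n_significant: int = 458
    n_expanded: int = 4430
    n_genes: int = 334
    top_n: int = 40
    planted_biomarkers: tuple[str, ...] = ("THBD", "F5")
    liver_genes: tuple[str, ...] = ("F2", "F9", "PROC")
    n_coag_extra: int = 10
    n_risk_other: int = 13
    n_filler_genes: int = 600
    n_samples_per_tissue: int = 30
    alpha: float = 5e-8
    r2_min: float = 0.8
    population: str = "ASN"
    fdr: float = 0.05
    min_overlap: int = 2
    min_score: int = 3
    tpm_min: float = 1.0
    # log-normal location/scale (natural log of TPM) per gene class & tissue
    blood_biomarker_mu: float = 3.0
    blood_biomarker_sigma: float = 0.25
    liver_gene_mu: float = 5.0
    liver_gene_blood_mu: float = -2.0
    background_mu: float = 0.7
    lognormal_sigma: float = 0.4

    def __post_init__(self) -> None:
        if self.n_significant > self.n_snps:
            raise ValueError("n_significant must be <= n_snps")
        if self.top_n > self.n_significant:
            raise ValueError("top_n must be <= n_significant")
        if self.n_expanded < self.n_significant:
            raise ValueError("n_expanded must be >= n_significant")
        n_named = len(self.planted_biomarkers) + len(self.liver_genes)
        if n_named + self.n_coag_extra + self.n_risk_other > self.n_genes:
            raise ValueError("gene classes exceed the gene pool")
        if not self.planted_biomarkers and not self.liver_genes:
            raise ValueError("at least one top-locus gene class must be non-empty")


def paper_scale(seed: int = 42) -> SimulationConfig:
    """The study-scale conditions: 689/458/4430/334 and 28/15/5/2 downstream."""
    return SimulationConfig(seed=seed)


def mini(seed: int = 42) -> SimulationConfig:
    """A structurally identical bundle that generates and runs in well under a second."""
    return SimulationConfig(
        seed=seed,
        n_snps=60,
        n_significant=30,
        n_expanded=90,
        n_genes=20,
        top_n=10,
        liver_genes=("F2",),
        n_coag_extra=2,
        n_risk_other=2,
        n_filler_genes=80,
        n_samples_per_tissue=8,
    )


@dataclass(slots=True)
class GroundTruth:
    """Per-stage expected sets, derivable from the planted evidence."""

    significant_rsids: list[str]
    expanded_rsids: list[str]
    mapped_genes: list[str]
    top_genes: list[str]
    flags: dict[str, dict[str, int]]
    risk_genes: list[str]
    coag_genes: list[str]
    network_genes: list[str]
    biomarkers: list[str]
    counts: dict[str, int]
    #: evidence types whose single removal must drop a planted gene from
    #: the final selection
    required_evidence: dict[str, list[str]] = field(default_factory=dict)
    #: gene -> missense proxy rsid (for strict-r² boundary experiments)
    missense_proxy: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=1, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as handle:
            return cls(**json.load(handle))


def _gene_pool(config: SimulationConfig) -> dict[str, list[str]]:
    """Partition the gene pool into evidence classes (deterministic)."""
    named = list(config.planted_biomarkers) + list(config.liver_genes)
    n_auto = config.n_genes - len(named)
    auto = [f"GENE{i:04d}" for i in range(1, n_auto + 1)]
    coag_extra = auto[: config.n_coag_extra]
    risk_other = auto[config.n_coag_extra : config.n_coag_extra + config.n_risk_other]
    decoys = auto[config.n_coag_extra + config.n_risk_other :]
    return {
        "biomarker": list(config.planted_biomarkers),
        "liver": list(config.liver_genes),
        "coag_extra": coag_extra,
        "risk_other": risk_other,
        "decoy": decoys,
    }


def _log_uniform(rng: np.random.Generator, low: float, high: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(low), np.log(high), size=size))


def generate_bundle(config: SimulationConfig, out_dir: str | Path) -> GroundTruth:
    """Write a coherent input bundle to ``out_dir`` and return its ground truth.

    Identical configs produce byte-identical bundles.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    classes = _gene_pool(config)
    top_locus_genes = classes["biomarker"] + classes["liver"]
    other_genes = classes["coag_extra"] + classes["risk_other"] + classes["decoy"]
    all_genes = top_locus_genes + other_genes

    # --- gene loci: one chromosome/base per gene ----------------------
    chroms = [str(c) for c in (1, 4, 9, 13, 20)]  # strongest loci first
    gene_chrom: dict[str, str] = {}
    gene_base: dict[str, int] = {}
    for i, gene in enumerate(all_genes):
        gene_chrom[gene] = chroms[i % len(chroms)] if i < len(top_locus_genes) else str(
            (i % 22) + 1
        )
        gene_base[gene] = 1_000_000 + i * 800_000

    # --- associations ---------------------------------------------------
    n_top = config.top_n
    n_sig = config.n_significant
    p_top = np.sort(_log_uniform(rng, 1e-30, 1e-20, n_top))
    p_sig_rest = np.sort(_log_uniform(rng, 1e-18, config.alpha * 0.99, n_sig - n_top))
    p_nonsig = _log_uniform(rng, config.alpha * 1.01, 0.9, config.n_snps - n_sig)
    pvalues = np.concatenate([p_top, p_sig_rest, p_nonsig])

    seed_rsids = [f"rs{100000 + i}" for i in range(config.n_snps)]
    seed_gene: dict[str, str] = {}
    for i in range(n_sig):
        if i < n_top:
            gene = top_locus_genes[i % len(top_locus_genes)]
        else:
            gene = other_genes[(i - n_top) % len(other_genes)]
        seed_gene[seed_rsids[i]] = gene
    for i in range(n_sig, config.n_snps):
        seed_gene[seed_rsids[i]] = all_genes[int(rng.integers(0, len(all_genes)))]

    snp_offset: dict[str, int] = {}
    assocs: list[io_gwas.SnpAssociation] = []
    for i, rsid in enumerate(seed_rsids):
        gene = seed_gene[rsid]
        snp_offset[gene] = snp_offset.get(gene, 0) + 400
        assocs.append(
            io_gwas.SnpAssociation(
                rsid=rsid,
                chrom=gene_chrom[gene],
                pos=gene_base[gene] + snp_offset[gene],
                pvalue=float(pvalues[i]),
                trait="deep vein thrombosis",
                mapped_genes=(gene,),
                study_id=f"GCST{90000 + i % 7}",
            )
        )
    io_gwas.write_associations(assocs, out / FILES["associations"])

    # --- LD panel -------------------------------------------------------
    sig_seeds = seed_rsids[:n_sig]
    n_proxies = config.n_expanded - n_sig
    panel: list[ld_expand.LdProxy] = []
    proxy_gene: dict[str, str] = {}
    proxies_of_seed: dict[str, list[str]] = {s: [] for s in sig_seeds}
    for j in range(n_proxies):
        seed = sig_seeds[j % n_sig]
        proxy = f"rs{500000 + j}"
        panel.append(
            ld_expand.LdProxy(
                seed_rsid=seed,
                proxy_rsid=proxy,
                r2=float(np.round(rng.uniform(0.82, 0.99), 4)),
                population=config.population,
            )
        )
        proxy_gene[proxy] = seed_gene[seed]
        proxies_of_seed[seed].append(proxy)
    # sub-threshold and off-population rows: never part of the expansion
    for j, seed in enumerate(sig_seeds[: min(n_sig, 40)]):
        panel.append(
            ld_expand.LdProxy(
                seed_rsid=seed,
                proxy_rsid=f"rs{900000 + j}",
                r2=float(np.round(rng.uniform(0.2, 0.79), 4)),
                population=config.population,
            )
        )
        panel.append(
            ld_expand.LdProxy(
                seed_rsid=seed,
                proxy_rsid=f"rs{950000 + j}",
                r2=0.95,
                population="EUR",
            )
        )
    ld_expand.write_ld_panel(panel, out / FILES["ld_panel"])

    expanded = sorted(set(sig_seeds) | set(proxy_gene))

    # --- variant-gene links (with planted missense proxies) -------------
    missense_proxy: dict[str, str] = {}
    missense_classes = classes["biomarker"] + classes["liver"] + classes["risk_other"]
    gene_first_seed: dict[str, str] = {}
    for seed in sig_seeds:
        gene_first_seed.setdefault(seed_gene[seed], seed)
    for gene in missense_classes:
        seed = gene_first_seed[gene]
        candidates = proxies_of_seed[seed]
        missense_proxy[gene] = candidates[0] if candidates else seed
    missense_snps = set(missense_proxy.values())
    links = [
        ld_expand.VariantGeneLink(
            rsid=rsid,
            gene=seed_gene.get(rsid, proxy_gene.get(rsid, "")),
            consequence="missense" if rsid in missense_snps else "other",
        )
        for rsid in expanded
    ]
    ld_expand.write_variant_links(links, out / FILES["variant_links"])

    # --- whole-blood eQTLs ----------------------------------------------
    decoy_eqtl = classes["decoy"][: len(classes["decoy"]) // 3]
    eqtl_rows: list[tuple[str, str, int]] = []
    for gene in classes["biomarker"] + classes["coag_extra"] + decoy_eqtl:
        eqtl_rows.append((gene, gene_first_seed[gene], 1))
    for gene in classes["liver"]:  # tested but non-significant in blood
        eqtl_rows.append((gene, gene_first_seed[gene], 0))
    with open(out / FILES["eqtl"], "w") as handle:
        handle.write("gene\trsid\tsignificant\n")
        for gene, rsid, flag in eqtl_rows:
            handle.write(f"{gene}\t{rsid}\t{flag}\n")

    # --- GO collections ---------------------------------------------------
    filler = [f"FILLER{i:04d}" for i in range(1, config.n_filler_genes + 1)]
    coag15 = classes["biomarker"] + classes["liver"] + classes["coag_extra"]
    half = max(1, len(classes["coag_extra"]) // 2)
    third = len(filler) // 3
    bp_filler, cc_filler, mf_filler = filler[:third], filler[third : 2 * third], filler[2 * third :]

    def decoy_terms(pool: list[str], prefix: str, count: int, size: int):
        terms = []
        for t in range(count):
            members = [pool[(t * 7 + m) % len(pool)] for m in range(size)]
            terms.append(
                enrich_mod.GeneSetTerm(
                    term_id=f"{prefix}:{9000 + t}",
                    name=f"{prefix.lower()} background process {t}",
                    namespace=prefix,
                    members=frozenset(members),
                )
            )
        return terms

# planted terms contain exactly their planted genes: the enrichment
    # signal is the point, term-size realism is not (see methods note)
    bp_terms = [
        enrich_mod.GeneSetTerm("GO:0050817", "coagulation", "BP", frozenset(coag15)),
        enrich_mod.GeneSetTerm(
            "GO:1903034",
            "regulation of response to wounding",
            "BP",
            frozenset(classes["biomarker"] + classes["liver"] + classes["coag_extra"][:half]),
        ),
        enrich_mod.GeneSetTerm(
            "GO:0042060",
            "wound healing",
            "BP",
            frozenset(classes["biomarker"] + classes["liver"] + classes["coag_extra"][half:]),
        ),
        *decoy_terms(bp_filler, "BP", 12, min(30, len(bp_filler))),
    ]
    cc_terms = list(decoy_terms(cc_filler, "CC", 8, min(25, len(cc_filler))))
    if classes["risk_other"]:
        cc_terms.insert(
            0,
            enrich_mod.GeneSetTerm(
                "GO:0031093", "platelet alpha granule lumen", "CC",
                frozenset(classes["risk_other"]),
            ),
        )
    mf_terms = list(decoy_terms(mf_filler, "MF", 8, min(25, len(mf_filler))))
    if classes["coag_extra"]:
        mf_terms.insert(
            0,
            enrich_mod.GeneSetTerm(
                "GO:0008236", "serine-type peptidase activity", "MF",
                frozenset(classes["coag_extra"]),
            ),
        )
    enrich_mod.write_gmt(bp_terms, out / FILES["go_bp"])
    enrich_mod.write_gmt(cc_terms, out / FILES["go_cc"])
    enrich_mod.write_gmt(mf_terms, out / FILES["go_mf"])

    # --- PID list ---------------------------------------------------------
    decoy_pid = classes["decoy"][
        len(classes["decoy"]) // 3 : len(classes["decoy"]) // 3 + max(1, len(classes["decoy"]) // 6)
    ]
    pid_genes = sorted(set(classes["risk_other"] + decoy_pid + filler[:10]))
    with open(out / FILES["pid"], "w") as handle:
        handle.write("# synthetic primary immunodeficiency gene list\n")
        for gene in pid_genes:
            handle.write(gene + "\n")

    # --- disease network ---------------------------------------------------
    edges: list[tuple[str, str, str, str]] = []
    network_genes = classes["biomarker"] + classes["liver"]
    for gene in network_genes:
        edges.append((gene, "DOID:DVT", "Deep vein thrombosis", "disease"))
    for gene in classes["biomarker"]:
        edges.append((gene, "DOID:THPH", "Thrombophilia", "disease"))
    for gene in classes["coag_extra"] + classes["risk_other"]:
        edges.append((gene, "HP:0001892", "Abnormal bleeding", "phenotype"))
    for gene in classes["decoy"][:3]:
        edges.append((gene, "DOID:DVT", "Deep vein thrombosis", "disease"))
    with open(out / FILES["network_edges"], "w") as handle:
        handle.write("gene\tconcept_id\tconcept_label\tsource\n")
        for row in edges:
            handle.write("\t".join(row) + "\n")

    # --- expression matrix --------------------------------------------------
    n_s = config.n_samples_per_tissue
    blood_samples = [f"BLD{i:03d}" for i in range(1, n_s + 1)]
    liver_samples = [f"LIV{i:03d}" for i in range(1, n_s + 1)]
    with open(out / FILES["tissue_map"], "w") as handle:
        handle.write("sample\ttissue\n")
        for s in blood_samples:
            handle.write(f"{s}\tWhole Blood\n")
        for s in liver_samples:
            handle.write(f"{s}\tLiver\n")

    def draw(mu: float, sigma: float, size: int) -> np.ndarray:
        return np.round(np.exp(rng.normal(mu, sigma, size=size)), 4)

    with open(out / FILES["expression"], "w") as handle:
        handle.write("gene\t" + "\t".join(blood_samples + liver_samples) + "\n")
        for gene in all_genes:
            if gene in classes["biomarker"]:
                blood = draw(config.blood_biomarker_mu, config.blood_biomarker_sigma, n_s)
                liver = draw(2.0, config.lognormal_sigma, n_s)
            elif gene in classes["liver"]:
                blood = draw(config.liver_gene_blood_mu, 0.5, n_s)
                liver = draw(config.liver_gene_mu, config.lognormal_sigma, n_s)
            else:
                blood = draw(config.background_mu, 0.5, n_s)
                liver = draw(config.background_mu, 0.5, n_s)
            values = "\t".join(f"{v:.4f}" for v in np.concatenate([blood, liver]))
            handle.write(f"{gene}\t{values}\n")

    # --- pipeline config (thresholds travel with the bundle) ----------------
    pipeline_cfg = {
        "alpha": config.alpha,
        "top_n": config.top_n,
        "r2_min": config.r2_min,
        "population": config.population,
        "min_score": config.min_score,
        "fdr": config.fdr,
        "min_overlap": config.min_overlap,
        "tpm_min": config.tpm_min,
        "term_labels": list(COAG_TERM_NAMES),
        "disease_labels": list(DISEASE_LABELS),
        "inputs": {
            key: FILES[key]
            for key in (
                "associations", "ld_panel", "variant_links", "eqtl",
                "go_bp", "go_cc", "go_mf", "pid", "network_edges",
                "expression", "tissue_map",
            )
        },
    }
    with open(out / FILES["config"], "w") as handle:
        yaml.safe_dump(pipeline_cfg, handle, sort_keys=True)

    # --- ground truth ---------------------------------------------------------
    flags: dict[str, dict[str, int]] = {}
    for gene in all_genes:
        flags[gene] = {
            "top_gwas": int(gene in top_locus_genes),
            "missense_ld": int(gene in missense_classes),
            "blood_eqtl": int(
                gene in classes["biomarker"] + classes["coag_extra"] + decoy_eqtl
            ),
            "go_bp": int(gene in coag15),
            "go_cc": int(gene in classes["risk_other"]),
            "go_mf": int(gene in classes["coag_extra"]),
            "pid": int(gene in pid_genes),
        }
    risk = sorted(
        (g for g, f in flags.items() if sum(f.values()) >= config.min_score),
        key=lambda g: (-sum(flags[g].values()), g),
    )
    truth = GroundTruth(
        significant_rsids=sorted(sig_seeds),
        expanded_rsids=expanded,
        mapped_genes=sorted(all_genes),
        top_genes=sorted(top_locus_genes),
        flags=flags,
        risk_genes=risk,
        coag_genes=sorted(coag15),
        network_genes=sorted(network_genes),
        biomarkers=sorted(classes["biomarker"]),
        counts={
            "n_snps": config.n_snps,
            "n_significant": n_sig,
            "n_expanded": config.n_expanded,
            "n_genes": config.n_genes,
            "n_risk_genes": len(risk),
            "n_coag_genes": len(coag15),
            "n_network_genes": len(network_genes),
            "n_biomarkers": len(classes["biomarker"]),
        },
        required_evidence={
            gene: ["blood_eqtl", "go_coagulation", "network_edge", "blood_expression"]
            for gene in classes["biomarker"]
        },
        missense_proxy=missense_proxy,
    )
    truth.to_json(out / FILES["ground_truth"])
    return truth


#: Evidence types understood by :func:`ablate_evidence`.
ABLATABLE = (
    "blood_eqtl",
    "go_coagulation",
    "network_edge",
    "blood_expression",
    "missense_r2_boundary",
)


def ablate_evidence(bundle_dir: str | Path, gene: str, evidence: str,
                    truth: GroundTruth | None = None) -> None:
    """Remove one evidence type for one gene from a bundle, in place.

    Supported ablations: drop the gene's whole-blood eQTL records; remove
    it from the coagulation/wound-healing GO terms; cut its direct
    disease edges; collapse its blood expression to trace level; or set
    its missense proxy's r² to exactly the 0.80 threshold (which the
    strictly-greater rule must exclude). Used by the recovery battery to
    check that each load-bearing evidence type is genuinely required.
    """
    bundle = Path(bundle_dir)
    symbol = gene.strip().upper()
    if evidence == "blood_eqtl":
        path = bundle / FILES["eqtl"]
        lines = path.read_text().splitlines()
        kept = [l for l in lines if l.startswith(("gene\t", "#")) or l.split("\t")[0] != symbol]
        path.write_text("\n".join(kept) + "\n")
    elif evidence == "go_coagulation":
        path = bundle / FILES["go_bp"]
        out_lines = []
        for line in path.read_text().splitlines():
            fields = line.split("\t")
            if len(fields) >= 3 and fields[1].strip().lower() in {n.lower() for n in COAG_TERM_NAMES}:
                fields = fields[:2] + [g for g in fields[2:] if g != symbol]
            out_lines.append("\t".join(fields))
        path.write_text("\n".join(out_lines) + "\n")
    elif evidence == "network_edge":
        path = bundle / FILES["network_edges"]
        wanted = {l.lower() for l in DISEASE_LABELS}
        kept = []
        for line in path.read_text().splitlines():
            fields = line.split("\t")
            if (
                len(fields) == 4
                and fields[0] == symbol
                and fields[2].strip().lower() in wanted
            ):
                continue
            kept.append(line)
        path.write_text("\n".join(kept) + "\n")
    elif evidence == "blood_expression":
        import pandas as pd

        matrix = pd.read_csv(bundle / FILES["expression"], sep="\t", index_col=0)
        tissue = pd.read_csv(bundle / FILES["tissue_map"], sep="\t")
        blood = tissue.loc[tissue["tissue"] == "Whole Blood", "sample"]
        matrix.loc[symbol, list(blood)] = 0.01
        matrix.to_csv(bundle / FILES["expression"], sep="\t", float_format="%.4f")
    elif evidence == "missense_r2_boundary":
        if truth is None or symbol not in truth.missense_proxy:
            raise ValueError(f"no missense proxy recorded for {symbol}")
        proxy = truth.missense_proxy[symbol]
        path = bundle / FILES["ld_panel"]
        out_lines = []
        for line in path.read_text().splitlines():
            fields = line.split("\t")
            if len(fields) == 4 and fields[1] == proxy:
                fields[2] = "0.8000"
            out_lines.append("\t".join(fields))
        path.write_text("\n".join(out_lines) + "\n")
    else:
        raise ValueError(f"unknown evidence type {evidence!r}; expected one of {ABLATABLE}")


def verify_recovery(truth: GroundTruth, report) -> dict[str, dict]:
    """Compare a pipeline :class:`~dvtpipe.pipeline.StageReport` to ground truth.

    Returns a per-stage dict with ``pass`` plus the expected/observed
    values, so a divergence is localized to the first stage it appears in.
    """
    checks: dict[str, dict] = {}

    def check(stage: str, expected, observed) -> None:
        checks[stage] = {
            "pass": expected == observed,
            "expected": expected,
            "observed": observed,
        }

    check("significant", truth.counts["n_significant"], report.counts["n_significant"])
    check("expanded", truth.counts["n_expanded"], report.counts["n_expanded"])
    check("mapped_genes", sorted(truth.mapped_genes), sorted(report.mapped_genes))
    check("risk_genes", sorted(truth.risk_genes), sorted(report.risk_genes))
    check("coag_genes", sorted(truth.coag_genes), sorted(report.coag_genes))
    check("network_genes", sorted(truth.network_genes), sorted(report.network_genes))
    check("biomarkers", sorted(truth.biomarkers), sorted(report.selected_biomarkers))
    checks["all"] = {"pass": all(c["pass"] for c in checks.values())}
    return checks
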