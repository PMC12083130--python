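# dvtpipe

Offline GWAS post-processing pipeline for prioritizing **blood-based
biomarkers of deep vein thrombosis (DVT)**.

Deep vein thrombosis is a polygenic disorder: genome-wide association
studies report hundreds of SNP–trait associations around coagulation
genes, but a clinically useful biomarker must also be *measurable in
blood*. `dvtpipe` implements the full prioritization chain that turns a
catalog of SNP associations into a short list of practical blood
biomarkers, as a tested, reusable library that runs entirely from local
files (no web-service queries):

1. **Significance filter** — keep catalog associations with
   p < 5×10⁻⁸ (genome-wide significance, strict inequality), and cut
   the top-*N* SNPs of the Manhattan plot (default *N* = 40).
2. **LD proxy expansion** — expand the significant SNPs with every
   panel variant in strong linkage disequilibrium (r² > 0.8, strict) in
   a chosen population (default ASN), then invert the expanded SNP set
   into a gene → SNP map.
3. **Seven-criterion scorecard** — flag each candidate gene for:
   top-GWAS locus, missense variant among its SNPs/LD proxies,
   whole-blood eQTL, membership in a significantly enriched GO
   biological-process / cellular-component / molecular-function term,
   and presence on the primary-immunodeficiency (IUIS-style) gene
   list. Genes scoring ≥ 3 of 7 are *biological risk genes*.
4. **Over-representation analysis** — hypergeometric upper-tail test
   of the risk set against GMT collections. For a universe of N genes,
   K in a term, and a query of n genes overlapping in k:
   p = P(X ≥ k), X ~ Hypergeometric(N, K, n), with
   enrichment ratio (k/n)/(K/N) and Benjamini–Hochberg FDR control
   (significant at q ≤ 0.05). Genes in the significant
   coagulation / response-to-wounding / wound-healing terms go forward.
5. **Disease-network filter** — keep genes with a *direct* edge to a
   DVT or thrombophilia concept in a gene–disease/phenotype bipartite
   graph.
6. **Biomarker call** — summarize liver vs whole-blood expression
   (median/IQR of TPM) and select genes satisfying
   `has_whole_blood_eQTL AND blood_median_TPM ≥ 1.0`.

A synthetic-data generator (`dvtpipe.simulate`) emulates all seven
input sources with planted ground truth, so the whole chain is testable
without downloads; its study-scale preset reproduces the reference
reduction 689 → 458 → 4430 → 334 → 28 → 15 → 5 → 2.

## Worked example

The package ships small synthetic reconstructions of the workflow's
published worked example (files marked `.synthetic.`):

```python
from dvtpipe import enrich, expression, fixtures, network, scorecard

profiles = scorecard.read_scorecard(fixtures.scorecard_path())
risk = scorecard.risk_genes(profiles, min_score=3)
print(len(risk), {g: s for g, s in ((p.gene, p.score) for p in profiles) if s >= 5})

terms = enrich.read_gmt(fixtures.go_bp_path(), "BP")
results = enrich.enrich(risk, terms, fdr=0.05, min_overlap=2)
coag = enrich.genes_in_terms(
    risk, results, terms,
    enrich.name_filter(["coagulation", "regulation of response to wounding", "wound healing"]),
)
linked = network.direct_disease_genes(network.read_edges(fixtures.network_edges_path()), coag)
matrix, tissues = expression.read_expression(fixtures.expression_path(), fixtures.tissue_map_path())
summaries = [s for g in sorted(linked) for s in expression.tissue_summary(matrix, tissues, g)]
calls = expression.call_biomarkers(linked, summaries, scorecard.read_eqtl_genes(fixtures.eqtl_path()))
print(sorted(coag), sorted(linked), expression.selected_genes(calls))
```

prints

```
28 {'IL6R': 6, 'F5': 5, 'ABO': 5}
['ADAMTS13', 'F11', 'F2', 'F5', 'F9', 'FGA', 'FGB', 'KLKB1', 'PLCG2', 'PLEK', 'PROC', 'SH2B3', 'ST3GAL4', 'THBD', 'VWF'] ['F2', 'F5', 'F9', 'PROC', 'THBD'] {'THBD', 'F5'}
```

i.e. 28 risk genes at score ≥ 3 (IL6R highest at 6), 15 genes in the
significantly enriched coagulation/wound-healing terms, 5 genes with
direct DVT/thrombophilia links, and the final blood-biomarker pair
**THBD** (thrombomodulin) and **F5** (coagulation factor V) — the two
candidates that combine whole-blood eQTL evidence with robust blood
expression, whereas F2, F9 and PROC are liver-dominant.

Run the same chain end to end on a generated bundle:

```bash
dvtpipe simulate --seed 42 --out-dir bundle --preset paper-scale
dvtpipe run --config bundle/pipeline_config.yaml --out-dir out
# {"stage_counts": [689, 458, 4430, 334, 28, 15, 5, 2], "selected": ["F5", "THBD"]}
```

## Layout

| module | role |
| --- | --- |
| `dvtpipe.io_gwas` | association TSV ingestion, significance filter, top-SNP cut, Manhattan coordinates |
| `dvtpipe.ld_expand` | LD panel reading, r² > 0.8 proxy expansion, SNP→gene mapping |
| `dvtpipe.scorecard` | seven-criterion profiles, score ≥ 3 risk-gene call |
| `dvtpipe.enrich` | hypergeometric ORA, BH-FDR, GMT I/O, term-gene extraction |
| `dvtpipe.network` | bipartite gene–concept graph, direct-disease-link filter |
| `dvtpipe.expression` | tissue summaries, eQTL + detectability biomarker call |
| `dvtpipe.simulate` | synthetic bundle generator, ground truth, ablations |
| `dvtpipe.pipeline` | end-to-end orchestration and stage report |
| `dvtpipe.cli` | `dvtpipe` command-line entry point |

See `docs/methods.md` for modeling assumptions, parameter defaults and
known limitations.
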