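# Methods

## The prioritization model

`dvtpipe` treats biomarker discovery as a chain of auditable set
reductions over a SNP-association catalog. Each stage has a single
decision rule with an explicit threshold; every intermediate is
materialized as a TSV so the chain can be inspected stage by stage.

**Significance filter.** Associations are kept when p < α with
α = 5×10⁻⁸, the conventional genome-wide significance level. The
comparison is strict; a p-value exactly at α is excluded. Duplicate
rsIDs reported by different studies are retained at this stage — SNP
counting follows catalog rows — and deduplicated only when the seed set
for LD expansion is formed.

**Top-SNP cut.** The top-*N* rule (default N = 40) selects the SNPs
with smallest p-values; the mapped genes of those SNPs receive
criterion 1 of the scorecard. "Visual prominence" on a Manhattan plot
is not machine-checkable, so ties at the boundary break
deterministically by (chromosome order, position, rsID). The p-value of
the N-th SNP (the plot's second threshold line) is always computed,
never a constant. Manhattan coordinates place chromosomes 1–22, X, Y on
a cumulative axis whose per-chromosome span is the largest observed
position; this is plot layout only and has no analytic role.

**LD expansion.** Seeds are expanded with every panel proxy satisfying
r² > 0.8 (strict) in the selected population (exact label match,
default ASN). A seed is trivially its own proxy, so the expanded set
always contains the seeds; seeds absent from the panel pass through
unexpanded. The package performs no LD computation from genotypes: the
panel is an input file, standing in for an LD server snapshot whose
backing reference-panel release is generally unrecoverable — which is
also why expanded-set counts are only meaningful relative to a given
panel file.

**Scorecard.** Seven binary criteria per gene: (1) top-GWAS locus
membership; (2) a missense consequence on an associated SNP or any of
its r² > 0.8 proxies; (3) a significant whole-blood eQTL; (4–6)
membership in at least one GO term of the namespace (BP/CC/MF) that is
*significantly enriched* in the mapped gene set at FDR ≤ 0.05 — raw GO
membership alone would flag nearly every gene and make the criteria
uninformative; (7) presence on a primary-immunodeficiency gene list,
probing immune–coagulation overlap. Flags are binary regardless of
evidence multiplicity; multiplicity is kept only in provenance. The
risk-gene rule is score ≥ 3 (non-strict).

**Over-representation.** For universe size N, term size K, query size
n and overlap k, p = P(X ≥ k) under X ~ Hypergeometric(N, K, n),
computed via the survival function (log-space stable; the upper tail
includes k). The enrichment ratio is (k/n)/(K/N); it is reported as
missing when the expectation is zero. BH adjustment is the classic
step-up procedure (via `statsmodels.multipletests`, checked in the test
suite against a hand-written definitional oracle); significance is
q ≤ 0.05, non-strict. The universe defaults to all genes annotated in
the loaded collection (an "annotated genome" reference) and is
configurable; query genes outside the universe are dropped from the
test. Terms overlapping the query in fewer than `min_overlap` genes
(default 2) are untested and excluded from the BH family, matching
common ORA practice and avoiding singleton noise.

**Network filter.** "Direct disease link" is operationalized as edge
incidence between a gene node and a concept node whose label matches a
target set (default {"deep vein thrombosis", "thrombophilia"},
case-insensitive). No statistic beyond adjacency is applied because the
underlying knowledge graphs supply no edge weights. A gene qualifies
via either a disease-ontology or a phenotype-ontology concept; an
optional `sources` argument restricts this.

**Biomarker call.** Per gene and tissue the summary is the median and
IQR of TPM across samples — the median, not the mean, because blood
expression of hepatocyte-made factors is strongly right-skewed across
individuals. Selection is the conjunction
`has_blood_eqtl AND blood_median_tpm ≥ tpm_min` with `tpm_min` = 1.0
TPM by default. The eQTL requirement encodes the argument that a
useful blood biomarker's variation must be visible in blood; the
detectability threshold is a configuration knob, since "substantial
expression" is otherwise qualitative.

## Synthetic data: what it emulates and what it does not

`dvtpipe.simulate.generate_bundle` writes all seven input files from
one seeded NumPy generator (identical seed ⇒ byte-identical bundle).
Gene classes plant a known answer:

* **biomarker class** (default THBD, F5): top-ranked SNPs, a missense
  proxy at r² ∈ (0.82, 0.99), a significant whole-blood eQTL,
  coagulation-term membership, direct DVT/thrombophilia edges, and
  blood-shifted expression (log-normal, location e³ ≈ 20 TPM,
  scale 0.25 — chosen so the blood median clears the 1.0 TPM threshold
  by more than twice the IQR);
* **liver class** (default F2, F9, PROC): identical upstream evidence
  but no blood eQTL and trace blood expression (location e⁻² ≈ 0.14
  TPM) against strong liver expression (e⁵ ≈ 150 TPM), mimicking
  hepatocyte-made coagulation factors;
* **coagulation/annotation decoy classes**: exactly three criteria each
  (reaching the risk set but failing later stages);
* **background decoys**: at most two criteria.

P-values are drawn log-uniformly within bands — top SNPs in
[10⁻³⁰, 10⁻²⁰), other significant SNPs in [10⁻¹⁸, α), the rest above
α — because the pipeline consumes only ranks and threshold crossings;
no genetic effect-size model is implied. LD fan-out is distributed
round-robin so every seed has at least one proxy; sub-threshold and
off-population rows are included to exercise both filters. Planted GO
terms contain exactly their planted genes, which makes their
enrichment robust at every bundle scale; term-size realism is
deliberately sacrificed, and the background terms carry filler genes
only. The study-scale preset fixes the stage magnitudes
(689/458/4430/334 → 28/15/5/2) by construction; the mini preset keeps
the identical structure at sub-second cost and uses a top-10 cut
(60 SNPs would otherwise push the top-40 cut below the significance
floor and hand criterion-1 flags to decoys).

Consequently, passing the recovery battery shows that every decision
rule implements its contract and that each load-bearing evidence type
is genuinely required (ablating a planted gene's eQTL, coagulation-term
membership, disease edge or blood expression removes it from the final
selection; setting its missense proxy to r² = 0.80 exactly clears
criterion 2). It does **not** show robustness to the noise of real
catalogs: symbol aliasing, multi-gene and intergenic mappings beyond
the supported delimiters, population-specific LD structure, GO DAG
redundancy, or expression batch effects are not simulated. Removing a
planted gene's top-GWAS or missense evidence alone does *not* remove it
from the selection — its score drops from 4 to exactly the threshold 3
— so the ground truth records which evidence types are required per
gene, and the ablation battery iterates those.

## Packaged worked-example fixtures

The files under `dvtpipe/data/` (all marked `.synthetic.`) are
constructed stand-ins for the worked example's inputs, sized so the
documented results are reproduced exactly by computation: a 28-gene
scorecard whose named genes carry their published totals (IL6R 6; F5
and ABO 5; eleven genes 4; the rest 3, with whole-blood eQTL flags
present for THBD/F5 and absent for F2/F9/PROC), a GO BP collection
whose three coagulation/wound-healing terms intersect the risk set in
exactly 15 genes, a disease edge list linking exactly five of those to
DVT/thrombophilia concepts, and a five-gene expression/eQTL bundle in
which only THBD and F5 pass the blood rule.

## Numerical choices and degenerate inputs

* Threshold conventions: strict `<` for significance and `>` for r²;
  non-strict `≥`/`≤` for score, FDR and TPM detectability. All five are
  pinned by boundary tests.
* Hypergeometric tails use `scipy.stats.hypergeom.sf(k−1, N, K, n)`;
  the test suite verifies agreement with brute-force pmf summation on
  the exhaustive grid N ≤ 30.
* `bh_adjust` rejects p-values outside (0, 1]; an empty vector adjusts
  to an empty vector.
* Unparseable association rows (bad p-value, unknown chromosome,
  position < 1) are dropped and counted in a warning, not fatal;
  malformed LD-panel and edge-list rows are rejected row-wise with line
  numbers. A matrix sample missing from the tissue map is a
  configuration error (silent tissue misassignment would corrupt the
  biomarker call).
* A gene missing a blood or liver summary yields an error entry in the
  biomarker table while the remaining genes are still called.
* Biomarker output ordering: selected first, then blood median
  descending, then symbol; risk genes: score descending, then symbol.

## Limitations

* Gene-symbol alias resolution is out of scope; all sources must use
  consistent symbols (fixtures and bundles do).
* No GO DAG propagation or term-redundancy pruning; enrichment treats
  terms independently.
* No liftover between genome builds; positions are taken as given.
* The LD step cannot recompute a web service's historical expansion:
  counts tied to a particular catalog snapshot and panel release are
  reproducible only against a matching packaged panel file.
* Expression input must already be TPM; no normalization from raw
  counts is performed.
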