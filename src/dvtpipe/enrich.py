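"""Hypergeometric over-representation analysis with BH-FDR control.

A query gene set is tested against GMT gene-set collections (GO BP/CC/MF
in the main workflow). For a universe of N genes of which K belong to a
term, and a query of n genes overlapping the term in k, the p-value is
the upper tail P(X ≥ k) of Hypergeometric(N, K, n) and the enrichment
ratio is the observed/expected overlap (k/n)/(K/N). P-values are adjusted
with the Benjamini–Hochberg step-up procedure; terms at q ≤ FDR are
called significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(slots=True, frozen=True)
class GeneSetTerm:
    """One annotation term (GO term, disease, phenotype) with its members."""

    term_id: str
    name: str
    namespace: str  # BP, CC, MF, disease, phenotype
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id} has no members")


@dataclass(slots=True)
class EnrichmentResult:
    """One term's over-representation test."""

    term_id: str
    name: str
    k: int  # overlap
    K: int  # term size in universe
    n: int  # query size in universe
    N: int  # universe size
    ratio: float
    p: float
    q: float = field(default=1.0)

    @property
    def genes_hit(self) -> int:
        return self.k


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n), including k itself.

    Computed through the survival function, which works in log space and
    stays stable for genome-scale N.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric bounds k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrichment_ratio(k: int, K: int, n: int, N: int) -> float | None:
    """Observed/expected overlap (k/n)/(K/N); ``None`` if expectation is 0."""
    if K <= 0 or n <= 0 or N <= 0:
        return None
    return (k / n) / (K / N)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, original order kept."""
    if len(pvalues) == 0:
        return []
    arr = np.asarray(pvalues, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return [float(v) for v in q]


def normalize_symbols(genes: Iterable[str]) -> set[str]:
    """Upper-case, whitespace-stripped gene symbols."""
    return {g.strip().upper() for g in genes if g and g.strip()}


def read_gmt(path: str | Path, namespace: str) -> list[GeneSetTerm]:
    """Parse a GMT file (term_id TAB description TAB member...).

    Lines with fewer than three fields or no members are skipped.
    """
    terms: list[GeneSetTerm] = []
    seen: set[str] = set()
    with open(path) as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                continue
            term_id, name = fields[0], fields[1]
            members = frozenset(normalize_symbols(fields[2:]))
            if not members or term_id in seen:
                continue
            seen.add(term_id)
            terms.append(GeneSetTerm(term_id=term_id, name=name, namespace=namespace, members=members))
    return terms


def write_gmt(terms: Iterable[GeneSetTerm], path: str | Path) -> None:
    with open(path, "w") as handle:
        for term in terms:
            handle.write("\t".join([term.term_id, term.name, *sorted(term.members)]) + "\n")


def collection_universe(collection: Sequence[GeneSetTerm]) -> set[str]:
    """All genes annotated anywhere in a collection (the default universe)."""
    universe: set[str] = set()
    for term in collection:
        universe |= term.members
    return universe


def enrich(
    query: Iterable[str],
    collection: Sequence[GeneSetTerm],
    universe: Iterable[str] | None = None,
    fdr: float = 0.05,
    min_overlap: int = 2,
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in each term of ``collection``.

    The universe defaults to every gene annotated in the collection
    (an "annotated genome" reference). Query genes outside the universe
    are dropped from the test. Terms overlapping the query in fewer than
    ``min_overlap`` genes are untested and do not enter the BH family.
    Results are sorted by (q, p, term_id).
    """
    universe_set = (
        collection_universe(collection) if universe is None else normalize_symbols(universe)
    )
    if not universe_set:
        raise ValueError("enrichment universe is empty")
    query_set = normalize_symbols(query) & universe_set
    n = len(query_set)
    N = len(universe_set)

    results: list[EnrichmentResult] = []
    for term in collection:
        members = term.members & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & query_set)
        if k < min_overlap:
            continue
        p = hypergeom_upper_tail(k, K, n, N)
        ratio = enrichment_ratio(k, K, n, N)
        results.append(
            EnrichmentResult(
                term_id=term.term_id, name=term.name,
                k=k, K=K, n=n, N=N,
                ratio=float("nan") if ratio is None else ratio, p=p,
            )
        )
    if results:
        qvals = bh_adjust([r.p for r in results])
        for r, q in zip(results, qvals):
            r.q = q
    results.sort(key=lambda r: (r.q, r.p, r.term_id))
    return results


def significant_terms(
    results: Sequence[EnrichmentResult], fdr: float = 0.05
) -> list[EnrichmentResult]:
    """Terms at q ≤ fdr (non-strict, matching the FDR ≤ 0.05 convention)."""
    return [r for r in results if r.q <= fdr]


def flagged_genes(
    query: Iterable[str],
    results: Sequence[EnrichmentResult],
    collection: Sequence[GeneSetTerm],
    fdr: float = 0.05,
) -> set[str]:
    """Query genes belonging to at least one significantly enriched term.

    This is how GO-based annotation criteria are assigned: raw term
    membership alone would flag nearly every gene, so only terms enriched
    in the query at the FDR threshold count as evidence.
    """
    return genes_in_terms(query, results, collection, term_filter=lambda name: True, fdr=fdr)


def genes_in_terms(
    query: Iterable[str],
    results: Sequence[EnrichmentResult],
    collection: Sequence[GeneSetTerm],
    term_filter: Callable[[str], bool],
    fdr: float = 0.05,
) -> set[str]:
    """Union over significant, filter-passing terms of (members ∩ query)."""
    query_set = normalize_symbols(query)
    by_id = {term.term_id: term for term in collection}
    hits: set[str] = set()
    for result in significant_terms(results, fdr):
        term = by_id.get(result.term_id)
        if term is not None and term_filter(term.name):
            hits |= term.members & query_set
    return hits


def name_filter(names: Iterable[str]) -> Callable[[str], bool]:
    """A term filter matching any of ``names`` case-insensitively."""
    wanted = {n.strip().lower() for n in names}
    return lambda name: name.strip().lower() in wanted


def results_to_table(results: Sequence[EnrichmentResult]):
    """Enrichment results as a pandas DataFrame (for TSV export)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "term_id": r.term_id, "name": r.name, "k": r.k, "K": r.K,
                "n": r.n, "N": r.N, "ratio": r.ratio, "p": r.p, "q": r.q,
            }
            for r in results
        ]
    )
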