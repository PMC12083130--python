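"""Gene–disease/phenotype bipartite network filtering.

Candidate genes are kept when they have a direct edge to a target
disease concept (by default deep vein thrombosis or thrombophilia) in a
bipartite gene–concept graph assembled from an edge list. No statistic
beyond adjacency is applied: the evidence is the edge itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_DISEASE_LABELS: frozenset[str] = frozenset({"deep vein thrombosis", "thrombophilia"})


@dataclass(slots=True)
class BipartiteGraph:
    """Bipartite gene–concept graph backed by a :class:`networkx.Graph`.

    Gene nodes carry ``bipartite="gene"``; concept nodes are keyed by
    concept id and carry ``label`` and ``source`` ("disease"/"phenotype").
    """

    graph: nx.Graph

    @property
    def gene_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("bipartite") == "gene"}

    @property
    def concept_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("bipartite") == "concept"}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def concept_label(self, concept_id: str) -> str:
        return self.graph.nodes[concept_id].get("label", "")


def read_edges(path: str | Path) -> BipartiteGraph:
    """Assemble the bipartite graph from a TSV edge list.

    Columns: gene, concept_id, concept_label, source. Duplicate edges
    collapse; malformed rows are rejected with their line numbers.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"gene", "concept_id", "concept_label", "source"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"edge list {path} missing columns: {sorted(missing)}")
    graph = nx.Graph()
    for idx, row in table.iterrows():
        gene = str(row["gene"]).strip().upper()
        concept = str(row["concept_id"]).strip()
        if not gene or gene == "NAN" or not concept or concept == "nan":
            log.warning("%s line %d: malformed edge row rejected", path, idx + 2)
            continue
        graph.add_node(gene, bipartite="gene")
        graph.add_node(
            concept,
            bipartite="concept",
            label=str(row["concept_label"]).strip(),
            source=str(row["source"]).strip().lower(),
        )
        graph.add_edge(gene, concept)
    return BipartiteGraph(graph=graph)


def direct_disease_genes(
    graph: BipartiteGraph,
    query_genes: Iterable[str],
    disease_labels: Iterable[str] = DEFAULT_DISEASE_LABELS,
    sources: Iterable[str] | None = None,
) -> set[str]:
    """Query genes with a direct edge to a target disease/phenotype concept.

    Labels are matched case-insensitively. ``sources`` optionally
    restricts which concept sources ("disease", "phenotype") may supply
    the link; the default accepts either.
    """
    wanted = {l.strip().lower() for l in disease_labels}
    source_filter = None if sources is None else {s.strip().lower() for s in sources}
    target_concepts = {
        n
        for n, d in graph.graph.nodes(data=True)
        if d.get("bipartite") == "concept"
        and d.get("label", "").strip().lower() in wanted
        and (source_filter is None or d.get("source") in source_filter)
    }
    if not target_concepts:
        log.warning("no concept node matches disease labels %s", sorted(wanted))
        return set()
    query = {str(g).strip().upper() for g in query_genes}
    hits: set[str] = set()
    for gene in query & graph.gene_nodes:
        if any(neigh in target_concepts for neigh in graph.graph.neighbors(gene)):
            hits.add(gene)
    return hits


def write_edges(graph: BipartiteGraph, path: str | Path) -> None:
    """Export the graph back to the edge-list TSV dialect."""
    rows = []
    for gene, concept in sorted(graph.graph.edges()):
        if graph.graph.nodes[gene].get("bipartite") != "gene":
            gene, concept = concept, gene
        data = graph.graph.nodes[concept]
        rows.append(
            {
                "gene": gene,
                "concept_id": concept,
                "concept_label": data.get("label", ""),
                "source": data.get("source", ""),
            }
        )
    pd.DataFrame(rows, columns=["gene", "concept_id", "concept_label", "source"]).to_csv(
        path, sep="\t", index=False
    )
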