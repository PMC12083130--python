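"""Linkage-disequilibrium proxy expansion from a packaged LD panel.

Replaces a live HaploReg query: seed SNPs are expanded to every panel
proxy with r² strictly above a threshold (default 0.8) in a chosen
population, and the expanded set is inverted into a gene → SNP map via a
variant–gene consequence table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

log = logging.getLogger(__name__)

MISSENSE = "missense"


@dataclass(slots=True, frozen=True)
class LdProxy:
    """A seed→proxy link with its r² and panel population."""

    seed_rsid: str
    proxy_rsid: str
    r2: float
    population: str = "ASN"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 must be in [0, 1], got {self.r2!r}")


@dataclass(slots=True, frozen=True)
class VariantGeneLink:
    """A SNP mapped to a gene with a consequence class (missense/other)."""

    rsid: str
    gene: str
    consequence: str = "other"

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")


class GeneMapping(NamedTuple):
    """Gene → supporting SNPs, plus the SNPs with no link at all."""

    genes: dict[str, set[str]]
    unmapped: set[str]


def read_ld_panel(path: str | Path) -> list[LdProxy]:
    """Read an LD panel TSV (seed_rsid, proxy_rsid, r2, population).

    Rows whose r² is malformed or outside [0, 1] are rejected one by one,
    with their line numbers logged; valid rows are kept.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"seed_rsid", "proxy_rsid", "r2", "population"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"LD panel {path} missing columns: {sorted(missing)}")
    records: list[LdProxy] = []
    for idx, row in table.iterrows():
        line = idx + 2  # 1-based, after header
        try:
            r2 = float(row["r2"])
        except (TypeError, ValueError):
            log.warning("%s line %d: malformed r2 %r, row rejected", path, line, row["r2"])
            continue
        if not 0.0 <= r2 <= 1.0:
            log.warning("%s line %d: r2=%g outside [0, 1], row rejected", path, line, r2)
            continue
        records.append(
            LdProxy(
                seed_rsid=str(row["seed_rsid"]).strip(),
                proxy_rsid=str(row["proxy_rsid"]).strip(),
                r2=r2,
                population=str(row["population"]).strip(),
            )
        )
    return records


def write_ld_panel(panel: Iterable[LdProxy], path: str | Path) -> None:
    rows = [
        {"seed_rsid": p.seed_rsid, "proxy_rsid": p.proxy_rsid,
         "r2": f"{p.r2:.4f}", "population": p.population}
        for p in panel
    ]
    pd.DataFrame(rows, columns=["seed_rsid", "proxy_rsid", "r2", "population"]).to_csv(
        path, sep="\t", index=False
    )


def expand_snps(
    seeds: Iterable[str],
    panel: Sequence[LdProxy],
    r2_min: float = 0.8,
    population: str = "ASN",
) -> set[str]:
    """Seeds plus every panel proxy with r² strictly greater than ``r2_min``.

    A seed is trivially its own proxy (r² = 1), so the output always
    contains the seed set; seeds absent from the panel pass through
    unexpanded. The population filter is an exact label match.
    """
    if not 0.0 <= r2_min <= 1.0:
        raise ValueError(f"r2_min must be in [0, 1], got {r2_min!r}")
    seed_set = set(seeds)
    if not panel:
        log.warning("LD panel is empty; returning seeds unexpanded")
        return set(seed_set)
    expanded = set(seed_set)
    for link in panel:
        if link.population == population and link.seed_rsid in seed_set and link.r2 > r2_min:
            expanded.add(link.proxy_rsid)
    return expanded


def read_variant_links(path: str | Path) -> list[VariantGeneLink]:
    """Read a variant→gene consequence TSV (rsid, gene, consequence)."""
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"rsid", "gene", "consequence"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"variant link table {path} missing columns: {sorted(missing)}")
    records: list[VariantGeneLink] = []
    for idx, row in table.iterrows():
        gene = str(row["gene"]).strip().upper()
        if not gene or gene == "NAN":
            log.warning("%s line %d: empty gene symbol, row rejected", path, idx + 2)
            continue
        records.append(
            VariantGeneLink(
                rsid=str(row["rsid"]).strip(),
                gene=gene,
                consequence=str(row["consequence"]).strip().lower(),
            )
        )
    return records


def write_variant_links(links: Iterable[VariantGeneLink], path: str | Path) -> None:
    rows = [{"rsid": l.rsid, "gene": l.gene, "consequence": l.consequence} for l in links]
    pd.DataFrame(rows, columns=["rsid", "gene", "consequence"]).to_csv(
        path, sep="\t", index=False
    )


def map_to_genes(
    snps: Iterable[str], links: Sequence[VariantGeneLink]
) -> GeneMapping:
    """Invert a SNP set into gene → supporting-SNP sets.

    SNPs with no link in the table are returned separately in
    ``unmapped`` rather than silently dropped.
    """
    snp_set = set(snps)
    genes: dict[str, set[str]] = {}
    linked: set[str] = set()
    for link in links:
        if link.rsid in snp_set:
            genes.setdefault(link.gene, set()).add(link.rsid)
            linked.add(link.rsid)
    return GeneMapping(genes=genes, unmapped=snp_set - linked)


def missense_genes(
    snps: Iterable[str], links: Sequence[VariantGeneLink]
) -> set[str]:
    """Genes carrying a missense consequence on any SNP in ``snps``."""
    snp_set = set(snps)
    return {
        link.gene
        for link in links
        if link.consequence == MISSENSE and link.rsid in snp_set
    }
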