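"""Ingestion of GWAS-Catalog-style association tables.

Reads tab-separated association exports, applies the genome-wide
significance filter (conventionally p < 5×10⁻⁸), selects the strongest
SNPs, collects the genes they map to, and lays out Manhattan-plot
coordinates on a cumulative genome axis.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

#: Chromosome display order: autosomes 1..22 then X, Y.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_RANK: dict[str, int] = {c: i for i, c in enumerate(CHROMOSOMES)}

#: Default GWAS Catalog export column names.
DEFAULT_COLUMNS: dict[str, str] = {
    "rsid": "SNPS",
    "chrom": "CHR_ID",
    "pos": "CHR_POS",
    "pvalue": "P-VALUE",
    "mapped_genes": "MAPPED_GENE",
    "trait": "DISEASE/TRAIT",
    "study_id": "STUDY ACCESSION",
}

# Catalog dialects separate multi-gene cells with commas, semicolons,
# " - " (intergenic flanks, both genes kept) or " x " (interactions).
_GENE_SPLIT = re.compile(r",|;|\s-\s|\sx\s")


@dataclass(slots=True)
class SnpAssociation:
    """One catalog association row (SNP, locus, p-value, trait, genes)."""

    rsid: str
    chrom: str
    pos: int
    pvalue: float
    trait: str = ""
    mapped_genes: tuple[str, ...] = field(default_factory=tuple)
    study_id: str = ""

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if not 0 < self.pvalue <= 1:
            raise ValueError(f"pvalue must be in (0, 1], got {self.pvalue!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos!r}")
        if self.chrom not in _CHROM_RANK:
            raise ValueError(f"unknown chromosome label {self.chrom!r}")


@dataclass(slots=True)
class ManhattanPoint:
    """One SNP placed on the cumulative genome axis of a Manhattan plot."""

    rsid: str
    cumulative_x: int
    neglog10p: float
    chrom: str


class ColumnError(KeyError):
    """A required column is missing from an input table."""


def normalize_chrom(label: object) -> str | None:
    """Normalize a chromosome label; ``None`` if it is not 1–22/X/Y."""
    text = str(label).strip()
    if text.lower().startswith("chr"):
        text = text[3:]
    text = text.upper()
    if text in _CHROM_RANK:
        return text
    # tolerate catalog exports where positions arrive as floats ("9.0")
    try:
        as_int = str(int(float(text)))
    except ValueError:
        return None
    return as_int if as_int in _CHROM_RANK else None


def chrom_sort_key(chrom: str) -> int:
    """Rank of a normalized chromosome label in 1..22, X, Y order."""
    return _CHROM_RANK[chrom]


def split_gene_cell(cell: object) -> tuple[str, ...]:
    """Split a mapped-gene cell into an ordered, deduplicated symbol tuple.

    Handles the catalog's delimiter dialects (",", ";", " - ", " x ");
    intergenic "A - B" annotations yield both flanking genes. Symbols are
    upper-cased and stripped.
    """
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return ()
    out: list[str] = []
    for token in _GENE_SPLIT.split(str(cell)):
        symbol = token.strip().upper()
        if symbol and symbol not in out:
            out.append(symbol)
    return tuple(out)


def read_associations(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SnpAssociation]:
    """Read a tab-separated association table into :class:`SnpAssociation` rows.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Optional remapping of logical field names (keys of
        :data:`DEFAULT_COLUMNS`) to header names in the file.

    Rows whose p-value does not parse, is out of (0, 1], or whose
    chromosome/position is invalid are dropped and counted in a warning.
    """
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for logical, header in columns.items():
        if header not in table.columns and logical in ("rsid", "chrom", "pos", "pvalue"):
            raise ColumnError(f"required column {header!r} (for {logical}) not found in {path}")
    if table.empty:
        log.warning("association table %s is empty", path)
        return []

    records: list[SnpAssociation] = []
    n_dropped = 0
    for _, row in table.iterrows():
        try:
            pvalue = float(row[columns["pvalue"]])
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        chrom = normalize_chrom(row[columns["chrom"]])
        try:
            pos = int(float(row[columns["pos"]]))
        except (TypeError, ValueError):
            pos = -1
        rsid = str(row[columns["rsid"]]).strip()
        if chrom is None or pos < 1 or not rsid or not 0 < pvalue <= 1:
            n_dropped += 1
            continue
        records.append(
            SnpAssociation(
                rsid=rsid,
                chrom=chrom,
                pos=pos,
                pvalue=pvalue,
                trait=str(row.get(columns["trait"], "") or ""),
                mapped_genes=split_gene_cell(row.get(columns["mapped_genes"])),
                study_id=str(row.get(columns["study_id"], "") or ""),
            )
        )
    if n_dropped:
        log.warning("dropped %d unparseable rows from %s", n_dropped, path)
    return records


def write_associations(records: Iterable[SnpAssociation], path: str | Path) -> None:
    """Write associations back to the default TSV dialect."""
    rows = [
        {
            "SNPS": r.rsid,
            "CHR_ID": r.chrom,
            "CHR_POS": r.pos,
            "P-VALUE": f"{r.pvalue:.17g}",
            "MAPPED_GENE": ", ".join(r.mapped_genes),
            "DISEASE/TRAIT": r.trait,
            "STUDY ACCESSION": r.study_id,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS.values())).to_csv(
        path, sep="\t", index=False
    )


def filter_genomewide(
    assocs: Sequence[SnpAssociation], alpha: float = 5e-8
) -> list[SnpAssociation]:
    """Keep associations with p strictly below ``alpha`` (order preserved).

    Duplicate rsIDs from different studies are retained: SNP counting at
    this stage follows catalog rows, and deduplication happens only when
    seed sets are formed downstream.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    return [a for a in assocs if a.pvalue < alpha]


def _top_key(a: SnpAssociation) -> tuple:
    return (a.pvalue, chrom_sort_key(a.chrom), a.pos, a.rsid)


def select_top_snps(assocs: Sequence[SnpAssociation], n: int = 40) -> list[SnpAssociation]:
    """The ``n`` records with smallest p-values.

    Ties are broken deterministically by (chromosome order, position,
    rsID). If fewer than ``n`` records exist, all are returned.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    return sorted(assocs, key=_top_key)[:n]


def top_mapped_genes(top_snps: Iterable[SnpAssociation]) -> set[str]:
    """Union of mapped gene symbols across records (upper-cased)."""
    genes: set[str] = set()
    for record in top_snps:
        genes.update(g.upper() for g in record.mapped_genes)
    return genes


def manhattan_coordinates(assocs: Sequence[SnpAssociation]) -> list[ManhattanPoint]:
    """Place SNPs on a cumulative genome axis with −log10(p) heights.

    Chromosomes are ordered 1..22, X, Y; each chromosome's offset is the
    sum of preceding chromosome spans, a span being the maximum position
    observed on that chromosome. Records with unknown chromosome labels
    are skipped with a warning.
    """
    valid: list[SnpAssociation] = []
    for a in assocs:
        if a.chrom in _CHROM_RANK:
            valid.append(a)
        else:  # pragma: no cover - dataclass invariant blocks this path
            log.warning("skipping %s: unknown chromosome %r", a.rsid, a.chrom)
    spans: dict[str, int] = {}
    for a in valid:
        spans[a.chrom] = max(spans.get(a.chrom, 0), a.pos)
    offsets: dict[str, int] = {}
    running = 0
    for chrom in CHROMOSOMES:
        if chrom in spans:
            offsets[chrom] = running
            running += spans[chrom]
    points = [
        ManhattanPoint(
            rsid=a.rsid,
            cumulative_x=offsets[a.chrom] + a.pos,
            neglog10p=-math.log10(a.pvalue),
            chrom=a.chrom,
        )
        for a in sorted(valid, key=lambda a: (chrom_sort_key(a.chrom), a.pos, a.rsid))
    ]
    return points


def top_snp_threshold(assocs: Sequence[SnpAssociation], n: int = 40) -> float | None:
    """The p-value of the n-th strongest SNP (the "red dashed line").

    Computed, never a constant; ``None`` when fewer than ``n`` records.
    """
    top = select_top_snps(assocs, n)
    return top[-1].pvalue if len(top) >= n else None


def manhattan_plot(
    points: Sequence[ManhattanPoint],
    out_path: str | Path,
    alpha: float = 5e-8,
    top_threshold: float | None = None,
) -> None:
    """Render a simple Manhattan plot with significance lines to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    colors = ("#2c7fb8", "#7fcdbb")
    for i, chrom in enumerate(CHROMOSOMES):
        xs = [p.cumulative_x for p in points if p.chrom == chrom]
        ys = [p.neglog10p for p in points if p.chrom == chrom]
        if xs:
            ax.scatter(xs, ys, s=6, color=colors[i % 2], label=None)
    ax.axhline(-math.log10(alpha), color="black", linestyle="--", linewidth=0.8)
    if top_threshold is not None:
        ax.axhline(-math.log10(top_threshold), color="red", linestyle="--", linewidth=0.8)
    ax.set_xlabel("cumulative genomic position")
    ax.set_ylabel("-log10(p)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
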