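"""Seven-criterion functional-annotation scorecard for candidate genes.

Each gene receives seven binary flags:

1. ``top_gwas``    — mapped from one of the strongest GWAS SNPs (the
   top-N cut of the Manhattan plot);
2. ``missense_ld`` — carries a missense variant on an associated SNP or
   one of its strong LD proxies (r² > 0.8);
3. ``blood_eqtl``  — has a whole-blood eQTL;
4. ``go_bp``       — member of a significantly enriched GO biological
   process term;
5. ``go_cc``       — member of a significantly enriched GO cellular
   component term;
6. ``go_mf``       — member of a significantly enriched GO molecular
   function term;
7. ``pid``         — on the primary-immunodeficiency (IUIS) gene list.

The total score is the flag sum (0–7); genes scoring at least 3 are
called biological risk genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

CRITERIA: tuple[str, ...] = (
    "top_gwas",
    "missense_ld",
    "blood_eqtl",
    "go_bp",
    "go_cc",
    "go_mf",
    "pid",
)


@dataclass(slots=True)
class GeneAnnotationProfile:
    """Per-gene binary criterion flags plus provenance of each set flag."""

    gene: str
    flags: dict[str, int] = field(default_factory=dict)
    evidence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {c: 0 for c in CRITERIA}
        for key, value in self.flags.items():
            if key not in full:
                raise ValueError(f"unknown criterion {key!r}")
            if value not in (0, 1):
                raise ValueError(f"flag {key}={value!r} must be 0 or 1")
            full[key] = value
        self.flags = full

    @property
    def score(self) -> int:
        return sum(self.flags.values())


def score(profile: GeneAnnotationProfile) -> int:
    """Arithmetic sum of the seven flags."""
    return profile.score


def build_profiles(
    genes: Iterable[str],
    top_genes: Iterable[str],
    missense: Iterable[str],
    eqtl_genes: Iterable[str],
    go_flags: Mapping[str, Iterable[str]],
    pid_list: Iterable[str],
) -> list[GeneAnnotationProfile]:
    """Assemble one profile per gene from the six evidence sources.

    Parameters
    ----------
    genes
        The candidate genes to profile (symbols, any case).
    top_genes
        Genes mapped from the top GWAS SNPs (criterion 1).
    missense
        Genes with a missense variant among associated SNPs/LD proxies
        (criterion 2); compute with :func:`dvtpipe.ld_expand.missense_genes`.
    eqtl_genes
        Genes with a whole-blood eQTL (criterion 3).
    go_flags
        Mapping with keys ``go_bp``, ``go_cc``, ``go_mf`` to the genes
        flagged in each namespace (criteria 4–6); compute with
        :func:`dvtpipe.enrich.flagged_genes`.
    pid_list
        The primary-immunodeficiency gene list (criterion 7).

    A gene absent from every source gets a valid all-zero profile. Flags
    are binary regardless of evidence multiplicity.
    """
    norm = lambda xs: {str(g).strip().upper() for g in xs}
    sources: dict[str, set[str]] = {
        "top_gwas": norm(top_genes),
        "missense_ld": norm(missense),
        "blood_eqtl": norm(eqtl_genes),
        "go_bp": norm(go_flags.get("go_bp", ())),
        "go_cc": norm(go_flags.get("go_cc", ())),
        "go_mf": norm(go_flags.get("go_mf", ())),
        "pid": norm(pid_list),
    }
    profiles: list[GeneAnnotationProfile] = []
    for gene in sorted(norm(genes)):
        flags: dict[str, int] = {}
        evidence: dict[str, str] = {}
        for criterion, members in sources.items():
            hit = int(gene in members)
            flags[criterion] = hit
            if hit:
                evidence[criterion] = f"{criterion}:{gene}"
        profiles.append(GeneAnnotationProfile(gene=gene, flags=flags, evidence=evidence))
    return profiles


def risk_genes(
    profiles: Sequence[GeneAnnotationProfile], min_score: int = 3
) -> list[str]:
    """Genes scoring at least ``min_score``, ordered (score desc, symbol asc)."""
    if not 0 <= min_score <= len(CRITERIA):
        raise ValueError(f"min_score must be in [0, 7], got {min_score!r}")
    hits = [p for p in profiles if p.score >= min_score]
    hits.sort(key=lambda p: (-p.score, p.gene))
    return [p.gene for p in hits]


def read_scorecard(path: str | Path) -> list[GeneAnnotationProfile]:
    """Read a scorecard TSV (gene + one 0/1 column per criterion)."""
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = ({"gene"} | set(CRITERIA)) - set(table.columns)
    if missing:
        raise KeyError(f"scorecard {path} missing columns: {sorted(missing)}")
    profiles: list[GeneAnnotationProfile] = []
    for _, row in table.iterrows():
        flags = {c: int(row[c]) for c in CRITERIA}
        profiles.append(GeneAnnotationProfile(gene=str(row["gene"]).strip().upper(), flags=flags))
    return profiles


def write_scorecard(profiles: Sequence[GeneAnnotationProfile], path: str | Path) -> None:
    """Write a scorecard TSV with the seven flag columns and the total."""
    rows = [
        {"gene": p.gene, **p.flags, "score": p.score}
        for p in sorted(profiles, key=lambda p: (-p.score, p.gene))
    ]
    pd.DataFrame(rows, columns=["gene", *CRITERIA, "score"]).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list (``#`` comments allowed)."""
    genes: set[str] = set()
    with open(path) as handle:
        for line in handle:
            symbol = line.strip().upper()
            if symbol and not symbol.startswith("#"):
                genes.add(symbol)
    return genes


def read_eqtl_genes(path: str | Path) -> set[str]:
    """Genes with at least one significant whole-blood eQTL record.

    Expects a TSV with columns ``gene``, ``rsid``, ``significant`` (0/1).
    """
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"gene", "significant"} - set(table.columns)
    if missing:
        raise KeyError(f"eQTL table {path} missing columns: {sorted(missing)}")
    mask = table["significant"].astype(int) == 1
    return {str(g).strip().upper() for g in table.loc[mask, "gene"]}
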