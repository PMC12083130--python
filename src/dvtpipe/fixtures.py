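"""Accessors for the packaged worked-example fixtures.

These files are synthetic reconstructions (``.synthetic.`` in every
filename) of the published worked example's inputs: a 28-gene
functional-annotation scorecard, a small GO biological-process
collection, a gene–disease edge list, and a five-gene liver/whole-blood
expression bundle with whole-blood eQTL flags. They are sized and
constrained so the documented results — the per-gene scores, the
15-gene coagulation set, the 5 disease-linked genes, and the {THBD, F5}
biomarker call — are reproduced exactly by the package's own code.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

_DATA = resources.files("dvtpipe.data")


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    path = Path(str(_DATA / name))
    if not path.exists():
        raise FileNotFoundError(f"no packaged fixture {name!r}")
    return path


def scorecard_path() -> Path:
    """28-gene seven-criterion scorecard (synthetic reconstruction)."""
    return fixture_path("table2_scorecard.synthetic.tsv")


def go_bp_path() -> Path:
    """GO biological-process GMT with coagulation/wound-healing terms."""
    return fixture_path("go_bp.synthetic.gmt")


def network_edges_path() -> Path:
    """Gene–disease/phenotype edge list around DVT and thrombophilia."""
    return fixture_path("network_edges.synthetic.tsv")


def expression_path() -> Path:
    """Five-gene TPM matrix over whole-blood and liver samples."""
    return fixture_path("expression_tpm.synthetic.tsv")


def tissue_map_path() -> Path:
    return fixture_path("tissue_map.synthetic.tsv")


def eqtl_path() -> Path:
    """Whole-blood eQTL flags for the five disease-linked genes."""
    return fixture_path("eqtl_blood.synthetic.tsv")


def pid_path() -> Path:
    """Small primary-immunodeficiency gene list snapshot (synthetic)."""
    return fixture_path("pid_genes.synthetic.txt")
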