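"""Tissue expression summaries and the blood-biomarker call.

A practical blood biomarker must be measurable in an accessible sample.
Candidates are summarized per tissue (median and IQR of TPM across
samples, the robust central tendency of a violin plot), and selected
when both conditions hold: the gene has a whole-blood eQTL, and its
blood median TPM reaches a detectability threshold (default 1.0 TPM).
Genes expressed mainly in liver (e.g. classical coagulation factors made
by hepatocytes) fail the blood arm even when strongly disease-linked.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

WHOLE_BLOOD = "Whole Blood"
LIVER = "Liver"


@dataclass(slots=True)
class ExpressionSummary:
    """Median/IQR of TPM for one gene in one tissue."""

    gene: str
    tissue: str
    n_samples: int
    median_tpm: float
    iqr_tpm: float

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.median_tpm < 0:
            raise ValueError("median_tpm must be >= 0")


@dataclass(slots=True)
class BiomarkerCall:
    """Final blood-biomarker decision for one gene."""

    gene: str
    has_blood_eqtl: bool
    blood_median_tpm: float
    liver_median_tpm: float
    blood_detectable: bool
    selected: bool
    error: str | None = None


def read_expression(
    matrix_path: str | Path, tissue_map_path: str | Path
) -> tuple[pd.DataFrame, pd.Series]:
    """Load a gene × sample TPM matrix and its sample→tissue map.

    The matrix TSV has gene symbols in the first column and sample IDs in
    the header; the companion TSV has columns ``sample`` and ``tissue``.
    Genes whose row is entirely missing are dropped with a warning; a
    matrix sample absent from the tissue map is a configuration error.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    matrix.index = matrix.index.astype(str).str.strip().str.upper()
    tissue_table = pd.read_csv(tissue_map_path, sep="\t", dtype=str, comment="#")
    missing_cols = {"sample", "tissue"} - set(tissue_table.columns)
    if missing_cols:
        raise KeyError(f"tissue map {tissue_map_path} missing columns: {sorted(missing_cols)}")
    tissues = pd.Series(
        tissue_table["tissue"].str.strip().values,
        index=tissue_table["sample"].str.strip(),
        name="tissue",
    )
    unmapped = [s for s in matrix.columns if s not in tissues.index]
    if unmapped:
        raise ValueError(f"samples missing from tissue map: {unmapped}")
    all_missing = matrix.isna().all(axis=1)
    if all_missing.any():
        import logging

        logging.getLogger(__name__).warning(
            "dropping %d all-missing gene rows", int(all_missing.sum())
        )
        matrix = matrix.loc[~all_missing]
    return matrix, tissues.loc[matrix.columns]


def tissue_summary(
    matrix: pd.DataFrame,
    tissues: pd.Series,
    gene: str,
    tissue_labels: Sequence[str] = (LIVER, WHOLE_BLOOD),
) -> list[ExpressionSummary]:
    """Per-tissue median and IQR of TPM for one gene."""
    symbol = gene.strip().upper()
    if symbol not in matrix.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    row = matrix.loc[symbol]
    summaries: list[ExpressionSummary] = []
    for tissue in tissue_labels:
        samples = tissues.index[tissues == tissue]
        values = row.loc[samples].dropna().to_numpy(dtype=float)
        if values.size == 0:
            raise ValueError(f"tissue {tissue!r} has no samples")
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        summaries.append(
            ExpressionSummary(
                gene=symbol,
                tissue=tissue,
                n_samples=int(values.size),
                median_tpm=float(med),
                iqr_tpm=float(q3 - q1),
            )
        )
    return summaries


def call_biomarkers(
    genes: Iterable[str],
    summaries: Sequence[ExpressionSummary],
    eqtl_genes: Iterable[str],
    tpm_min: float = 1.0,
) -> list[BiomarkerCall]:
    """Apply the blood-biomarker rule to each gene.

    ``selected = has_blood_eqtl AND (blood median TPM ≥ tpm_min)``.
    A gene missing its blood or liver summary yields an error entry; the
    other genes are still called. Output is sorted selected-first, then
    by blood median descending, then symbol.
    """
    eqtl = {g.strip().upper() for g in eqtl_genes}
    by_gene_tissue: dict[tuple[str, str], ExpressionSummary] = {
        (s.gene, s.tissue): s for s in summaries
    }
    calls: list[BiomarkerCall] = []
    for gene in sorted({g.strip().upper() for g in genes}):
        blood = by_gene_tissue.get((gene, WHOLE_BLOOD))
        liver = by_gene_tissue.get((gene, LIVER))
        if blood is None or liver is None:
            missing = WHOLE_BLOOD if blood is None else LIVER
            calls.append(
                BiomarkerCall(
                    gene=gene, has_blood_eqtl=gene in eqtl,
                    blood_median_tpm=float("nan"), liver_median_tpm=float("nan"),
                    blood_detectable=False, selected=False,
                    error=f"missing {missing} summary",
                )
            )
            continue
        detectable = blood.median_tpm >= tpm_min
        has_eqtl = gene in eqtl
        calls.append(
            BiomarkerCall(
                gene=gene,
                has_blood_eqtl=has_eqtl,
                blood_median_tpm=blood.median_tpm,
                liver_median_tpm=liver.median_tpm,
                blood_detectable=detectable,
                selected=detectable and has_eqtl,
            )
        )
    calls.sort(key=lambda c: (not c.selected, -(c.blood_median_tpm if c.blood_median_tpm == c.blood_median_tpm else -1.0), c.gene))
    return calls


def selected_genes(calls: Sequence[BiomarkerCall]) -> set[str]:
    return {c.gene for c in calls if c.selected}


def calls_to_table(calls: Sequence[BiomarkerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "has_blood_eqtl": int(c.has_blood_eqtl),
                "blood_median_tpm": c.blood_median_tpm,
                "liver_median_tpm": c.liver_median_tpm,
                "blood_detectable": int(c.blood_detectable),
                "selected": int(c.selected),
                "error": c.error or "",
            }
            for c in calls
        ]
    )


def expression_plot(
    matrix: pd.DataFrame,
    tissues: pd.Series,
    genes: Sequence[str],
    out_path: str | Path,
    tissue_labels: Sequence[str] = (LIVER, WHOLE_BLOOD),
) -> None:
    """Strip-plot of per-sample TPM by tissue for each gene."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(genes), figsize=(2.2 * len(genes), 3.2), sharey=False)
    if len(genes) == 1:
        axes = [axes]
    colors = {LIVER: "#41ab5d", WHOLE_BLOOD: "#f768a1"}
    for ax, gene in zip(axes, genes):
        row = matrix.loc[gene.strip().upper()]
        for i, tissue in enumerate(tissue_labels):
            samples = tissues.index[tissues == tissue]
            values = row.loc[samples].to_numpy(dtype=float)
            jitter = np.linspace(-0.15, 0.15, values.size)
            ax.scatter(np.full(values.size, i) + jitter, values, s=8,
                       color=colors.get(tissue, "grey"), alpha=0.7)
        ax.set_xticks(range(len(tissue_labels)))
        ax.set_xticklabels([t.split()[0] for t in tissue_labels], fontsize=8)
        ax.set_title(gene, fontsize=9)
        ax.set_yscale("log")
    axes[0].set_ylabel("TPM")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
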