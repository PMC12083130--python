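import math

import pytest

from dvtpipe import expression


def write_bundle(tmp_path, matrix_rows, tissue_rows):
    matrix = tmp_path / "expr.tsv"
    tmap = tmp_path / "tissues.tsv"
    matrix.write_text("\n".join(matrix_rows) + "\n")
    tmap.write_text("sample\ttissue\n" + "\n".join(tissue_rows) + "\n")
    return matrix, tmap


@pytest.fixture
def small_bundle(tmp_path):
    matrix, tmap = write_bundle(
        tmp_path,
        [
            "gene\tS1\tS2\tS3\tS4\tS5\tS6",
            "THBD\t1\t3\t5\t4\t4\t4",
            "F2\t0.1\t0.2\t0.3\t100\t120\t140",
        ],
        [
            "S1\tWhole Blood", "S2\tWhole Blood", "S3\tWhole Blood",
            "S4\tLiver", "S5\tLiver", "S6\tLiver",
        ],
    )
    return expression.read_expression(matrix, tmap)


class TestReadExpression:
    def test_rows_retained(self, small_bundle):
        matrix, tissues = small_bundle
        assert list(matrix.index) == ["THBD", "F2"]
        assert tissues.loc["S1"] == "Whole Blood"

    def test_sample_missing_from_tissue_map_is_error(self, tmp_path):
        matrix, tmap = write_bundle(
            tmp_path,
            ["gene\tS1\tS2", "THBD\t1\t2"],
            ["S1\tLiver"],
        )
        with pytest.raises(ValueError, match="S2"):
            expression.read_expression(matrix, tmap)

    def test_all_missing_rows_dropped(self, tmp_path, caplog):
        matrix, tmap = write_bundle(
            tmp_path,
            ["gene\tS1\tS2", "THBD\t1\t2", "EMPTY\t\t"],
            ["S1\tLiver", "S2\tLiver"],
        )
        with caplog.at_level("WARNING"):
            frame, _ = expression.read_expression(matrix, tmap)
        assert list(frame.index) == ["THBD"]


class TestTissueSummary:
    def test_hand_computed_median_and_iqr(self, small_bundle):
        matrix, tissues = small_bundle
        blood = expression.tissue_summary(matrix, tissues, "THBD", ["Whole Blood"])[0]
        assert blood.median_tpm == 3 and blood.iqr_tpm == 2 and blood.n_samples == 3

    def test_constant_values_have_zero_iqr(self, small_bundle):
        matrix, tissues = small_bundle
        liver = expression.tissue_summary(matrix, tissues, "THBD", ["Liver"])[0]
        assert liver.median_tpm == 4 and liver.iqr_tpm == 0

    def test_unknown_gene_is_lookup_error(self, small_bundle):
        matrix, tissues = small_bundle
        with pytest.raises(KeyError):
            expression.tissue_summary(matrix, tissues, "NOPE")

    def test_case_insensitive_gene_lookup(self, small_bundle):
        matrix, tissues = small_bundle
        assert expression.tissue_summary(matrix, tissues, "thbd", ["Liver"])[0].gene == "THBD"


def summaries_for(gene, blood_median, liver_median):
    return [
        expression.ExpressionSummary(gene, expression.WHOLE_BLOOD, 8, blood_median, 1.0),
        expression.ExpressionSummary(gene, expression.LIVER, 8, liver_median, 1.0),
    ]


class TestCallBiomarkers:
    def test_eqtl_is_required_regardless_of_expression(self):
        calls = expression.call_biomarkers(
            {"F2"}, summaries_for("F2", 100.0, 1.0), eqtl_genes=set()
        )
        assert calls[0].blood_detectable and not calls[0].selected

    def test_undetectable_blood_expression_blocks_selection(self):
        calls = expression.call_biomarkers(
            {"PROC"}, summaries_for("PROC", 0.0, 150.0), eqtl_genes={"PROC"}
        )
        assert not calls[0].selected

    def test_threshold_boundary_is_inclusive(self):
        calls = expression.call_biomarkers(
            {"THBD"}, summaries_for("THBD", 1.0, 5.0), eqtl_genes={"THBD"}, tpm_min=1.0
        )
        assert calls[0].selected

    def test_missing_summary_yields_error_entry_others_called(self):
        calls = expression.call_biomarkers(
            {"THBD", "GHOST"}, summaries_for("THBD", 12.0, 5.0), eqtl_genes={"THBD"}
        )
        by_gene = {c.gene: c for c in calls}
        assert by_gene["THBD"].selected
        assert by_gene["GHOST"].error and not by_gene["GHOST"].selected
        assert math.isnan(by_gene["GHOST"].blood_median_tpm)

    def test_selected_first_then_blood_median_descending(self):
        summaries = (
            summaries_for("A", 5.0, 1.0) + summaries_for("B", 50.0, 1.0)
            + summaries_for("C", 80.0, 1.0)
        )
        calls = expression.call_biomarkers({"A", "B", "C"}, summaries, eqtl_genes={"A", "B"})
        assert [c.gene for c in calls] == ["B", "A", "C"]

    def test_monotone_nonincreasing_in_tpm_min(self):
        summaries = summaries_for("A", 2.0, 1.0) + summaries_for("B", 10.0, 1.0)
        selected = [
            expression.selected_genes(
                expression.call_biomarkers({"A", "B"}, summaries, {"A", "B"}, tpm_min=t)
            )
            for t in (0.5, 2.0, 5.0, 20.0)
        ]
        for tighter, looser in zip(selected[1:], selected):
            assert tighter <= looser

    def test_permutation_invariance_in_gene_order(self):
        summaries = summaries_for("A", 2.0, 1.0) + summaries_for("B", 10.0, 1.0)
        first = expression.call_biomarkers(["A", "B"], summaries, {"A"})
        second = expression.call_biomarkers(["B", "A"], summaries, {"A"})
        assert first == second


def test_generated_matrix_medians_match_planted_profiles(mini_bundle):
    """Blood medians of planted biomarkers sit far above the detectability
    threshold while liver-class genes stay below it, as the generator plants."""
    bundle, truth = mini_bundle
    matrix, tissues = expression.read_expression(
        bundle / "expression_tpm.tsv", bundle / "tissue_map.tsv"
    )
    for gene in truth.biomarkers:
        blood = expression.tissue_summary(matrix, tissues, gene, ["Whole Blood"])[0]
        assert blood.median_tpm > 1.0 + 2 * blood.iqr_tpm
    liver_only = set(truth.network_genes) - set(truth.biomarkers)
    for gene in liver_only:
        blood = expression.tissue_summary(matrix, tissues, gene, ["Whole Blood"])[0]
        liver = expression.tissue_summary(matrix, tissues, gene, ["Liver"])[0]
        assert blood.median_tpm < 1.0 < liver.median_tpm
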