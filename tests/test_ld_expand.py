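import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dvtpipe import ld_expand


def panel_strategy():
    rsids = st.sampled_from([f"rs{i}" for i in range(12)])
    return st.lists(
        st.builds(
            ld_expand.LdProxy,
            seed_rsid=rsids,
            proxy_rsid=rsids,
            r2=st.floats(0.0, 1.0),
            population=st.sampled_from(["ASN", "EUR"]),
        ),
        max_size=40,
    )


class TestReadPanel:
    def test_valid_rows_parsed(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "seed_rsid\tproxy_rsid\tr2\tpopulation\n"
            "rsA\trsB\t0.91\tASN\nrsA\trsC\t0.85\tASN\nrsD\trsE\t0.99\tEUR\n"
        )
        assert len(ld_expand.read_ld_panel(path)) == 3

    def test_out_of_range_r2_rejected_row_wise(self, tmp_path, caplog):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "seed_rsid\tproxy_rsid\tr2\tpopulation\n"
            "rsA\trsB\t1.2\tASN\nrsA\trsC\t0.85\tASN\nrsA\trsD\tbad\tASN\n"
        )
        with caplog.at_level("WARNING"):
            panel = ld_expand.read_ld_panel(path)
        assert [p.proxy_rsid for p in panel] == ["rsC"]
        assert any("line 2" in r.message for r in caplog.records)
        assert any("line 4" in r.message for r in caplog.records)

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text("seed_rsid\tproxy_rsid\tr2\nrsA\trsB\t0.9\n")
        with pytest.raises(KeyError, match="population"):
            ld_expand.read_ld_panel(path)

    def test_write_read_roundtrip(self, tmp_path):
        import numpy as np

        rng = np.random.default_rng(5)
        panel = [
            ld_expand.LdProxy(f"rs{i}", f"rs{1000+i}", float(np.round(rng.uniform(0, 1), 4)), "ASN")
            for i in range(30)
        ]
        path = tmp_path / "panel.tsv"
        ld_expand.write_ld_panel(panel, path)
        assert ld_expand.read_ld_panel(path) == panel


class TestExpand:
    def test_strict_threshold_boundary(self):
        panel = [
            ld_expand.LdProxy("rsA", "rsB", 0.85, "ASN"),
            ld_expand.LdProxy("rsA", "rsC", 0.8, "ASN"),
        ]
        assert ld_expand.expand_snps({"rsA"}, panel) == {"rsA", "rsB"}

    def test_r2_min_one_returns_seeds(self):
        panel = [ld_expand.LdProxy("rsA", "rsB", 1.0, "ASN")]
        assert ld_expand.expand_snps({"rsA"}, panel, r2_min=1.0) == {"rsA"}

    def test_empty_panel_returns_seeds_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = ld_expand.expand_snps({"rsA", "rsB"}, [])
        assert out == {"rsA", "rsB"}
        assert any("empty" in r.message for r in caplog.records)

    def test_population_exact_match(self):
        panel = [ld_expand.LdProxy("rsA", "rsB", 0.95, "EUR")]
        assert ld_expand.expand_snps({"rsA"}, panel, population="ASN") == {"rsA"}
        assert ld_expand.expand_snps({"rsA"}, panel, population="EUR") == {"rsA", "rsB"}

    @given(panel=panel_strategy(), seeds=st.sets(st.sampled_from([f"rs{i}" for i in range(12)]), max_size=6),
           r2_min=st.floats(0.0, 1.0))
    def test_matches_exhaustive_scan_oracle(self, panel, seeds, r2_min):
        oracle = set(seeds) | {
            p.proxy_rsid
            for p in panel
            if p.seed_rsid in seeds and p.r2 > r2_min and p.population == "ASN"
        }
        got = ld_expand.expand_snps(seeds, panel, r2_min, "ASN")
        if panel:
            assert got == oracle
        assert got >= set(seeds)  # self-LD: seeds always included

    @given(panel=panel_strategy(), seeds=st.sets(st.sampled_from([f"rs{i}" for i in range(12)]), max_size=6),
           thresholds=st.tuples(st.floats(0, 1), st.floats(0, 1)))
    def test_monotone_nonincreasing_in_r2_min(self, panel, seeds, thresholds):
        lo, hi = min(thresholds), max(thresholds)
        assert ld_expand.expand_snps(seeds, panel, hi) <= ld_expand.expand_snps(seeds, panel, lo)


class TestGeneMapping:
    def test_inverted_index(self):
        links = [
            ld_expand.VariantGeneLink("rs1", "F5"),
            ld_expand.VariantGeneLink("rs2", "F5"),
            ld_expand.VariantGeneLink("rs3", "ABO"),
        ]
        mapping = ld_expand.map_to_genes({"rs1", "rs2"}, links)
        assert mapping.genes == {"F5": {"rs1", "rs2"}}
        assert mapping.unmapped == set()

    def test_unmapped_snps_reported_separately(self):
        mapping = ld_expand.map_to_genes({"rs1", "rs9"}, [ld_expand.VariantGeneLink("rs1", "F5")])
        assert mapping.unmapped == {"rs9"}

    def test_empty_links_leaves_all_unmapped(self):
        mapping = ld_expand.map_to_genes({"rs1", "rs2"}, [])
        assert mapping.genes == {} and mapping.unmapped == {"rs1", "rs2"}

    def test_distinct_gene_count_matches_groupby_oracle(self):
        import numpy as np

        rng = np.random.default_rng(9)
        links = [
            ld_expand.VariantGeneLink(f"rs{i}", f"G{int(rng.integers(0, 30))}")
            for i in range(200)
        ]
        snps = {f"rs{i}" for i in range(0, 200, 3)}
        frame = pd.DataFrame([(l.rsid, l.gene) for l in links], columns=["rsid", "gene"])
        oracle = frame[frame.rsid.isin(snps)].groupby("gene").size()
        mapping = ld_expand.map_to_genes(snps, links)
        assert set(mapping.genes) == set(oracle.index)
        assert {g: len(s) for g, s in mapping.genes.items()} == oracle.to_dict()

    def test_missense_genes_restricted_to_snp_set(self):
        links = [
            ld_expand.VariantGeneLink("rs1", "F5", "missense"),
            ld_expand.VariantGeneLink("rs2", "ABO", "missense"),
            ld_expand.VariantGeneLink("rs3", "FGB", "other"),
        ]
        assert ld_expand.missense_genes({"rs1", "rs3"}, links) == {"F5"}


def test_link_round_trip(tmp_path):
    links = [
        ld_expand.VariantGeneLink("rs1", "F5", "missense"),
        ld_expand.VariantGeneLink("rs2", "ABO", "other"),
    ]
    path = tmp_path / "links.tsv"
    ld_expand.write_variant_links(links, path)
    assert ld_expand.read_variant_links(path) == links
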