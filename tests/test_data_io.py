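import numpy as np
import pandas as pd
import pytest

from iimat import GeneRoleCatalog
from iimat import data_io
from iimat.types import ProbeAnnotation


class TestGeneRoles:
    def test_plain_list_tags_given_role(self, tmp_path):
        p = tmp_path / "immune.txt"
        p.write_text("JAK3\nIL4R\n")
        cat = data_io.read_gene_roles(p, role="IMMUNE")
        assert len(cat) == 2
        assert cat.roles_of("jak3") == {"IMMUNE"}
        assert cat.roles_of("IL4R") == {"IMMUNE"}

    def test_duplicate_lines_collapse(self, tmp_path):
        p = tmp_path / "roles.txt"
        p.write_text("A\nA\n a \n")
        cat = data_io.read_gene_roles(p, role="DISEASE")
        assert len(cat) == 1

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("  \n")
        with pytest.raises(ValueError, match="empty"):
            data_io.read_gene_roles(p, role="IMMUNE")

    def test_malformed_line_skipped(self, tmp_path, caplog):
        p = tmp_path / "roles.txt"
        p.write_text("A\nB\textra\nC\n")
        with caplog.at_level("WARNING"):
            cat = data_io.read_gene_roles(p, role="IMMUNE")
        assert sorted(cat.entries) == ["A", "C"]
        assert "malformed" in caplog.text

    def test_gmt_roundtrip(self, tmp_path):
        cat = GeneRoleCatalog({
            "A": {"IMMUNE"}, "B": {"IMMUNE", "INFLAMMATION"},
            "C": {"DISEASE"},
        })
        p = tmp_path / "roles.gmt"
        data_io.write_gene_roles_gmt(cat, p)
        back = data_io.read_gene_roles(p, fmt="gmt")
        assert back.entries == cat.entries

    def test_merge_unions_roles(self):
        a = GeneRoleCatalog.from_symbols(["A", "B"], "IMMUNE")
        b = GeneRoleCatalog.from_symbols(["B", "C"], "INFLAMMATION")
        merged = data_io.merge_catalogs(a, b)
        assert merged.roles_of("B") == {"IMMUNE", "INFLAMMATION"}
        assert len(merged) == 3

    def test_merge_commutative_idempotent(self):
        a = GeneRoleCatalog.from_symbols(["A", "B"], "IMMUNE")
        b = GeneRoleCatalog.from_symbols(["B"], "DISEASE")
        ab = data_io.merge_catalogs(a, b)
        ba = data_io.merge_catalogs(b, a)
        assert ab.entries == ba.entries
        assert data_io.merge_catalogs(ab, ab).entries == ab.entries


class TestPPI:
    def test_dedup_and_self_loops(self, tmp_path):
        p = tmp_path / "ppi.tsv"
        p.write_text("A\tB\nB\tA\nA\tA\n")
        g = data_io.read_ppi_edges(p)
        assert g.number_of_nodes() == 2
        assert g.number_of_edges() == 1

    def test_empty_file(self, tmp_path):
        p = tmp_path / "ppi.tsv"
        p.write_text("")
        g = data_io.read_ppi_edges(p)
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_triangle(self, tmp_path):
        p = tmp_path / "ppi.tsv"
        p.write_text("A\tB\nB\tC\nA\tC\n")
        g = data_io.read_ppi_edges(p)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3

    def test_hprd_flat_dialect(self, tmp_path):
        p = tmp_path / "hprd.txt"
        p.write_text("ALDH1A1\t00001\tNP_000680.2\tJAK3\t00002\tNP_x\tin vivo\t123\n")
        g = data_io.read_ppi_edges(p, dialect="hprd-flat")
        assert set(g.edges) == {("ALDH1A1", "JAK3")}

    def test_roundtrip(self, tmp_path):
        p = tmp_path / "ppi.tsv"
        p.write_text("A\tB\nB\tC\nD\tA\n")
        g = data_io.read_ppi_edges(p)
        out = tmp_path / "out.tsv"
        data_io.write_ppi_edges(g, out)
        g2 = data_io.read_ppi_edges(out)
        assert set(g.nodes) == set(g2.nodes)
        assert {frozenset(e) for e in g.edges} == {frozenset(e) for e in g2.edges}


class TestCollapseProbes:
    def test_mean_over_probes(self):
        raw = pd.DataFrame([[1, 3], [3, 5]], index=["p1", "p2"],
                           columns=["s1", "s2"])
        ann = ProbeAnnotation({"p1": ("G",), "p2": ("G",)})
        expr = data_io.collapse_probes(raw, ann,
                                       {"s1": "CASE", "s2": "CONTROL"})
        assert expr.data.loc["G"].tolist() == [2.0, 4.0]

    def test_single_probe_identity_and_unannotated_dropped(self):
        raw = pd.DataFrame([[1.5, 2.5], [9, 9]], index=["p1", "px"],
                           columns=["s1", "s2"])
        ann = ProbeAnnotation({"p1": ("G",)})
        expr = data_io.collapse_probes(raw, ann,
                                       {"s1": "CASE", "s2": "CONTROL"})
        assert expr.genes == ["G"]
        assert expr.data.loc["G"].tolist() == [1.5, 2.5]

    def test_row_count_matches_gene_count(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(rng.normal(size=(10, 4)),
                           index=[f"p{i}" for i in range(10)],
                           columns=[f"s{i}" for i in range(4)])
        ann = ProbeAnnotation({f"p{i}": (f"G{i % 4}",) for i in range(10)})
        labels = {f"s{i}": ("CASE" if i < 2 else "CONTROL") for i in range(4)}
        expr = data_io.collapse_probes(raw, ann, labels)
        assert len(expr.genes) == 4

    def test_probe_order_invariance(self):
        rng = np.random.default_rng(1)
        raw = pd.DataFrame(rng.normal(size=(6, 3)),
                           index=[f"p{i}" for i in range(6)],
                           columns=["s1", "s2", "s3"])
        ann = ProbeAnnotation({f"p{i}": (f"G{i % 2}",) for i in range(6)})
        labels = {"s1": "CASE", "s2": "CASE", "s3": "CONTROL"}
        a = data_io.collapse_probes(raw, ann, labels)
        b = data_io.collapse_probes(raw.iloc[::-1], ann, labels)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_multi_symbol_probe_contributes_to_each(self):
        raw = pd.DataFrame([[2.0, 4.0]], index=["p1"], columns=["s1", "s2"])
        ann = ProbeAnnotation({"p1": ("A", "B")})
        expr = data_io.collapse_probes(raw, ann,
                                       {"s1": "CASE", "s2": "CONTROL"})
        assert expr.data.loc["A"].tolist() == expr.data.loc["B"].tolist()

    def test_no_mappable_probe_is_an_error(self):
        raw = pd.DataFrame([[1.0]], index=["p1"], columns=["s1"])
        with pytest.raises(ValueError, match="no probe"):
            data_io.collapse_probes(raw, ProbeAnnotation({}), {"s1": "CASE"})


class TestSeriesMatrix:
    def test_header_block_skipped(self, tmp_path):
        p = tmp_path / "series.txt"
        p.write_text(
            "!Series_title\t\"x\"\n"
            "!Sample_geo_accession\t\"GSM1\"\t\"GSM2\"\n"
            "!series_matrix_table_begin\n"
            "\"ID_REF\"\t\"GSM1\"\t\"GSM2\"\n"
            "\"p1\"\t1.0\t2.0\n"
            "\"p2\"\t3.0\t4.0\n"
            "!series_matrix_table_end\n"
        )
        df = data_io.read_series_matrix(p)
        assert list(df.index) == ["p1", "p2"]
        assert df.loc["p1", "GSM2"] == 2.0

    def test_missing_markers_error(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("just\ttext\n")
        with pytest.raises(ValueError, match="markers"):
            data_io.read_series_matrix(p)


class TestDrugTargets:
    def _write(self, tmp_path, body):
        p = tmp_path / "drugs.tsv"
        p.write_text("drug_id\tdrug_name\tgene_symbol\n" + body)
        return p

    def test_exact_duplicate_dropped(self, tmp_path):
        p = self._write(tmp_path, "D1\tAspirin\tPTGS2\nD1\tAspirin\tPTGS2\n"
                                  "D1\tAspirin\tPTGS1\n")
        table = data_io.read_drug_targets(p)
        assert len(table) == 2

    def test_empty_symbol_skipped(self, tmp_path, caplog):
        p = self._write(tmp_path, "D1\tAspirin\t\nD2\tOther\tPTGS2\n")
        with caplog.at_level("WARNING"):
            table = data_io.read_drug_targets(p)
        assert len(table) == 1

    def test_shared_target_kept_for_both_drugs(self, tmp_path):
        p = self._write(tmp_path, "D1\tA\tJAK3\nD2\tB\tJAK3\n")
        table = data_io.read_drug_targets(p)
        assert len(table) == 2

    def test_missing_column_is_an_error(self, tmp_path):
        p = tmp_path / "drugs.tsv"
        p.write_text("drug_id\tgene_symbol\nD1\tJAK3\n")
        with pytest.raises(ValueError, match="missing required columns"):
            data_io.read_drug_targets(p)
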