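import numpy as np
import pandas as pd
import pytest

import refstab as rs
from refstab.data_io import geometric_mean


def write(path, text):
    path.write_text(text)
    return path


class TestReadCtTable:
    def test_small_table_with_metadata(self, tmp_path):
        ct_file = write(tmp_path / "ct.tsv",
                        "gene\ts1\ts2\ts3\nACT7\t20\t21\t22\nFAB2\t27\t27.5\t28\n")
        meta = write(tmp_path / "meta.tsv",
                     "sample\tstage\treplicate\ns1\tAC\t1\ns2\tAC\t2\ns3\tMMC\t1\n")
        ct = rs.read_ct_table(ct_file, meta)
        assert ct.genes == ["ACT7", "FAB2"]
        assert ct.samples == ["s1", "s2", "s3"]
        assert ct.stages == ["AC", "MMC"]
        assert ct.replicate_of["s2"] == 2
        assert ct.values.at["FAB2", "s3"] == 28.0

    def test_comma_dialect_autodetected(self, tmp_path):
        ct_file = write(tmp_path / "ct.csv", "gene,AC_1,AC_2\nACT7,20,21\n")
        ct = rs.read_ct_table(ct_file)          # stage parsed from sample names
        assert ct.group_of == {"AC_1": "AC", "AC_2": "AC"}

    def test_duplicate_gene_row_rejected(self, tmp_path):
        ct_file = write(tmp_path / "ct.tsv",
                        "gene\ts1\ts2\nACT7\t20\t21\nACT7\t22\t23\n")
        meta = write(tmp_path / "meta.tsv", "sample\tstage\ns1\tAC\ns2\tAC\n")
        with pytest.raises(rs.StructuralError, match="ACT7"):
            rs.read_ct_table(ct_file, meta)

    def test_duplicate_sample_column_rejected(self, tmp_path):
        ct_file = write(tmp_path / "ct.tsv", "gene\ts1\ts1\nACT7\t20\t21\n")
        meta = write(tmp_path / "meta.tsv", "sample\tstage\ns1\tAC\n")
        with pytest.raises(rs.StructuralError, match="s1"):
            rs.read_ct_table(ct_file, meta)

    def test_sample_absent_from_metadata(self, tmp_path):
        ct_file = write(tmp_path / "ct.tsv", "gene\ts1\ts2\nACT7\t20\t21\n")
        meta = write(tmp_path / "meta.tsv", "sample\tstage\ns1\tAC\n")
        with pytest.raises(rs.MetadataError, match="s2"):
            rs.read_ct_table(ct_file, meta)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        ct_file = write(tmp_path / "ct.tsv",
                        "gene\ts1\ts2\nACT7\t20\toops\n")
        meta = write(tmp_path / "meta.tsv", "sample\tstage\ns1\tAC\ns2\tAC\n")
        with pytest.raises(rs.TableParseError) as err:
            rs.read_ct_table(ct_file, meta)
        assert "ACT7" in str(err.value) and "s2" in str(err.value)

    def test_missing_ct_allowed_and_flagged(self, tmp_path):
        ct_file = write(tmp_path / "ct.tsv",
                        "gene\ts1\ts2\nACT7\t20\tNA\nFAB2\t27\t28\n")
        meta = write(tmp_path / "meta.tsv", "sample\tstage\ns1\tAC\ns2\tAC\n")
        ct = rs.read_ct_table(ct_file, meta)
        assert ct.n_missing()["ACT7"] == 1
        assert ct.drop_sparse_genes(0.2).genes == ["FAB2"]

    def test_nonpositive_ct_rejected(self, tmp_path):
        ct_file = write(tmp_path / "ct.tsv", "gene\ts1\ts2\nACT7\t-3\t21\n")
        meta = write(tmp_path / "meta.tsv", "sample\tstage\ns1\tAC\ns2\tAC\n")
        with pytest.raises(rs.DomainError):
            rs.read_ct_table(ct_file, meta)

    def test_round_trip_full_design(self, tmp_path):
        ct, _ = rs.generate_ct_dataset(12, 6, seed=5)   # 18 genes, 5x3 samples
        rs.write_ct_table(ct, tmp_path / "ct.tsv", tmp_path / "meta.tsv")
        back = rs.read_ct_table(tmp_path / "ct.tsv", tmp_path / "meta.tsv")
        assert back.genes == ct.genes and back.samples == ct.samples
        assert np.allclose(back.values, ct.values, atol=1e-9)
        assert back.group_of == ct.group_of
        assert back.replicate_of == ct.replicate_of


class TestExpressionMatrix:
    def test_single_gene_echo(self, tmp_path):
        f = write(tmp_path / "rpkm.tsv",
                  "gene\tAC\tMMC\tMeiosis\tMitosis\tMature\ng1\t1\t2\t3\t4\t5\n")
        m = rs.read_expression_matrix(f)
        assert m.conditions == ["AC", "MMC", "Meiosis", "Mitosis", "Mature"]
        assert m.values.loc["g1"].mean() == 3.0

    def test_negative_value_rejected(self, tmp_path):
        f = write(tmp_path / "rpkm.tsv", "gene\tAC\tMMC\ng1\t1\t-2.0\n")
        with pytest.raises(rs.DomainError):
            rs.read_expression_matrix(f)

    def test_fifty_gene_round_trip(self, tmp_path):
        m, _ = rs.generate_rpkm_dataset(25, 25, seed=2)
        rs.write_expression_matrix(m, tmp_path / "rpkm.tsv")
        back = rs.read_expression_matrix(tmp_path / "rpkm.tsv")
        assert back.genes == m.genes
        assert np.allclose(back.values, m.values, atol=1e-9)


class TestRankingReport:
    @staticmethod
    def _consensus_and_tables():
        ranks = {"genorm": {"A": 1, "B": 2, "C": 3},
                 "normfinder": {"A": 2, "B": 1, "C": 3},
                 "bestkeeper": {"A": 1, "B": 2, "C": 3}}
        cons = rs.geometric_mean_ranking(ranks)
        tables = [
            rs.StabilityTable("genorm", {"A": 0.1, "B": 0.2, "C": 0.3},
                              ["A", "B", "C"]),
            rs.StabilityTable("normfinder", {"A": 0.2, "B": 0.1, "C": 0.3},
                              ["B", "A", "C"]),
            rs.StabilityTable(
                "bestkeeper", {"A": 1.0, "B": 2.0, "C": 3.0}, ["A", "B", "C"],
                aux={g: {"mean_ct": 25.0, "sd": s, "cv_pct": 100 * s / 25.0,
                         "r_with_index": 0.9}
                     for g, s in {"A": 1.0, "B": 2.0, "C": 3.0}.items()}),
        ]
        return cons, tables

    def test_three_rows_for_three_genes(self, tmp_path):
        cons, tables = self._consensus_and_tables()
        out = tmp_path / "report.tsv"
        rs.write_ranking_report(cons, tables, out)
        report = pd.read_csv(out, sep="\t", comment="#")
        assert len(report) == 3
        assert list(report["consensus_gene"]) == cons.order

    def test_gene_set_mismatch_rejected(self, tmp_path):
        cons, tables = self._consensus_and_tables()
        bad = rs.StabilityTable("genorm", {"A": 0.1, "B": 0.2, "D": 0.3},
                                ["A", "B", "D"])
        with pytest.raises(rs.ConsistencyError):
            rs.write_ranking_report(cons, [bad] + tables[1:], tmp_path / "r.tsv")


class TestInvariants:
    @pytest.mark.parametrize("corruption", ["dup_gene", "dup_sample",
                                            "negative_ct", "missing_meta"])
    def test_reader_rejects_invariant_violations(self, tmp_path, corruption):
        rows = {"dup_gene": "g1\t20\t21\ng1\t22\t23\n",
                "dup_sample": None, "negative_ct": "g1\t20\t-1\n",
                "missing_meta": "g1\t20\t21\n"}
        header = "gene\ts1\ts1\n" if corruption == "dup_sample" else "gene\ts1\ts2\n"
        body = rows[corruption] or "g1\t20\t21\n"
        f = write(tmp_path / "ct.tsv", header + body)
        meta_text = "sample\tstage\ns1\tAC\n" if corruption in (
            "dup_sample", "missing_meta") else "sample\tstage\ns1\tAC\ns2\tAC\n"
        meta = write(tmp_path / "meta.tsv", meta_text)
        with pytest.raises(rs.RefstabError):
            rs.read_ct_table(f, meta)

    def test_geometric_mean_positive_only(self):
        assert geometric_mean([2, 8]) == pytest.approx(4.0)
        with pytest.raises(rs.DomainError):
            geometric_mean([1.0, 0.0])
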