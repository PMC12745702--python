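"""Data model, format readers/writers, interval arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teescape.core import (
    ContactPair,
    EmptyInputError,
    FormatError,
    GenomicInterval,
    MalformedRecordError,
    interval_distance,
    is_te_feature_id,
    parse_te_id,
)
from teescape.io import (
    read_contacts,
    read_de_table,
    read_gene_models,
    read_gmt,
    read_intervals_bed,
    read_te_annotation,
    write_contacts,
    write_de_table,
    write_gene_models,
    write_gmt,
    write_te_annotation,
)


class TestGenomicInterval:
    def test_rejects_degenerate_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 100)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 100, 200), ("chr1", 150, 250), 0),  # overlap
            (("chr1", 100, 200), ("chr1", 205, 300), 5),  # gap
            (("chr1", 100, 200), ("chr2", 100, 200), math.inf),  # trans
            (("chr1", 100, 200), ("chr1", 200, 300), 0),  # abutting
        ],
    )
    def test_interval_distance(self, a, b, expected):
        ia, ib = GenomicInterval(*a), GenomicInterval(*b)
        assert interval_distance(ia, ib) == expected

    @given(
        st.lists(
            st.tuples(st.integers(0, 10_000), st.integers(1, 500)),
            min_size=3,
            max_size=3,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_distance_symmetric_and_triangle_bounded(self, triples):
        ivs = [GenomicInterval("chr1", s, s + w) for s, w in triples]
        a, b, c = ivs
        assert interval_distance(a, b) == interval_distance(b, a)
        assert interval_distance(a, c) <= (
            interval_distance(a, b) + interval_distance(b, c) + b.length
        )


class TestTEIdParsing:
    @pytest.mark.parametrize(
        "fid, is_te",
        [
            ("L1Md_F:L1:LINE", True),
            ("IAPEz-int:ERVK:LTR", True),
            ("Gapdh", False),
            ("a:b", False),
            ("a:b:c:d", False),
        ],
    )
    def test_triplet_pattern(self, fid, is_te):
        assert is_te_feature_id(fid) is is_te

    def test_custom_delimiter(self):
        assert is_te_feature_id("L1Md_F|L1|LINE", delimiter="|")
        assert parse_te_id("L1Md_F|L1|LINE", delimiter="|") == ("L1Md_F", "L1", "LINE")


class TestDETableIO:
    def _write(self, path, rows, header="feature\tbaseMean\tlog2FoldChange\tpvalue\tpadj"):
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    def test_gene_vs_te_classification(self, tmp_path):
        p = self._write(
            tmp_path / "de.tsv",
            [
                "Gapdh\t100\t0.5\t0.2\t0.4",
                "L1Md_F:L1:LINE\t50\t1.2\t0.01\t0.05",
                "IAPEz-int:ERVK:LTR\t30\t-0.8\t0.03\t0.09",
            ],
        )
        table = read_de_table(p, "VPR")
        assert len(table.genes) == 1
        assert len(table.tes) == 2

    def test_missing_pvalue_column_is_format_error(self, tmp_path):
        p = self._write(
            tmp_path / "de.tsv",
            ["Gapdh\t100\t0.5"],
            header="feature\tbaseMean\tlog2FoldChange",
        )
        with pytest.raises(FormatError, match="pvalue"):
            read_de_table(p, "VPR")

    def test_empty_table_rejected(self, tmp_path):
        p = (tmp_path / "de.tsv")
        p.write_text("feature\tbaseMean\tlog2FoldChange\tpvalue\tpadj\n")
        with pytest.raises(EmptyInputError):
            read_de_table(p, "VPR")

    def test_na_pvalues_dropped(self, tmp_path):
        p = self._write(
            tmp_path / "de.tsv",
            ["Gapdh\t100\t0.5\t0.2\t0.4", "Actb\t90\t0.1\tNA\tNA"],
        )
        table = read_de_table(p, "VPR")
        assert table.data["feature_id"].tolist() == ["Gapdh"]

    def test_round_trip_identity(self, default_cohort, tmp_path):
        table = default_cohort.tables["VPR"]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_de_table(table, p1)
        again = read_de_table(p1, "VPR")
        write_de_table(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        pd.testing.assert_frame_equal(table.data, again.data)


class TestContactsIO:
    def _lines(self):
        return [
            "chr1\t100\t5100\tchr1\t50000\t55000\texcitatory\t2",
            "chr1\t200\t5200\tchr2\t100\t5100\tinhibitory\t1",
            "chr2\t900\t5900\tchr2\t60000\t65000\texcitatory\t1",
            "chr1\t70000\t75000\tchr1\t100\t5100\texcitatory\t1",
            "chr2\t40\t5040\tchr1\t10\t5010\tastrocyte\t1",
        ]

    def test_cell_type_filter(self, tmp_path):
        p = tmp_path / "c.bedpe"
        p.write_text("\n".join(self._lines()) + "\n")
        assert len(read_contacts(p, "excitatory")) == 3
        assert len(read_contacts(p, None)) == 5

    def test_anchor_normalization(self, tmp_path):
        p = tmp_path / "c.bedpe"
        p.write_text("chr1\t70000\t75000\tchr1\t100\t5100\texcitatory\t1\n")
        (pair,) = read_contacts(p)
        assert pair.anchor_a.start == 100 and pair.anchor_b.start == 70000
        # normalization is idempotent
        renorm = ContactPair(pair.anchor_a, pair.anchor_b, pair.cell_type)
        assert renorm.anchor_a == pair.anchor_a

    def test_malformed_record_carries_line_number(self, tmp_path):
        p = tmp_path / "c.bedpe"
        p.write_text(self._lines()[0] + "\nchr1\t500\t400\tchr1\t10\t20\n")
        with pytest.raises(MalformedRecordError, match="line 2"):
            read_contacts(p)

    def test_round_trip(self, tmp_path, small_cohort):
        p1, p2 = tmp_path / "a.bedpe", tmp_path / "b.bedpe"
        write_contacts(small_cohort.contacts, p1)
        write_contacts(read_contacts(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestAnnotationIO:
    def test_gmt_deduplicates_members(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("immuneA\tdesc\tg1\tg2\tg2\n")
        coll = read_gmt(p)
        assert coll["immuneA"] == {"g1", "g2"}

    def test_gmt_round_trip(self, tmp_path, small_cohort):
        p1, p2 = tmp_path / "a.gmt", tmp_path / "b.gmt"
        write_gmt(small_cohort.gene_sets, p1)
        write_gmt(read_gmt(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_gtf_coordinate_convention(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text('chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "G1";\n')
        (gene,) = read_gene_models(p)
        assert (gene.body.start, gene.body.end) == (1000, 2000)

    def test_gtf_round_trip_identity(self, tmp_path, small_cohort):
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gene_models(small_cohort.gene_models, p1)
        again = read_gene_models(p1)
        write_gene_models(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert again == small_cohort.gene_models

    def test_bed_convention_and_te_grouping(self, tmp_path):
        p = tmp_path / "te.bed"
        p.write_text(
            "chr1\t999\t2000\tL1Md_F:L1:LINE\t0\t+\n"
            "chr2\t10\t500\tL1Md_F:L1:LINE\t0\t-\n"
            "chr1\t5000\t5600\tIAP:ERVK:LTR\t0\t+\n"
        )
        tes = read_te_annotation(p)
        by_id = {t.te_id: t for t in tes}
        assert by_id["L1Md_F:L1:LINE"].loci[0].start == 999
        assert len(by_id["L1Md_F:L1:LINE"].loci) == 2
        assert by_id["IAP:ERVK:LTR"].te_class_raw == "LTR"

    def test_te_bed_round_trip(self, tmp_path, small_cohort):
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_te_annotation(small_cohort.te_features, p1)
        write_te_annotation(read_te_annotation(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_negative_coordinate_rejected(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text('chr1\tsrc\tgene\t0\t2000\t.\t+\t.\tgene_id "G1";\n')
        with pytest.raises(FormatError):
            read_gene_models(p)
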