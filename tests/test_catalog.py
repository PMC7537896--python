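"""GFF3 parsing, structure statistics and catalog assembly."""

import numpy as np
import pytest

from mybkit.catalog import (
    CatalogEntry,
    build_catalog,
    bhlh_crosstab,
    catalog_summary,
    chromosome_distribution,
    exon_histogram,
    family_share,
    load_catalog,
    parse_gff,
    save_catalog,
)
from mybkit.data import fixture_path
from mybkit.domain_scan import RepeatHit, classify_architecture
from mybkit.errors import GFFParseError, MybkitError, ReconciliationError
from mybkit.motif_scan import MotifHit

SINGLE_GENE_GFF = """##gff-version 3
Ma01\ttest\tgene\t100\t1000\t.\t+\t.\tID=Ma01_g00010
Ma01\ttest\tmRNA\t100\t1000\t.\t+\t.\tID=Ma01_g00010.t1;Parent=Ma01_g00010
Ma01\ttest\texon\t100\t300\t.\t+\t.\tID=e1;Parent=Ma01_g00010.t1
Ma01\ttest\texon\t400\t600\t.\t+\t.\tID=e2;Parent=Ma01_g00010.t1
Ma01\ttest\texon\t700\t1000\t.\t+\t.\tID=e3;Parent=Ma01_g00010.t1
Ma01\ttest\tCDS\t150\t300\t.\t+\t0\tID=c1;Parent=Ma01_g00010.t1
Ma01\ttest\tCDS\t400\t600\t.\t+\t0\tID=c2;Parent=Ma01_g00010.t1
"""

MINUS_STRAND_GFF = """##gff-version 3
Ma02\ttest\tgene\t50\t500\t.\t-\t.\tID=g1
Ma02\ttest\tmRNA\t50\t500\t.\t-\t.\tID=g1.t1;Parent=g1
Ma02\ttest\texon\t300\t500\t.\t-\t.\tID=x2;Parent=g1.t1
Ma02\ttest\texon\t50\t200\t.\t-\t.\tID=x1;Parent=g1.t1
"""


class TestParseGff:
    def test_single_gene_exon_count(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(SINGLE_GENE_GFF)
        (model,) = parse_gff(p)
        assert model.n_exons == 3
        assert (model.chrom, model.start, model.end) == ("Ma01", 100, 1000)

    def test_cds_counting_mode(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(SINGLE_GENE_GFF)
        (model,) = parse_gff(p, count_cds=True)
        assert model.n_exons == 2

    def test_minus_strand_exons_in_ascending_genomic_order(self):
        (model,) = parse_gff(MINUS_STRAND_GFF)
        assert model.strand == "-"
        assert model.exons == [(50, 200), (300, 500)]

    def test_missing_mrna_is_a_parse_error(self):
        bad = "##gff-version 3\nMa01\tt\tgene\t1\t10\t.\t+\t.\tID=g1\n"
        with pytest.raises(GFFParseError):
            parse_gff(bad)

    def test_generated_models_roundtrip_manifest(self, bundle):
        models = {m.gene_id: m for m in parse_gff(bundle.gff3)}
        man = bundle.manifest["genes"]
        assert set(models) == set(man)
        for gid, m in models.items():
            assert m.n_exons == man[gid]["n_exons"]
            assert m.chrom == man[gid]["chrom"]
            assert m.strand == man[gid]["strand"]
            assert (m.start, m.end) == (man[gid]["start"], man[gid]["end"])


class TestStatistics:
    def test_exon_histogram_matches_printed_survey(self, table1):
        hist = exon_histogram(table1, type_filter="R2R3")
        assert hist[3] == (155, 54.4)
        assert hist[4] == (67, 23.5)
        assert hist[1] == (7, 2.5)
        assert hist[2] == (23, 8.1)
        assert hist[5] == (21, 7.4)
        assert hist[6] == (8, 2.8)
        assert sum(c for c, _ in hist.values()) == 285

    def test_histogram_partitions_filtered_set(self, bundle):
        models = {m.gene_id: m for m in parse_gff(bundle.gff3)}
        entries = [
            CatalogEntry(
                gene_id=g,
                chrom=m.chrom,
                start=m.start,
                end=m.end,
                strand=m.strand,
                bhlh_flag=False,
                n_exons=m.n_exons,
                peptide_length=0,
                myb_type="R2R3",
            )
            for g, m in models.items()
        ]
        hist = exon_histogram(entries)
        assert sum(c for c, _ in hist.values()) == len(entries)

    def test_empty_filter_yields_empty_map(self, table1):
        assert exon_histogram(table1, type_filter="no-such-type") == {}

    def test_chromosome_distribution_matches_printed_survey(self, table1):
        counts, placed, unplaced = chromosome_distribution(table1)
        assert placed == 291 and unplaced == 3
        assert sum(counts.values()) == 294
        assert counts["Ma00"] == 3
        assert list(counts)[-1] == "Ma00"  # unplaced bin sorts last

    def test_single_chromosome_set(self):
        entries = [
            CatalogEntry("Ma05_g%05d" % i, "Ma05", i, i + 10, "+", False, 3, 100, "R2R3")
            for i in range(1, 6)
        ]
        counts, placed, unplaced = chromosome_distribution(entries)
        assert counts == {"Ma05": 5} and placed == 5 and unplaced == 0

    @pytest.mark.parametrize(
        "n,bg,decimals,expected",
        [(285, 35276, 2, 0.81), (285, 3155, 1, 9.0), (0, 100, 1, 0.0)],
    )
    def test_family_share(self, n, bg, decimals, expected):
        assert family_share(n, bg, decimals) == expected

    def test_family_share_zero_background_rejected(self):
        with pytest.raises(MybkitError):
            family_share(10, 0)

    def test_bhlh_crosstab_matches_printed_survey(self, table1):
        ct = bhlh_crosstab(table1)
        assert ct == {"22": 9, "25": 6, "23": 4, "27": 4, "24": 3, "unassigned": 4}
        assert sum(v for k, v in ct.items() if k != "unassigned") == 26

    def test_summary_totals(self, table1):
        s = catalog_summary(table1)
        assert s["n_total"] == 294
        assert s["type_counts"] == {"R2R3": 285, "3R": 6, "4R": 2, "CDC5": 1}
        assert s["n_bhlh"] == 30


class TestCatalogIO:
    def test_fixture_reserializes_byte_identical(self, table1):
        assert save_catalog(table1) == fixture_path("table1_catalog.tsv").read_text()

    def test_load_rejects_unknown_columns(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("foo\tbar\n1\t2\n")
        with pytest.raises(MybkitError):
            load_catalog(p)


class TestBuildCatalog:
    @staticmethod
    def _hit(i):
        return RepeatHit(1 + 60 * i, 52 + 60 * i, 100.0, (None,) * 3, 0, i + 1)

    def _model(self, gid, chrom="Ma01", start=100):
        from mybkit.catalog import GeneModel

        return GeneModel(
            gene_id=gid,
            chrom=chrom,
            start=start,
            end=start + 900,
            strand="+",
            exons=[(start, start + 900)],
            peptide_length=250,
        )

    def test_three_gene_example(self):
        archs = {
            "g2r": classify_architecture("g2r", [self._hit(0), self._hit(1)]),
            "g3r": classify_architecture("g3r", [self._hit(i) for i in range(3)]),
            "g1r": classify_architecture("g1r", [self._hit(0)]),
        }
        motifs = {"g2r": [MotifHit("g2r", 150, 169, "DLAARAAALAAAAAALAAAR")]}
        models = {g: self._model(g, start=100 + 10 * i) for i, g in enumerate(archs)}
        entries = build_catalog(archs, motifs, models)
        assert [e.gene_id for e in entries] == ["g2r", "g3r"]  # 1R excluded
        assert entries[0].bhlh_flag is True
        assert entries[1].bhlh_flag is False
        assert entries[0].myb_type == "R2R3" and entries[1].myb_type == "3R"

    def test_empty_inputs_give_empty_catalog(self):
        assert build_catalog({}, {}, {}) == []

    def test_missing_model_raises_reconciliation_error(self):
        archs = {"g": classify_architecture("g", [self._hit(0), self._hit(1)])}
        with pytest.raises(ReconciliationError, match="g"):
            build_catalog(archs, {}, {})

    def test_cdc5_supplied_by_annotation(self):
        archs = {"cdc": classify_architecture("cdc", [self._hit(0), self._hit(1)])}
        entries = build_catalog(
            archs, {}, {"cdc": self._model("cdc")}, cdc5_ids={"cdc"}
        )
        assert entries[0].myb_type == "2R" and entries[0].is_cdc5

    def test_entries_ordered_by_chromosome_then_start(self):
        archs = {
            g: classify_architecture(g, [self._hit(0), self._hit(1)])
            for g in ("a", "b", "c")
        }
        models = {
            "a": self._model("a", chrom="Ma00", start=5),
            "b": self._model("b", chrom="Ma02", start=500),
            "c": self._model("c", chrom="Ma02", start=100),
        }
        entries = build_catalog(archs, {}, models)
        assert [e.gene_id for e in entries] == ["c", "b", "a"]
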