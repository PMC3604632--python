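"""Table IO: dialect parsing, provenance attachment, round-trips, errors."""

import pytest

from genid_audit.annotation_io import (
    GeneInterval,
    GeneRecord,
    MappedPosition,
    Provenance,
    SnpRecord,
    TableIntegrityError,
    TableParseError,
    TableSchemaError,
    ValidationError,
    normalize_chromosome,
    read_gene_table,
    read_snp_table,
    write_gene_table,
    write_snp_table,
)

PROV = Provenance(database_name="TestDB", version="1", genome_build="Hg19")

GENE_HEADER = "GeneID\tSymbol\tSynonyms\tChromosome\tDescription\tHg18\tHg19\n"


def _write(tmp_path, text, name="t.tsv"):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestGeneTable:
    def test_published_fixture_parses_verbatim(self, table1):
        assert len(table1) == 6
        assert {r.gene_id for r in table1} == {9214, 5284, 83953, 148, 147, 146}
        faim3 = table1.by_id(9214)
        assert faim3.official_symbol == "FAIM3"
        assert "TOSO" in faim3.synonyms
        assert faim3.intervals["Hg19"] == GeneInterval("Hg19", "1", 207076633, 207095378)

    def test_unavailable_interval(self, table1):
        iv = table1.by_id(83953).intervals["Hg17"]
        assert not iv.available and iv.start is None and iv.end is None

    def test_fixture_carries_provenance(self, table1):
        assert table1.provenance.database_name
        assert table1.provenance.genome_build

    def test_empty_data_section(self, tmp_path):
        t = read_gene_table(_write(tmp_path, GENE_HEADER), provenance=PROV)
        assert len(t) == 0

    def test_round_trip_identity(self, table1, tmp_path):
        out = tmp_path / "rt.tsv"
        write_gene_table(table1, out)
        again = read_gene_table(out)
        assert again.records == table1.records
        assert again.provenance == table1.provenance

    def test_chr_prefix_normalized(self, tmp_path):
        row = "1\tA\t-\tchr22\tx\t10-20\t10-20\n"
        t = read_gene_table(_write(tmp_path, GENE_HEADER + row), provenance=PROV)
        assert t.records[0].chromosome == "22"
        assert t.records[0].intervals["Hg19"].chromosome == "22"

    def test_dash_means_no_synonyms(self, tmp_path):
        row = "1\tA\t-\t1\tx\t10-20\t10-20\n"
        t = read_gene_table(_write(tmp_path, GENE_HEADER + row), provenance=PROV)
        assert t.records[0].synonyms == ()

    def test_duplicate_gene_id_rejected(self, tmp_path):
        rows = "1\tA\t-\t1\tx\t10-20\t10-20\n1\tB\t-\t1\ty\t10-20\t10-20\n"
        with pytest.raises(TableIntegrityError, match="duplicate GeneID 1"):
            read_gene_table(_write(tmp_path, GENE_HEADER + rows), provenance=PROV)

    def test_malformed_coordinate_names_row_and_column(self, tmp_path):
        row = "1\tA\t-\t1\tx\t10-20\tbogus\n"
        with pytest.raises(TableParseError, match=r"row 2 column Hg19"):
            read_gene_table(_write(tmp_path, GENE_HEADER + row), provenance=PROV)

    def test_missing_column_is_schema_error(self, tmp_path):
        with pytest.raises(TableSchemaError, match="Synonyms"):
            read_gene_table(
                _write(tmp_path, "GeneID\tSymbol\tChromosome\tDescription\tHg19\n"),
                provenance=PROV,
            )

    def test_provenance_from_header_comments(self, tmp_path):
        text = "# db=X\n# version=2\n# build=Hg19\n" + GENE_HEADER
        t = read_gene_table(_write(tmp_path, text))
        assert t.provenance.database_name == "X"
        assert t.provenance.genome_build == "Hg19"

    def test_provenance_from_yaml_sidecar(self, tmp_path):
        p = _write(tmp_path, GENE_HEADER)
        (tmp_path / "t.tsv.provenance.yaml").write_text(
            "database_name: Y\nversion: '3'\ngenome_build: Hg18\n", encoding="utf-8"
        )
        assert read_gene_table(p).provenance.database_name == "Y"

    def test_no_provenance_anywhere_refused(self, tmp_path):
        with pytest.raises(TableSchemaError, match="provenance"):
            read_gene_table(_write(tmp_path, GENE_HEADER))


class TestSnpTable:
    def test_published_fixture(self, table2):
        assert len(table2) == 1
        (snp,) = table2
        assert snp.rsid == "rs2844871"
        assert any(
            mp.chromosome == "2" and mp.position == 125655701
            and mp.source.database_name == "dbSNP" and mp.source.version == "July 2011"
            for mp in snp.positions
        )

    def test_listed_no_position_rows(self, rs2844871):
        listed = [p for p in rs2844871.positions if p.status == "listed_no_position"]
        assert len(listed) == 2
        assert all(p.chromosome is None and p.position is None for p in listed)

    def test_not_available_row(self, rs2844871):
        assert sum(1 for p in rs2844871.positions if p.status == "not_available") == 1

    def test_row_order_preserved_within_rsid(self, rs2844871):
        first = rs2844871.positions[0]
        assert first.source.database_name == "Affymetrix 6.0"
        assert first.position == 14459243

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "rsid\tdatabase\tversion\tgenome_build\tchromosome\tposition\tstatus\n",
            encoding="utf-8",
        )
        assert read_snp_table(p) == []

    def test_location_column_dialect(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "rsid\tdatabase\tversion\tgenome_build\tlocation\n"
            "rs1\tD\tv\tHg19\tchr22: 14459242\n"
            "rs1\tD\tv\tHg19\tSNP is listed, but no position information given\n"
            "rs1\tD\tv\tHg19\tNA\n",
            encoding="utf-8",
        )
        (snp,) = read_snp_table(p)
        assert [(m.chromosome, m.position, m.status) for m in snp.positions] == [
            ("22", 14459242, "mapped"),
            (None, None, "listed_no_position"),
            (None, None, "not_available"),
        ]

    def test_non_numeric_position_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "rsid\tdatabase\tversion\tgenome_build\tchromosome\tposition\tstatus\n"
            "rs1\tD\tv\tHg19\t1\tabc\tmapped\n",
            encoding="utf-8",
        )
        with pytest.raises(TableParseError, match="position"):
            read_snp_table(p)

    def test_bad_rsid_error_vs_warn(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "rsid\tdatabase\tversion\tgenome_build\tchromosome\tposition\tstatus\n"
            "snp_9\tD\tv\tHg19\t1\t100\tmapped\n",
            encoding="utf-8",
        )
        with pytest.raises(ValidationError):
            read_snp_table(p)
        with pytest.warns(UserWarning):
            assert read_snp_table(p, on_bad_rsid="warn") == []

    def test_snp_round_trip(self, table2, tmp_path):
        out = tmp_path / "rt.tsv"
        write_snp_table(table2, out)
        assert read_snp_table(out) == table2


class TestDomainInvariants:
    def test_chromosome_normalization(self):
        assert normalize_chromosome("chr22") == "22"
        assert normalize_chromosome("chrUn_gl000244") == "Un_gl000244"
        assert normalize_chromosome(" 5 ") == "5"

    def test_interval_requires_ordered_coordinates(self):
        with pytest.raises(ValidationError):
            GeneInterval("Hg19", "1", 100, 50)
        with pytest.raises(ValidationError):
            GeneInterval("Hg19", "1", 0, 50)

    def test_unavailable_interval_forbids_coordinates(self):
        with pytest.raises(ValidationError):
            GeneInterval("Hg19", "1", 100, 200, available=False)

    def test_official_symbol_cannot_be_own_synonym(self):
        with pytest.raises(ValidationError):
            GeneRecord(1, "ABC", ("abc",), "1", "x")

    def test_mapped_status_requires_both_coordinates(self):
        with pytest.raises(ValidationError):
            MappedPosition(PROV, chromosome="1", position=None, status="mapped")
        with pytest.raises(ValidationError):
            MappedPosition(PROV, chromosome="1", position=5, status="not_available")

    def test_rsid_pattern_enforced(self):
        with pytest.raises(ValidationError):
            SnpRecord("SNP123")

    def test_provenance_requires_database_and_build(self):
        with pytest.raises(ValidationError):
            Provenance(database_name="", version="1", genome_build="Hg19")
        with pytest.raises(ValidationError):
            Provenance(database_name="D", version="1", genome_build=" ")
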