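"""Table dialect, GAF parsing and report round trips."""

import numpy as np
import pandas as pd
import pytest

from phosphoshift.design import DeltaDeltaRecord, is_missing
from phosphoshift.tables_io import (
    PhosphoSiteQuant,
    maxquant_to_dialect,
    read_delta_table,
    read_gaf,
    read_site_table,
    round_half_away,
    write_results,
    write_site_table,
    write_typed_results,
)

HEADER = ("protein\tgene\tposition\tresidue\tlocalization_prob\t"
          "Intensity L exp1_1\tIntensity M exp1_1")


def write_tsv(path, *rows):
    path.write_text("\n".join([HEADER, *rows]) + "\n", encoding="utf-8")


class TestSiteTableReader:
    def test_well_formed_rows_all_parsed(self, tmp_path, design):
        path = tmp_path / "sites.tsv"
        write_tsv(path,
                  "P1\tg1\t10\tS\t0.99\t100\t200",
                  "P2\t\t20\tT\t0.80\t300\t400",
                  "P3\tg3\t30\tY\t1.0\t500\t600")
        result = read_site_table(path, design)
        assert len(result.records) == 3
        assert result.n_rows == 3
        assert result.n_rejected_rows == 0

    def test_empty_cell_becomes_missing(self, tmp_path, design):
        path = tmp_path / "sites.tsv"
        write_tsv(path, "P1\t\t10\tS\t0.99\t\t200")
        rec = read_site_table(path, design).records[0]
        assert is_missing(rec.intensity("exp1", 1, "Lys0"))
        assert rec.intensity("exp1", 1, "Lys4") == 200.0

    def test_unparsable_cell_missing_and_counted(self, tmp_path, design):
        path = tmp_path / "sites.tsv"
        write_tsv(path, "P1\t\t10\tS\t0.99\tgarbage\t200")
        result = read_site_table(path, design)
        assert result.n_unparsable_cells == 1
        assert is_missing(result.records[0].intensity("exp1", 1, "Lys0"))

    def test_identity_columns_of_a_wt_only_substrate_row(self, tmp_path,
                                                         design):
        """The isocitrate lyase S398 site parses with its exact
        identity fields."""
        path = tmp_path / "sites.tsv"
        write_tsv(path, "AceA\taceA\t398\tS\t1.0\t1000\t1917.5")
        rec = read_site_table(path, design).records[0]
        assert (rec.protein, rec.position, rec.residue) == ("AceA", 398, "S")

    def test_missing_key_column_is_hard_error(self, tmp_path, design):
        path = tmp_path / "sites.tsv"
        path.write_text("protein\tposition\tresidue\nP1\t10\tS\n",
                        encoding="utf-8")
        with pytest.raises(ValueError, match="localization_prob"):
            read_site_table(path, design)

    def test_bad_residue_rejected_and_accounted(self, tmp_path, design):
        path = tmp_path / "sites.tsv"
        write_tsv(path,
                  "P1\t\t10\tS\t0.99\t100\t200",
                  "P2\t\t20\tH\t0.99\t100\t200")
        result = read_site_table(path, design)
        # no silent drops: every input row is a record or rejected
        assert result.n_rows == len(result.records) + result.n_rejected_rows
        assert result.n_rejected_rows == 1

    def test_write_read_round_trip(self, tmp_path, design):
        rng = np.random.default_rng(5)
        records = [
            PhosphoSiteQuant(
                protein=f"P{i}", position=i + 1,
                residue="STY"[i % 3], localization_prob=0.9,
                intensities={
                    slot: float(2.0 ** rng.uniform(10, 30))
                    for slot in design.channel_slots()
                    if rng.random() > 0.3
                },
            )
            for i in range(20)
        ]
        path = tmp_path / "sites.tsv"
        write_site_table(records, path, design)
        back = read_site_table(path, design).records
        assert len(back) == 20
        for orig, new in zip(records, back):
            assert orig.key == new.key
            assert set(orig.intensities) == set(new.intensities)
            for slot, value in orig.intensities.items():
                assert new.intensities[slot] == pytest.approx(value,
                                                              rel=1e-9)


class TestMaxQuantAdapter:
    def test_renames_identity_columns(self):
        frame = pd.DataFrame({
            "Proteins": ["P1"], "Gene names": ["g1"], "Position": [10],
            "Amino acid": ["S"], "Localization prob": [0.98],
            "Intensity L exp1_1": [100.0], "Sequence window": ["XXX"],
        })
        out = maxquant_to_dialect(frame)
        assert list(out.columns) == ["protein", "gene", "position",
                                     "residue", "localization_prob",
                                     "Intensity L exp1_1"]


class TestGaf:
    def test_aspects_mapped_and_grouped(self, tmp_path):
        lines = [
            "!gaf-version: 2.1",
            "\t".join(["UniProtKB", "P0", "aceA", "", "GO:0019752", "REF",
                       "IEA", "", "P", "", "", "protein", "taxon:83333",
                       "20180602", "GOA", "", ""]),
            "\t".join(["UniProtKB", "P0", "aceA", "", "GO:0004451", "REF",
                       "IEA", "", "F", "", "", "protein", "taxon:83333",
                       "20180602", "GOA", "", ""]),
        ]
        path = tmp_path / "a.gaf"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        anno = read_gaf(path)
        assert anno.by_gene == {
            "aceA": {("GO:0019752", "biological_process"),
                     ("GO:0004451", "molecular_function")}
        }

    def test_comment_only_file_is_empty(self, tmp_path):
        path = tmp_path / "a.gaf"
        path.write_text("!gaf-version: 2.1\n! more comments\n",
                        encoding="utf-8")
        assert read_gaf(path).by_gene == {}

    def test_duplicate_line_deduplicated(self, tmp_path):
        line = "\t".join(["DB", "P0", "g", "", "GO:1", "REF", "IEA", "", "C",
                          "", "", "protein", "taxon:1", "20180602", "GOA",
                          "", ""])
        path = tmp_path / "a.gaf"
        path.write_text(line + "\n" + line + "\n", encoding="utf-8")
        anno = read_gaf(path)
        assert anno.by_gene == {"g": {("GO:1", "cellular_component")}}

    def test_short_line_skipped_and_counted(self, tmp_path):
        path = tmp_path / "a.gaf"
        path.write_text("DB\tP0\tg\tGO:1\n", encoding="utf-8")
        anno = read_gaf(path)
        assert anno.by_gene == {}
        assert anno.n_lines_skipped == 1


class TestResultWriter:
    def test_published_amplified_site_formats_at_two_decimals(self, tmp_path):
        rec = DeltaDeltaRecord(protein="GlyA", site=55, residue="Y",
                               wt_shift=-3.391, ko_shift=7.579,
                               delta=7.579 - (-3.391))
        path = tmp_path / "out.tsv"
        write_results([rec], path)
        text = path.read_text(encoding="utf-8")
        for token in ("-3.39", "7.58", "10.97"):
            assert token in text

    def test_empty_record_list_yields_header_only(self, tmp_path):
        path = tmp_path / "out.tsv"
        write_typed_results([], path, ("protein", "delta"))
        assert path.read_text(encoding="utf-8") == "protein\tdelta\n"

    def test_round_trip_of_random_records_at_two_decimals(self, tmp_path):
        rng = np.random.default_rng(11)
        records = [
            DeltaDeltaRecord(
                protein=f"P{i}", site=i + 1, residue="S",
                wt_shift=float(rng.normal(0, 2)),
                ko_shift=float(rng.normal(0, 2)),
                delta=0.0,
            )
            for i in range(20)
        ]
        records = [
            DeltaDeltaRecord(
                protein=r.protein, site=r.site, residue=r.residue,
                wt_shift=r.wt_shift, ko_shift=r.ko_shift,
                delta=r.ko_shift - r.wt_shift,
            )
            for r in records
        ]
        path = tmp_path / "out.tsv"
        write_results(records, path)
        frame = read_delta_table(path)
        for rec, row in zip(records, frame.itertuples(index=False)):
            assert row.wt_shift == pytest.approx(
                round_half_away(rec.wt_shift), abs=1e-12)
            assert row.ko_shift == pytest.approx(
                round_half_away(rec.ko_shift), abs=1e-12)
            assert row.delta == pytest.approx(
                round_half_away(rec.delta), abs=1e-12)


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.005, 0.01), (-0.005, -0.01), (2.675, 2.68), (1.0, 1.0),
         (-1.834999, -1.83)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value) == pytest.approx(expected)
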