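"""I/O, coordinate conventions, and validation."""

import numpy as np
import pandas as pd
import pytest

from macscan import genome_io as gio


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadGenome:
    def test_base_counts_and_adenines(self, tmp_path):
        g = gio.load_genome(write(tmp_path, "g.fa", ">c1\nAATT\n"))
        assert g.lengths == {"c1": 4}
        assert g.base_counts["c1"]["A"] == 2
        # complement counting: plus-strand A + plus-strand T
        assert g.total_adenines == 4

    def test_empty_file_errors(self, tmp_path):
        with pytest.raises(ValueError, match="no records"):
            gio.load_genome(write(tmp_path, "e.fa", ""))

    def test_duplicate_names_error(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            gio.load_genome(write(tmp_path, "d.fa", ">c1\nAA\n>c1\nTT\n"))

    def test_invalid_character_named_with_position(self, tmp_path):
        with pytest.raises(ValueError, match="'X' at position 2"):
            gio.load_genome(write(tmp_path, "x.fa", ">c1\nAAXT\n"))

    def test_softmask_preserved_and_uppercased(self, tmp_path):
        g = gio.load_genome(write(tmp_path, "m.fa", ">c1\nAatT\n"))
        assert g.sequences["c1"] == "AATT"
        assert list(g.mask["c1"]) == [False, True, True, False]


class TestAnnotation:
    GFF = (
        "##gff-version 3\n"
        "c1\tsrc\tgene\t101\t400\t.\t{strand}\t.\tID=g1\n"
        "c1\tsrc\tmRNA\t101\t400\t.\t{strand}\t.\tID=t1;Parent=g1\n"
        "c1\tsrc\texon\t101\t400\t.\t{strand}\t.\tID=e1;Parent=t1\n"
    )

    @pytest.fixture
    def genome(self):
        return gio.GenomeIndex({"c1": "A" * 1000})

    def test_plus_strand_tss(self, tmp_path, genome):
        genes = gio.load_annotation(
            write(tmp_path, "a.gff3", self.GFF.format(strand="+")), genome
        )
        assert genes[0].tss == 100
        assert genes[0].exons == ((100, 400),)

    def test_minus_strand_tss(self, tmp_path, genome):
        genes = gio.load_annotation(
            write(tmp_path, "a.gff3", self.GFF.format(strand="-")), genome
        )
        assert genes[0].tss == 399

    def test_unknown_contig_errors(self, tmp_path, genome):
        bad = self.GFF.format(strand="+").replace("c1", "cX")
        with pytest.raises(ValueError, match="unknown contig"):
            gio.load_annotation(write(tmp_path, "b.gff3", bad), genome)

    def test_gene_without_exons_skipped_with_warning(self, tmp_path, genome):
        gff = "c1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
        with pytest.warns(UserWarning, match="no exons"):
            genes = gio.load_annotation(write(tmp_path, "c.gff3", gff), genome)
        assert genes == []

    def test_gff3_round_trip(self, tmp_path, genome):
        genes = gio.load_annotation(
            write(tmp_path, "a.gff3", self.GFF.format(strand="-")), genome
        )
        out = tmp_path / "out.gff3"
        gio.write_annotation(genes, out)
        again = gio.load_annotation(out, genome)
        assert [(g.gene_id, g.start, g.end, g.strand, g.exons) for g in again] == [
            (g.gene_id, g.start, g.end, g.strand, g.exons) for g in genes
        ]
        # original 1-based coordinates restored verbatim
        assert "\tgene\t101\t400\t" in out.read_text()


class TestModificationCalls:
    @pytest.fixture
    def genome(self):
        return gio.GenomeIndex({"c1": "AATT"})

    def test_one_based_to_internal(self, tmp_path, genome):
        p = write(
            tmp_path, "s.tsv",
            "contig\tposition\tstrand\tcoverage\tn_mod\nc1\t2\t+\t20\t20\n",
        )
        sites = gio.load_modification_calls(p, genome)
        assert sites.loc[0, "position"] == 1
        assert sites.loc[0, "ratio"] == 1.0

    def test_non_adenine_rows_rejected_and_counted(self, tmp_path):
        genome = gio.GenomeIndex({"c1": "AATT" * 60 + "GGGG"})
        seq = genome.sequences["c1"]
        rows = ["contig\tposition\tstrand\tcoverage\tn_mod"]
        rows += [f"c1\t{p + 1}\t+\t20\t20" for p in range(240) if seq[p] == "A"]
        rows += [f"c1\t{len(seq)}\t+\t20\t20"]  # a G position: rejected
        with pytest.warns(UserWarning, match="rejected 1 "):
            sites = gio.load_modification_calls(
                write(tmp_path, "s.tsv", "\n".join(rows) + "\n"), genome
            )
        assert len(sites) == 120

    def test_high_rejection_rate_is_hard_error(self, tmp_path, genome):
        p = write(
            tmp_path, "s.tsv",
            "contig\tposition\tstrand\tcoverage\tn_mod\nc1\t3\t+\t20\t20\n",
        )
        with pytest.raises(ValueError, match="coordinate-convention"):
            gio.load_modification_calls(p, genome)

    def test_fraction_rounds_half_even(self, tmp_path, genome):
        p = write(
            tmp_path, "s.tsv",
            "contig\tposition\tstrand\tcoverage\tfrac_mod\nc1\t1\t+\t21\t0.5\n",
        )
        sites = gio.load_modification_calls(p, genome)
        assert sites.loc[0, "n_mod"] == 10  # 10.5 rounds to even

    def test_modification_gff_dialect(self, tmp_path, genome):
        p = write(
            tmp_path, "s.gff",
            "##gff-version 3\n"
            "c1\tbasemod\tm6A\t2\t2\t32.5\t+\t.\tcoverage=25;frac=0.9\n",
        )
        sites = gio.load_modification_calls(p, genome)
        assert sites.loc[0, "position"] == 1
        assert sites.loc[0, "coverage"] == 25
        assert sites.loc[0, "n_mod"] == 22  # rint(22.5) -> 22
        assert sites.loc[0, "mqv"] == 32.5

    def test_tsv_round_trip(self, tmp_path, genome):
        sites = pd.DataFrame(
            {
                "contig": ["c1", "c1"],
                "position": [0, 2],
                "strand": ["+", "-"],
                "coverage": [20, 15],
                "n_mod": [20, 8],
                "mqv": [40.0, np.nan],
                "ratio": [1.0, 8 / 15],
            }
        )
        p = tmp_path / "rt.tsv"
        gio.write_modification_calls(sites, p)
        again = gio.load_modification_calls(p, genome)
        pd.testing.assert_frame_equal(sites, again)


class TestCxAndExpression:
    def test_context_rederived_and_mismatch_counted(self, tmp_path):
        genome = gio.GenomeIndex({"c1": "AACGT" * 120})
        rows = [f"c1\t{5*i+3}\t+\t5\t5\tCG" for i in range(120)]
        rows.append("c1\t3\t+\t5\t5\tCHH")  # file claims CHH, genome says CG
        with pytest.warns(UserWarning, match="context mismatches"):
            cx = gio.load_cx_report(
                write(tmp_path, "cx.txt", "\n".join(rows) + "\n"), genome
            )
        assert (cx["context"] == "CG").all()

    def test_high_mismatch_rate_errors(self, tmp_path):
        genome = gio.GenomeIndex({"c1": "AACGTAACGT"})
        p = write(tmp_path, "cx.txt", "c1\t3\t+\t5\t5\tCHH\n")
        with pytest.raises(ValueError, match="disagree"):
            gio.load_cx_report(p, genome)

    def test_negative_abundance_errors(self, tmp_path):
        p = write(tmp_path, "e.tsv", "gene_id\tabundance\ng1\t-1.0\n")
        with pytest.raises(ValueError, match="negative abundance"):
            gio.load_expression(p)

    def test_expression_optional_columns_filled(self, tmp_path):
        p = write(tmp_path, "e.tsv", "gene_id\tabundance\ng1\t5.0\n")
        df = gio.load_expression(p)
        assert list(df.columns) == gio.EXPRESSION_COLUMNS
        assert np.isnan(df.loc[0, "log2fc"])
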