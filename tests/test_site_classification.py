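"""Site filtering, symmetry, motif summaries, digest, telomeres."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_sites
from macscan import site_classification as sc
from macscan.genome_io import GenomeIndex, revcomp


class TestFilter:
    def test_coverage_and_strict_mqv_boundaries(self):
        sites = make_sites(
            [("c1", 0, "+", 14, 14), ("c1", 1, "+", 15, 15), ("c1", 2, "+", 30, 30)]
        )
        sites["mqv"] = [30.0, 26.0, 25.0]
        kept, removed = sc.filter_sites(sites, sc.FilterPolicy(15, 25.0))
        # mQv exactly 25 fails the strict > 25 requirement
        assert list(kept["coverage"]) == [15]
        assert removed == {"low_coverage": 1, "low_mqv": 1}

    def test_fallback_policy_boundary(self):
        sites = make_sites([("c1", 0, "+", 5, 5)])
        sites["mqv"] = [21.0]
        kept, _ = sc.filter_sites(sites, sc.FALLBACK_POLICY)
        assert len(kept) == 1

    def test_empty_input(self):
        kept, removed = sc.filter_sites(make_sites([]))
        assert len(kept) == 0

    @pytest.mark.parametrize("behavior,expected", [("pass", 1), ("fail", 0)])
    def test_mqv_absent_behavior(self, behavior, expected):
        sites = make_sites([("c1", 0, "+", 20, 20)])
        sites["mqv"] = np.nan
        kept, _ = sc.filter_sites(sites, sc.FilterPolicy(15, 25.0, behavior))
        assert len(kept) == expected


class TestSymmetry:
    def test_symmetric_pair(self, toy_genome):
        sites = make_sites([("c1", 1, "+"), ("c1", 2, "-")])
        s = sc.classify_symmetry(sites, toy_genome)
        assert s.fraction_symmetric == 1.0
        assert list(s.pairs["symmetry"]) == ["symmetric"]

    def test_hemi_watson(self, toy_genome):
        s = sc.classify_symmetry(make_sites([("c1", 1, "+")]), toy_genome)
        assert s.fraction_symmetric == 0.0
        assert list(s.pairs["symmetry"]) == ["hemi-watson"]

    def test_non_apt_site(self):
        genome = GenomeIndex({"c1": "AAAA"})
        s = sc.classify_symmetry(make_sites([("c1", 2, "+")]), genome)
        assert s.n_non_apt_sites == 1
        assert s.fraction_apt == 0.0

    def test_minus_site_without_at_never_paired(self):
        genome = GenomeIndex({"c1": "TTTT"})
        s = sc.classify_symmetry(make_sites([("c1", 2, "-")]), genome)
        assert len(s.pairs) == 0
        assert s.n_non_apt_sites == 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_partition_identity(self, data):
        """symmetric + hemi + non-ApT site counts always equal the input."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        seq = "".join(rng.choice(list("ACGT"), size=60))
        genome = GenomeIndex({"c1": seq})
        rows = []
        for pos in range(60):
            for strand in "+-":
                base = seq[pos] if strand == "+" else revcomp(seq[pos])
                if base == "A" and rng.random() < 0.3:
                    rows.append(("c1", pos, strand))
        sites = make_sites(rows)
        s = sc.classify_symmetry(sites, genome)
        assert s.n_symmetric_sites + s.n_hemi_sites + s.n_non_apt_sites == len(sites)


class TestMotifSummary:
    def test_identical_windows(self):
        genome = GenomeIndex({"c1": "GGGGGGATGGGGG" * 3})
        sites = make_sites([("c1", 6, "+"), ("c1", 19, "+"), ("c1", 32, "+")])
        m = sc.summarize_contexts(sites, genome)
        assert m.consensus[6] == "A"
        assert m.consensus[7] == "T"
        assert m.fraction_apt == 1.0
        assert m.n_sites == 3

    def test_minus_strand_window_reverse_complemented(self):
        # a plus site and a minus site whose extracted windows coincide
        seq = "GGGGGGATGGGGG"
        genome = GenomeIndex({"c1": seq + "NNNN" + revcomp(seq)})
        plus = make_sites([("c1", 6, "+")])
        minus = make_sites([("c1", len(seq) + 4 + 6, "-")])
        m_plus = sc.summarize_contexts(plus, genome)
        m_minus = sc.summarize_contexts(minus, genome)
        pd.testing.assert_frame_equal(m_plus.pfm, m_minus.pfm)

    def test_apt_fraction_counts_column_plus_one(self):
        rng = np.random.default_rng(5)
        seq = []
        rows = []
        cursor = 0
        for i in range(100):
            block = "GGGGGGA" + ("T" if i < 97 else "G") + "GGGGG"
            rows.append(("c1", cursor + 6, "+"))
            seq.append(block)
            cursor += len(block)
        genome = GenomeIndex({"c1": "".join(seq)})
        m = sc.summarize_contexts(make_sites(rows), genome)
        assert m.fraction_apt == pytest.approx(0.97)

    def test_zero_usable_sites_errors(self):
        genome = GenomeIndex({"c1": "AATT"})
        with pytest.raises(ValueError, match="no usable sites"):
            sc.summarize_contexts(make_sites([("c1", 1, "+")]), genome)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_pfm_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        genome = GenomeIndex({"c1": seq})
        rows = [("c1", int(p), "+") for p in range(10, 190) if seq[p] == "A"][:20]
        if not rows:
            return
        m = sc.summarize_contexts(make_sites(rows), genome)
        assert np.allclose(m.pfm.sum(axis=0), 1.0, atol=1e-12)


class TestGlobalLevel:
    def test_quarter(self, toy_genome):
        assert sc.global_level(make_sites([("c1", 1, "+")]), toy_genome) == 25.0

    def test_zero_and_full(self, toy_genome):
        assert sc.global_level(make_sites([]), toy_genome) == 0.0
        all_sites = make_sites(
            [("c1", 0, "+"), ("c1", 1, "+"), ("c1", 2, "-"), ("c1", 3, "-")]
        )
        assert sc.global_level(all_sites, toy_genome) == 100.0

    def test_no_adenines_errors(self):
        with pytest.raises(ValueError, match="no adenines"):
            sc.global_level(make_sites([]), GenomeIndex({"c1": "GGCC"}))


class TestDigest:
    def test_methylated_gatc(self):
        # one central GA^TC cut in the 8-mer: fragments of 4 and 4
        genome = GenomeIndex({"c1": "NNGATCNN"})
        sites = make_sites([("c1", 3, "+")])  # the A of GATC
        assert sc.insilico_digest(genome, sites, "DpnI")["c1"] == [4, 4]
        assert sc.insilico_digest(genome, sites, "DpnII")["c1"] == [8]

    def test_unmethylated_gatc(self):
        genome = GenomeIndex({"c1": "NGATCNNN"})
        none = make_sites([])
        assert sc.insilico_digest(genome, none, "DpnI")["c1"] == [8]
        assert sc.insilico_digest(genome, none, "DpnII")["c1"] == [3, 5]

    def test_minus_strand_adenine_counts_as_methylated(self):
        genome = GenomeIndex({"c1": "NNGATCNN"})
        sites = make_sites([("c1", 4, "-")])  # A opposite the T of GATC
        assert sc.insilico_digest(genome, sites, "DpnI")["c1"] == [4, 4]

    def test_no_gatc(self):
        genome = GenomeIndex({"c1": "AAAATTTT"})
        assert sc.insilico_digest(genome, make_sites([]), "DpnI")["c1"] == [8]


class TestTelomeres:
    def test_plus_strand_run_at_start(self):
        genome = GenomeIndex({"c1": "TTAGGGTTAGGG" + "A" * 30})
        hits = sc.find_telomeric_repeats(genome)
        assert [(h.start, h.end, h.strand, h.n_units) for h in hits] == [(0, 12, "+", 2)]
        assert hits[0].distance_to_end == 0

    def test_minus_strand_run_at_end(self):
        genome = GenomeIndex({"c1": "A" * 30 + "CCCTAACCCTAA"})
        hits = sc.find_telomeric_repeats(genome)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].end == 42

    def test_single_unit_is_not_a_hit(self):
        genome = GenomeIndex({"c1": "A" * 10 + "TTAGGG" + "A" * 10})
        assert sc.find_telomeric_repeats(genome) == []
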