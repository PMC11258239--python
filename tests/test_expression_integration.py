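"""Expression strata, gain/loss, Welch test, term enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from _oracles import hypergeom_enrichment_p
from conftest import make_sites
from macscan import expression_integration as ei
from macscan.genome_io import GeneModel
from macscan.mac_detection import MAC


def expr(values, ids=None):
    ids = ids or [f"g{i}" for i in range(len(values))]
    return pd.DataFrame({"gene_id": ids, "abundance": values})


class TestStratify:
    def test_quartiles_by_rank(self):
        strata = ei.stratify_expression(expr([8, 7, 6, 5, 4, 3, 2, 1]), n_top=2)
        q1 = set(strata.loc[strata["quartile"] == "Q1", "gene_id"])
        assert q1 == {"g0", "g1"}
        assert set(strata.loc[strata["in_top"], "gene_id"]) == {"g0", "g1"}

    def test_all_silent_degenerate(self):
        strata = ei.stratify_expression(expr([0, 0, 0, 0]), n_top=1)
        assert strata["silent"].all()
        assert (strata["quartile"] == "Q4").all()
        # deterministic tie rule: ranked by gene id
        assert list(strata["gene_id"]) == ["g0", "g1", "g2", "g3"]

    def test_truncated_sets_warn(self):
        with pytest.warns(UserWarning, match="truncating"):
            strata = ei.stratify_expression(expr([3, 2, 1]), n_top=400)
        assert strata["in_top"].sum() == 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1e4), min_size=4, max_size=40, unique=True))
    def test_invariant_to_monotone_transform(self, values):
        a = ei.stratify_expression(expr(values), n_top=2)
        b = ei.stratify_expression(expr([np.log1p(v) for v in values]), n_top=2)
        pd.testing.assert_series_equal(a["quartile"], b["quartile"])
        pd.testing.assert_series_equal(a["rank"], b["rank"])


class TestByStratum:
    def test_identical_counts_identical_distributions(self):
        strata = ei.stratify_expression(expr([4, 3, 2, 1]), n_top=1)
        counts = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(4)], "n_sites": 7, "n_macs": 0}
        )
        out = ei.methylation_by_stratum(strata, counts)
        assert (out["median"] == 7).all()
        assert (out["prop_with_mac"] == 0).all()

    def test_planted_association_recovered(self, sym_bundle):
        """clusters planted by expression stratum reappear as a MAC gradient."""
        assoc = sym_bundle["results"]["stratum_association"].set_index("stratum")
        probs = sym_bundle["truth"]["params"]["plant_prob_by_quartile"]
        for q, p in zip(["Q1", "Q2", "Q3", "Q4"], probs):
            assert abs(assoc.loc[q, "prop_with_mac"] - p) < 0.2
        assert assoc.loc["Q1", "prop_with_mac"] > assoc.loc["Q4", "prop_with_mac"]


class TestGainLoss:
    @staticmethod
    def gene(gid, tss):
        return GeneModel(gid, "c1", "+", tss, tss + 500, ((tss, tss + 500),))

    @staticmethod
    def mac(start, end):
        return MAC("c1", start, end, 5, 5, 0, 4)

    def test_labels(self):
        genes = [self.gene("gained", 1000), self.gene("lost", 5000),
                 self.gene("stable", 9000), self.gene("none", 13_000)]
        macs_a = [self.mac(1000, 1100), self.mac(9000, 9100)]
        macs_b = [self.mac(5000, 5100), self.mac(9200, 9300)]  # shifted but in window
        out = ei.mac_gain_loss(macs_a, macs_b, genes).set_index("gene_id")
        assert out.loc["gained", "change"] == "gained"
        assert out.loc["lost", "change"] == "lost"
        assert out.loc["stable", "change"] == "stable"  # presence-based
        assert out.loc["none", "change"] == "none"


class TestWelch:
    def test_identical_distributions(self):
        r = ei.welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0
        assert r.pvalue == 1.0

    def test_matches_reference_implementation(self):
        x, y = [1, 2, 3, 4, 5], [2, 3, 4, 5, 6]
        mine = ei.welch_ttest(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert mine.t == pytest.approx(ref.statistic, abs=1e-6)
        assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-6)
        assert mine.df == pytest.approx(ref.df, abs=1e-6)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            ei.welch_ttest([1.0], [1.0, 2.0])


class TestRatioShift:
    @staticmethod
    def gene(gid, tss):
        return GeneModel(gid, "c1", "+", tss, tss + 500, ((tss, tss + 500),))

    def make_inputs(self):
        up = [self.gene("up1", 1000)]
        down = [self.gene("dn1", 5000)]
        pos_up = [1010, 1020, 1030]
        pos_dn = [5010, 5020, 5030]
        a = make_sites([("c1", p, "+", 10, 8) for p in pos_up]
                       + [("c1", p, "+", 10, 4) for p in pos_dn]
                       + [("c1", 1040, "+", 10, 9)])  # present in A only
        b = make_sites([("c1", p, "+", 10, 4) for p in pos_up]
                       + [("c1", p, "+", 10, 8) for p in pos_dn])
        return a, b, {"up": up, "down": down}

    def test_fold_direction_and_matching(self):
        a, b, sets = self.make_inputs()
        out = ei.ratio_shift_test(a, b, sets)
        assert out["per_set"]["up"]["mean_fold"] == pytest.approx(2.0)
        assert out["per_set"]["down"]["mean_fold"] == pytest.approx(0.5)
        assert out["per_set"]["up"]["n_unmatched"] == 1  # A-only site excluded
        assert out["welch"] is not None
        assert out["welch"].pvalue < 0.01

    def test_identical_conditions_fold_one(self):
        a, _, sets = self.make_inputs()
        out = ei.ratio_shift_test(a, a, sets)
        assert out["per_set"]["up"]["mean_fold"] == 1.0
        assert out["welch"].t == 0.0


class TestTermEnrichment:
    def test_perfectly_enriched_term(self):
        background = {f"g{i}" for i in range(10)}
        selected = {f"g{i}" for i in range(5)}
        annotations = {g: {"T"} for g in selected}
        out = ei.term_enrichment(selected, background, annotations)
        from math import comb

        assert out.loc[0, "pvalue"] == pytest.approx(1 / comb(10, 5))
        assert bool(out.loc[0, "significant"])

    def test_equal_frequency_not_enriched(self):
        background = {f"g{i}" for i in range(10)}
        selected = {f"g{i}" for i in range(5)}
        annotations = {"g0": {"T"}, "g1": {"T"}, "g5": {"T"}, "g6": {"T"}}
        out = ei.term_enrichment(selected, background, annotations)
        assert out.loc[0, "pvalue"] >= 0.5

    def test_term_absent_from_selection(self):
        background = {f"g{i}" for i in range(10)}
        out = ei.term_enrichment({"g0"}, background, {"g9": {"T"}})
        assert out.loc[0, "pvalue"] == 1.0

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ei.term_enrichment(set(), {"g0"}, {})

    def test_matches_enumeration_oracle(self):
        background = {f"g{i}" for i in range(12)}
        selected = {f"g{i}" for i in range(5)}
        annotations = {f"g{i}": {"T"} for i in (0, 1, 2, 6, 7, 8, 9)}
        out = ei.term_enrichment(selected, background, annotations)
        assert out.loc[0, "pvalue"] == pytest.approx(
            hypergeom_enrichment_p(12, 7, 5, 3), abs=1e-12
        )
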