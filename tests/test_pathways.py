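import numpy as np
import pandas as pd
import pytest

from gutapns.io import PathwayAbundanceTable
from gutapns.pathways import (contribution_tables, group_contribution,
                              taxon_fractions)


class TestTaxonFractions:
    def test_simple_split(self, toy_pathway_table):
        frac = taxon_fractions(toy_pathway_table, "PWY-T", rank="genus")
        assert frac.loc["s1", "A"] == pytest.approx(0.6)
        assert frac.loc["s1", "B"] == pytest.approx(0.4)
        assert frac.loc["s1", "C"] == pytest.approx(0.0)

    def test_species_of_one_genus_pool_at_genus_rank(self):
        data = {
            "P: x": [10.0],
            "P: x|g__G.s__G_sp1": [6.0],
            "P: x|g__G.s__G_sp2": [3.0],
            "P: x|g__H.s__H_sp1": [1.0],
        }
        table = PathwayAbundanceTable(
            pd.DataFrame(data, index=pd.Index(["s1"], name="sample_id"))
        )
        genus = taxon_fractions(table, "P", rank="genus")
        assert genus.loc["s1", "G"] == pytest.approx(0.9)
        species = taxon_fractions(table, "P", rank="species")
        # species view refines the genus view
        assert species.loc["s1", ["G_sp1", "G_sp2"]].sum() == pytest.approx(
            genus.loc["s1", "G"])

    def test_all_zero_sample_yields_na_row(self):
        data = {
            "P: x": [10.0, 0.0],
            "P: x|g__G.s__G_sp1": [10.0, 0.0],
        }
        table = PathwayAbundanceTable(
            pd.DataFrame(data, index=pd.Index(["s1", "s2"], name="sample_id"))
        )
        frac = taxon_fractions(table, "P")
        assert frac.loc["s2"].isna().all()
        assert frac.loc["s1", "G"] == 1.0

    def test_unknown_pathway_rejected(self, toy_pathway_table):
        with pytest.raises(KeyError):
            taxon_fractions(toy_pathway_table, "NOPE-PWY")

    def test_invariant_to_stratified_row_order(self, toy_pathway_table):
        shuffled = PathwayAbundanceTable(
            toy_pathway_table.data[list(toy_pathway_table.data.columns[::-1])]
        )
        f1 = taxon_fractions(toy_pathway_table, "PWY-T").sort_index(axis=1)
        f2 = taxon_fractions(shuffled, "PWY-T").sort_index(axis=1)
        pd.testing.assert_frame_equal(f1, f2)

    def test_duplicate_strata_for_one_taxon_sum(self):
        # two rows mapping to the same genus (different species) pool correctly
        data = {
            "P: x": [8.0],
            "P: x|g__G.s__G_a": [2.0],
            "P: x|g__G.s__G_b": [6.0],
        }
        table = PathwayAbundanceTable(
            pd.DataFrame(data, index=pd.Index(["s1"], name="sample_id"))
        )
        frac = taxon_fractions(table, "P", rank="genus")
        assert frac.loc["s1", "G"] == 1.0


class TestGroupContribution:
    def test_single_sample_group_reproduces_split(self, toy_pathway_table):
        frac = taxon_fractions(toy_pathway_table, "PWY-T")
        groups = pd.Series({"s1": "g1", "s2": "g2", "s3": "g2", "s4": "g2"})
        out = group_contribution(frac, groups)
        assert out.loc["A", "g1"] == pytest.approx(60.0)
        assert out.loc["B", "g1"] == pytest.approx(40.0)

    def test_identical_groups_identical_columns(self, toy_pathway_table):
        frac = taxon_fractions(toy_pathway_table, "PWY-T")
        # both groups contain the same (duplicated) membership pattern
        groups = pd.Series({"s1": "g1", "s2": "g2", "s3": "g1", "s4": "g2"})
        doubled = pd.concat([frac.loc[["s1", "s3"]], frac.loc[["s1", "s3"]]])
        doubled.index = ["s1", "s3", "x1", "x2"]
        g = pd.Series({"s1": "g1", "s3": "g1", "x1": "g2", "x2": "g2"})
        out = group_contribution(doubled, g)
        pd.testing.assert_series_equal(out["g1"], out["g2"], check_names=False)

    def test_hand_computed_two_group_oracle(self):
        # spreadsheet oracle: fractions per sample, group means, x100
        # g1: s1 (.6,.4,0), s2 (.25,.25,.5)  -> means (.425,.325,.25)
        # g2: s3 (.25,0,.75), s4 (0,.5,.5)   -> means (.125,.25,.625)
        data = {
            "P: x": [10.0, 8.0, 4.0, 10.0],
            "P: x|g__A.s__a": [6.0, 2.0, 1.0, 0.0],
            "P: x|g__B.s__b": [4.0, 2.0, 0.0, 5.0],
            "P: x|g__C.s__c": [0.0, 4.0, 3.0, 5.0],
        }
        table = PathwayAbundanceTable(
            pd.DataFrame(data, index=pd.Index(["s1", "s2", "s3", "s4"],
                                              name="sample_id"))
        )
        frac = taxon_fractions(table, "P")
        groups = pd.Series({"s1": "g1", "s2": "g1", "s3": "g2", "s4": "g2"})
        out = group_contribution(frac, groups)
        assert out["g1"].to_dict() == {"A": 42.5, "B": 32.5, "C": 25.0}
        assert out["g2"].to_dict() == {"A": 12.5, "B": 25.0, "C": 62.5}

    def test_columns_sum_to_100(self, default_cohort):
        from gutapns.pathways import DEFAULT_PATHWAYS
        groups = pd.Series("all", index=default_cohort.pathways.data.index)
        table = contribution_tables(default_cohort.pathways, groups,
                                    pathway_ids=DEFAULT_PATHWAYS)
        for pid, sub in table.groupby("pathway"):
            assert sub["all"].sum() == pytest.approx(100.0, abs=0.1)

    def test_empty_group_omitted_with_warning(self):
        data = {"P: x": [10.0, 0.0], "P: x|g__G.s__g": [10.0, 0.0]}
        table = PathwayAbundanceTable(
            pd.DataFrame(data, index=pd.Index(["s1", "s2"], name="sample_id"))
        )
        frac = taxon_fractions(table, "P")
        groups = pd.Series({"s1": "ok", "s2": "empty"})  # s2 is all-NA
        with pytest.warns(UserWarning, match="omitted"):
            out = group_contribution(frac, groups)
        assert list(out.columns) == ["ok"]

    def test_pooled_mode_weights_by_abundance(self):
        # pooled mode: (6+0)/(10+10) vs mean-of-fractions (0.6+0)/2
        data = {
            "P: x": [10.0, 10.0],
            "P: x|g__A.s__a": [6.0, 0.0],
            "P: x|g__B.s__b": [4.0, 10.0],
        }
        table = PathwayAbundanceTable(
            pd.DataFrame(data, index=pd.Index(["s1", "s2"], name="sample_id"))
        )
        groups = pd.Series({"s1": "g", "s2": "g"})
        out = contribution_tables(table, groups, pathway_ids=["P"], mode="pooled")
        a = out.set_index("taxon").loc["A", "g"]
        assert a == pytest.approx(30.0)


class TestRankRefinement:
    def test_species_percents_sum_to_genus_percent(self, default_cohort):
        groups = pd.Series("all", index=default_cohort.pathways.data.index)
        pid = default_cohort.pathways.pathway_keys[0].split(":")[0]
        genus = contribution_tables(default_cohort.pathways, groups,
                                    pathway_ids=[pid], rank="genus")
        species = contribution_tables(default_cohort.pathways, groups,
                                      pathway_ids=[pid], rank="species")
        frac_g = taxon_fractions(default_cohort.pathways, pid, rank="genus")
        frac_s = taxon_fractions(default_cohort.pathways, pid, rank="species")
        # refinement on the raw fractions: summing species of a genus
        # reproduces the genus fraction sample-by-sample
        from gutapns.simulate import genus_of
        for g in frac_g.columns:
            members = [s for s in frac_s.columns if s.startswith(g + "_")]
            if members:
                pd.testing.assert_series_equal(
                    frac_s[members].sum(axis=1), frac_g[g], check_names=False
                )
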