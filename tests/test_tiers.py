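"""High-PCS selection, the tier rules, Tier 0 and Venn differences."""

import numpy as np
import pandas as pd
import pytest

from cdmkit import consistency, io, simulate, tiers


def records_frame(rows):
    """Rows of (probe, gene, platform, pcs, direction, high) -> record table."""
    return pd.DataFrame(
        [{"probe_id": p, "gene_symbol": g, "platform": plat, "pcs": pcs,
          "direction": d, "mean_intensity": 100.0,
          "passed_intensity_filter": True, "high_pcs": high}
         for p, g, plat, pcs, d, high in rows])


class TestSelectHighPcs:
    def _records(self, n, pcs=None):
        pcs = pcs if pcs is not None else np.linspace(1, 2, n)
        return pd.DataFrame({
            "probe_id": [f"p{i:03d}" for i in range(n)],
            "platform": "AFFY",
            "pcs": pcs,
            "passed_intensity_filter": True,
        })

    def test_top_10_percent_of_100_is_10(self):
        out = tiers.select_high_pcs(self._records(100), 0.10)
        assert out["high_pcs"].sum() == 10
        assert set(out.loc[out["high_pcs"], "probe_id"]) == {
            f"p{i:03d}" for i in range(90, 100)}

    def test_fraction_one_flags_everything(self):
        out = tiers.select_high_pcs(self._records(7), 1.0)
        assert out["high_pcs"].all()

    def test_all_equal_pcs_breaks_ties_lexicographically(self):
        out = tiers.select_high_pcs(self._records(30, pcs=np.ones(30)), 0.10)
        assert list(out.loc[out["high_pcs"], "probe_id"]) == ["p000", "p001", "p002"]

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            tiers.select_high_pcs(self._records(0), 0.1)

    def test_ranking_is_within_platform(self):
        rec = pd.concat([self._records(10), self._records(10).assign(platform="ILMN")],
                        ignore_index=True)
        out = tiers.select_high_pcs(rec, 0.10)
        assert out.groupby("platform")["high_pcs"].sum().tolist() == [1, 1]


class TestTierRules:
    """Constructed probe configurations exercising each assignment rule."""

    def test_two_same_platform_probes_down_is_tier2a(self):
        rec = records_frame([
            ("a1", "GENEA", "AFFY", 3.0, -1, True),
            ("a2", "GENEA", "AFFY", 2.5, -1, True),
            ("z1", "OTHER", "ILMN", 2.0, 1, True),
        ])
        out = tiers.assign_tiers(rec).set_index("gene_symbol")
        assert out.loc["GENEA", "tier"] == "2"
        assert "T2a" in out.loc["GENEA", "rules_fired"]
        assert out.loc["GENEA", "consensus_direction"] == -1

    def test_cross_platform_plus_multiprobe_up_is_tier1a(self):
        rec = records_frame([
            ("a1", "GENEB", "AFFY", 3.0, 1, True),
            ("a2", "GENEB", "AFFY", 2.5, 1, True),
            ("i1", "GENEB", "ILMN", 2.0, 1, True),
        ])
        out = tiers.assign_tiers(rec, multi_probe_platform="AFFY").set_index("gene_symbol")
        assert out.loc["GENEB", "tier"] == "1"
        assert "T1a" in out.loc["GENEB", "rules_fired"]

    def test_discordant_probes_cannot_reach_tier2(self):
        rec = records_frame([
            ("a1", "GENEC", "AFFY", 3.0, 1, True),
            ("a2", "GENEC", "AFFY", 2.5, -1, True),
            ("z1", "OTHER", "ILMN", 2.0, 1, True),
        ])
        out = tiers.assign_tiers(rec).set_index("gene_symbol")
        assert out.loc["GENEC", "tier"] == "high_pcs_unconfirmed"

    def test_three_concordant_same_platform_probes_is_tier1c(self):
        rec = records_frame([
            ("a1", "GENED", "AFFY", 3.0, -1, True),
            ("a2", "GENED", "AFFY", 2.5, -1, True),
            ("a3", "GENED", "AFFY", 2.2, -1, True),
            ("z1", "OTHER", "ILMN", 2.0, 1, True),
        ])
        out = tiers.assign_tiers(rec, multi_probe_platform="AFFY").set_index("gene_symbol")
        assert out.loc["GENED", "tier"] == "1"
        assert "T1c" in out.loc["GENED", "rules_fired"]

    def test_single_probe_per_platform_concordant_is_tier2b(self):
        rec = records_frame([
            ("a1", "GENEE", "AFFY", 3.0, -1, True),
            ("i1", "GENEE", "ILMN", 2.0, -1, True),
        ])
        out = tiers.assign_tiers(rec, multi_probe_platform="AFFY").set_index("gene_symbol")
        assert out.loc["GENEE", "tier"] == "2"
        assert "T2b" in out.loc["GENEE", "rules_fired"]

    def test_tier2_plus_shared_pathway_is_tier1b(self):
        rec = records_frame([
            ("a1", "GENEF", "AFFY", 3.0, -1, True),
            ("i1", "GENEF", "ILMN", 2.0, -1, True),
            ("i2", "GENEG", "ILMN", 2.1, 1, True),
        ])
        gene_sets = io.GeneSetCollection(sets={"PW1": {"GENEF", "GENEG"}})
        out = tiers.assign_tiers(rec, gene_sets, multi_probe_platform="AFFY")
        out = out.set_index("gene_symbol")
        assert out.loc["GENEF", "tier"] == "1"
        assert "T1b" in out.loc["GENEF", "rules_fired"]
        # the pathway partner gets Tier 3 only
        assert out.loc["GENEG", "tier"] == "3"

    def test_oversized_gene_set_does_not_grant_tier3(self):
        rec = records_frame([
            ("a1", "GENEH", "AFFY", 3.0, 1, True),
            ("i1", "GENEI", "ILMN", 2.0, 1, True),
        ])
        big = {f"G{i}" for i in range(600)} | {"GENEH", "GENEI"}
        gene_sets = io.GeneSetCollection(sets={"BIG": big})
        out = tiers.assign_tiers(rec, gene_sets).set_index("gene_symbol")
        assert (out["tier"] == "high_pcs_unconfirmed").all()

    def test_single_platform_records_rejected(self):
        rec = records_frame([("a1", "GENEA", "AFFY", 3.0, 1, True)])
        with pytest.raises(ValueError):
            tiers.assign_tiers(rec)


class TestTier0AndVenn:
    def _aux_records(self, gene_pcs):
        return pd.DataFrame([
            {"probe_id": f"x{i}", "gene_symbol": g, "platform": "AUX",
             "pcs": p, "direction": -1, "mean_intensity": 10.0,
             "passed_intensity_filter": True}
            for i, (g, p) in enumerate(gene_pcs.items())])

    def test_tier0_is_intersection_with_auxiliary_high_pcs(self):
        aux = self._aux_records({"B": 5.0, "C": 4.0, "D": 3.0, **{f"N{i}": 0.1 for i in range(27)}})
        tier0 = tiers.assign_tier0({"A", "B", "C"}, aux, top_fraction=0.10)
        assert tier0 == {"B", "C"}

    def test_disjoint_sets_give_empty_tier0(self):
        aux = self._aux_records({"X": 5.0, "Y": 0.1})
        assert tiers.assign_tier0({"A", "B"}, aux, top_fraction=0.5) == set()

    def test_auxiliary_fraction_one_returns_tier12(self):
        aux = self._aux_records({"A": 1.0, "B": 0.5, "C": 0.2})
        assert tiers.assign_tier0({"A", "B"}, aux, top_fraction=1.0) == {"A", "B"}

    def test_empty_auxiliary_records_error(self):
        with pytest.raises(ValueError):
            tiers.assign_tier0({"A"}, self._aux_records({}).iloc[:0])

    def test_venn_differences(self):
        venn = tiers.venn_difference(tier0={"A"}, tier1={"A", "B"},
                                     tier2={"A", "B"}, tier3={"A", "B", "C", "D"})
        assert venn["tier1_minus_0"] == {"B"}
        assert venn["tier2_minus_1"] == set()
        assert venn["tier3_minus_2"] == {"C", "D"}

    def test_nested_sets_partition(self):
        t0, t1, t2, t3 = {"A"}, {"A", "B"}, {"A", "B", "C"}, {"A", "B", "C", "D"}
        venn = tiers.venn_difference(t0, t1, t2, t3)
        union = venn["tier1_minus_0"] | venn["tier2_minus_1"] | venn["tier3_minus_2"]
        assert union == t3 - t0


class TestTierMonotonicity:
    def test_relaxing_top_fraction_never_demotes_a_gene(self, small_study):
        datasets, annotation, _ = small_study
        records = pd.concat([
            consistency.score_dataset(datasets[p], annotation)
            for p in ("AFFY1", "ILMN1")], ignore_index=True)
        rank = {t: i for i, t in enumerate(tiers.TIER_ORDER)}

        def tiers_at(frac):
            flagged = tiers.select_high_pcs(records, frac)
            out = tiers.assign_tiers(flagged)
            return {g: rank[t] for g, t in zip(out["gene_symbol"], out["tier"])}

        strict, relaxed = tiers_at(0.05), tiers_at(0.15)
        for gene, level in strict.items():
            assert relaxed[gene] <= level, gene

    def test_every_tier0_gene_is_in_tier1_or_tier2(self, small_study):
        datasets, annotation, _ = small_study
        records = {p: consistency.score_dataset(datasets[p], annotation)
                   for p in datasets}
        primary = pd.concat([records["AFFY1"], records["ILMN1"]], ignore_index=True)
        flagged = tiers.select_high_pcs(primary)
        assignments = tiers.assign_tiers(flagged)
        sets_ = tiers.tier_gene_sets(assignments)
        tier12 = sets_.get("1", set()) | sets_.get("2", set())
        tier0 = tiers.assign_tier0(tier12, records["ILMN2"])
        assert tier0 <= tier12
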