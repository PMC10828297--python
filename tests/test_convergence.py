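"""Trend-aware DEG-set intersection and sharing thresholds."""

import numpy as np
import pandas as pd
import pytest

from gerosig import GerosigError, InterventionRule, trend_intersection
from gerosig.convergence import (direction_consistency,
                                 direction_consistency_summary,
                                 flag_trend_conflicts, intervention_deg_set,
                                 shared_gene_report, venn_counts, ypar_deg_set)
from gerosig.sig_io import SignedGeneList

from conftest import make_table


class TestInterventionDegSet:
    def _tables(self, per_unit_up, intervention="senolysis"):
        """per_unit_up: unit -> genes upregulated there (others absent)."""
        out = []
        for unit, genes in per_unit_up.items():
            out.append(make_table(genes, np.ones(len(genes)), unit=unit,
                                  role="GI", intervention=intervention))
        return out

    def test_min_one_context_includes_single_organ_deg(self, thresholds):
        tabs = self._tables({"liver": ["A"], "lung": ["B"]})
        rule = InterventionRule("senolysis", 1, "up")
        assert intervention_deg_set(tabs, rule, thresholds) == {"A", "B"}

    def test_min_two_contexts_excludes_single_organ_deg(self, thresholds):
        tabs = self._tables({"liver": ["A", "B"], "pancreas": ["B"]},
                            "reprogramming")
        rule = InterventionRule("reprogramming", 2, "up")
        assert intervention_deg_set(tabs, rule, thresholds) == {"B"}

    def test_min_three_cell_types(self, thresholds):
        tabs = []
        for unit in ("hep", "endo", "kupffer"):
            tabs.append(make_table(["A"], [-1.0], unit=unit,
                                   role="GI", intervention="parabiosis",
                                   modality="single_cell"))
        rule = InterventionRule("parabiosis", 3, "down")
        assert intervention_deg_set(tabs, rule, thresholds) == {"A"}

    def test_intervention_mismatch_rejected(self, thresholds):
        tabs = self._tables({"liver": ["A"]}, "senolysis")
        rule = InterventionRule("reprogramming", 1, "up")
        with pytest.raises(GerosigError):
            intervention_deg_set(tabs, rule, thresholds)

    def test_raising_min_contexts_never_grows_set(self, thresholds):
        rng = np.random.default_rng(0)
        per_unit = {u: [f"g{i}" for i in rng.choice(20, 8, replace=False)]
                    for u in ("a", "b", "c")}
        tabs = self._tables(per_unit)
        prev = None
        for k in (1, 2, 3):
            cur = intervention_deg_set(
                tabs, InterventionRule("senolysis", k, "up"), thresholds)
            if prev is not None:
                assert cur <= prev
            prev = cur


def trend_oracle(gi_sets, ypar, aging_genes):
    """Per-gene membership by direct enumeration."""
    sets = dict(gi_sets, ypar=ypar, aging=aging_genes)
    out = {}
    for g in set().union(*sets.values()):
        out[g] = {sid: g in members for sid, members in sets.items()}
    return out


class TestTrendIntersection:
    GI = {"senolysis": frozenset("ABC"), "caloric_restriction": frozenset("BC"),
          "reprogramming": frozenset("C"), "parabiosis": frozenset("CD")}
    AGING = SignedGeneList(frozenset("BCE"), frozenset("XY"))

    def test_matches_enumeration_oracle(self):
        ypar = frozenset("CE")
        df = trend_intersection(self.GI, ypar, self.AGING, "gi_down_aging_up")
        oracle = trend_oracle(self.GI, ypar, self.AGING.up)
        assert set(df.index) == set(oracle)
        for g, memb in oracle.items():
            for sid, val in memb.items():
                assert df.loc[g, sid] == val
            assert df.loc[g, "n_sets"] == sum(memb.values())

    def test_counts_shared_sets(self):
        df = trend_intersection(self.GI, frozenset(), self.AGING,
                                "gi_down_aging_up")
        # B: senolysis + caloric_restriction + aging-up
        assert df.loc["B", "n_sets"] == 3

    def test_opposite_trend_uses_down_aging_genes(self):
        df = trend_intersection(self.GI, frozenset(), self.AGING,
                                "gi_up_aging_down")
        assert set(df.index[df["aging"]]) == {"X", "Y"}

    def test_single_set_gene_retained(self):
        df = trend_intersection(self.GI, frozenset(), self.AGING,
                                "gi_down_aging_up")
        assert df.loc["D", "n_sets"] == 1


class TestSharedGeneReport:
    def _memberships(self):
        gi = {"senolysis": frozenset("AB"), "caloric_restriction": frozenset("A"),
              "reprogramming": frozenset(), "parabiosis": frozenset("A")}
        aging = SignedGeneList(frozenset("AB"), frozenset("C"))
        up = trend_intersection(gi, frozenset("B"), aging, "gi_down_aging_up")
        down = trend_intersection(
            {k: frozenset() for k in gi}, frozenset(), aging,
            "gi_up_aging_down")
        return pd.concat([up, down])

    def test_threshold_filters_and_sorting(self):
        rep = shared_gene_report(self._memberships(), k=3)
        assert list(rep["gene"]) == ["A", "B"]
        assert rep["n_sets"].iloc[0] >= rep["n_sets"].iloc[1]

    def test_k_one_keeps_every_retained_gene(self):
        memb = self._memberships()
        rep = shared_gene_report(memb, k=1)
        assert set(rep["gene"]) == set(memb.index)

    def test_unattainable_k_gives_empty_report(self):
        rep = shared_gene_report(self._memberships(), k=6)
        assert rep.empty

    def test_raising_k_never_grows_report(self):
        memb = self._memberships()
        sizes = [len(shared_gene_report(memb, k)) for k in (1, 2, 3, 4)]
        assert sizes == sorted(sizes, reverse=True)

    def test_fold_change_matrix_has_missing_for_untested(self, thresholds):
        memb = self._memberships()
        t = make_table(["A"], [2.0], study_id="t1")
        rep = shared_gene_report(memb, k=1, tables=[t])
        col = t.context.label
        assert rep.loc[rep["gene"] == "A", col].iloc[0] == pytest.approx(2.0)
        assert rep.loc[rep["gene"] == "B", col].isna().all()

    def test_venn_regions_partition_memberships(self):
        memb = self._memberships()
        counts = venn_counts(memb)
        assert counts["n_genes"].sum() == len(memb)

    def test_gene_in_both_trends_flagged(self):
        gi = {"senolysis": frozenset(["A"])}
        aging = SignedGeneList(frozenset(["A"]), frozenset(["A2"]))
        up = trend_intersection(gi, frozenset(), aging, "gi_down_aging_up")
        down = trend_intersection(gi, frozenset(), aging, "gi_up_aging_down")
        flagged = flag_trend_conflicts(pd.concat([up, down]))
        assert flagged.loc["A", "conflict"].all()
        assert not flagged.loc["A2", "conflict"].any()


class TestDirectionConsistency:
    def _tables(self, signs):
        return [make_table(["G"], [s * 1.0], study_id=f"s{i}")
                for i, s in enumerate(signs)]

    @pytest.mark.parametrize("signs,expected", [
        ((1, 1, 1, -1), 0.75),
        ((1, 1, 1), 1.0),
        ((1, 1, -1, -1), 0.5),
    ])
    def test_majority_fraction(self, signs, expected, thresholds):
        assert direction_consistency("G", self._tables(signs),
                                     thresholds) == expected

    def test_never_deg_is_an_error(self, thresholds):
        with pytest.raises(GerosigError):
            direction_consistency("G", [make_table(["G"], [0.0])], thresholds)

    def test_summary_requires_multiple_calls(self, thresholds):
        tabs = self._tables((1, 1, -1))
        s = direction_consistency_summary(tabs, thresholds, min_tables=2)
        assert s["G"] == pytest.approx(2 / 3)


def test_ypar_set_uses_cell_type_rule(thresholds):
    tabs = [make_table(["A", "B"], [1.0, 1.0], unit=u, role="YPAR",
                       modality="single_cell", study_id="par")
            for u in ("hep", "endo", "kupffer")]
    tabs.append(make_table(["B"], [1.0], unit="tcell", role="YPAR",
                           modality="single_cell", study_id="par"))
    assert ypar_deg_set(tabs, "up", thresholds, 3) == {"A", "B"}
    assert ypar_deg_set(tabs, "up", thresholds, 4) == {"B"}
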