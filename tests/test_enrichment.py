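"""Over-representation tests and rank scoring."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from gerosig import (ContextKey, DEGThresholds, GeneSetLibrary, GerosigError,
                     ora_test, pathway_rank_scores, rank_score_correlation)
from gerosig.enrichment import (ci_gene_scores, ci_pathway_scores,
                                overlay_report)

from conftest import make_table


def hypergeom_tail_oracle(k, M, n, N):
    """P(X >= k) by direct enumeration of overlap outcomes."""
    return sum(comb(n, j) * comb(M - n, N - j)
               for j in range(k, min(n, N) + 1)) / comb(M, N)


def _library(n_bg=100, sets=None):
    bg = frozenset(f"g{i}" for i in range(n_bg))
    sets = sets or {"S1": frozenset(f"g{i}" for i in range(10))}
    return GeneSetLibrary(sets, bg)


class TestOraTest:
    def test_pvalue_matches_enumeration_small_background(self):
        # every background <= 30 configuration against the exact tail
        for M, n, N, k_in in [(20, 5, 8, 4), (30, 10, 12, 6), (25, 6, 6, 3)]:
            bg = [f"g{i}" for i in range(M)]
            lib = GeneSetLibrary({"S": frozenset(bg[:n])}, frozenset(bg))
            degs = bg[:k_in] + bg[n:n + (N - k_in)]
            res = ora_test(degs, lib, min_overlap=1, p_cutoff=1.0,
                           min_enrichment=0.0)
            assert res["overlap"].iloc[0] == k_in
            assert res["pvalue"].iloc[0] == pytest.approx(
                hypergeom_tail_oracle(k_in, M, n, N), abs=1e-12)

    def test_reference_example_fold_enrichment_and_tail(self):
        bg = [f"g{i}" for i in range(100)]
        lib = GeneSetLibrary({"S": frozenset(bg[:10])}, frozenset(bg))
        degs = bg[:5] + bg[50:55]  # overlap 5, list 10
        res = ora_test(degs, lib, p_cutoff=1.0, min_enrichment=0.0)
        assert res["fold_enrichment"].iloc[0] == pytest.approx(5.0)
        assert res["pvalue"].iloc[0] == pytest.approx(
            hypergeom_tail_oracle(5, 100, 10, 10), abs=1e-12)

    def test_overlap_one_omitted_regardless_of_p(self):
        bg = [f"g{i}" for i in range(100)]
        lib = GeneSetLibrary({"S": frozenset(bg[:1])}, frozenset(bg))
        res = ora_test([bg[0]], lib)  # overlap 1, p is tiny (1/100)
        assert res.empty

    def test_empty_deg_list_gives_empty_result(self):
        assert ora_test([], _library()).empty

    def test_genes_outside_background_dropped(self):
        lib = _library(20, {"S": frozenset(f"g{i}" for i in range(5))})
        res = ora_test(["g0", "g1", "NOT_MEASURED"], lib, min_overlap=1,
                       p_cutoff=1.0, min_enrichment=0.0)
        assert res["list_size"].iloc[0] == 2

    def test_empty_background_rejected(self):
        with pytest.raises(GerosigError):
            ora_test(["A"], GeneSetLibrary({}, frozenset()))


def _ctx(i, modality="bulk", role="AGING"):
    return ContextKey(f"s{i}", "g", f"u{i}", modality, role)


class TestPathwayRankScores:
    def _result(self, fdr):
        return pd.DataFrame({"set_id": ["S"], "overlap": [5], "list_size": [10],
                             "set_size": [10], "background_size": [100],
                             "fold_enrichment": [5.0], "pvalue": [1e-4],
                             "fdr": [fdr]})

    def test_organ_and_celltype_weights(self):
        results = {_ctx(i): self._result(1e-3) for i in range(3)}
        results.update({_ctx(10 + i, "single_cell"): self._result(1e-3)
                        for i in range(2)})
        scores = pathway_rank_scores(results)
        assert scores["S"] == pytest.approx(3 * 1.0 + 2 * 0.5)

    def test_fdr_at_cutoff_scores_zero(self):
        scores = pathway_rank_scores({_ctx(0): self._result(0.02)})
        assert scores["S"] == 0.0

    def test_no_hits_scores_zero(self):
        empty = self._result(1e-3).iloc[:0]
        assert pathway_rank_scores({_ctx(0): empty}).empty

    def test_additive_over_context_partition(self):
        all_results = {_ctx(i): self._result(1e-3) for i in range(4)}
        part_a = {c: r for c, r in list(all_results.items())[:2]}
        part_b = {c: r for c, r in list(all_results.items())[2:]}
        total = pathway_rank_scores(all_results)["S"]
        assert total == pathway_rank_scores(part_a)["S"] + \
            pathway_rank_scores(part_b)["S"]


class TestRankScoreCorrelation:
    def test_identical_tables_give_rho_one(self):
        s = pd.Series({"A": 3.0, "B": 2.0, "C": 1.0})
        rho, p, n = rank_score_correlation(s, s)
        assert rho == pytest.approx(1.0)
        assert n == 3

    def test_union_fills_absent_with_zero(self):
        a = pd.Series({"A": 3.0, "B": 1.0})
        b = pd.Series({"A": 2.0, "C": 1.0})
        rho, p, n = rank_score_correlation(a, b)
        assert n == 3

    def test_too_few_items_rejected(self):
        with pytest.raises(GerosigError):
            rank_score_correlation(pd.Series({"A": 1.0}),
                                   pd.Series({"B": 1.0}))


class TestCiGeneScores:
    def test_signed_counts_by_modality(self, thresholds):
        tabs = [
            make_table(["G"], [1.0], study_id="b1", role="CI"),
            make_table(["G"], [1.0], study_id="b2", role="CI"),
            make_table(["G"], [-1.0], study_id="b3", role="CI"),
            make_table(["G"], [-1.0], study_id="c1", role="CI",
                       modality="single_cell"),
            make_table(["G"], [-1.0], study_id="c2", role="CI",
                       modality="single_cell"),
            make_table(["G"], [-1.0], study_id="c3", role="CI",
                       modality="single_cell"),
        ]
        s = ci_gene_scores(tabs, thresholds)
        assert s.loc["G", "bulk_score"] == 1  # +1 +1 -1
        assert s.loc["G", "sc_score"] == -3

    def test_never_deg_scores_zero_zero(self, thresholds):
        tabs = [make_table(["G", "H"], [1.0, 0.0], study_id="b1", role="CI")]
        s = ci_gene_scores(tabs, thresholds)
        assert tuple(s.loc["H"]) == (0, 0)

    def test_scores_bounded_by_context_counts(self, thresholds):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        tabs = [make_table(genes, rng.normal(0, 1.5, 30), study_id=f"b{i}",
                           role="CI") for i in range(4)]
        s = ci_gene_scores(tabs, thresholds)
        assert s["bulk_score"].abs().max() <= 4
        assert (s["bulk_score"] == s["bulk_score"].astype(int)).all()


def test_ci_pathway_scores_signed_by_direction():
    hit = pd.DataFrame({"set_id": ["S"], "overlap": [5], "list_size": [10],
                        "set_size": [10], "background_size": [100],
                        "fold_enrichment": [5.0], "pvalue": [1e-4],
                        "fdr": [1e-3]})
    results = {
        (_ctx(0, role="CI"), "up"): hit,
        (_ctx(1, role="CI"), "up"): hit,
        (_ctx(2, role="CI"), "down"): hit,
        (_ctx(3, "single_cell", "CI"), "down"): hit,
    }
    s = ci_pathway_scores(results)
    assert s.loc["S", "bulk_score"] == 1  # +2 up, -1 down
    assert s.loc["S", "sc_score"] == -1


class TestOverlayReport:
    def test_unscored_highlights_appended_with_zero(self):
        scores = pd.DataFrame({"bulk_score": [2, -1, 3], "sc_score": [1, 0, 2]},
                              index=["A", "B", "C"])
        highlight = pd.Series(
            {g: "gi_down" for g in ["A", "B", "C", "D", "E"]})
        out = overlay_report(scores, highlight)
        assert len(out) == 5
        assert out.loc["D", "bulk_score"] == 0
        assert out["highlighted"].all()

    def test_empty_highlight_returns_plain_table(self):
        scores = pd.DataFrame({"bulk_score": [2], "sc_score": [1]},
                              index=["A"])
        out = overlay_report(scores, None)
        assert list(out.index) == ["A"]
        assert not out["highlighted"].any()
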