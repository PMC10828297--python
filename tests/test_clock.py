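"""Linear transcriptomic-clock application and cross-species plumbing."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from gerosig import (ClockModel, ExpressionMatrix, GerosigError, apply_clock,
                     compare_groups, map_homologs, normalize_for_clock,
                     scale_ages, simulate_clock_expression)
from gerosig.clock import (ClockTransform, UMI_GENE_LENGTH, read_clock_model,
                           read_homolog_map, write_clock_model)
from gerosig.synthetic import clock_homolog_map, make_test_clock


def _expr(values, genes, samples, lengths=None, units="counts"):
    vals = pd.DataFrame(values, index=genes, columns=samples, dtype=float)
    lengths = pd.Series(lengths, index=genes, dtype=float) \
        if lengths is not None else None
    return ExpressionMatrix(vals, lengths, units)


class TestMapHomologs:
    MAP = pd.DataFrame({"source": ["Cat", "Actb", "Gm1", "Gm2"],
                        "target": ["CAT", "ACTB", "SHARED", "SHARED"]})

    def test_rows_renamed_to_target_symbols(self):
        e = _expr([[1, 2]], ["Cat"], ["s1", "s2"], [1000])
        out = map_homologs(e, self.MAP)
        assert list(out.values.index) == ["CAT"]

    def test_collision_sum_conserves_abundance(self):
        e = _expr([[1, 2], [10, 20], [5, 5]], ["Gm1", "Gm2", "Cat"],
                  ["s1", "s2"], [500, 800, 1000])
        out = map_homologs(e, self.MAP, "sum")
        assert out.values.loc["SHARED"].tolist() == [11.0, 22.0]
        assert out.values.to_numpy().sum() == e.values.to_numpy().sum()

    def test_collision_max_policy(self):
        e = _expr([[1], [10]], ["Gm1", "Gm2"], ["s1"], [500, 800])
        out = map_homologs(e, self.MAP, "max")
        assert out.values.loc["SHARED", "s1"] == 10.0

    def test_collision_error_policy_names_target(self):
        e = _expr([[1], [10]], ["Gm1", "Gm2"], ["s1"], [500, 800])
        with pytest.raises(GerosigError, match="SHARED"):
            map_homologs(e, self.MAP, "error")

    def test_unmapped_genes_dropped(self):
        e = _expr([[1], [9]], ["Cat", "Unknown9"], ["s1"], [1000, 1000])
        out = map_homologs(e, self.MAP)
        assert list(out.values.index) == ["CAT"]

    def test_one_to_many_uses_first_listed_target(self):
        m = pd.DataFrame({"source": ["Dup", "Dup"], "target": ["T1", "T2"]})
        e = _expr([[4]], ["Dup"], ["s1"], [1000])
        out = map_homologs(e, m)
        assert list(out.values.index) == ["T1"]


class TestNormalize:
    def test_umi_units_force_10kb_lengths(self):
        # equal counts, UMI units: both genes get identical abundance
        e = _expr([[100], [100]], ["A", "B"], ["s1"], units="UMI")
        t = normalize_for_clock(e)
        assert t.loc["A", "s1"] == t.loc["B", "s1"]
        # and the abundance equals counts scaled by the fixed 10 kb length
        fpkm = 100 * 1e9 / (UMI_GENE_LENGTH * 200)
        assert t.loc["A", "s1"] == pytest.approx(np.log2(fpkm + 1))

    def test_length_normalization_ratio(self):
        e = _expr([[100], [100]], ["short", "long"], ["s1"], [1000, 10000])
        t = normalize_for_clock(e)
        ratio = (2 ** t.loc["short", "s1"] - 1) / (2 ** t.loc["long", "s1"] - 1)
        assert ratio == pytest.approx(10.0)

    def test_all_zero_sample_transforms_to_floor(self):
        e = _expr([[0], [0]], ["A", "B"], ["s1"], [1000, 1000])
        t = normalize_for_clock(e)
        assert (t == 0.0).all().all()  # log2(0 + 1)

    def test_counts_without_lengths_rejected(self):
        e = _expr([[1]], ["A"], ["s1"])
        with pytest.raises(GerosigError):
            normalize_for_clock(e)


class TestApplyClock:
    def test_intercept_only_clock(self):
        clock = ClockModel(50.0, pd.Series({"A": 0.0, "B": 1e-12}))
        t = pd.DataFrame([[0.0, 0.0], [0.0, 0.0]], index=["A", "B"],
                         columns=["s1", "s2"])
        ages = apply_clock(t, clock)
        np.testing.assert_allclose(ages, 50.0)

    def test_linearity_in_transformed_expression(self):
        clock = ClockModel(10.0, pd.Series({"A": 2.0, "B": -1.0}))
        t = pd.DataFrame([[1.0], [3.0]], index=["A", "B"], columns=["s"])
        base = apply_clock(t, clock)["s"]
        t2 = t.copy()
        t2.loc["A"] += 0.5
        assert apply_clock(t2, clock)["s"] == pytest.approx(base + 2.0 * 0.5)

    def test_missing_clock_genes_imputed_at_zero_transform(self):
        clock = ClockModel(10.0, pd.Series({"A": 2.0, "MISSING": 5.0}),
                           ClockTransform(pseudocount=1.0))
        t = pd.DataFrame([[1.0]], index=["A"], columns=["s"])
        # log2(0+1) = 0 contribution from the missing gene
        assert apply_clock(t, clock)["s"] == pytest.approx(12.0)

    def test_no_clock_gene_present_rejected(self):
        clock = ClockModel(10.0, pd.Series({"A": 2.0}))
        t = pd.DataFrame([[1.0]], index=["OTHER"], columns=["s"])
        with pytest.raises(GerosigError):
            apply_clock(t, clock)


class TestScaleAges:
    def test_none_is_identity(self):
        ages = pd.Series([40.0, 60.0], index=["a", "b"])
        pd.testing.assert_series_equal(scale_ages(ages, "none"), ages)

    def test_zscore_population_convention(self):
        ages = pd.Series([40.0, 60.0], index=["a", "b"])
        np.testing.assert_allclose(scale_ages(ages, "zscore"), [-1.0, 1.0])

    def test_minmax(self):
        ages = pd.Series([40.0, 50.0, 60.0], index=list("abc"))
        np.testing.assert_allclose(scale_ages(ages, "minmax"), [0, 0.5, 1])

    def test_scaling_within_panels(self):
        ages = pd.Series([40.0, 60.0, 0.0, 10.0], index=list("abcd"))
        panels = pd.Series(["p1", "p1", "p2", "p2"], index=list("abcd"))
        out = scale_ages(ages, "zscore", panels)
        np.testing.assert_allclose(out, [-1, 1, -1, 1])

    def test_constant_panel_warns_and_zeroes(self):
        ages = pd.Series([50.0, 50.0], index=["a", "b"])
        with pytest.warns(UserWarning):
            out = scale_ages(ages, "minmax")
        np.testing.assert_allclose(out, 0.0)


def ranksum_oracle(x, y):
    """Two-sided exact rank-sum p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:len(x)].sum()
    mid = len(pooled) * (len(pooled) + 1) / 2 * len(x) / len(pooled)
    stats = []
    for idx in combinations(range(len(pooled)), len(x)):
        stats.append(ranks[list(idx)].sum())
    stats = np.array(stats)
    return np.mean(np.abs(stats - mid) >= abs(obs - mid) - 1e-12)


class TestCompareGroups:
    def test_identical_groups(self):
        ages = pd.Series([1.0, 2.0, 1.0, 2.0])
        groups = pd.Series(["a", "a", "b", "b"])
        delta, p = compare_groups(ages, groups)
        assert delta == 0.0 and p == 1.0

    def test_exact_enumeration_small_groups(self):
        ages = pd.Series([1.0, 2.0, 3.0, 4.0])
        groups = pd.Series(["ref", "ref", "test", "test"])
        delta, p = compare_groups(ages, groups, order=("ref", "test"))
        assert delta == pytest.approx(2.0)
        assert p == pytest.approx(1 / 3)  # 2 of 6 assignments as extreme

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, 4), rng.normal(1, 1, 5)
        ages = pd.Series(np.concatenate([x, y]))
        groups = pd.Series(["a"] * 4 + ["b"] * 5)
        _, p = compare_groups(ages, groups, order=("a", "b"))
        assert p == pytest.approx(ranksum_oracle(x, y), abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(GerosigError):
            compare_groups(pd.Series([1.0, 2.0, 3.0]),
                           pd.Series(["a", "b", "b"]))


class TestClockSimulation:
    def test_noiseless_full_protocol_recovers_ages(self):
        clock = make_test_clock(seed=3)
        ages = [70.0, 55.0, 41.5, 30.0]
        expr = simulate_clock_expression(clock, ages, mouse_symbols=True)
        mapped = map_homologs(expr, clock_homolog_map(clock))
        pred = apply_clock(normalize_for_clock(mapped, clock.transform),
                           clock)
        np.testing.assert_allclose(pred.to_numpy(), ages, atol=1e-6)

    def test_equal_ages_give_constant_readout(self):
        clock = make_test_clock(seed=2)
        expr = simulate_clock_expression(clock, [50.0] * 4)
        pred = apply_clock(normalize_for_clock(expr, clock.transform), clock)
        np.testing.assert_allclose(pred, 50.0, atol=1e-6)

    def test_recovery_error_monotone_in_noise(self):
        clock = make_test_clock(seed=1)
        ages = np.array([70.0, 60.0, 50.0, 40.0, 30.0])
        errs = []
        for noise in (0.2, 2.0, 20.0):
            level = []
            for seed in range(10):
                expr = simulate_clock_expression(clock, ages, noise_sd=noise,
                                                 seed=seed)
                pred = apply_clock(
                    normalize_for_clock(expr, clock.transform), clock)
                level.append(np.abs(pred.to_numpy() - ages).mean())
            errs.append(np.mean(level))
        assert errs[0] < errs[1] < errs[2]

    def test_unrepresentable_ages_rejected(self):
        clock = make_test_clock(seed=0)
        with pytest.raises(GerosigError):
            simulate_clock_expression(clock, [10000.0])


def test_clock_model_file_round_trip(tmp_path):
    clock = make_test_clock(seed=4, intercept=42.5)
    path = tmp_path / "clock.tsv"
    write_clock_model(clock, path)
    back = read_clock_model(path)
    assert back.intercept == clock.intercept
    pd.testing.assert_series_equal(back.coefficients, clock.coefficients)
    assert back.transform == clock.transform


def test_homolog_map_reader_requires_columns(tmp_path):
    path = tmp_path / "map.tsv"
    path.write_text("mouse\thuman\nCat\tCAT\n")
    with pytest.raises(GerosigError):
        read_homolog_map(path)


def test_all_zero_coefficients_rejected():
    with pytest.raises(GerosigError):
        ClockModel(40.0, pd.Series({"A": 0.0, "B": 0.0}))
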