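"""Condition enrichment, core-TF selection, meta-analysis, permutation null."""

from math import comb, log

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import trnkit as tk
from trnkit.enrich import (
    Condition,
    call_degs,
    conditions_from_design,
    core_tf_selection,
    correlation_enrichment,
    differential_expression,
    fisher_enrichment,
    fisher_method_meta,
    geneset_enrichment,
    ingest_de_table,
    overlap_test,
    permutation_fdr,
    signed_logp_matrix,
)
from trnkit.trn import TFModule


def exact_tail(a, b, c, d):
    """One-sided Fisher P by full hypergeometric enumeration (integers)."""
    n, k, m = a + b + c + d, a + c, a + b
    num = sum(comb(k, j) * comb(n - k, m - j) for j in range(a, min(k, m) + 1))
    return num / comb(n, m)


def module(genes):
    return TFModule("T", tuple(genes), {})


class TestConditions:
    def test_fifteen_default_contrasts(self, default_study):
        conds = conditions_from_design(default_study.design)
        assert len(conds) == 15
        assert all(c.ref_allele == "Q20" for c in conds)

    def test_case_equals_reference_rejected(self):
        with pytest.raises(ValueError):
            Condition("Q20", "Q20", 6)


class TestDifferentialExpression:
    def test_small_group_error_names_condition(self, default_study):
        cond = Condition("Q80", "Q20", 6)
        tiny = default_study.design.iloc[:3]
        with pytest.raises(ValueError, match="Q80@6mo"):
            differential_expression(default_study.counts, tiny, cond)

    def test_direction_consistent_with_fold_change(self, default_study):
        de = differential_expression(
            default_study.counts, default_study.design, Condition("Q175", "Q20", 10)
        )
        up = de[de["direction"] == "up"]
        assert (up["log2_fc"] > 0).all()

    def test_ingest_external_table(self):
        tab = pd.DataFrame(
            {"gene": ["a", "b"], "log2_fc": [1.0, -2.0], "pvalue": [0.001, 0.5]}
        )
        de = ingest_de_table(tab)
        assert list(de["direction"]) == ["up", "down"]
        with pytest.raises(ValueError):
            ingest_de_table(tab.drop(columns=["pvalue"]))


class TestCallDegs:
    DE = pd.DataFrame(
        {
            "log2_fc": [1.0, -1.0, 0.5, 0.0, -0.2],
            "pvalue": [0.009, 0.009, 0.01, 0.001, 0.5],
        },
        index=list("abcde"),
    )

    def test_strict_threshold_and_zero_fc_exclusion(self):
        up, down = call_degs(self.DE)
        assert up == {"a"}          # p exactly 0.01 (gene c) excluded
        assert down == {"b"}        # zero fold change (gene d) excluded

    def test_partition_identity(self):
        up, down = call_degs(self.DE, p_threshold=0.05)
        expected = self.DE[(self.DE.pvalue < 0.05) & (self.DE.log2_fc != 0)]
        assert len(up) + len(down) == len(expected)


class TestFisherEnrichment:
    def test_balanced_table(self):
        universe = {f"g{i}" for i in range(20)}
        res = fisher_enrichment(
            module([f"g{i}" for i in range(10)]),
            {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(10, 15)},
            universe,
        )
        assert (res.a, res.b, res.c, res.d) == (5, 5, 5, 5)
        assert res.odds_ratio == 1.0
        assert res.p == pytest.approx(0.6718591006516703, rel=1e-9)

    def test_full_overlap_minimum_p(self):
        universe = {f"g{i}" for i in range(20)}
        mod = [f"g{i}" for i in range(5)]
        res = fisher_enrichment(module(mod), set(mod), universe)
        assert res.p == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_zero_overlap_direction(self):
        universe = {f"g{i}" for i in range(20)}
        res = fisher_enrichment(
            module([f"g{i}" for i in range(5)]),
            {f"g{i}" for i in range(5, 10)},
            universe,
        )
        assert res.odds_ratio == 0.0
        assert res.odds_ratio_display > 0
        assert res.p > 0.9

    def test_empty_module_after_intersection_raises(self):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                fisher_enrichment(module(["x"]), {"a"}, {"a", "b"})

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 13, size=4)
            if a + b == 0 or a + c == 0:
                continue
            universe = {f"g{i}" for i in range(a + b + c + d)}
            ul = sorted(universe)
            res = fisher_enrichment(
                module(ul[: a + b]), set(ul[:a]) | set(ul[a + b : a + b + c]), universe
            )
            assert res.p == pytest.approx(exact_tail(a, b, c, d), rel=1e-10)


class TestCoreSelection:
    def _table(self, pvals):
        rows = []
        for i, p in enumerate(pvals):
            rows.append(dict(module="T", condition=f"c{i}", direction="up", p=p,
                             odds_ratio=2.0))
            rows.append(dict(module="T", condition=f"c{i}", direction="down", p=0.5,
                             odds_ratio=1.0))
        return pd.DataFrame(rows)

    def test_five_significant_conditions_is_core(self):
        rep = core_tf_selection(self._table([1e-7] * 5 + [0.5] * 10))
        assert bool(rep.loc[rep.module == "T", "core"].iloc[0])

    def test_four_conditions_not_core(self):
        rep = core_tf_selection(self._table([1e-7] * 4 + [0.5] * 11))
        assert not bool(rep.loc[rep.module == "T", "core"].iloc[0])

    def test_threshold_is_strict(self):
        rep = core_tf_selection(self._table([1e-6] * 15))
        assert rep.loc[rep.module == "T", "n_sig_conditions"].iloc[0] == 0

    def test_min_over_directions(self):
        tab = self._table([0.5])
        tab.loc[tab.direction == "down", "p"] = 1e-8
        rep = core_tf_selection(tab)
        assert rep.loc[rep.module == "T", "n_sig_conditions"].iloc[0] == 1


class TestPermutationNull:
    def test_zero_permutations_rejected(self, default_study):
        modules = {"T": module(list(default_study.truth.gene_ids[:20]))}
        with pytest.raises(ValueError):
            permutation_fdr(
                default_study.counts, default_study.design, modules, B=0
            )

    def test_seeded_determinism(self, default_study):
        modules = {
            tf: TFModule(tf, tuple(default_study.truth.targets_of(tf)), {})
            for tf in default_study.config.core_tf_ids[:2]
        }
        kw = dict(B=3, seed=42)
        n1 = permutation_fdr(default_study.counts, default_study.design, modules, **kw)
        n2 = permutation_fdr(default_study.counts, default_study.design, modules, **kw)
        assert n1.counts.equals(n2.counts)

    def test_empirical_fdr_definition(self, default_study):
        modules = {"T": module(list(default_study.truth.gene_ids[:30]))}
        null = permutation_fdr(
            default_study.counts, default_study.design, modules, B=2, seed=0
        )
        assert np.isnan(null.empirical_fdr(0))
        assert 0 <= null.empirical_fdr(3) <= 1


class TestFisherMethod:
    def test_reference_value(self):
        res = fisher_method_meta([0.05, 0.05])
        assert res.chi2 == pytest.approx(11.98293, abs=1e-3)
        assert res.df == 4
        numeric = integrate.quad(lambda x: stats.chi2.pdf(x, 4), res.chi2, np.inf)[0]
        assert res.combined_p == pytest.approx(numeric, abs=1e-6)

    def test_all_ones(self):
        assert fisher_method_meta([1.0, 1.0]).combined_p == 1.0

    def test_single_study_identity(self):
        assert fisher_method_meta([0.2]).combined_p == pytest.approx(0.2, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        ps=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6),
        j=st.integers(0, 5),
        factor=st.floats(1.0, 10.0),
    )
    def test_monotone_in_each_input(self, ps, j, factor):
        base = fisher_method_meta(ps).combined_p
        ps2 = list(ps)
        k = j % len(ps2)
        ps2[k] = min(1.0, ps2[k] * factor)
        assert fisher_method_meta(ps2).combined_p >= base - 1e-12

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_method_meta([0.0, 0.5])


class TestCorrelationEnrichment:
    CAG = np.array([20, 80, 92, 111, 140, 175], dtype=float)

    def test_perfect_correlation(self):
        ab = pd.DataFrame([2.0 * self.CAG], index=["p1"])
        noise = pd.DataFrame(
            np.random.default_rng(0).normal(size=(30, 6)),
            index=[f"n{i}" for i in range(30)],
        )
        stats_df, _, _ = correlation_enrichment(
            pd.concat([ab, noise]), self.CAG, {}, p_threshold=0.01
        )
        assert stats_df.loc["p1", "r"] == pytest.approx(1.0)
        assert stats_df.loc["p1", "pvalue"] < 1e-10

    def test_null_significant_fraction(self, rng):
        cag = np.repeat(self.CAG, 8)
        ab = pd.DataFrame(rng.normal(size=(2000, len(cag))))
        stats_df, _, _ = correlation_enrichment(ab, cag, {}, p_threshold=0.01)
        frac = float((stats_df["pvalue"] < 0.01).mean())
        assert 0.003 <= frac <= 0.03

    def test_constant_rows_excluded(self):
        ab = pd.DataFrame(
            [[1.0] * 6, list(range(6))], index=["const", "ok"]
        )
        stats_df, _, n_excl = correlation_enrichment(ab, self.CAG, {})
        assert n_excl == 1 and list(stats_df.index) == ["ok"]

    def test_module_equal_to_signed_set_gets_minimum_p(self, rng):
        cag = np.repeat(self.CAG, 3)
        n = len(cag)
        pos = pd.DataFrame(
            cag * 1.0 + rng.normal(scale=1.0, size=(10, n)),
            index=[f"p{i}" for i in range(10)],
        )
        null = pd.DataFrame(
            rng.normal(size=(90, n)), index=[f"n{i}" for i in range(90)]
        )
        ab = pd.concat([pos, null])
        modules = {"M": TFModule("M", tuple(pos.index), {})}
        _, enr, _ = correlation_enrichment(ab, cag, modules)
        row = enr[(enr.direction == "positive")].iloc[0]
        assert row.a == 10 and row.b == 0
        assert row.p == pytest.approx(
            exact_tail(row.a, row.b, row.c, row.d), rel=1e-9
        )


class TestOverlapTest:
    def test_subset_of_universe_degenerate(self):
        b = {f"g{i}" for i in range(5)}
        a = {f"g{i}" for i in range(3)}
        shared, _, p = overlap_test(a, b, b)
        assert shared == 3 and p == pytest.approx(1.0)

    def test_disjoint_or_zero(self):
        universe = {f"g{i}" for i in range(10)}
        _, orat, _ = overlap_test({"g0"}, {"g1"}, universe)
        assert orat == 0.0

    def test_cortex_style_overlap_matches_enumeration(self):
        universe = {f"g{i}" for i in range(718)}
        ul = sorted(universe)
        a = set(ul[:48])
        b = set(ul[:16]) | set(ul[48 : 48 + 84])
        shared, orat, p = overlap_test(a, b, universe)
        assert shared == 16
        table = (16, 32, 84, 718 - 16 - 32 - 84)
        assert orat == pytest.approx((16 * table[3]) / (32 * 84))
        assert p == pytest.approx(exact_tail(*table), rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_test(set(), set(), set())


class TestGenesetEnrichment:
    UNIVERSE = {f"g{i}" for i in range(100)}

    def test_size_bounds_exclude_small_sets(self):
        mods = {"M": module([f"g{i}" for i in range(20)])}
        sets = {"small": {f"g{i}" for i in range(9)}}
        with pytest.warns(UserWarning, match="size bounds"):
            out = geneset_enrichment(mods, sets, self.UNIVERSE)
        assert len(out) == 0

    def test_identical_set_ranks_first(self):
        target = {f"g{i}" for i in range(15)}
        mods = {"M": module(sorted(target))}
        sets = {
            "match": target,
            "other": {f"g{i}" for i in range(40, 60)},
        }
        out = geneset_enrichment(mods, sets, self.UNIVERSE)
        best = out.sort_values("p").iloc[0]
        assert best.condition == "match" and best.a == 15

    def test_bh_step_up(self):
        mods = {"M": module([f"g{i}" for i in range(10, 30)])}
        sets = {f"s{i}": {f"g{j}" for j in range(i, i + 12)} for i in range(4)}
        out = geneset_enrichment(mods, sets, self.UNIVERSE)
        # BH on the explicit example from the step-up definition
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04] * 4)
        assert "p_bh" in out.columns


def test_signed_logp_matrix_orientation():
    tab = pd.DataFrame(
        [
            dict(module="M", condition="c1", direction="up", p=1e-4),
            dict(module="M", condition="c1", direction="down", p=0.5),
            dict(module="M", condition="c2", direction="down", p=1e-3),
            dict(module="M", condition="c2", direction="up", p=0.9),
        ]
    )
    mat = signed_logp_matrix(tab)
    assert mat.loc["M", "c1"] == pytest.approx(4.0)
    assert mat.loc["M", "c2"] == pytest.approx(-3.0)
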