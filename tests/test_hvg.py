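"""Fisher combination, BH adjustment, lfc ranking, HVG selection and merge."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import wallwise as w
from wallwise.hvg import HVGList


def bh_stepup_oracle(p):
    """Brute-force step-up definition: adj_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestFisher:
    def test_all_ones_combine_to_one(self):
        x2, p = w.fisher_combine([1.0, 1.0])
        assert x2 == 0.0
        assert p == 1.0

    def test_single_p_is_identity(self):
        for p in (0.01, 0.2, 0.97):
            _, comb = w.fisher_combine([p])
            assert comb == pytest.approx(p, rel=1e-12)

    def test_matches_chi2_df4_closed_form(self):
        """For two p-values the combined p equals the chi-square(4) survival
        function e^(-x/2) (1 + x/2) evaluated at -2 sum(ln p)."""
        x2, comb = w.fisher_combine([0.05, 0.05])
        assert x2 == pytest.approx(-4 * math.log(0.05), rel=1e-12)
        closed = math.exp(-x2 / 2) * (1 + x2 / 2)
        assert comb == pytest.approx(closed, abs=1e-10)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(0)
        pmat = rng.uniform(1e-6, 1, size=(50, 2))
        _, comb = w.fisher_combine(pmat)
        for row, ours in zip(pmat, comb):
            ref = stats.combine_pvalues(row, method="fisher").pvalue
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            _, comb = w.fisher_combine([0.0, 0.5])
        assert 0.0 <= comb < 1e-200

    @given(st.floats(min_value=1e-6, max_value=1.0),
           st.floats(min_value=1e-6, max_value=1.0),
           st.floats(min_value=0.01, max_value=0.99))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_in_each_input(self, p1, p2, shrink):
        _, base = w.fisher_combine([p1, p2])
        _, smaller = w.fisher_combine([p1 * shrink, p2])
        assert smaller <= base + 1e-15


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_array_equal(w.bh_adjust([0.2]), [0.2])

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(w.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], rtol=1e-12)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(w.bh_adjust(p), bh_stepup_oracle(p),
                                       rtol=1e-12, atol=1e-15)

    def test_nan_excluded_from_m_and_propagated(self):
        p = np.array([0.01, np.nan, 0.04])
        adj = w.bh_adjust(p)
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], bh_stepup_oracle([0.01, 0.04]))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_dominates_raw_and_bounded_by_one(self, p):
        adj = w.bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)


class TestOverallLfc:
    def test_constant_positive(self):
        assert w.overall_lfc([2, 2, 2]) == pytest.approx(2.0)
        assert w.overall_lfc([2, 2, 2], mode="as_printed") == pytest.approx(2.0)

    def test_negative_trajectory_modes_differ(self):
        assert w.overall_lfc([-2, -2, -2]) == pytest.approx(-2.0)
        assert w.overall_lfc([-2, -2, -2], mode="as_printed") == pytest.approx(2.0)

    def test_mixed_signs_average(self):
        assert w.overall_lfc([3, -1, 1]) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            w.overall_lfc([])


def _eligibility(n, rng):
    genes = [f"g{i:04d}" for i in range(n)]
    return pd.DataFrame({"combined_p": rng.uniform(0, 0.01, n),
                         "adjusted_p": rng.uniform(0, 0.04, n)},
                        index=pd.Index(genes, name="gene_id"))


class TestSelection:
    def test_200_eligible_yield_10_plus_10(self):
        rng = np.random.default_rng(0)
        elig = _eligibility(200, rng)
        lfc = pd.Series(rng.normal(size=200), index=elig.index)
        lst = w.select_hvgs(elig, lfc, fraction=0.05)
        assert len(lst.top) == 10 and len(lst.bottom) == 10
        assert not (set(lst.top) & set(lst.bottom))
        # top 10% of differentially expressed genes in total
        assert len(lst.genes) == 20

    def test_ceiling_rule_on_small_lists(self):
        rng = np.random.default_rng(1)
        elig = _eligibility(10, rng)
        lfc = pd.Series(rng.normal(size=10), index=elig.index)
        lst = w.select_hvgs(elig, lfc, fraction=0.05)
        assert len(lst.top) == 1 and len(lst.bottom) == 1

    def test_zero_eligible_gives_empty_list(self):
        rng = np.random.default_rng(2)
        elig = _eligibility(5, rng)
        elig["adjusted_p"] = 0.9
        lst = w.select_hvgs(elig, pd.Series(0.0, index=elig.index))
        assert lst.top == [] and lst.bottom == []

    def test_top_has_largest_lfc_and_all_pass_threshold(self):
        rng = np.random.default_rng(3)
        elig = _eligibility(60, rng)
        elig.loc[elig.index[:5], "adjusted_p"] = 0.5   # ineligible
        lfc = pd.Series(np.linspace(-3, 3, 60), index=elig.index)
        lst = w.select_hvgs(elig, lfc, fraction=0.05, alpha=0.05)
        k = math.ceil(0.05 * 55)
        assert len(lst.top) == k
        eligible_lfc = lfc[elig["adjusted_p"] < 0.05]
        assert set(lst.top) == set(eligible_lfc.nlargest(k).index)
        assert set(lst.bottom) == set(eligible_lfc.nsmallest(k).index)
        assert (elig.loc[list(lst.genes), "adjusted_p"] < 0.05).all()

    def test_overlap_truncated_when_list_tiny(self):
        rng = np.random.default_rng(4)
        elig = _eligibility(1, rng)
        lst = w.select_hvgs(elig, pd.Series([1.0], index=elig.index))
        assert len(lst.top) == 1 and len(lst.bottom) == 0


class TestMerge:
    @staticmethod
    def _mklist(label, genes):
        return HVGList(label=label, top=list(genes), bottom=[],
                       table=pd.DataFrame(), n_eligible=len(genes))

    def test_union_of_disjoint_lists(self):
        from wallwise.hvg import HVGCollection
        lists = [self._mklist(f"l{i}", [f"g{i}_{j}" for j in range(5)])
                 for i in range(8)]
        merged = {}
        for lst in lists:
            for g in lst.genes:
                merged.setdefault(g, []).append(lst.label)
        coll = HVGCollection(lists=lists, merged=merged)
        assert len(coll.merged_genes) == 40

    def test_eight_lists_built_and_labeled(self, recovery_run):
        coll = recovery_run["collection"]
        assert len(coll.lists) == 8
        labels = {lst.label for lst in coll.lists}
        assert labels == {
            f"{cond}.full.{g}" for cond in ("preflowering", "postflowering")
            for g in ("RTx430", "BTx642")
        } | {
            f"preflowering.{win}.{g}" for win in ("drought", "recovery")
            for g in ("RTx430", "BTx642")
        }
        for lst in coll.lists:
            k = math.ceil(0.05 * lst.n_eligible)
            assert len(lst.top) == k
            assert len(lst.bottom) <= k

    def test_merged_tags_point_to_source_lists(self, recovery_run):
        coll = recovery_run["collection"]
        by_label = {lst.label: lst.genes for lst in coll.lists}
        for gene, labels in coll.merged.items():
            for label in labels:
                assert gene in by_label[label]

    def test_null_experiment_yields_near_empty_merge(self, null_de):
        _, _, results = null_de
        coll = w.build_and_merge_lists(results)
        # BH at 5% on a global null: a handful of false discoveries at most
        assert len(coll.merged) <= 10
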