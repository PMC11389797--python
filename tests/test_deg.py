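import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mucoseq as mq
from mucoseq.deg import exact_two_sided_p
from mucoseq.exceptions import EmptyInputError, InvalidDesignError

from oracles import enum_mw_two_sided_p


def _frame(a, b):
    """One-gene matrix with groups a and b."""
    cols_a = [f"a{i}" for i in range(len(a))]
    cols_b = [f"b{i}" for i in range(len(b))]
    data = dict(zip(cols_a + cols_b, list(a) + list(b)))
    return pd.DataFrame({k: [v] for k, v in data.items()}), cols_a, cols_b


class TestExactBranch:
    def test_fully_separated_three_vs_three(self):
        df, ga, gb = _frame([1, 2, 3], [4, 5, 6])
        table = mq.mann_whitney_deg(df, ga, gb)
        assert table["u"].iloc[0] == 0.0
        assert table["p"].iloc[0] == pytest.approx(0.1)  # 2/20 arrangements
        assert table["direction"].iloc[0] == 1

    @pytest.mark.parametrize("n1", [3, 4, 5])
    @pytest.mark.parametrize("n2", [3, 4, 5])
    def test_matches_enumeration_and_scipy_on_tiefree_data(self, n1, n2, rng):
        for _ in range(10):
            a = rng.normal(size=n1)
            b = rng.normal(loc=rng.normal(), size=n2)
            df, ga, gb = _frame(a, b)
            p = mq.mann_whitney_deg(df, ga, gb)["p"].iloc[0]
            assert p == pytest.approx(enum_mw_two_sided_p(a, b), abs=1e-12)
            assert p == pytest.approx(
                stats.mannwhitneyu(a, b, method="exact").pvalue, abs=1e-12
            )

    def test_cdf_is_symmetric_and_complete(self):
        cdf = mq.deg.exact_u_cdf(5, 5)
        assert cdf[-1] == pytest.approx(1.0)
        pmf = np.diff(np.concatenate([[0.0], cdf]))
        np.testing.assert_allclose(pmf, pmf[::-1], atol=1e-12)

    def test_exact_p_never_below_attainable_minimum(self):
        # smallest two-sided p at 5v5 is 2/252
        p = exact_two_sided_p(np.array([0]), 5, 5)
        assert p[0] == pytest.approx(2 / 252)


class TestAsymptoticBranch:
    def test_identical_groups_give_null_result(self):
        df, ga, gb = _frame([2, 2, 2, 2], [2, 2, 2, 2])
        table = mq.mann_whitney_deg(df, ga, gb)
        assert table["p"].iloc[0] == 1.0
        assert table["log2fc"].iloc[0] == 0.0
        assert table["direction"].iloc[0] == 0

    def test_tied_data_matches_scipy_asymptotic(self, rng):
        for _ in range(20):
            a = rng.integers(0, 4, size=6).astype(float)
            b = rng.integers(0, 4, size=6).astype(float)
            if not np.any(np.diff(np.sort(np.concatenate([a, b]))) == 0):
                continue
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                continue
            df, ga, gb = _frame(a, b)
            p = mq.mann_whitney_deg(df, ga, gb)["p"].iloc[0]
            expected = stats.mannwhitneyu(a, b, method="asymptotic").pvalue
            assert p == pytest.approx(expected, rel=1e-8)

    def test_large_groups_use_approximation(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        df, ga, gb = _frame(a, b)
        p = mq.mann_whitney_deg(df, ga, gb)["p"].iloc[0]
        expected = stats.mannwhitneyu(a, b, method="asymptotic").pvalue
        assert p == pytest.approx(expected, rel=1e-8)


class TestContract:
    def test_label_swap_flips_directions_and_preserves_p(self, rng):
        norm = pd.DataFrame(
            rng.integers(0, 30, size=(100, 10)).astype(float),
            columns=[f"s{i}" for i in range(10)],
        )
        ga, gb = [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)]
        fwd = mq.mann_whitney_deg(norm, ga, gb)
        rev = mq.mann_whitney_deg(norm, gb, ga)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)
        assert (fwd["direction"] == -rev["direction"]).all()

    def test_overlapping_groups_rejected(self, rng):
        norm = pd.DataFrame(rng.random((5, 6)), columns=list("abcdef"))
        with pytest.raises(InvalidDesignError, match="overlap"):
            mq.mann_whitney_deg(norm, ["a", "b", "c"], ["c", "d", "e"])

    def test_undersized_group_rejected(self, rng):
        norm = pd.DataFrame(rng.random((5, 6)), columns=list("abcdef"))
        with pytest.raises(InvalidDesignError, match="underpowered"):
            mq.mann_whitney_deg(norm, ["a", "b"], ["c", "d", "e"])


class TestSignificantSet:
    def test_global_null_gives_empty_members_full_universe(self):
        table = pd.DataFrame(
            {"u": [1.0, 2.0], "p": [1.0, 1.0], "log2fc": [0.5, -0.5],
             "direction": [1, -1]},
            index=["g1", "g2"],
        )
        sig = mq.significant_set(table)
        assert len(sig) == 0
        assert sig.universe == frozenset(["g1", "g2"])

    def test_threshold_is_strict(self):
        table = pd.DataFrame(
            {"u": [0.0, 0.0], "p": [0.05, 0.049], "log2fc": [1.0, 1.0],
             "direction": [1, 1]},
            index=["at_alpha", "below_alpha"],
        )
        sig = mq.significant_set(table, alpha=0.05)
        assert set(sig.members) == {"below_alpha"}

    def test_three_vs_three_minimum_p_excluded_at_005(self):
        # the fully separated 3v3 gene has p = 0.1, so never significant
        df, ga, gb = _frame([1, 2, 3], [4, 5, 6])
        sig = mq.significant_set(mq.mann_whitney_deg(df, ga, gb), alpha=0.05)
        assert len(sig) == 0

    def test_bh_correction_shrinks_set(self, cohort_deg):
        table = cohort_deg["SPF"].table
        raw = mq.significant_set(table, alpha=0.05)
        adj = mq.significant_set(table, alpha=0.05, correction="bh")
        assert set(adj.members) <= set(raw.members)

    def test_empty_table_raises(self):
        with pytest.raises(EmptyInputError):
            mq.significant_set(pd.DataFrame(columns=["p", "direction"]))


class TestRecoveryOnSyntheticData:
    def test_shared_effect_genes_recovered_with_correct_sign(
        self, effect_dataset, cohort_deg
    ):
        """At a log2 effect of 3 with 5 mice/group, the two-cohort DEG +
        direction-consistent intersection recovers >= 80% of the genes
        engineered to shift the same way in both cohorts."""
        _, truth, _ = effect_dataset
        sets = {c: r.significant_set() for c, r in cohort_deg.items()}
        shared = truth.index[truth["class"] == "shared"]
        hit = sum(
            1
            for g in shared
            if sets["SPF"].members.get(g, 0) == truth.loc[g, "true_direction"]
            and sets["GF"].members.get(g, 0) == truth.loc[g, "true_direction"]
        )
        assert hit / len(shared) >= 0.80

    def test_sensitivity_monotone_in_effect_size(self, fmt_design):
        sens = []
        for effect in (1.0, 2.0, 3.0):
            spec = mq.EffectSpec(
                n_genes=2_000, n_shared_effect=200, log2_effect_size=effect, seed=7
            )
            counts, truth = mq.generate_counts(fmt_design, spec)
            filtered, _ = mq.filter_sparse_genes(counts)
            norm = mq.normalize_library_size(filtered)
            ctrl = fmt_design.index[
                (fmt_design.cohort == "SPF") & (fmt_design.treatment == "PBS")
            ]
            trt = fmt_design.index[
                (fmt_design.cohort == "SPF") & (fmt_design.treatment == "Van")
            ]
            sig = mq.DifferentialExpression(norm, ctrl, trt).fit().significant_set()
            shared = truth.index[truth["class"] == "shared"]
            sens.append(
                sum(
                    1
                    for g in shared
                    if sig.members.get(g, 0) == truth.loc[g, "true_direction"]
                )
                / len(shared)
            )
        assert sens[0] <= sens[1] <= sens[2]
        assert sens[2] > sens[0]
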