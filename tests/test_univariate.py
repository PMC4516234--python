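import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cytopred.cohort import VariableSpec
from cytopred.univariate import (
    TestResult as UnivariateResult,
    bh_adjust,
    dispatch_test,
    rank_features,
    rank_from_pvalues,
    univariate_scan,
)


def fisher_two_sided_oracle(table):
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    rv = sps.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(rv.pmf(k) for k in range(lo, hi + 1)
               if rv.pmf(k) <= p_obs * (1 + 1e-9))


class TestDispatch:
    def test_fisher_small_table_matches_enumeration(self):
        """2x2 table [[3,1],[1,3]] -> two-sided p ~= 0.486."""
        x = np.array([1, 1, 1, 0, 1, 0, 0, 0], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = dispatch_test(x, y, "binary")
        assert res.test_used == "fisher_exact"
        oracle = fisher_two_sided_oracle([[3, 1], [1, 3]])
        assert res.p_raw == pytest.approx(oracle, rel=1e-9)
        assert res.p_raw == pytest.approx(0.4857, abs=5e-4)

    def test_chi_square_when_expected_counts_large(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 80).astype(float)
        y = np.repeat([0, 1], 40)
        res = dispatch_test(x, y, "binary")
        assert res.test_used == "chi_square"

    def test_fisher_when_any_expected_count_below_5(self):
        x = np.array([1, 0, 0, 0, 0, 1, 1, 1, 0, 0], dtype=float)
        y = np.array([0] * 5 + [1] * 5)
        res = dispatch_test(x, y, "binary")
        assert res.test_used == "fisher_exact"

    def test_continuous_dispatches_t_test(self):
        res = dispatch_test([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1], "continuous")
        assert res.test_used == "t_test"
        t, p = sps.ttest_ind([1.0, 2.0], [3.0, 4.0])
        assert res.p_raw == pytest.approx(p)

    def test_ordinal_dispatches_mann_whitney(self):
        res = dispatch_test([0, 1, 2, 3, 1, 2], [0, 0, 0, 1, 1, 1], "ordinal")
        assert res.test_used == "mann_whitney"

    def test_identical_constant_groups_degenerate(self):
        res = dispatch_test([5.0] * 6, [0, 0, 0, 1, 1, 1], "continuous")
        assert res.statistic == 0.0
        assert res.p_raw == 1.0

    def test_undefined_when_group_too_small(self):
        res = dispatch_test([1.0, 2.0, 3.0, np.nan], [0, 0, 0, 1], "continuous")
        assert res.test_used == "undefined"
        assert np.isnan(res.p_raw)

    def test_missing_excluded_pairwise(self):
        full = dispatch_test([1.0, 2.0, 5.0, 6.0], [0, 0, 1, 1], "continuous")
        padded = dispatch_test([1.0, 2.0, np.nan, 5.0, 6.0, np.nan],
                               [0, 0, 0, 1, 1, 1], "continuous")
        assert padded.p_raw == pytest.approx(full.p_raw)

    def test_two_sided_p_invariant_under_label_swap(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        for vt in ("continuous", "ordinal"):
            a = dispatch_test(x if vt == "continuous" else np.round(x.clip(0) * 3),
                              y, vt)
            b = dispatch_test(x if vt == "continuous" else np.round(x.clip(0) * 3),
                              1 - y, vt)
            assert a.p_raw == pytest.approx(b.p_raw)


def bh_literal(p, m):
    """Literal step-up reference: independent of the implementation."""
    p = list(p)
    order = sorted(range(len(p)), key=lambda i: p[i])
    q = [None] * len(p)
    running = 1.0
    for rank_idx in range(len(p) - 1, -1, -1):
        i = order[rank_idx]
        val = p[i] * m / (rank_idx + 1)
        running = min(running, val)
        q[i] = min(running, 1.0)
    return q


class TestBHAdjust:
    def test_printed_worked_example(self):
        """The two smallest of 296 p-values both adjust to ~0.2180631 (the
        rank-2 step-up cap)."""
        out = bh_adjust([0.001171648, 0.0014734], m=296)
        assert out == pytest.approx([0.2180631, 0.2180631], rel=1e-6)

    def test_single_p_with_m_one_unchanged(self):
        assert bh_adjust([0.037], m=1)[0] == pytest.approx(0.037)

    def test_matches_literal_step_up_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            k = rng.integers(1, 60)
            p = rng.random(k)
            m = k + int(rng.integers(0, 10))
            assert bh_adjust(p, m=m) == pytest.approx(bh_literal(p, m))

    def test_matches_statsmodels_when_m_equals_length(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(3)
        p = rng.random(40)
        ours = bh_adjust(p)
        theirs = sm.multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_adjust([1.2])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.2], m=1)

    def test_nan_entries_ignored_but_preserved(self):
        out = bh_adjust([0.01, np.nan, 0.04], m=3)
        assert np.isnan(out[1])
        assert out[[0, 2]] == pytest.approx(bh_literal([0.01, 0.04], 3))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    def test_permutation_invariance_and_monotonicity(self, p, rnd):
        out = bh_adjust(p)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        out_perm = bh_adjust([p[i] for i in perm])
        assert out_perm == pytest.approx([out[i] for i in perm])
        for i in range(len(p)):
            for j in range(len(p)):
                if p[i] <= p[j]:
                    assert out[i] <= out[j] + 1e-12
        assert all(oi >= pi - 1e-12 for oi, pi in zip(out, p))


class TestRanking:
    def _results(self, pairs):
        return [UnivariateResult(name, "t_test", 0.0, p) for name, p in pairs]

    def test_sorted_by_ascending_p(self):
        ranked = rank_features(self._results([("A", 0.01), ("B", 0.001), ("C", 0.5)]))
        assert ranked == ["B", "A", "C"]

    def test_ties_broken_lexicographically(self):
        ranked = rank_features(self._results([("zeta", 0.01), ("alpha", 0.01)]))
        assert ranked == ["alpha", "zeta"]

    def test_undefined_ranked_last(self):
        ranked = rank_features(self._results([("A", np.nan), ("B", 0.9)]))
        assert ranked == ["B", "A"]

    def test_rank_from_pvalues_agrees(self):
        p = pd.Series({"A": 0.01, "B": 0.001, "C": np.nan, "D": 0.01})
        assert rank_from_pvalues(p) == ["B", "A", "D", "C"]


class TestVectorisedScan:
    def test_matches_per_variable_dispatch(self):
        """The fast scan must equal the scalar dispatch on every column."""
        rng = np.random.default_rng(4)
        n = 60
        specs = [
            VariableSpec(name="c1", vtype="continuous", provenance="cytokine",
                         cytokine="IL2", stimulation="LPS", duration_h=24,
                         timepoint="CB"),
            VariableSpec(name="c2", vtype="continuous", provenance="cytokine",
                         cytokine="IL4", stimulation="PHA", duration_h=96,
                         timepoint="2m"),
            VariableSpec(name="ord", vtype="ordinal", provenance="clinical"),
            VariableSpec(name="bin", vtype="binary", provenance="clinical"),
        ]
        X = pd.DataFrame({
            "c1": rng.normal(size=n),
            "c2": rng.lognormal(size=n),
            "ord": rng.integers(0, 4, n).astype(float),
            "bin": rng.integers(0, 2, n).astype(float),
        }, index=[f"P{i}" for i in range(n)])
        X.iloc[rng.integers(0, n, 15), 0] = np.nan
        X.iloc[rng.integers(0, n, 15), 1] = np.nan
        y = rng.integers(0, 2, n)
        p = univariate_scan(X, y, specs)
        for col, spec in zip(X.columns, specs):
            ref = dispatch_test(X[col].to_numpy(), y, spec.vtype)
            assert p[col] == pytest.approx(ref.p_raw, rel=1e-10), col

    def test_degenerate_columns_handled(self):
        specs = [VariableSpec(name="c", vtype="continuous", provenance="cytokine",
                              cytokine="IL2", stimulation="LPS", duration_h=24,
                              timepoint="CB")]
        X = pd.DataFrame({"c": [1.0] * 8}, index=[f"P{i}" for i in range(8)])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert univariate_scan(X, y, specs)["c"] == 1.0
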