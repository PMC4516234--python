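"""Per-variable two-group tests, Benjamini-Hochberg FDR adjustment and
deterministic feature ranking.

Test dispatch follows variable type: continuous -> unpaired two-sample
t-test (equal-variance Student by default, Welch optional); ordinal ->
Mann-Whitney U (exact null for combined n <= 20 without ties, normal
approximation with tie correction otherwise); binary/nominal ->
chi-square, switching to Fisher's exact test when any expected cell count
falls below 5. All tests are two-sided; missing values are excluded
pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import VariableSpec


@dataclass
class TestResult:
    """Outcome of one univariate two-group comparison."""

    variable: str
    test_used: str        # t_test | mann_whitney | chi_square | fisher_exact | undefined
    statistic: float
    p_raw: float          # NaN when the test is undefined
    p_adjusted: float | None = None
    group_summary: tuple = ()   # (mean0, mean1) or contingency counts
    n0: int = 0
    n1: int = 0


# ---------------------------------------------------------------------------
# single-variable dispatch


def _t_test(x0: np.ndarray, x1: np.ndarray, welch: bool) -> tuple[float, float]:
    if not welch and np.var(x0, ddof=1) == 0 and np.var(x1, ddof=1) == 0:
        # degenerate: both groups constant
        if x0[0] == x1[0]:
            return 0.0, 1.0
        return float("inf"), 0.0
    stat, p = sps.ttest_ind(x0, x1, equal_var=not welch)
    return float(stat), float(p)


def _mann_whitney(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float]:
    ties = len(np.unique(np.concatenate([x0, x1]))) < x0.size + x1.size
    method = "exact" if (x0.size + x1.size <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x0, x1, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _contingency(x0: np.ndarray, x1: np.ndarray) -> np.ndarray:
    cats = np.unique(np.concatenate([x0, x1]))
    table = np.array([[np.sum(g == c) for c in cats] for g in (x0, x1)])
    return table


def _categorical_test(x0: np.ndarray, x1: np.ndarray, yates: bool
                      ) -> tuple[str, float, float, tuple]:
    table = _contingency(x0, x1)
    summary = tuple(map(tuple, table.tolist()))
    if table.shape[1] < 2:
        return "undefined", float("nan"), float("nan"), summary
    expected = sps.contingency.expected_freq(table)
    if (expected < 5).any() and table.shape == (2, 2):
        stat, p = sps.fisher_exact(table, alternative="two-sided")
        return "fisher_exact", float(stat), float(p), summary
    stat, p, _, _ = sps.chi2_contingency(table, correction=yates)
    return "chi_square", float(stat), float(p), summary


def dispatch_test(values: Sequence[float], labels: Sequence[int], vtype: str,
                  welch: bool = False, yates: bool = False) -> TestResult:
    """Type-appropriate two-group test of one variable.

    ``labels`` is the binary task vector; group 1 is the positive class.
    A group with fewer than 2 observations yields an undefined result
    (``p_raw`` NaN), ranked last downstream.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    obs = ~np.isnan(v)
    x0, x1 = v[obs & (y == 0)], v[obs & (y == 1)]
    name = ""
    if x0.size < 2 or x1.size < 2:
        return TestResult(name, "undefined", float("nan"), float("nan"),
                          n0=x0.size, n1=x1.size)
    if vtype == "continuous":
        stat, p = _t_test(x0, x1, welch)
        return TestResult(name, "t_test", stat, p,
                          group_summary=(float(x0.mean()), float(x1.mean())),
                          n0=x0.size, n1=x1.size)
    if vtype == "ordinal":
        stat, p = _mann_whitney(x0, x1)
        return TestResult(name, "mann_whitney", stat, p,
                          group_summary=(float(np.median(x0)), float(np.median(x1))),
                          n0=x0.size, n1=x1.size)
    if vtype in ("binary", "nominal"):
        used, stat, p, summary = _categorical_test(x0, x1, yates)
        return TestResult(name, used, stat, p, group_summary=summary,
                          n0=x0.size, n1=x1.size)
    raise ValueError(f"unknown vtype {vtype!r}")


# ---------------------------------------------------------------------------
# multiplicity


def bh_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the total number of simultaneous tests and may exceed the
    vector length (variables that were tested elsewhere still count toward
    the correction). Sorted ascending, q_i = p_(i) * m / i; monotonicity is
    enforced from the largest rank downward; values are capped at 1 and
    returned in input order. NaN entries (undefined tests) stay NaN and do
    not consume a rank.
    """
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    k = pv.size
    if m is None:
        m = k
    if m < k:
        raise ValueError("m must be >= number of p-values")
    order = np.argsort(pv, kind="stable")
    ranks = np.arange(1, k + 1)
    q = pv[order] * m / ranks
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.full(p.shape, np.nan)
    adj = np.empty(k)
    adj[order] = q
    out[valid] = adj
    return out


def rank_features(results: Sequence[TestResult]) -> list[str]:
    """Variables ordered by ascending raw p; ties broken lexicographically.

    Undefined tests (NaN p) rank last, themselves ordered by name.
    """
    def key(r: TestResult):
        return (np.isnan(r.p_raw), r.p_raw if not np.isnan(r.p_raw) else 0.0,
                r.variable)
    return [r.variable for r in sorted(results, key=key)]


# ---------------------------------------------------------------------------
# vectorised scan (used inside the resampling loop and for reports)


def _vectorised_t(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Equal-variance two-sided t-test p-values per column, NaN-aware."""
    p_out = np.full(X.shape[1], np.nan)
    obs = ~np.isnan(X)
    n0 = (obs & (y == 0)[:, None]).sum(axis=0)
    n1 = (obs & (y == 1)[:, None]).sum(axis=0)
    ok = (n0 >= 2) & (n1 >= 2)
    X0 = np.where((y == 0)[:, None] & obs, X, 0.0)
    X1 = np.where((y == 1)[:, None] & obs, X, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = X0.sum(axis=0) / n0
        m1 = X1.sum(axis=0) / n1
        ss0 = ((np.where((y == 0)[:, None] & obs, X - m0, 0.0)) ** 2).sum(axis=0)
        ss1 = ((np.where((y == 1)[:, None] & obs, X - m1, 0.0)) ** 2).sum(axis=0)
        df = n0 + n1 - 2
        sp2 = (ss0 + ss1) / df
        se = np.sqrt(sp2 * (1 / n0 + 1 / n1))
        t = (m0 - m1) / se
        p = 2 * sps.t.sf(np.abs(t), df)
    # degenerate zero-variance columns
    zero = ok & (sp2 == 0)
    p[zero & (m0 == m1)] = 1.0
    p[zero & (m0 != m1)] = 0.0
    p_out[ok] = p[ok]
    return p_out


def univariate_scan(X: pd.DataFrame, y: np.ndarray,
                    specs: Sequence[VariableSpec], welch: bool = False,
                    yates: bool = False) -> pd.Series:
    """Raw p-value per variable (NaN where undefined).

    Continuous columns are tested with a vectorised equal-variance t-test
    (identical to :func:`dispatch_test`, checked by tests); discrete
    columns go through the per-variable dispatch.
    """
    vt = {v.name: v.vtype for v in specs}
    y = np.asarray(y)
    cont = [c for c in X.columns if vt[c] == "continuous"]
    p = pd.Series(np.nan, index=X.columns, dtype=float)
    if cont:
        if welch:
            for c in cont:
                p[c] = dispatch_test(X[c].to_numpy(), y, "continuous", welch=True).p_raw
        else:
            p[cont] = _vectorised_t(X[cont].to_numpy(dtype=float), y)
    for c in X.columns:
        if vt[c] != "continuous":
            p[c] = dispatch_test(X[c].to_numpy(), y, vt[c], yates=yates).p_raw
    return p


def rank_from_pvalues(p: pd.Series) -> list[str]:
    """Ascending-p ranking with the same tie/undefined rules as
    :func:`rank_features`."""
    items = [(bool(np.isnan(v)), v if not np.isnan(v) else 0.0, name)
             for name, v in p.items()]
    return [name for _, _, name in sorted(items)]


def univariate_table(X: pd.DataFrame, y: np.ndarray,
                     specs: Sequence[VariableSpec], m: int | None = None,
                     welch: bool = False, yates: bool = False) -> pd.DataFrame:
    """Descriptive univariate report over all variables.

    One row per variable with the test used, group summaries, direction
    marker, raw and BH-adjusted p-values (adjusted over ``m`` total
    variables), sorted by ascending raw p.
    """
    vt = {v.name: v.vtype for v in specs}
    rows = []
    for c in X.columns:
        r = dispatch_test(X[c].to_numpy(), np.asarray(y), vt[c],
                          welch=welch, yates=yates)
        r.variable = c
        rows.append(r)
    p_raw = np.array([r.p_raw for r in rows])
    p_adj = bh_adjust(p_raw, m=m)
    recs = []
    for r, q in zip(rows, p_adj):
        if r.test_used == "t_test":
            g0, g1 = r.group_summary
            direction = "pos<neg" if g1 < g0 else ("pos>neg" if g1 > g0 else "=")
            summary = f"neg {g0:.4g} / pos {g1:.4g}"
        else:
            direction = ""
            summary = str(r.group_summary)
        recs.append({"variable": r.variable, "test_used": r.test_used,
                     "group_summary": summary, "direction": direction,
                     "statistic": r.statistic, "p_raw": r.p_raw,
                     "p_adjusted": q, "n_neg": r.n0, "n_pos": r.n1})
    out = pd.DataFrame(recs)
    return out.sort_values(["p_raw", "variable"], na_position="last",
                           kind="stable").reset_index(drop=True)
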