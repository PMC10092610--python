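"""The statistical battery used by the pipeline.

Paired t, Wilcoxon matched-pairs signed-rank, one-way ANOVA with Holm-Sidak
post-hoc comparisons, balanced two-way ANOVA (time x condition, interaction
being the test of interest for induced power) and the Holm-Sidak step-down
adjustment.  All p-values are two-sided.  Degenerate inputs (zero-variance
differences, zero within-group variance) are flagged explicitly instead of
propagating silent NaNs or infinities.

Trials are treated as independent units, matching the pooled 40-trial design
the pipeline emulates; a rat-level mixed model is a documented non-goal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "paired_t",
    "wilcoxon_signed_rank",
    "one_way_anova",
    "two_way_anova",
    "holm_sidak",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    df: float | tuple | None
    p: float
    adjusted_p: float | None = None
    flags: tuple = ()
    extra: dict = field(default_factory=dict)

    @property
    def degenerate(self) -> bool:
        return any("degenerate" in f for f in self.flags)


def _as_paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-d vectors")
    if a.shape[0] < 2:
        raise ValueError("paired tests need at least 2 pairs")
    return a, b


def paired_t(a, b) -> TestResult:
    """Two-sided paired t test: T = mean(d) / (sd(d)/sqrt(n)), df = n-1."""
    a, b = _as_paired(a, b)
    d = a - b
    n = d.shape[0]
    # relative threshold: constant offsets leave only float cancellation noise
    if np.std(d, ddof=1) <= 1e-12 * max(1.0, float(np.abs(d).max())):
        return TestResult(
            "paired t", float("nan"), n - 1, float("nan"),
            flags=("degenerate: zero-variance differences",),
        )
    res = sps.ttest_rel(a, b)
    return TestResult("paired t", float(res.statistic), n - 1, float(res.pvalue))


def wilcoxon_signed_rank(a, b, exact_max_n: int = 25) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped before ranking (Wilcoxon's original policy)
    and their count is recorded.  The null distribution is exact for up to
    ``exact_max_n`` nonzero, untied differences; otherwise the normal
    approximation with tie correction is used.
    """
    a, b = _as_paired(a, b)
    d = a - b
    n_zero = int((d == 0).sum())
    d = d[d != 0]
    n = d.shape[0]
    flags = (f"zeros dropped: {n_zero}",) if n_zero else ()
    if n < 1:
        return TestResult(
            "wilcoxon signed-rank", float("nan"), None, float("nan"),
            flags=flags + ("degenerate: no nonzero differences",),
        )
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= exact_max_n and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=False, method=method)
    return TestResult(
        "wilcoxon signed-rank", float(res.statistic), None, float(res.pvalue),
        flags=flags, extra={"n_nonzero": n, "method": method},
    )


def one_way_anova(groups: Sequence[np.ndarray], posthoc: bool = False):
    """One-way ANOVA F test, optionally with Holm-Sidak pairwise post-hocs.

    Returns the omnibus :class:`TestResult`, or ``(omnibus, posthoc_results)``
    when ``posthoc`` is requested; post-hoc results are pairwise two-sample t
    tests with Holm-Sidak adjusted p-values stored in ``adjusted_p``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(g.shape[0] < 2 for g in arrs):
        raise ValueError("one-way ANOVA needs >= 2 groups with >= 2 values each")
    k = len(arrs)
    n_total = sum(g.shape[0] for g in arrs)
    df = (k - 1, n_total - k)
    if all(np.std(g, ddof=1) == 0 for g in arrs):
        means = [g.mean() for g in arrs]
        flag = (
            "degenerate: zero within-group variance"
            + (", unequal means (F unbounded)" if len(set(means)) > 1 else "")
        ,)
        omnibus = TestResult("one-way ANOVA", float("inf") if len(set(means)) > 1
                             else float("nan"), df, float("nan"), flags=flag)
    else:
        res = sps.f_oneway(*arrs)
        omnibus = TestResult("one-way ANOVA", float(res.statistic), df, float(res.pvalue))
    if not posthoc:
        return omnibus
    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    results = []
    for i, j in pairs:
        t = sps.ttest_ind(arrs[i], arrs[j])
        raw.append(float(t.pvalue))
        results.append(TestResult(f"t {i} vs {j}", float(t.statistic),
                                  arrs[i].shape[0] + arrs[j].shape[0] - 2,
                                  float(t.pvalue)))
    adj = holm_sidak(np.array(raw))
    for r, ap in zip(results, adj):
        r.adjusted_p = float(ap)
    return omnibus, results


def two_way_anova(values, factor_a, factor_b, names: tuple[str, str] = ("time", "condition")):
    """Balanced two-way ANOVA with interaction via the standard SS decomposition.

    ``values`` is a flat vector; ``factor_a``/``factor_b`` give each value's
    level on the two factors.  The layout must be balanced (equal cell sizes,
    each >= 2).  Returns a dict of :class:`TestResult` keyed by
    ``names[0]``, ``names[1]`` and ``"interaction"``.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.shape == fa.shape == fb.shape) or y.ndim != 1:
        raise ValueError("values and factors must be equal-length 1-d vectors")
    la, lb = np.unique(fa), np.unique(fb)
    if len(la) < 2 or len(lb) < 2:
        raise ValueError("both factors need at least 2 levels")
    cells = {}
    for a in la:
        for b in lb:
            cell = y[(fa == a) & (fb == b)]
            cells[(a, b)] = cell
    sizes = {len(c) for c in cells.values()}
    if len(sizes) != 1:
        raise ValueError("two-way ANOVA requires a balanced layout")
    n = sizes.pop()
    if n < 2:
        raise ValueError("each cell needs >= 2 replicates for an error term")

    grand = y.mean()
    ss_a = len(lb) * n * sum((y[fa == a].mean() - grand) ** 2 for a in la)
    ss_b = len(la) * n * sum((y[fb == b].mean() - grand) ** 2 for b in lb)
    ss_cells = n * sum((c.mean() - grand) ** 2 for c in cells.values())
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(((c - c.mean()) ** 2).sum() for c in cells.values())
    df_a, df_b = len(la) - 1, len(lb) - 1
    df_ab = df_a * df_b
    df_err = len(la) * len(lb) * (n - 1)

    def _test(label: str, ss: float, df_num: int) -> TestResult:
        if ss_err == 0:
            return TestResult(
                f"two-way ANOVA {label}", float("inf") if ss > 0 else 0.0,
                (df_num, df_err), float("nan"),
                flags=("degenerate: zero error variance",),
                extra={"ss": float(ss)},
            )
        ms = ss / df_num
        f = ms / (ss_err / df_err)
        p = float(sps.f.sf(f, df_num, df_err))
        return TestResult(f"two-way ANOVA {label}", float(f), (df_num, df_err), p,
                          extra={"ss": float(ss)})

    out = {
        names[0]: _test(names[0], ss_a, df_a),
        names[1]: _test(names[1], ss_b, df_b),
        "interaction": _test("interaction", ss_ab, df_ab),
    }
    out["interaction"].extra["ss_total"] = float(((y - grand) ** 2).sum())
    out["interaction"].extra["ss_error"] = float(ss_err)
    return out


def holm_sidak(pvals) -> np.ndarray:
    """Holm-Sidak step-down adjustment.

    After sorting ascending, ``adj_(i) = 1 - (1 - p_(i))^(m - i + 1)`` for
    the i-th smallest of m p-values (1-based), with monotonicity enforced by
    a running maximum, then restored to the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a nonempty 1-d vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("all p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty_like(adj_sorted)
    out[order] = adj_sorted
    return out
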