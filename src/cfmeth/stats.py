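"""Longitudinal cohort statistics.

Nonparametric tests with explicit, reproducible exact/approximate switching:

* Wilcoxon matched-pairs signed rank (zero differences dropped; exact
  two-sided p by enumerating sign assignments for n <= 25 without ties,
  otherwise normal approximation with tie correction),
* Mann-Whitney U (exact by enumerating group assignments when the combined
  n <= 12 without ties, otherwise normal approximation with tie correction),
* Spearman rank correlation (exact permutation p for n <= 8, otherwise
  the t approximation),
* Benjamini-Hochberg step-up FDR adjustment and the Benjamini-Krieger-
  Yekutieli adaptive two-stage step-up procedure.

Two-sided exact p-values are min(1, 2 * smaller tail including the observed
statistic). The exact enumerations are computed by subset-sum convolution,
which is identical to brute-force enumeration of all sign patterns / group
assignments when ranks are untied integers.

Also the small derived quantities of the longitudinal analysis: fold change
relative to pre-transplant and the combined POD7/POD30 average, plus helpers
that run the paired pre/post and injury-outcome contrasts over a long-format
cohort table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, t as t_dist

EXACT_WILCOXON_MAX_N = 25
EXACT_MANNWHITNEY_MAX_N = 12
EXACT_SPEARMAN_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    exact: bool

    def __post_init__(self):
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def _two_sided_from_tails(lo_tail: float, hi_tail: float) -> float:
    return min(1.0, 2.0 * min(lo_tail, hi_tail))


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed rank
# ---------------------------------------------------------------------------


def _signed_rank_null_counts(ranks: Sequence[int]) -> np.ndarray:
    """counts[w] = number of sign assignments with positive-rank sum w."""
    total = int(sum(ranks))
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float] | None = None) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed rank test on x - y.

    Zero differences are dropped (Wilcoxon's original convention). All
    differences zero -> undefined: statistic and p are NaN with n = 0.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if y is not None and d.size != np.asarray(y).size:
        raise ValueError("paired samples must have equal length")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(float("nan"), float("nan"), 0, "wilcoxon_signed_rank", False)
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    if n <= EXACT_WILCOXON_MAX_N and not has_ties:
        int_ranks = [int(round(r)) for r in ranks]
        counts = _signed_rank_null_counts(int_ranks)
        denom = counts.sum()  # 2**n
        w = int(round(w_pos))
        lo = counts[: w + 1].sum() / denom
        hi = counts[w:].sum() / denom
        return TestResult(w_pos, _two_sided_from_tails(lo, hi), n, "wilcoxon_signed_rank", True)
    mean = n * (n + 1) / 4
    tie_sizes = np.unique(np.abs(d), return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24 - float(((tie_sizes**3 - tie_sizes) / 48).sum())
    if var <= 0:
        return TestResult(w_pos, 1.0, n, "wilcoxon_signed_rank", False)
    z = (w_pos - mean) / np.sqrt(var)
    return TestResult(w_pos, float(min(1.0, 2 * norm.sf(abs(z)))), n, "wilcoxon_signed_rank", False)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _mann_whitney_null_counts(n_a: int, n_b: int) -> np.ndarray:
    """counts[u] = number of group assignments giving U statistic u."""
    # dp[k][s]: ways to choose k of ranks 1..N with rank-sum s
    N = n_a + n_b
    max_sum = N * (N + 1) // 2
    dp = np.zeros((n_a + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n_a), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    sums = dp[n_a]
    offset = n_a * (n_a + 1) // 2  # U = ranksum_a - n_a(n_a+1)/2
    return sums[offset : offset + n_a * n_b + 1]


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test (U of the first sample, midranks)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
    has_ties = np.unique(pooled).size < pooled.size
    if n_a + n_b <= EXACT_MANNWHITNEY_MAX_N and not has_ties:
        counts = _mann_whitney_null_counts(n_a, n_b)
        denom = counts.sum()  # C(N, n_a)
        ui = int(round(u))
        lo = counts[: ui + 1].sum() / denom
        hi = counts[ui:].sum() / denom
        return TestResult(u, _two_sided_from_tails(lo, hi), n_a + n_b, "mann_whitney", True)
    N = n_a + n_b
    mean = n_a * n_b / 2
    tie_sizes = np.unique(pooled, return_counts=True)[1]
    tie_term = float((tie_sizes**3 - tie_sizes).sum()) / (N * (N - 1)) if N > 1 else 0.0
    var = n_a * n_b / 12 * ((N + 1) - tie_term)
    if var <= 0:
        return TestResult(u, 1.0, N, "mann_whitney", False)
    z = (u - mean) / np.sqrt(var)
    return TestResult(u, float(min(1.0, 2 * norm.sf(abs(z)))), N, "mann_whitney", False)


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rho (Pearson correlation of midranks) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    rx = rankdata(x)
    ry = rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return TestResult(float("nan"), float("nan"), n, "spearman", False)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        u = rx - rx.mean()
        v = ry - ry.mean()
        denom = np.sqrt((u**2).sum() * (v**2).sum())
        perms = np.array(list(itertools.permutations(range(n))))
        rho_perm = (v[perms] @ u) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        return TestResult(rho, p, n, "spearman", True)
    if abs(rho) >= 1.0:
        return TestResult(rho, 0.0, n, "spearman", False)
    t_stat = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = float(min(1.0, 2 * t_dist.sf(abs(t_stat), n - 2)))
    return TestResult(rho, p, n, "spearman", False)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = alpha * np.arange(1, m + 1) / m
    below = p[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        mask[order[: k + 1]] = True
    return mask


def bky_two_stage(pvals: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Krieger-Yekutieli adaptive two-stage step-up procedure.

    Stage 1 runs BH at alpha' = alpha / (1 + alpha) to estimate the number of
    true nulls m0 = m - r1; stage 2 runs BH at alpha' * m / m0 (all rejected
    when m0 = 0). Returns the sorted indices of rejected hypotheses.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([], dtype=int)
    alpha1 = alpha / (1 + alpha)
    r1 = int(_bh_reject(p, alpha1).sum())
    m0 = m - r1
    if m0 == 0:
        return np.arange(m)
    mask = _bh_reject(p, alpha1 * m / m0)
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Longitudinal derived quantities and cohort contrasts
# ---------------------------------------------------------------------------


def fold_change(pre: float, post: float) -> float:
    """post / pre; NaN (never infinity) when the baseline is zero."""
    if pre < 0 or post < 0:
        raise ValueError("fold change requires non-negative inputs")
    if pre == 0 or np.isnan(pre) or np.isnan(post):
        return float("nan")
    return post / pre


def combined_average(pod7: float, pod30: float) -> float:
    """Mean of the POD7/POD30 values that are present; NaN when both missing."""
    vals = [v for v in (pod7, pod30) if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


NO_INJURY_LABEL = "no_injury"


def pre_post_contrast(
    table: pd.DataFrame,
    cell_type: str,
    value: str = "fraction",
    pre: str = "PRE",
    post: str = "POD0",
) -> tuple[TestResult, float]:
    """Paired pre-transplant vs post-reperfusion contrast for one cell type.

    Returns the Wilcoxon signed-rank result over patients with both
    timepoints, and the median per-patient fold change.
    """
    sub = table[table["cell_type"] == cell_type]
    wide = sub.pivot_table(index="patient_id", columns="timepoint", values=value, aggfunc="first")
    if pre not in wide.columns or post not in wide.columns:
        raise ValueError(f"timepoints {pre}/{post} not present in table")
    paired = wide[[pre, post]].dropna()
    res = wilcoxon_signed_rank(paired[post].to_numpy(), paired[pre].to_numpy())
    fc = np.array([fold_change(a, b) for a, b in zip(paired[pre], paired[post])])
    fc = fc[~np.isnan(fc)]
    median_fc = float(np.median(fc)) if fc.size else float("nan")
    return res, median_fc


def injury_combined_levels(
    table: pd.DataFrame,
    cell_type: str,
    value: str = "fraction",
    timepoints: tuple[str, str] = ("POD7", "POD30"),
) -> pd.DataFrame:
    """Per-patient combined POD7/POD30 average with the injury outcome label."""
    sub = table[table["cell_type"] == cell_type]
    wide = sub.pivot_table(index="patient_id", columns="timepoint", values=value, aggfunc="first")
    for tp in timepoints:
        if tp not in wide.columns:
            wide[tp] = np.nan
    combined = wide.apply(lambda r: combined_average(r[timepoints[0]], r[timepoints[1]]), axis=1)
    outcome = sub.groupby("patient_id")["outcome"].first()
    out = pd.DataFrame({"combined": combined, "outcome": outcome}).dropna(subset=["combined"])
    out["injured"] = out["outcome"] != NO_INJURY_LABEL
    return out


def injury_contrast(
    table: pd.DataFrame,
    cell_type: str,
    value: str = "fraction",
) -> TestResult:
    """Mann-Whitney test of combined POD7/POD30 levels, injury vs no injury."""
    levels = injury_combined_levels(table, cell_type, value)
    inj = levels.loc[levels["injured"], "combined"].to_numpy()
    no = levels.loc[~levels["injured"], "combined"].to_numpy()
    return mann_whitney(inj, no)


def enzyme_correlation(
    table: pd.DataFrame,
    cell_type: str = "hepatocyte",
    enzyme: str = "AST",
    timepoint: str = "POD0",
    value: str = "geq_per_ml",
) -> TestResult:
    """Spearman correlation of a liver enzyme with cell-type Geq/mL."""
    sub = table[(table["cell_type"] == cell_type) & (table["timepoint"] == timepoint)]
    sub = sub.dropna(subset=[enzyme, value])
    return spearman(sub[enzyme].to_numpy(), sub[value].to_numpy())
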