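"""Differential and coupling statistics for circRNA landscapes.

Covers fold-change classification against a fold threshold, the
normality-gated global-shift test (D'Agostino–Pearson omnibus gate, then
Wilcoxon matched-pairs signed-rank or paired t), circ–linear coupling
regression (OLS slope, Pearson R², F-test on the slope), strict
threshold-based differential-record filtering and Benjamini–Hochberg
adjustment.

The signed-rank test is implemented here rather than delegated: the exact
two-sided tail for n <= 25 is computed from the full null distribution of
the positive-rank sum (dynamic program over doubled midranks, so ties are
handled exactly), with a tie-corrected normal approximation beyond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DiffRecord",
    "GlobalShiftResult",
    "CouplingResult",
    "fold_change",
    "classify_regulation",
    "dagostino_pearson",
    "wilcoxon_signed_rank",
    "global_shift_test",
    "coupling_regression",
    "threshold_filter",
    "bh_adjust",
    "ma_table",
    "fold_difference",
]

EXACT_MAX_N = 25  # exact signed-rank null up to here, normal approx beyond


@dataclass(frozen=True)
class DiffRecord:
    """One feature's differential-expression summary."""

    id: str
    basemean: float
    log2fc: float
    p_value: float
    adj_p: float | None = None

    @property
    def fc(self) -> float:
        return float(2.0 ** self.log2fc)


@dataclass(frozen=True)
class GlobalShiftResult:
    normality_p: dict[str, float]
    test_used: str          # "wilcoxon" | "paired_t" | "degenerate"
    statistic: float
    p_value: float
    n_pairs_used: int


@dataclass(frozen=True)
class CouplingResult:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int


def fold_change(
    mean_a: float, mean_b: float, pseudocount: float = 0.0
) -> tuple[float, float]:
    """(fc, log2fc) for b vs a: fc = (mean_b + c) / (mean_a + c)."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be nonnegative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if mean_a + pseudocount == 0:
        raise ValueError("undefined fold change: mean_a + pseudocount = 0")
    if mean_b + pseudocount == 0:
        raise ValueError("undefined fold change: mean_b + pseudocount = 0")
    fc = (mean_b + pseudocount) / (mean_a + pseudocount)
    return fc, float(np.log2(fc))


def classify_regulation(log2fc: float, threshold_fold: float = 2.0) -> str:
    """"up" iff fc strictly exceeds the fold threshold, "down" iff it falls
    strictly below its reciprocal, else "unchanged".

    Strict inequalities: a fold change of exactly the threshold is
    "unchanged" (the rule counts changes of *more than* the threshold).
    """
    if threshold_fold <= 1:
        raise ValueError("threshold_fold must be > 1")
    fc = 2.0 ** log2fc
    if fc > threshold_fold:
        return "up"
    if fc < 1.0 / threshold_fold:
        return "down"
    return "unchanged"


def dagostino_pearson(values) -> tuple[float, float]:
    """D'Agostino–Pearson omnibus normality test (K² = Zs² + Zk², chi²_2)."""
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError(f"need n >= 8, got {x.size}")
    k2, p = stats.normaltest(x)
    return float(k2), float(p)


def _signed_rank_exact_tail(doubled_ranks: np.ndarray, doubled_w: int) -> float:
    """Two-sided exact p for the positive-rank sum.

    ``doubled_ranks`` are midranks x 2 (integers even under ties). The null
    assigns each pair's sign independently with probability 1/2; the DP
    counts sign assignments per achievable doubled rank sum. Two-sided p is
    the doubled smaller tail, capped at 1.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    lo = counts[: doubled_w + 1].sum()
    hi = counts[doubled_w:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_signed_rank(a, b) -> tuple[float, float, int]:
    """Wilcoxon matched-pairs signed-rank test of b vs a, two-sided.

    Zero differences are dropped (Wilcoxon's convention); ties in |d| get
    midranks. Returns (W+ statistic, p, n_pairs_used). Exact null for
    n <= 25 (ties included), else normal approximation with tie correction.
    All pairs equal -> degenerate (p = 1, n = 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, 0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        doubled = np.rint(2 * ranks).astype(int)
        doubled_w = int(np.rint(2 * w_plus))
        p = _signed_rank_exact_tail(doubled, doubled_w)
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return w_plus, min(p, 1.0), n


def global_shift_test(
    paired_a,
    paired_b,
    alpha_normality: float = 0.05,
    test: str = "auto",
) -> GlobalShiftResult:
    """Test for a global shift between paired expression vectors.

    In ``auto`` mode each vector and the paired differences pass through
    the D'Agostino–Pearson normality gate; if any fails at
    ``alpha_normality`` the Wilcoxon signed-rank test is used, otherwise a
    paired t-test. ``test='wilcoxon'`` or ``'t'`` forces the choice (and
    skips the gate, so n >= 8 is only required in auto mode).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = b - a
    if np.all(d == 0):
        return GlobalShiftResult({}, "degenerate", 0.0, 1.0, 0)

    normality_p: dict[str, float] = {}
    if test == "auto":
        if a.size < 8:
            raise ValueError("normality gate needs n >= 8; force test= instead")
        for name, v in (("a", a), ("b", b), ("diff", d)):
            _, normality_p[name] = dagostino_pearson(v)
        use_wilcoxon = any(p < alpha_normality for p in normality_p.values())
    elif test in ("wilcoxon", "t"):
        use_wilcoxon = test == "wilcoxon"
    else:
        raise ValueError(f"unknown test {test!r}")

    if use_wilcoxon:
        w, p, n_used = wilcoxon_signed_rank(a, b)
        return GlobalShiftResult(normality_p, "wilcoxon", w, p, n_used)
    t_stat, p = stats.ttest_rel(b, a)
    return GlobalShiftResult(normality_p, "paired_t", float(t_stat), float(p), a.size)


def coupling_regression(x, y) -> CouplingResult:
    """OLS of y on x with Pearson R² and F-test on the slope.

    F = r²(n-2)/(1-r²) on (1, n-2) df — algebraically t² for the slope, so
    the p-value equals the two-sided slope t-test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]):
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if r2 >= 1.0:
        f = np.inf
        p = 0.0
    else:
        f = r2 * (n - 2) / (1.0 - r2)
        p = float(stats.f.sf(f, 1, n - 2))
    return CouplingResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        f_statistic=float(f),
        p_value=p,
        n=n,
    )


def threshold_filter(
    records: list[DiffRecord],
    p_max: float = 0.05,
    bm_min: float | None = 10.0,
    abs_log2fc_min: float = 0.5,
    use_adj: bool = False,
) -> list[DiffRecord]:
    """Retain records passing ALL strict thresholds.

    p < p_max (raw or adjusted per ``use_adj``), basemean > bm_min (skipped
    when ``bm_min`` is None, as in adjusted-p mode without an abundance
    cut), |log2fc| > abs_log2fc_min. Boundary values are excluded — the
    rules are strict inequalities.
    """
    out = []
    for rec in records:
        if use_adj:
            if rec.adj_p is None:
                raise ValueError(f"record {rec.id} lacks adj_p")
            p = rec.adj_p
        else:
            p = rec.p_value
        if p >= p_max:
            continue
        if bm_min is not None and rec.basemean <= bm_min:
            continue
        if abs(rec.log2fc) <= abs_log2fc_min:
            continue
        out.append(rec)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ma_table(
    mean_expr, log2fc, threshold_fold: float = 2.0, ids=None
) -> pd.DataFrame:
    """MA-plot table: A = mean expression, M = log2 fold change, plus the
    regulation class at ``threshold_fold``."""
    a = np.asarray(mean_expr, dtype=float)
    m = np.asarray(log2fc, dtype=float)
    if a.size != m.size:
        raise ValueError("mean_expr and log2fc must have equal length")
    cls = [classify_regulation(v, threshold_fold) for v in m]
    df = pd.DataFrame({"A": a, "M": m, "regulation": cls})
    if ids is not None:
        df.insert(0, "id", list(ids))
    return df


def fold_difference(mean_a: float, mean_b: float) -> int:
    """Nearest-integer fold difference between two printed means (a vs b)."""
    if mean_b <= 0:
        raise ValueError("denominator mean must be positive")
    return int(round(mean_a / mean_b))
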