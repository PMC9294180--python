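"""Statistical procedures for group comparisons and gene-set enrichment.

Covers the tissue-specificity index tau, the pooled two-proportion z-test,
Pearson chi-square, two-sided Fisher's exact test, odds ratios with
Haldane-Anscombe correction, Pearson correlation, and Fisher-based gene-set
enrichment with Benjamini-Hochberg adjustment (significance at adjusted
p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str
    df: int | None = None


# ------------------------------------------------------------------------- tau

def tau(expr: pd.DataFrame, log_transform: bool = False) -> pd.Series:
    """Tissue-specificity index per gene over a genes x tissues expression panel.

    tau = sum_i (1 - x_i / max_i x_i) / (n - 1); 0 = broadly expressed,
    1 = expressed in a single tissue.  Computed on linear expression values by
    default; ``log_transform`` applies log2(x+1) first.  Genes with all-zero
    expression get NaN (tau undefined).
    """
    if expr.shape[1] < 2:
        raise ValueError("tau needs at least 2 tissues")
    x = expr.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative expression values")
    if log_transform:
        x = np.log2(x + 1.0)
    mx = x.max(axis=1)
    ok = mx > 0
    xhat = np.divide(x, mx[:, None], out=np.zeros_like(x), where=ok[:, None])
    t = (1.0 - xhat).sum(axis=1) / (x.shape[1] - 1)
    t[~ok] = np.nan
    return pd.Series(t, index=expr.index, name="tau")


# ----------------------------------------------------------------- basic tests

def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Pooled two-proportion z-test, two-sided.

    Degenerate pooled proportions (0 or 1) give statistic 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    if pool in (0.0, 1.0):
        return TestResult(0.0, 1.0, "ztest")
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2 * sps.norm.sf(abs(z))
    return TestResult(float(z), float(p), "ztest")


def chi2_test(table) -> TestResult:
    """Pearson chi-square on a 2 x k table, no continuity correction, df = k-1."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal")
    stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return TestResult(float(stat), float(p), "chi2", df=int(df))


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2 x 2 table.

    p = sum of hypergeometric probabilities, over all tables with the observed
    marginals, that do not exceed the observed table's probability.  Computed
    in exact integer arithmetic (all probabilities share the denominator
    C(n, r1), so tables are compared by integer numerators), which makes tie
    handling exact.
    """
    from fractions import Fraction
    from math import comb

    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return TestResult(odds_ratio(table)[0], 1.0, "fisher")
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    nums = [comb(c1, k) * comb(n - c1, r1 - k) for k in range(lo, hi + 1)]
    obs = nums[a - lo]
    total = sum(x for x in nums if x <= obs)
    p = float(Fraction(total, comb(n, r1)))
    return TestResult(odds_ratio(table)[0], min(1.0, p), "fisher")


def odds_ratio(table) -> tuple[float, bool]:
    """(a*d)/(b*c) for a 2x2 table.

    When b or c is zero, all cells get the Haldane-Anscombe +0.5 correction;
    the second return value flags that the correction was applied.
    """
    a, b = float(table[0][0]), float(table[0][1])
    c, d = float(table[1][0]), float(table[1][1])
    if b == 0 or c == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c), True
    return (a * d) / (b * c), False


def pearson_correlation(x, y) -> TestResult:
    """Pearson r with two-sided p via the t transform (n-2 df).

    Pairs with a NaN in either vector are dropped first (e.g. genes whose m6A
    level is undefined).  Zero variance gives NaN statistic and p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(float("nan"), float("nan"), "pearson")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), "pearson", df=len(x) - 2)


# ------------------------------------------------------------------ enrichment

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def geneset_enrichment(group_genes, sets: dict[str, set], universe,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Fisher-exact enrichment of one gene group against named gene sets.

    Each set is intersected with the universe; the 2x2 table is
    (in-group / out-group) x (in-set / out-set).  P-values are BH-adjusted
    across the query's sets; significant means adjusted p < ``alpha``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    group = set(group_genes) & universe
    rows = []
    for name in sorted(sets):
        s = set(sets[name]) & universe
        a = len(group & s)
        b = len(group - s)
        c = len(s - group)
        d = len(universe) - a - b - c
        res = fisher_exact([[a, b], [c, d]])
        orr, corrected = odds_ratio([[a, b], [c, d]])
        rows.append({"set_id": name, "overlap": a, "odds_ratio": orr,
                     "or_corrected": corrected, "pvalue": res.pvalue})
    out = pd.DataFrame(rows)
    if len(out):
        out["adjusted_p"] = bh_adjust(out["pvalue"].to_numpy())
        out["significant"] = out["adjusted_p"] < alpha
        out = out.sort_values(["adjusted_p", "pvalue", "set_id"]).reset_index(drop=True)
    return out


def read_gene_set(path: str) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def read_gmt(path: str) -> dict[str, set[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
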