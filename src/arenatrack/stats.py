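"""Statistical tests used in the benchmarking comparisons.

Two-tailed tests throughout: the two-sample F-test for equal variances
(IFIs and d_p residual variances are compared this way), the Wilcoxon
signed-rank test for paired per-cell metrics, a one-sample test of
proportions against 50%, and Holm-Bonferroni step-down adjustment for
the families of paired comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    p_value: float
    extra: dict | None = None


def f_test_equal_variance(var1: float, df1: int, var2: float, df2: int) -> TestResult:
    """Two-sample F-test for equal variances; f = var1 / var2 as given.

    The ratio is not reordered, so f < 1 is possible; the two-tailed
    p-value covers both tails of the F(df1, df2) distribution.
    """
    if var1 <= 0 or var2 <= 0:
        raise ValueError("variances must be positive")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    f = var1 / var2
    p = 2.0 * min(sps.f.sf(f, df1, df2), sps.f.cdf(f, df1, df2))
    return TestResult(float(f), float(min(p, 1.0)))


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray | None = None) -> TestResult:
    """Wilcoxon signed-rank test, normal approximation with a signed z.

    Differences of zero are dropped; tied absolute differences receive
    averaged ranks; the variance includes the tie correction and the
    statistic a 0.5 continuity correction.  The z statistic is signed by
    the direction of the rank sum: positive when positive differences
    (x > y) dominate.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= np.sum(counts ** 3 - counts) / 48.0
    if var <= 0:
        return TestResult(0.0, 1.0, {"n": n, "w_plus": w_plus})
    diff = w_plus - mu
    correction = 0.5 * np.sign(diff)
    z = (diff - correction) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(float(z), float(min(p, 1.0)), {"n": n, "w_plus": w_plus})


def proportion_z_test(successes: int, n: int, p0: float = 0.5) -> TestResult:
    """One-sample test of proportions: Z = (p_hat - p0) / sqrt(p0 (1-p0) / n).

    Both one-sided (in the direction of the observed deviation) and
    two-sided p-values are reported (``extra['p_one_sided']``).
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= successes <= n or n < 1:
        raise ValueError("need 0 <= successes <= n and n >= 1")
    p_hat = successes / n
    z = (p_hat - p0) / np.sqrt(p0 * (1 - p0) / n)
    p_one = sps.norm.sf(abs(z))
    return TestResult(float(z), float(2 * p_one), {"p_one_sided": float(p_one)})


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p_values = np.asarray(p_values, dtype=float)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p_values.size == 0:
        return p_values
    return multipletests(p_values, method="holm")[1]
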