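"""Independent oracle implementations used by the test suite.

These deliberately avoid the library's code paths: plain normal-equations
OLS, closed-form binary entropy, exhaustive rank-sum enumeration, and
direct hypergeometric/2x2 computations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def ols_oracle(x_cols: np.ndarray, y: np.ndarray) -> dict:
    """Normal-equations OLS of y on [1, x_cols]; stats for coefficient 1.

    ``x_cols`` is n x k (age first).  Returns slope/se/t/p for the first
    regressor after the intercept.
    """
    n = len(y)
    x = np.column_stack([np.ones(n), x_cols])
    xtx = x.T @ x
    xtx_inv = np.linalg.inv(xtx)
    b = xtx_inv @ (x.T @ y)
    resid = y - x @ b
    dof = n - x.shape[1]
    s2 = float(resid @ resid) / dof
    se = math.sqrt(s2 * xtx_inv[1, 1])
    t = b[1] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return {"slope": float(b[1]), "se": se, "t": float(t), "p": float(p)}


def binary_entropy(b: float) -> float:
    """Closed-form entropy of a Bernoulli(b) variable, bits."""
    if b in (0.0, 1.0):
        return 0.0
    return -(b * math.log2(b) + (1 - b) * math.log2(1 - b))


def ranksum_enumeration_p(values_m, values_u) -> float:
    """One-sided (M stochastically smaller) rank-sum p by exhaustive
    enumeration over all labelings of the pooled values."""
    pooled = list(values_m) + list(values_u)
    m = len(values_m)
    ranks = stats.rankdata(pooled)
    obs = ranks[:m].sum()
    total = 0
    at_most = 0
    for combo in itertools.combinations(range(len(pooled)), m):
        total += 1
        if ranks[list(combo)].sum() <= obs:
            at_most += 1
    return at_most / total


def fisher_greater_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p from the hypergeometric tail."""
    # drawing (a+b) from a+b+c+d with a+c 'successes'; observing >= a
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def log_or_ci(a, b, c, d) -> tuple[float, float, float]:
    """Odds ratio and Wald 95% CI, Haldane correction for zero cells."""
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    orr = (cells[0] * cells[3]) / (cells[1] * cells[2])
    se = math.sqrt(np.sum(1.0 / cells))
    return orr, orr * math.exp(-1.96 * se), orr * math.exp(1.96 * se)


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook Welch t statistic."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    return float((a.mean() - b.mean()) / math.sqrt(va / len(a) + vb / len(b)))


def chi2_2x2(table: np.ndarray) -> float:
    """Uncorrected chi-squared statistic for a 2x2 table."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    return float(n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d)))


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation."""
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))
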