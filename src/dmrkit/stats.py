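"""Statistical primitives: two-sided Fisher's exact test and BH adjustment.

The caller runs one Fisher test per 200 bp window genome-wide (tens of
thousands per run), so the test is computed directly from hypergeometric
log-pmfs on a shared log-factorial table rather than through per-call
``scipy.stats.fisher_exact`` objects. Results agree with scipy to floating
precision; the test suite checks both against exact rational enumeration.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

# Tables whose probability is within this relative factor of the observed
# table's count as ties (same convention as scipy); for the count totals a
# per-cytosine test can see, distinct hypergeometric probabilities are
# separated by far more than this, so true ties and only true ties are kept.
_TIE_RTOL = 1e-7


class UndefinedTestError(ValueError):
    """Fisher test requested for a sample with zero total coverage."""


def _logfactorials(n: int) -> np.ndarray:
    """log(k!) for k = 0..n."""
    return gammaln(np.arange(n + 1, dtype=np.float64) + 1.0)


def _two_sided_p(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int,
                 lf: np.ndarray) -> float:
    r1 = meth_a + unmeth_a
    r2 = meth_b + unmeth_b
    c1 = meth_a + meth_b
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    logp = (
        lf[r1] - lf[k] - lf[r1 - k]
        + lf[r2] - lf[c1 - k] - lf[r2 - c1 + k]
        - (lf[n] - lf[c1] - lf[n - c1])
    )
    log_obs = logp[meth_a - lo]
    p = float(np.exp(logp[logp <= log_obs + np.log1p(_TIE_RTOL)]).sum())
    return min(p, 1.0)


@lru_cache(maxsize=1 << 18)
def _cached_p(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> float:
    n = meth_a + unmeth_a + meth_b + unmeth_b
    return _two_sided_p(meth_a, unmeth_a, meth_b, unmeth_b, _logfactorials(n))


def fisher_exact_two_sided(meth_a: int, unmeth_a: int,
                           meth_b: int, unmeth_b: int) -> float:
    """Two-sided Fisher's exact p for the 2×2 table
    [[meth_a, unmeth_a], [meth_b, unmeth_b]].

    The p-value is the sum of hypergeometric probabilities, over all tables
    with the observed margins, of tables no more probable than the observed
    one (ties included). Both per-sample coverages must be positive.
    """
    a, b, c, d = (int(meth_a), int(unmeth_a), int(meth_b), int(unmeth_b))
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise UndefinedTestError(
            "Fisher test undefined for a sample with zero coverage"
        )
    return _cached_p(a, b, c, d)


def fisher_exact_many(tables: np.ndarray) -> np.ndarray:
    """Two-sided Fisher p for each row (meth_a, unmeth_a, meth_b, unmeth_b)
    of an integer array. Rows must have positive per-sample coverage."""
    tables = np.asarray(tables, dtype=np.int64)
    if tables.ndim != 2 or tables.shape[1] != 4:
        raise ValueError("tables must be (n, 4)")
    out = np.empty(len(tables), dtype=np.float64)
    if len(tables) == 0:
        return out
    if tables.min() < 0:
        raise ValueError("counts must be non-negative")
    rows_a = tables[:, 0] + tables[:, 1]
    rows_b = tables[:, 2] + tables[:, 3]
    if (rows_a == 0).any() or (rows_b == 0).any():
        raise UndefinedTestError(
            "Fisher test undefined for a sample with zero coverage"
        )
    lf = _logfactorials(int((rows_a + rows_b).max()))
    for i, (a, b, c, d) in enumerate(tables):
        out[i] = _two_sided_p(int(a), int(b), int(c), int(d), lf)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} (p_(j) * n / j) on the sorted p's, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
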