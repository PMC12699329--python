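"""Exact hypergeometric machinery shared by all profiling methods.

All methods end in a Fisher exact test on a 2x2 contingency table.  The
one-tailed ("greater") test is the upper hypergeometric tail of the top-left
cell with margins fixed; the two-sided test sums the probabilities of all
tables at least as extreme (point probability not larger than the observed
one, up to a small relative epsilon for floating-point ties).

Probabilities are accumulated in log space through ``gammaln`` so tables with
populations up to ~1e6 are handled without overflow.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom

__all__ = ["fisher", "fisher_greater_vec"]

# relative slack when deciding whether a table's point probability is
# "no larger than" the observed one in the two-sided rule
_TWO_SIDED_EPS = 1e-7


def _log_comb(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher(a: int, b: int, c: int, d: int, alternative: str = "two_sided") -> float:
    """Fisher exact p-value for the table ((a, b), (c, d)).

    alternative="greater" gives P(X >= a) for hypergeometric X with the
    table's margins fixed; "two_sided" sums all tables whose point
    probability does not exceed the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be nonnegative")
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1 = a + b  # row margin
    c1 = a + c  # column margin
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    if lo == hi:  # degenerate margin: only one table possible
        return 1.0
    support = np.arange(lo, hi + 1)
    logpmf = (
        _log_comb(c1, support)
        + _log_comb(n - c1, r1 - support)
        - _log_comb(n, r1)
    )
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= math.fsum(pmf)  # compensated normalisation
    obs = pmf[a - lo]
    if alternative == "greater":
        p = math.fsum(pmf[a - lo :])
    else:
        p = math.fsum(pmf[pmf <= obs * (1.0 + _TWO_SIDED_EPS)])
    return min(1.0, float(p))


def fisher_greater_vec(
    a: np.ndarray, r1: np.ndarray, c1: np.ndarray, n: np.ndarray | int
) -> np.ndarray:
    """Vectorised upper-tail P(X >= a) with margins (r1, c1) and population n.

    Backed by scipy's hypergeometric survival function; agreement with
    :func:`fisher` is asserted in the test suite.
    """
    a = np.asarray(a)
    return np.minimum(1.0, hypergeom.sf(a - 1, n, c1, r1))
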