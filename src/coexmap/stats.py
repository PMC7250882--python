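"""Exact combinatorial statistics shared across the pipeline.

Upper-tail hypergeometric tests score the orthologous overlap between
co-expression modules of two species; two-sided Fisher's exact tests back
the term and phylostratum enrichment analyses.  Both reduce to tail sums of
the hypergeometric distribution with fixed margins; the heavy lifting is
delegated to :mod:`scipy.stats`, which evaluates the tails in log space.
Benjamini-Hochberg adjustment is offered for the (optional) multiple-testing
columns of the enrichment tables.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_upper_tail", "fisher_two_sided", "benjamini_hochberg"]


def _check_int(name: str, v) -> int:
    if not float(v).is_integer():
        raise ValueError(f"{name} must be an integer, got {v!r}")
    v = int(v)
    if v < 0:
        raise ValueError(f"{name} must be non-negative, got {v}")
    return v


def hypergeom_upper_tail(x: int, N: int, K: int, n: int) -> float:
    """P[X >= x] for X ~ Hypergeometric(N, K, n).

    ``N`` is the universe size, ``K`` the category (e.g. orthogroups of one
    module), ``n`` the draw (orthogroups of the other module) and ``x`` the
    observed overlap.  ``x > min(K, n)`` is impossible and returns 0 by
    convention; ``x <= 0`` returns 1.

    >>> round(hypergeom_upper_tail(3, 10, 4, 5), 6)
    0.261905
    """
    x = _check_int("x", x)
    N = _check_int("N", N)
    K = _check_int("K", K)
    n = _check_int("n", n)
    if K > N or n > N:
        raise ValueError(f"inconsistent margins: K={K}, n={n} must be <= N={N}")
    if x > min(K, n):
        return 0.0
    if x <= 0:
        return 1.0
    # sf(x-1) = P[X > x-1] = P[X >= x]
    return float(min(1.0, _st.hypergeom.sf(x - 1, N, K, n)))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table ((a, b), (c, d)).

    The two-sided p sums the probabilities of all tables with the observed
    margins whose point probability does not exceed the observed one (up to
    a small relative tolerance for floating-point ties) -- the convention of
    R's ``fisher.test``.  An all-zero table returns 1.
    """
    a = _check_int("a", a)
    b = _check_int("b", b)
    c = _check_int("c", c)
    d = _check_int("d", d)
    if a + b + c + d == 0:
        return 1.0
    _, p = _st.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(1.0, p))


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
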