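"""Shared small-sample statistics helpers."""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import stats

__all__ = ["spearman_test", "EXACT_PERMUTATION_MAX_N"]

# Full enumeration of n! rank permutations stays cheap up to 9 (362,880).
EXACT_PERMUTATION_MAX_N = 9


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    sx, sy = np.std(rx), np.std(ry)
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_test(x, y, exact_max_n: int = EXACT_PERMUTATION_MAX_N):
    """Spearman rank correlation with average-rank ties and a two-sided p-value.

    For n <= exact_max_n the p-value is the exact permutation tail
    P(|rho_perm| >= |rho_obs|) over all n! orderings of one variable; for larger
    n the usual t approximation t = rho * sqrt((n-2) / (1-rho^2)) is used.

    Returns (rho, p, method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_corr(rx, ry)
    if np.isnan(rho):
        return np.nan, np.nan, "undefined"
    if n <= exact_max_n:
        perms = np.array(list(permutations(range(n))))
        ry_perm = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        num = ryc @ rxc
        den = np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
        rhos = num / den
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, p, "exact-permutation"
    if abs(rho) >= 1.0:
        return rho, 0.0, "t-approximation"
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p, "t-approximation"
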