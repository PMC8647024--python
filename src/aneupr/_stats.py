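"""Shared statistical helpers: BH adjustment and Spearman utilities.

A single Benjamini-Hochberg routine backs every FDR correction in the
package so that q-values are comparable across stages.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    NaN entries (untestable hypotheses) are ignored for the correction and
    propagate as NaN. q-values are monotone in p and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    m = pm.size
    if m == 0:
        return q
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qm = np.empty(m)
    qm[order] = np.minimum(ranked, 1.0)
    q[mask] = qm
    return q


def spearman_t_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a Spearman coefficient via Student's t with df = n - 2."""
    if n < 3 or np.isnan(rho):
        return np.nan
    r = float(np.clip(rho, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def rank_matrix(x: np.ndarray) -> np.ndarray:
    """Row-wise average ranks of a genes x samples matrix."""
    return stats.rankdata(x, axis=-1)


def spearman_matrix(x: np.ndarray) -> np.ndarray:
    """Gene x gene Spearman correlation from a genes x samples matrix.

    Constant rows yield 0 off-diagonal (no rank information) and 1 on the
    diagonal.
    """
    r = rank_matrix(np.asarray(x, dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(r)
    c = np.atleast_2d(c)
    bad = ~np.isfinite(c)
    if bad.any():
        c[bad] = 0.0
    np.fill_diagonal(c, 1.0)
    return c
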