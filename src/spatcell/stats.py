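"""Shared statistical helpers: FDR correction and p-value combination."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr", "weighted_stouffer", "pearson_with_p"]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, clipped at 1).

    NaN entries (undefined tests) are excluded from the correction and
    returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pv.size:
        out[valid] = multipletests(pv, method="fdr_bh")[1]
    return out


def weighted_stouffer(pvalues, weights) -> tuple[float, float]:
    """Combine one-sided p-values across ROIs by the weighted Stouffer method.

    Z = Σ w_i Φ⁻¹(1 − p_i) / sqrt(Σ w_i²); returns (Z, combined one-sided p).
    ROIs with NaN p or zero weight still contribute their weight of zero;
    pairs where no ROI is defined return (nan, nan).
    """
    p = np.asarray(pvalues, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    ok = ~np.isnan(p) & (w > 0)
    if not ok.any():
        return float("nan"), float("nan")
    res = sps.combine_pvalues(p[ok], method="stouffer", weights=w[ok])
    return float(res.statistic), float(res.pvalue)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-distribution p (df = n − 2).

    Returns (nan, nan) on zero variance or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
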