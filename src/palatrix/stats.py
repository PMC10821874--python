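"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up); NaNs pass through."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def pearson_columns(X: np.ndarray, y: np.ndarray):
    """Pearson r of every column of X with y, plus two-sided t-test p.

    Columns with zero variance get r = nan, p = nan.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    bad = (sx == 0) | (sy == 0)
    r[bad] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r ** 2))
    p = 2.0 * ss.t.sf(np.abs(t), df=n - 2)
    p[bad] = np.nan
    return r, p


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Z-score columns; zero-variance columns become all-zero."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd
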