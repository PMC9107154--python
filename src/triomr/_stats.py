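"""Small shared statistical utilities (multiple testing, trigamma inversion)."""

from __future__ import annotations

import numpy as np
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs pass through as NaN."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def storey_pi0(pvals: np.ndarray, lam: float = 0.5) -> float:
    """Storey's null-proportion estimate pi0 = #{p > lambda} / (m (1-lambda))."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    pi0 = (p > lam).mean() / (1.0 - lam)
    return float(min(max(pi0, 0.0), 1.0))


def qvalues(pvals: np.ndarray, method: str = "bh") -> np.ndarray:
    """FDR q-values: plain BH (default) or BH scaled by Storey's pi0."""
    q = bh_adjust(pvals)
    if method == "bh":
        return q
    if method == "storey":
        return np.clip(q * storey_pi0(pvals), 0.0, 1.0)
    raise ValueError(f"unknown q-value method {method!r}")


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Uses the monotone decreasing shape of trigamma; the update is performed on
    1/y where trigamma is close to linear, which converges from the standard
    series starting value 0.5 + 1/x.
    """
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)
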