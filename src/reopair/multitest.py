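"""Multiple-testing corrections: Storey's positive FDR q-values and BH FDR.

The gene and gene-pair screens use Storey's pFDR (q-values) with the
fixed-lambda pi0 estimator; every downstream differential analysis uses
Benjamini-Hochberg, delegated to statsmodels.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["storey_qvalues", "bh_fdr"]


def storey_qvalues(pvalues, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the fixed-lambda pi0 estimator.

    pi0 is estimated as #{p > lam} / ((1 - lam) * m), clipped to (0, 1];
    a +1 in the numerator guards the estimate away from zero when every
    p-value is small (finite-sample conservativeness). q-values are the
    step-up cumulative minimum of pi0 * m * p_(i) / i.

    Parameters
    ----------
    pvalues : array-like of p-values in [0, 1]; NaNs propagate as NaN.
    lam : tuning parameter of the pi0 estimator, default 0.5.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    pi0 = min(1.0, ((pv > lam).sum() + 1.0) / ((1.0 - lam) * m))
    order = np.argsort(pv, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * pv[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    out[ok] = q
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs propagate."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
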