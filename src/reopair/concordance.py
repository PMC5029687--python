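"""Concordance score s/k between two directional feature lists and its
cumulative-binomial significance.

Two modes:

* DEG-vs-DEG: features shared by both lists are concordant when their
  dysregulation directions agree.
* methylation-vs-expression: a hypermethylated gene is concordant when
  underexpressed, a hypomethylated gene when overexpressed (promoter
  methylation represses transcription).

Significance is the exact upper tail P(X >= s) of Binomial(k, p_e) with
p_e = 0.5 by default: the chance a gene agrees in direction when the two
lists are unrelated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = ["ConcordanceResult", "concordance_score", "binomial_tail"]

# direction-label pairs that count as concordant in meth-vs-expr mode
_METH_EXPR_CONCORDANT = {("hyper", "down_in_high"), ("hyper", "down"),
                         ("hypo", "up_in_high"), ("hypo", "up")}


@dataclass
class ConcordanceResult:
    k: int            # shared features
    s: int            # concordant shared features
    p_e: float        # null per-feature concordance probability
    score: float      # s / k
    p: float          # upper-tail binomial P(X >= s)

    def __post_init__(self):
        if not 0 <= self.s <= self.k:
            raise ValueError("need 0 <= s <= k")


def binomial_tail(s: int, k: int, p_e: float = 0.5) -> float:
    """Exact upper-tail binomial probability P(X >= s), X ~ Bin(k, p_e).

    Computed in log space (log-gamma binomial coefficients + logsumexp)
    so tails far below double-epsilon remain meaningful. Returns 1 when
    s = 0 (the empty lower sum).
    """
    if not (isinstance(s, (int, np.integer)) and isinstance(k, (int, np.integer))):
        raise TypeError("s and k must be integers")
    if s < 0 or k < 0 or s > k:
        raise ValueError("need 0 <= s <= k")
    if not 0.0 < p_e < 1.0:
        raise ValueError("p_e must lie strictly in (0, 1)")
    if s == 0:
        return 1.0
    i = np.arange(s, k + 1)
    log_terms = (gammaln(k + 1) - gammaln(i + 1) - gammaln(k - i + 1)
                 + i * np.log(p_e) + (k - i) * np.log1p(-p_e))
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def concordance_score(list_a: dict[str, str], list_b: dict[str, str],
                      mode: str = "deg", p_e: float = 0.5) -> ConcordanceResult:
    """Concordance between two feature->direction mappings.

    mode 'deg' (symmetric): concordant when directions are equal.
    mode 'meth_expr': list_a holds methylation directions
    ('hyper'/'hypo'), list_b expression directions; concordant means
    hyper<->down and hypo<->up.
    """
    if mode not in ("deg", "meth_expr"):
        raise ValueError("mode must be 'deg' or 'meth_expr'")
    shared = sorted(set(list_a) & set(list_b))
    k = len(shared)
    if k == 0:
        raise ValueError("no shared features: concordance score undefined")
    if mode == "deg":
        s = sum(list_a[f] == list_b[f] for f in shared)
    else:
        s = sum((list_a[f], list_b[f]) in _METH_EXPR_CONCORDANT
                for f in shared)
    return ConcordanceResult(k=k, s=s, p_e=p_e, score=s / k,
                             p=binomial_tail(s, k, p_e))
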