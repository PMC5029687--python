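"""Hypergeometric gene-set over-representation with BH FDR.

Gene sets come from a GMT file (or an in-memory mapping); the background
universe defaults to all genes of the expression matrix under analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from gseapy import read_gmt
from scipy import stats

from .multitest import bh_fdr

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "hypergeom_enrich"]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict[str, set]
    universe: set = field(default_factory=set)

    def __post_init__(self):
        self.universe = set(self.universe)
        filtered = {}
        for name, members in self.sets.items():
            members = set(members) & self.universe if self.universe else set(members)
            if members:
                filtered[name] = members
            else:
                logger.info("gene set %r empty after universe filtering", name)
        self.sets = filtered

    @classmethod
    def from_gmt(cls, path, universe) -> "GeneSetCollection":
        raw = read_gmt(str(path))
        return cls(sets={k: set(v) for k, v in raw.items()},
                   universe=set(universe))


def hypergeom_enrich(query, collection: GeneSetCollection,
                     fdr_cut: float | None = 0.05,
                     p_cut: float | None = None) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    P(X >= overlap) with population N = |universe|, successes K =
    |set|, draws n = |query|. Query genes outside the universe are
    dropped with a logged count. Significance flag from BH ``fdr_cut``,
    or from the raw p-value when ``p_cut`` is given.
    """
    query = set(query)
    if collection.universe:
        dropped = len(query - collection.universe)
        if dropped:
            logger.info("%d query genes outside the universe dropped", dropped)
        query &= collection.universe
    if not query:
        raise ValueError("query is empty after universe filtering")
    n_universe = len(collection.universe)
    rows = []
    for name, members in collection.sets.items():
        overlap = len(query & members)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe,
                                     len(members), len(query)))
        rows.append((name, overlap, len(members), min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    if p_cut is not None:
        out["significant"] = out["p"] < p_cut
    else:
        out["significant"] = out["fdr"] < (fdr_cut if fdr_cut is not None
                                           else 0.05)
    return out.sort_values("p", kind="stable").reset_index(drop=True)
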