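"""REO gene-pair prognostic signature discovery and classification.

The pipeline: (1) screen genes whose expression associates with survival
(univariate Cox, Storey pFDR), (2) form all pairs of screened genes and
screen the binary within-sample ordering indicator (E_a > E_b) the same
way, (3) grow the signature by greedy forward selection on Harrell's
C-index under the majority-vote risk score, (4) classify each sample
independently by counting pairs whose observed ordering matches the
high-risk direction.

Because only within-sample orderings are read at prediction time, risk
calls are invariant to any strictly increasing per-sample transform of
the expression values (batch effects, normalization, unit changes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .multitest import storey_qvalues
from .survival import DegenerateInputError, ConvergenceError, c_index, cox_univariate

logger = logging.getLogger(__name__)

__all__ = [
    "GenePairRecord", "SignatureModel", "RiskCall", "reo_indicator",
    "screen_genes", "screen_pairs", "forward_select", "classify",
    "write_signature", "read_signature",
]


class MissingGeneError(KeyError):
    """A gene required by the signature is absent from the expression data."""


@dataclass
class GenePairRecord:
    """An ordered gene pair with its prognostic statistics.

    ``high_risk_reo`` names the within-sample ordering observed in
    high-risk patients: ``a_gt_b`` means E_a > E_b votes high risk.
    ``beta`` is the Cox log-hazard of carrying the high-risk ordering and
    is always positive after orientation.
    """

    gene_a: str
    gene_b: str
    beta: float
    pfdr: float
    c_index: float
    high_risk_reo: str  # 'a_gt_b' | 'a_lt_b'

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError("gene_a and gene_b must differ")
        if self.high_risk_reo not in ("a_gt_b", "a_lt_b"):
            raise ValueError("high_risk_reo must be 'a_gt_b' or 'a_lt_b'")


@dataclass
class SignatureModel:
    """An ordered list of gene pairs with a majority-vote threshold."""

    pairs: list[GenePairRecord]
    vote_threshold: int
    training_c_index: float

    def __post_init__(self):
        if self.vote_threshold != math.ceil(len(self.pairs) / 2):
            raise ValueError("vote_threshold must be ceil(n_pairs / 2)")

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.gene_a)
            seen.setdefault(p.gene_b)
        return list(seen)


@dataclass
class RiskCall:
    sample_id: str
    votes_high: int
    label: str  # 'high' | 'low'


def reo_indicator(expr_row: pd.Series, gene_a: str, gene_b: str) -> int:
    """Within-sample ordering indicator: 1 if E_a > E_b else 0 (ties -> 0)."""
    for g in (gene_a, gene_b):
        if g not in expr_row.index or pd.isna(expr_row[g]):
            raise MissingGeneError(
                f"gene {g!r} missing for sample {expr_row.name!r}")
    return int(expr_row[gene_a] > expr_row[gene_b])


def _pair_votes(expr: pd.DataFrame, pairs: list[GenePairRecord]) -> np.ndarray:
    """Per-sample count of pairs voting high risk (vectorized)."""
    missing = [g for p in pairs for g in (p.gene_a, p.gene_b)
               if g not in expr.columns]
    if missing:
        raise MissingGeneError(f"expression lacks signature genes: "
                               f"{sorted(set(missing))}")
    votes = np.zeros(len(expr), dtype=int)
    for p in pairs:
        ind = (expr[p.gene_a].to_numpy(float)
               > expr[p.gene_b].to_numpy(float)).astype(int)
        votes += ind if p.high_risk_reo == "a_gt_b" else 1 - ind
    return votes


def screen_genes(expr: pd.DataFrame, time, event,
                 pfdr_cut: float = 0.20) -> pd.DataFrame:
    """Screen genes whose expression is prognostic.

    Univariate Cox on the continuous expression of each gene; Storey
    q-values over all testable genes; returns genes with pfdr < pfdr_cut
    as a DataFrame (gene, beta, p, pfdr) sorted by p. Genes whose fit
    fails (constant expression, separation) are excluded from the
    multiple-testing family with a logged warning.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two genes to screen")
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    rows = []
    for gene in expr.columns:
        x = expr[gene].to_numpy(float)
        try:
            beta, _, p = cox_univariate(x, t, e)
        except (DegenerateInputError, ConvergenceError) as exc:
            logger.warning("gene %s excluded from screen: %s", gene, exc)
            continue
        rows.append((gene, beta, p))
    out = pd.DataFrame(rows, columns=["gene", "beta", "p"])
    out["pfdr"] = storey_qvalues(out["p"].to_numpy())
    out = out[out["pfdr"] < pfdr_cut].sort_values("p", kind="stable")
    return out.reset_index(drop=True)


def screen_pairs(genes: list[str], expr: pd.DataFrame, time, event,
                 pfdr_cut: float = 0.10) -> list[GenePairRecord]:
    """Screen all unordered pairs of screened genes by their REO indicator.

    For each pair (A, B) in lexicographic order the indicator 1[E_a > E_b]
    enters a univariate Cox fit; the stored record is oriented so beta > 0
    (``high_risk_reo`` flips instead of the gene order). The pair C-index
    uses the high-risk-ordering indicator as the risk score. Storey
    q-values are computed over all testable pairs; pairs whose indicator
    is constant are skipped with a logged reason.
    """
    if len(genes) < 2:
        raise ValueError("need at least two screened genes")
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    cand = []
    for a, b in combinations(sorted(genes), 2):
        ind = (expr[a].to_numpy(float) > expr[b].to_numpy(float)).astype(float)
        if ind.min() == ind.max():
            logger.info("pair (%s, %s) skipped: constant REO indicator", a, b)
            continue
        try:
            beta, _, p = cox_univariate(ind, t, e)
        except (DegenerateInputError, ConvergenceError) as exc:
            logger.info("pair (%s, %s) skipped: %s", a, b, exc)
            continue
        if beta >= 0:
            reo, risk = "a_gt_b", ind
        else:
            reo, beta, risk = "a_lt_b", -beta, 1.0 - ind
        cand.append((a, b, beta, p, reo, c_index(risk, t, e)))
    if not cand:
        return []
    pfdr = storey_qvalues([r[3] for r in cand])
    records = [
        GenePairRecord(gene_a=a, gene_b=b, beta=beta, pfdr=float(q),
                       c_index=ci, high_risk_reo=reo)
        for (a, b, beta, p, reo, ci), q in zip(cand, pfdr) if q < pfdr_cut
    ]
    records.sort(key=lambda r: (-r.c_index, r.gene_a, r.gene_b))
    return records


def forward_select(candidates: list[GenePairRecord], expr: pd.DataFrame,
                   time, event, use_votes: bool = True) -> SignatureModel:
    """Greedy forward selection of the signature by ensemble C-index.

    Seeds with the highest-C-index pair, then visits the remaining
    candidates in descending single-pair C-index order, keeping an
    addition only when the ensemble C-index strictly improves, and stops
    at the first non-improving candidate. The ensemble risk score is the
    per-sample high-risk vote count (``use_votes=True``, default) or the
    binary majority label.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    ordered = sorted(candidates, key=lambda r: (-r.c_index, r.gene_a, r.gene_b))

    def ensemble_c(pairs: list[GenePairRecord]) -> float:
        votes = _pair_votes(expr, pairs)
        if use_votes:
            score = votes
        else:
            score = (votes >= math.ceil(len(pairs) / 2)).astype(int)
        return c_index(score, t, e)

    selected = [ordered[0]]
    best = ensemble_c(selected)
    for nxt in ordered[1:]:
        trial = ensemble_c(selected + [nxt])
        if trial > best:
            selected.append(nxt)
            best = trial
        else:
            break
    return SignatureModel(pairs=selected,
                          vote_threshold=math.ceil(len(selected) / 2),
                          training_c_index=best)


def classify(expr: pd.DataFrame, model: SignatureModel) -> list[RiskCall]:
    """Classify each sample independently by the majority-vote rule.

    A sample is called high risk iff at least ``vote_threshold`` pairs
    show their high-risk ordering. Only the sample's own row is read, so
    a sample's call is identical whether it is classified alone or within
    any cohort.
    """
    votes = _pair_votes(expr, model.pairs)
    return [RiskCall(sample_id=str(sid), votes_high=int(v),
                     label="high" if v >= model.vote_threshold else "low")
            for sid, v in zip(expr.index, votes)]


def risk_labels(calls: list[RiskCall]) -> pd.Series:
    """Convenience: RiskCalls as a sample-indexed 'high'/'low' Series."""
    return pd.Series({c.sample_id: c.label for c in calls}, name="label")


# ---------------------------------------------------------------------------
# plain-text model serialization (exact round trip)

def write_signature(model: SignatureModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#vote_threshold={model.vote_threshold}\t"
                 f"training_c_index={float(model.training_c_index)!r}\n")
        fh.write("gene_a\tgene_b\thigh_risk_reo\tbeta\tc_index\tpfdr\n")
        for p in model.pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.high_risk_reo}\t"
                     f"{float(p.beta)!r}\t{float(p.c_index)!r}\t"
                     f"{float(p.pfdr)!r}\n")


def read_signature(path) -> SignatureModel:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#vote_threshold="):
            raise ValueError(f"{path}: missing signature header line")
        meta = dict(tok.split("=", 1) for tok in header[1:].split("\t"))
        fh.readline()  # column header
        pairs = []
        for line in fh:
            a, b, reo, beta, ci, pfdr = line.rstrip("\n").split("\t")
            pairs.append(GenePairRecord(
                gene_a=a, gene_b=b, beta=float(beta), pfdr=float(pfdr),
                c_index=float(ci), high_risk_reo=reo))
    return SignatureModel(pairs=pairs,
                          vote_threshold=int(meta["vote_threshold"]),
                          training_c_index=float(meta["training_c_index"]))
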