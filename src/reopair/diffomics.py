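"""Differential analyses between predicted risk groups across omics layers.

Expression: Student's t-test (single-batch cohorts) or the Rank Product
algorithm (multi-batch cohorts, rank-based hence batch-insensitive).
Methylation: per-locus Wilcoxon rank-sum with gene-level aggregation.
Copy number / mutation: per-gene Fisher exact frequency tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .multitest import bh_fdr

logger = logging.getLogger(__name__)

__all__ = ["deg_ttest", "rank_product_degs", "dm_loci", "dm_genes",
           "frequency_test", "aggregate_regions"]

UP, DOWN = "up_in_high", "down_in_high"


def _split_groups(values: pd.DataFrame, labels: pd.Series, min_per_group=2):
    labels = labels.reindex(values.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    hi = values.loc[labels == "high"]
    lo = values.loc[labels == "low"]
    if len(hi) < min_per_group or len(lo) < min_per_group:
        raise ValueError(
            f"each group needs >= {min_per_group} samples "
            f"(got high={len(hi)}, low={len(lo)})")
    return hi, lo


def deg_ttest(expr: pd.DataFrame, labels: pd.Series,
              fdr_cut: float = 0.01) -> pd.DataFrame:
    """Differentially expressed genes by equal-variance Student's t-test.

    Returns one row per gene: feature_id, direction (from the group mean
    difference), statistic, p, fdr (BH), significant (fdr < fdr_cut).
    """
    hi, lo = _split_groups(expr, labels)
    res = stats.ttest_ind(hi.to_numpy(float), lo.to_numpy(float),
                          axis=0, equal_var=True)
    stat = np.nan_to_num(res.statistic, nan=0.0)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    diff = hi.mean(axis=0).to_numpy() - lo.mean(axis=0).to_numpy()
    out = pd.DataFrame({
        "feature_id": expr.columns,
        "direction": np.where(diff >= 0, UP, DOWN),
        "statistic": stat,
        "p": p,
        "fdr": bh_fdr(p),
    })
    out["significant"] = out["fdr"] < fdr_cut
    return out


def rank_product_degs(expr: pd.DataFrame, labels: pd.Series,
                      fdr_cut: float = 0.01, n_permutations: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Differentially expressed genes by the two-class Rank Product.

    For every (high sample, low sample) pairing the genes are ranked by
    the expression difference (rank 1 = most up-regulated in the high
    sample for the up run, most down-regulated for the down run); a
    gene's rank product is the geometric mean of its ranks across all
    pairings. Significance comes from permutations that redraw each
    pairing's ranks uniformly (the null in which genes are exchangeable
    within comparisons): p is the expected number of null genes at or
    below the observed rank product divided by (n_permutations * genes),
    and fdr is Breitling's expected proportion of false predictions.

    Because only within-pairing ranks of differences enter, any shift
    applied to all genes of one sample (a batch offset) leaves the result
    unchanged.
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    hi, lo = _split_groups(expr, labels)
    genes = expr.columns
    g = len(genes)
    diffs = (hi.to_numpy(float)[:, None, :]
             - lo.to_numpy(float)[None, :, :]).reshape(-1, g)
    k = diffs.shape[0]  # number of pairings

    def rank_product(mat_desc: np.ndarray) -> np.ndarray:
        # rank 1 = largest value in each row
        ranks = stats.rankdata(-mat_desc, axis=1, method="average")
        return np.exp(np.log(ranks).mean(axis=0))

    rp_up = rank_product(diffs)
    rp_down = rank_product(-diffs)

    rng = np.random.default_rng(seed)
    exceed_up = np.zeros(g)
    exceed_down = np.zeros(g)
    for _ in range(n_permutations):
        null_ranks = np.argsort(
            rng.random((k, g)), axis=1).argsort(axis=1) + 1.0
        rp_null = np.exp(np.log(null_ranks).mean(axis=0))
        rp_null.sort()
        exceed_up += np.searchsorted(rp_null, rp_up, side="right")
        exceed_down += np.searchsorted(rp_null, rp_down, side="right")

    def table(rp, exceed, direction):
        p = exceed / (n_permutations * g)
        order = stats.rankdata(rp, method="ordinal")
        pfp = np.minimum(exceed / n_permutations / order, 1.0)
        return pd.DataFrame({"feature_id": genes, "direction": direction,
                             "statistic": rp, "p": np.minimum(p, 1.0),
                             "fdr": pfp})

    up = table(rp_up, exceed_up, UP)
    down = table(rp_down, exceed_down, DOWN)
    # keep, per gene, the direction with the smaller rank product
    out = pd.concat([up, down], ignore_index=True)
    out = (out.sort_values(["feature_id", "statistic"], kind="stable")
              .groupby("feature_id", sort=False).head(1))
    out = (out.set_index("feature_id").loc[genes]
              .rename_axis("feature_id").reset_index())
    out["significant"] = out["fdr"] < fdr_cut
    return out


def dm_loci(meth: pd.DataFrame, labels: pd.Series,
            fdr_cut: float = 0.01) -> pd.DataFrame:
    """Differentially methylated CpG loci by Wilcoxon rank-sum.

    Direction is hyper (``up_in_high``) when the high-risk median beta
    exceeds the low-risk median. Constant loci get p = 1 by convention.
    """
    hi, lo = _split_groups(meth, labels)
    a, b = hi.to_numpy(float), lo.to_numpy(float)
    const = np.ptp(meth.to_numpy(float), axis=0) == 0
    with np.errstate(all="ignore"):
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    p = np.asarray(res.pvalue, float)
    p[const] = 1.0
    if const.any():
        logger.info("%d constant loci assigned p = 1", int(const.sum()))
    med_diff = np.median(a, axis=0) - np.median(b, axis=0)
    out = pd.DataFrame({
        "feature_id": meth.columns,
        "direction": np.where(med_diff >= 0, UP, DOWN),
        "statistic": np.asarray(res.statistic, float),
        "p": p,
        "fdr": bh_fdr(p),
    })
    out["significant"] = out["fdr"] < fdr_cut
    return out


def dm_genes(loci_table: pd.DataFrame,
             locus_gene_map: pd.DataFrame) -> pd.DataFrame:
    """Aggregate significant DM loci to gene-level methylation calls.

    A gene is hyper (hypo) iff it has at least one significant hyper
    (hypo) locus and none of the opposite direction; genes with both are
    excluded, genes with no significant locus are absent. Returns a
    DataFrame (gene_id, direction in {'hyper', 'hypo'}).
    """
    mapping = locus_gene_map.set_index("locus_id")["gene_id"]
    sig = loci_table[loci_table["significant"]].copy()
    sig["gene_id"] = sig["feature_id"].map(mapping)
    unmapped = sig["gene_id"].isna().sum()
    if unmapped:
        logger.info("%d significant loci without gene mapping dropped",
                    int(unmapped))
    sig = sig.dropna(subset=["gene_id"])
    rows = []
    for gene, grp in sig.groupby("gene_id", sort=True):
        dirs = set(grp["direction"])
        if dirs == {UP}:
            rows.append((gene, "hyper"))
        elif dirs == {DOWN}:
            rows.append((gene, "hypo"))
        # both directions -> excluded
    return pd.DataFrame(rows, columns=["gene_id", "direction"])


def aggregate_regions(alterations: pd.DataFrame,
                      gene_region_map: pd.DataFrame,
                      mode: str = "gain") -> pd.DataFrame:
    """Collapse gene-level alteration calls to region-level indicators.

    A sample is altered in a region when any mapped gene carries the
    alteration (gain: value > 0, loss: value < 0, mutation: value == 1).
    ``gene_region_map`` needs columns gene_id, region_id; unmapped genes
    are ignored. The result (samples x regions, 0/1) feeds
    :func:`frequency_test` with mode='mutation' for cytoband-style
    frequency comparisons.
    """
    if mode not in ("gain", "loss", "mutation"):
        raise ValueError("mode must be 'gain', 'loss' or 'mutation'")
    altered = {"gain": alterations > 0, "loss": alterations < 0,
               "mutation": alterations == 1}[mode]
    cols = {}
    for region, grp in gene_region_map.groupby("region_id", sort=True):
        genes = [g for g in grp["gene_id"] if g in altered.columns]
        if genes:
            cols[region] = altered[genes].any(axis=1).astype(int)
    return pd.DataFrame(cols, index=alterations.index)


def frequency_test(alterations: pd.DataFrame, labels: pd.Series,
                   mode: str, fdr_cut: float | None = 0.10,
                   p_cut: float | None = None) -> pd.DataFrame:
    """Per-gene Fisher exact test of alteration frequency between groups.

    mode 'gain' counts values > 0, 'loss' values < 0, 'mutation' values
    == 1. Returns per gene: frequencies in each group, two-sided Fisher
    p, BH fdr, and a significance flag from ``fdr_cut`` (or raw ``p_cut``
    when given, as used for mutation screens).
    """
    if mode not in ("gain", "loss", "mutation"):
        raise ValueError("mode must be 'gain', 'loss' or 'mutation'")
    hi, lo = _split_groups(alterations, labels, min_per_group=1)
    a, b = hi.to_numpy(), lo.to_numpy()
    altered = {"gain": lambda m: m > 0, "loss": lambda m: m < 0,
               "mutation": lambda m: m == 1}[mode]
    ah, al = altered(a).sum(axis=0), altered(b).sum(axis=0)
    nh, nl = len(hi), len(lo)
    rows = []
    for gene, kh, kl in zip(alterations.columns, ah, al):
        if kh + kl == 0:
            p = 1.0
        else:
            p = float(stats.fisher_exact(
                [[kh, nh - kh], [kl, nl - kl]]).pvalue)
        rows.append((gene, kh / nh, kl / nl, p))
    out = pd.DataFrame(rows, columns=["feature_id", "freq_high",
                                      "freq_low", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    if p_cut is not None:
        out["significant"] = out["p"] < p_cut
    else:
        out["significant"] = out["fdr"] < (fdr_cut if fdr_cut is not None
                                           else 0.10)
    out["direction"] = np.where(out["freq_high"] >= out["freq_low"], UP, DOWN)
    return out
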