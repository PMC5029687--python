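"""Synthetic multi-omics cohort generator with planted ground truth.

Emulates the statistical structure the discovery pipeline assumes: two
latent prognostic groups with a proportional-hazards survival difference,
gene pairs whose within-sample relative expression ordering (REO) reverses
between the groups, correlated disease-free and overall survival, promoter
methylation differences concordant with expression, focal copy-number
gains with overexpression, and group-biased mutation frequencies.

Design notes
------------
* Event times are exponential with the high-risk hazard multiplied by
  ``hazard_ratio``; censoring is administrative-uniform on [0, T_max] with
  T_max solved numerically so the expected censoring fraction equals
  ``censor_rate``.
* Overall survival is disease-free survival plus an independent positive
  exponential increment whose variance is chosen so the correlation of the
  uncensored times equals ``dfs_os_correlation``.
* Expression is Gaussian on a log2-like scale; only within-sample
  orderings carry the planted pair signal, so the distributional family is
  immaterial downstream.
* Each omics layer draws from its own child stream of the master seed, so
  adding or resizing one layer never perturbs another.
* Planted gene blocks (pair genes, DM genes, amplified genes, mutated
  genes) are disjoint so each signal can be recovered independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = ["CohortConfig", "GroundTruth", "CohortBundle", "generate_cohort"]

# magnitudes of planted effects, in units of the unit-variance expression
# noise / the logit-scale methylation noise
_PAIR_GAP_MEAN = 1.2
_DM_EXPR_SHIFT = 1.2
_DM_LOGIT_SHIFT = 1.0
_AMP_EXPR_SHIFT = 1.2
_AMP_RATE_HIGH, _AMP_RATE_LOW = 0.60, 0.15
_MUT_RATE_HIGH, _MUT_RATE_LOW = 0.35, 0.05
_BACKGROUND_CNA_RATE = 0.05
_BACKGROUND_MUT_RATE = 0.02


class CohortConfigError(ValueError):
    """A CohortConfig field is out of its valid range."""


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror a single-institution early-stage HCC training cohort:
    170 patients, ~40% relapsing early (high-risk), a disease-free-survival
    hazard ratio of 6 between latent groups, DFS-OS correlation 0.78, and
    REO fidelity 0.95 for the planted prognostic pairs.
    """

    n_samples: int = 170
    n_genes: int = 1000
    n_planted_pairs: int = 20
    frac_high_risk: float = 0.4
    hazard_ratio: float = 6.0
    baseline_median_dfs_months: float = 60.0
    censor_rate: float = 0.4
    dfs_os_correlation: float = 0.78
    reo_fidelity: float = 0.95
    n_dm_genes: int = 200
    n_amplified_genes: int = 50
    n_mutation_genes: int = 50
    dm_expression_concordance: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        def check(cond, name, msg):
            if not cond:
                raise CohortConfigError(f"{name}: {msg}")

        check(self.n_samples > 0, "n_samples", "must be positive")
        check(self.n_genes > 0, "n_genes", "must be positive")
        check(self.n_planted_pairs >= 0, "n_planted_pairs", "must be >= 0")
        check(0 < self.frac_high_risk < 1, "frac_high_risk",
              "must lie strictly in (0, 1)")
        check(self.hazard_ratio > 0, "hazard_ratio", "must be positive")
        check(self.baseline_median_dfs_months > 0,
              "baseline_median_dfs_months", "must be positive")
        check(0 <= self.censor_rate < 1, "censor_rate", "must lie in [0, 1)")
        check(0 < self.dfs_os_correlation <= 1, "dfs_os_correlation",
              "must lie in (0, 1]")
        check(0.5 < self.reo_fidelity <= 1, "reo_fidelity",
              "must lie in (0.5, 1]")
        for nm in ("n_dm_genes", "n_amplified_genes", "n_mutation_genes"):
            check(getattr(self, nm) >= 0, nm, "must be >= 0")
        check(0 <= self.dm_expression_concordance <= 1,
              "dm_expression_concordance", "must lie in [0, 1]")
        if 2 * self.n_planted_pairs > self.n_genes:
            raise CohortConfigError(
                "n_planted_pairs: 2*n_planted_pairs exceeds n_genes")
        reserved = (2 * self.n_planted_pairs + self.n_dm_genes
                    + self.n_amplified_genes + self.n_mutation_genes)
        if reserved > self.n_genes:
            raise CohortConfigError(
                f"n_genes: {reserved} planted genes requested but only "
                f"{self.n_genes} genes available")


@dataclass
class GroundTruth:
    """Planted entities of a synthetic cohort."""

    sample_risk_labels: dict[str, str]
    planted_pairs: list[dict]          # gene_a, gene_b, high_risk_reo
    planted_dm_genes: dict[str, dict]  # gene -> {direction, expression_direction}
    planted_amplified_genes: list[str]
    planted_mutated_genes: list[str]

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortBundle:
    """All layers of one synthetic cohort (samples in rows throughout)."""

    expression: pd.DataFrame          # samples x genes, log2-like scale
    clinical: pd.DataFrame            # per-sample survival + covariates
    methylation: pd.DataFrame         # samples x CpG loci, beta values
    locus_gene_map: pd.DataFrame      # locus_id, gene_id
    copy_number: pd.DataFrame         # samples x genes, values in {-2..2}
    mutation: pd.DataFrame            # samples x genes, values in {0,1}
    truth: GroundTruth
    config: CohortConfig = field(repr=False, default=None)


def _censoring_horizon(lams: np.ndarray, weights: np.ndarray,
                       censor_rate: float) -> float:
    """Solve for the uniform-censoring horizon achieving censor_rate.

    With C ~ U(0, T_max) and T ~ Exp(lam), P(C < T) integrates to
    (1 - exp(-lam*T_max)) / (lam*T_max); the mixture over groups is
    monotone decreasing in T_max, so a bracketed root always exists.
    """

    def pc(tmax):
        return float(np.sum(
            weights * (1 - np.exp(-lams * tmax)) / (lams * tmax)))

    lo, hi = 1e-9, 1.0
    while pc(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e12:
            break
    return brentq(lambda tm: pc(tm) - censor_rate, lo, hi)


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate one multi-omics cohort; byte-identical for identical config."""
    config.validate()
    c = config
    streams = np.random.SeedSequence(c.seed).spawn(6)
    rng_lab, rng_surv, rng_expr, rng_meth, rng_cna, rng_mut = (
        np.random.default_rng(s) for s in streams)

    samples = [f"S{i:04d}" for i in range(1, c.n_samples + 1)]
    genes = [f"G{i:04d}" for i in range(1, c.n_genes + 1)]

    # ---- latent risk groups -------------------------------------------------
    n_high = int(round(c.frac_high_risk * c.n_samples))
    n_high = min(max(n_high, 1), c.n_samples - 1)
    is_high = np.zeros(c.n_samples, dtype=bool)
    is_high[rng_lab.choice(c.n_samples, size=n_high, replace=False)] = True

    # ---- survival -----------------------------------------------------------
    lam_low = np.log(2.0) / c.baseline_median_dfs_months
    lam = np.where(is_high, lam_low * c.hazard_ratio, lam_low)
    t_dfs = rng_surv.exponential(1.0 / lam)
    # positive OS increment sized to hit the requested correlation of the
    # uncensored times: corr(T, T+Z) = sd(T) / sqrt(var(T) + var(Z))
    w = np.array([1 - n_high / c.n_samples, n_high / c.n_samples])
    mus = np.array([1 / lam_low, 1 / (lam_low * c.hazard_ratio)])
    var_t = float(np.sum(w * mus**2) + np.sum(w * mus**2)
                  - np.sum(w * mus) ** 2)  # E[1/lam^2]*w terms + mean spread
    rho = c.dfs_os_correlation
    if rho >= 1.0:
        t_os = t_dfs.copy()
        _ = rng_surv.exponential(1.0, size=c.n_samples)  # keep stream aligned
    else:
        sd_z = np.sqrt(var_t * (1.0 / rho**2 - 1.0))
        t_os = t_dfs + rng_surv.exponential(sd_z, size=c.n_samples)

    if c.censor_rate > 0:
        tmax = _censoring_horizon(np.array([lam_low, lam_low * c.hazard_ratio]),
                                  w, c.censor_rate)
        cens = rng_surv.uniform(0, tmax, size=c.n_samples)
    else:
        cens = np.full(c.n_samples, np.inf)
    dfs_time = np.minimum(t_dfs, cens)
    dfs_event = (t_dfs <= cens).astype(int)
    os_time = np.minimum(t_os, cens)
    os_event = (t_os <= cens).astype(int)

    # clinical covariates, mildly associated with risk for realism
    stage = np.where(rng_surv.uniform(size=c.n_samples)
                     < np.where(is_high, 0.55, 0.40), "II", "I")
    hbv = np.where(rng_surv.uniform(size=c.n_samples) < 0.7, 1, 0)
    cirrhosis = np.where(rng_surv.uniform(size=c.n_samples) < 0.85, 1, 0)
    afp = np.where(rng_surv.uniform(size=c.n_samples)
                   < np.where(is_high, 0.5, 0.35), "high", "low")

    clinical = pd.DataFrame({
        "sample_id": samples,
        "dfs_time": dfs_time, "dfs_event": dfs_event,
        "os_time": os_time, "os_event": os_event,
        "stage": stage, "hbv": hbv, "cirrhosis": cirrhosis,
        "afp_group": afp,
    }).set_index("sample_id")

    # ---- expression ---------------------------------------------------------
    # disjoint planted-gene blocks
    p2 = 2 * c.n_planted_pairs
    dm_lo, dm_hi = p2, p2 + c.n_dm_genes
    amp_lo, amp_hi = dm_hi, dm_hi + c.n_amplified_genes
    mut_lo, mut_hi = amp_hi, amp_hi + c.n_mutation_genes

    expr = rng_expr.normal(loc=8.0, scale=1.0,
                           size=(c.n_samples, c.n_genes))

    planted_pairs = []
    for k in range(c.n_planted_pairs):
        ia, ib = 2 * k, 2 * k + 1
        mid = 8.0 + rng_expr.normal(0.0, 1.0, size=c.n_samples)
        gap = np.abs(rng_expr.normal(_PAIR_GAP_MEAN, 0.3,
                                     size=c.n_samples)) + 0.2
        follows = rng_expr.uniform(size=c.n_samples) < c.reo_fidelity
        # high-risk REO: E_a > E_b; low-risk samples show the reverse
        a_gt_b = np.where(is_high, follows, ~follows)
        sgn = np.where(a_gt_b, 1.0, -1.0)
        expr[:, ia] = mid + sgn * gap / 2.0
        expr[:, ib] = mid - sgn * gap / 2.0
        planted_pairs.append({"gene_a": genes[ia], "gene_b": genes[ib],
                              "high_risk_reo": "a_gt_b"})

    # ---- methylation + DM expression shifts ---------------------------------
    n_dm = c.n_dm_genes
    dm_genes = genes[dm_lo:dm_hi]
    n_hyper = n_dm // 2
    n_conc = int(round(c.dm_expression_concordance * n_dm))
    concordant = np.zeros(n_dm, dtype=bool)
    if n_dm:
        concordant[rng_meth.choice(n_dm, size=n_conc, replace=False)] = True

    truth_dm: dict[str, dict] = {}
    loci_rows = []
    n_bg_loci = max(50, n_dm)
    n_loci = 2 * n_dm + n_bg_loci
    base_logit = rng_meth.normal(0.0, 1.0, size=n_loci)
    meth_logit = (base_logit[None, :]
                  + rng_meth.normal(0.0, 0.4, size=(c.n_samples, n_loci)))
    for j, gene in enumerate(dm_genes):
        direction = "hyper" if j < n_hyper else "hypo"
        shift = _DM_LOGIT_SHIFT if direction == "hyper" else -_DM_LOGIT_SHIFT
        for li in (2 * j, 2 * j + 1):
            meth_logit[is_high, li] += shift
            loci_rows.append((f"cg{li:05d}", gene))
        # expression response: concordant genes move opposite to promoter
        # methylation in the high-risk group, discordant genes move with it
        if direction == "hyper":
            edir = "down" if concordant[j] else "up"
        else:
            edir = "up" if concordant[j] else "down"
        expr[is_high, dm_lo + j] += _DM_EXPR_SHIFT if edir == "up" else -_DM_EXPR_SHIFT
        truth_dm[gene] = {"direction": direction,
                          "expression_direction": edir,
                          "concordant": bool(concordant[j])}
    # background loci map to genes outside every planted block
    free_genes = genes[mut_hi:] or genes
    for b in range(n_bg_loci):
        loci_rows.append((f"cg{2 * n_dm + b:05d}",
                          free_genes[b % len(free_genes)]))
    meth = 1.0 / (1.0 + np.exp(-meth_logit))
    loci_ids = [r[0] for r in loci_rows]
    # loci_rows order: DM loci first (2 per gene), then background; the
    # logit matrix was built in the same order
    methylation = pd.DataFrame(meth, index=samples, columns=loci_ids)
    locus_gene_map = pd.DataFrame(loci_rows, columns=["locus_id", "gene_id"])

    # ---- copy number --------------------------------------------------------
    cna = np.zeros((c.n_samples, c.n_genes), dtype=int)
    bg = rng_cna.uniform(size=(c.n_samples, c.n_genes))
    cna[bg < _BACKGROUND_CNA_RATE / 2] = 1
    cna[bg > 1 - _BACKGROUND_CNA_RATE / 2] = -1
    amp_genes = genes[amp_lo:amp_hi]
    for j in range(c.n_amplified_genes):
        rate = np.where(is_high, _AMP_RATE_HIGH, _AMP_RATE_LOW)
        gained = rng_cna.uniform(size=c.n_samples) < rate
        level = np.where(rng_cna.uniform(size=c.n_samples) < 0.3, 2, 1)
        col = amp_lo + j
        cna[:, col] = np.where(gained, level, 0)
        expr[is_high, col] += _AMP_EXPR_SHIFT
    copy_number = pd.DataFrame(cna, index=samples, columns=genes)

    # ---- mutation -----------------------------------------------------------
    mut = (rng_mut.uniform(size=(c.n_samples, c.n_genes))
           < _BACKGROUND_MUT_RATE).astype(int)
    mut_genes = genes[mut_lo:mut_hi]
    for j in range(c.n_mutation_genes):
        rate = np.where(is_high, _MUT_RATE_HIGH, _MUT_RATE_LOW)
        mut[:, mut_lo + j] = (rng_mut.uniform(size=c.n_samples)
                              < rate).astype(int)
    mutation = pd.DataFrame(mut, index=samples, columns=genes)

    expression = pd.DataFrame(expr, index=samples, columns=genes)
    truth = GroundTruth(
        sample_risk_labels={s: ("high" if h else "low")
                            for s, h in zip(samples, is_high)},
        planted_pairs=planted_pairs,
        planted_dm_genes=truth_dm,
        planted_amplified_genes=list(amp_genes),
        planted_mutated_genes=list(mut_genes),
    )
    return CohortBundle(expression=expression, clinical=clinical,
                        methylation=methylation,
                        locus_gene_map=locus_gene_map,
                        copy_number=copy_number, mutation=mutation,
                        truth=truth, config=c)
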