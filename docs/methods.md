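# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions a maintainer needs.

## Survival machinery

**Cox regression.** The gene and pair screens run many thousands of
single-covariate Cox fits, so the univariate path is an in-package
Newton–Raphson maximizer of the Breslow partial likelihood (covariates
are standardized internally for conditioning; step-halving guards the
ascent; the Wald p-value and 95% CI come from the observed information).
It agrees with R's `coxph(ties = "breslow")` to seven digits on tied
data and with lifelines on tie-free data. The multivariate path
(adjusting the signature for clinical covariates) delegates to
lifelines' `CoxPHFitter`, which uses Efron tie handling; the two
conventions coincide when event times are distinct, which holds almost
surely for the continuous times the generator draws. A per-SD
coefficient exceeding 15 during iteration is treated as a monotone
likelihood (complete separation) and raised as a convergence error: the
MLE does not exist and no finite value would be meaningful.

**C-index.** Harrell's concordance index with the comparability rule
"the strictly smaller time belongs to an event"; pairs tied on time are
not comparable, and pairs tied on risk score contribute 1/2. Ties count
half because the signature's vote counts take few distinct values, so
tie handling materially affects the selection path. The implementation
is vectorized all-pairs counting; the test suite checks it against a
literal pair-enumeration oracle on hundreds of random instances.

**Kaplan–Meier and log-rank** delegate to lifelines; Pearson correlation
with its Fisher-z 95% interval (used to justify substituting OS for DFS)
delegates to scipy.

## Signature discovery

The REO indicator is 1 when *E_a* > *E_b*, with ties mapped to 0: the
rule names only strict orderings, a deterministic convention is needed,
and ties have measure zero for continuous expression. Pairs are screened
unordered in lexicographic storage order and reoriented so the fitted
log-hazard of the high-risk ordering is positive; the pFDR family is the
set of all testable pairs (constant indicators are skipped and logged).

Storey q-values use the fixed-lambda pi0 estimator at λ = 0.5 with a +1
numerator guard; a fixed λ keeps the screen deterministic and testable,
at the cost of a slightly conservative pi0 when the signal fraction is
large.

Forward selection visits candidates in descending single-pair C-index —
the natural extension of seeding with the best pair — accepts only
strict ensemble improvements, and stops at the first rejection rather
than scanning ahead; both choices prevent unbounded growth on ties. The
ensemble risk score during selection is the integer high-risk vote
count, which is finer-grained than the binary majority label; the final
classifier still applies the ⌈m/2⌉ threshold. Classification reads one
sample row at a time by construction, which is what makes the
cross-platform claim testable: any strictly increasing per-sample
transform leaves every call unchanged, and the suite asserts exactly
zero changed calls on a 400-sample cohort under mixed affine, cubic and
rank transforms.

## Differential omics

* **t-test DEGs:** equal-variance Student's t (the classical two-sample
  form), BH FDR, direction from the group mean difference.
* **Rank Product:** for all high×low sample pairings, genes are ranked
  within each pairing by expression difference; the statistic is the
  geometric mean rank, run separately per direction, and the reported
  direction is the smaller rank product. Significance comes from
  redrawing the within-pairing ranks uniformly (gene exchangeability
  null), giving a per-gene expected-false-positive p and Breitling-style
  expected proportion of false predictions as the FDR column. The
  permutation count defaults to 1000 and is configurable; the cost is
  O(n_high × n_low × genes) per permutation, so multi-batch cohorts of a
  few dozen samples per group are the intended scale. Only within-
  pairing ranks enter, so any per-sample additive offset (batch shift)
  leaves the output bit-identical.
* **Methylation:** two-sided Wilcoxon rank-sum per promoter CpG locus
  (invariant to monotone transforms of beta values), BH FDR; direction
  from the median beta difference; constant loci get p = 1 by
  convention. Gene aggregation: hyper (hypo) iff ≥ 1 significant hyper
  (hypo) locus and none opposite; genes with both directions are
  excluded outright, so {hyper} ∩ {hypo} = ∅ by construction.
* **Copy number / mutation:** per-gene 2×2 Fisher exact tests
  (two-sided by the method of small p-values, which matches exhaustive
  hypergeometric enumeration — asserted in tests for margins ≤ 30).
  Gain collapses GISTIC-style calls {1, 2}, loss {−1, −2}. The mutation
  screen supports a raw p < 0.05 threshold alongside FDR, since sparse
  binary mutation matrices rarely survive FDR control at modest n.

## Concordance and enrichment

The concordance score s/k compares two directional lists; its null is
Binomial(k, p_e) with p_e = 0.5 (configurable): an unrelated shared gene
agrees in direction with probability one half. The upper tail is summed
in log space from log-gamma binomial coefficients, so results like
1.3 × 10⁻²¹ at (s = 242, k = 318) are exact rather than clamped at
double-epsilon display floors. Enrichment is the standard upper-tail
hypergeometric over-representation test over GMT gene sets with BH FDR;
the default background universe is the expression matrix's gene set,
configurable, since an inflated universe inflates significance.

## Driver network

A driver is a gene whose omic alteration is concordant with its
expression change in the high-risk group — hypermethylated+down,
hypomethylated+up, amplified+up — or any gene from the mutation screen
(mutation needs no direction). The network links drivers found in the
signed edge resource to significant DEGs with a direct edge to or from a
driver; edges deduplicate on (source, target, sign), and a gene pair may
carry both an activating and an inhibitory edge. Components are weak
(direction-ignoring), with size ties broken by the lexicographically
smallest member; hub degree is in+out ignoring sign, the only reading
under which a single "largest degree" ranking is well defined.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with defaults shaped like a single-institution early-stage resection
cohort: 170 samples, 40% latent high-risk, DFS hazard ratio 6, DFS–OS
correlation 0.78, REO fidelity 0.95, censoring fraction 0.4, baseline
median DFS 60 months.

* Event times are exponential (Weibull shape 1) with the high-risk
  hazard multiplied by the configured ratio — the simplest model
  consistent with proportional hazards. Censoring is uniform on
  [0, T_max] with T_max solved by root-finding so the expected censored
  fraction equals `censor_rate` exactly in expectation.
* OS = DFS + an independent exponential increment whose standard
  deviation solves corr(T, T+Z) = ρ using the analytic mixture variance
  of T; both endpoints share one censoring time, as in a single
  follow-up window.
* Planted pairs write a common midpoint and a positive gap (mean 1.2
  noise-SD units) with the group-specific ordering held with probability
  `reo_fidelity` per sample; all other genes are exchangeable Gaussian
  noise on a log2-like scale. Only orderings matter downstream, so the
  distributional family is immaterial.
* Methylation is logit-normal per locus (two loci per planted DM gene);
  DM genes shift by 1.0 logit in high-risk samples, and their expression
  moves opposite to promoter methylation for a `dm_expression_concordance`
  fraction, in the same direction for the rest — so the measured
  concordance of the emitted cohort tracks the configured value (the
  suite checks ±0.1 at 200 DM genes).
* Amplified genes gain copies in 60% of high-risk vs 15% of low-risk
  samples with a +1.2 expression shift in the high-risk group; planted
  mutation frequencies are 35% vs 5%; background alteration rates are
  5% (CNA) and 2% (mutation). These magnitudes make planted effects
  detectable at n ≈ 300–400 without being trivial at n ≈ 100.
* Each omics layer draws from its own child stream of the master seed
  (`SeedSequence.spawn`), so resizing one layer never perturbs another,
  and identical configs yield byte-identical bundles.
* Planted blocks (pair, DM, amplified, mutated genes) are disjoint, and
  validation requires their total not to exceed `n_genes`, keeping each
  planted signal independently recoverable.

What the generator does **not** emulate: probe-level measurement,
non-monotone batch distortions, correlated co-expression modules,
realistic genomic coordinates or region structure for CNAs, tumor
purity, or competing risks. Passing tests therefore demonstrate that the
algorithms recover the signals they assume, under the assumed sampling
model — not that the signature generalizes to any particular clinical
dataset.

## Problem sizes in the test suite

Recovery and robustness checks run at 400 samples × 150 genes with 5
planted pairs over 20 seeds; confidence-interval coverage uses 100
cohorts of 120 samples; null calibration uses 20 null cohorts of 150 ×
150. These sizes put Monte-Carlo noise well inside the asserted margins
while keeping the default suite in the low minutes on one core.

## Known limitations

* The pair screen's multiple-testing family counts each unordered pair
  once; testing both orientations separately would double the
  denominator and slightly change pFDR values.
* Storey's fixed-λ estimator can exceed BH in conservativeness for very
  small families (< ~50 tests).
* The Rank Product permutation null regenerates ranks rather than
  permuting sample labels, which assumes gene exchangeability within
  comparisons; heavy inter-gene correlation makes its FDR optimistic.
* `forward_select` is greedy with no look-back; it returns a local
  optimum of the ensemble C-index by design.
* Region-level copy-number summaries (cytoband frequencies) are reduced
  to gene-level tests by default; `aggregate_regions` collapses genes to
  regions under an any-gene-altered rule given a user-supplied
  gene→region map, but other aggregation rules (e.g. mean frequency
  across genes) are equally defensible and not provided.
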