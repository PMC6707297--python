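# Methods

`epitwas` implements epigenome-informed transcriptome imputation for
transcriptome-wide association studies (TWAS), together with the summary-
statistic association step and the downstream analyses that consume
gene-trait associations (GTAs): tissue-specificity enrichment,
connectivity-score drug repurposing, and trait causal networks.  Everything
is exercised on synthetic data generated by the package itself; this note
records the models, the defaults and why, and what the synthetic conditions
do and do not establish.

## The imputation model

For each gene, expression `y` over `n` individuals is modeled as a sparse
linear function of the dosages `X` of its cis-SNPs (±1 Mb around the TSS):

```
minimize over (b0, b):  (1/2n) ||y − b0 − X b||² + λ Σ_s v_s (α|b_s| + (1−α)/2 b_s²)
```

a weighted elastic net: each SNP carries a penalty factor `v_s ∈ (0, 1]`
that scales its share of the penalty.  `v_s = 1` for every SNP recovers the
plain elastic net (the uniform-penalty baseline used throughout as the
comparison arm).  Solved by cyclic coordinate descent on standardized
predictors — the update is the soft-threshold rule
`b_j ← S(ρ_j, λαv_j) / (1 + λ(1−α)v_j)` — with warm starts along a
100-point log-spaced λ path from `λ_max = max_j |x_jᵀy| / (nα v_j)` down by
a factor 10³.  The Gram-matrix path solver is numba-compiled because nested
cross-validation visits it tens of thousands of times per study.

* `α = 0.5` by default — the mixing value established for elastic-net TWAS
  predictors; configurable.
* λ is chosen by inner CV minimizing mean squared error; the performance
  metric `R²_CV` is the squared Pearson correlation between concatenated
  out-of-fold predictions and observed expression (5 outer × 5 inner folds),
  set to 0 when the correlation is non-positive or the prediction constant.
  `perf_p` is the one-sided correlation-test p-value, BH-adjusted across
  genes; models pass the pred.perf gate at q ≤ 0.01.
* Fold assignment depends only on the seed, so the prior-informed and
  uniform-penalty arms always share folds — method deltas are never fold
  noise.

## SNP priors

Penalty factors come from per-SNP priors estimated by an empirical-Bayes EM
on the stacked per-gene eQTL scan plus binary epigenomic annotations.  The
model assumes one latent causal SNP per gene, with prior
`softmax(γ·A_s)` over the cis-SNPs (`A_s` the annotation vector) and
single-SNP evidence summarized by the Wakefield approximate Bayes factor
`log ABF = ½ log(se²/(se²+W)) + W z²/(2(se²+W))` with effect-prior variance
`W = 0.1`.  The E-step is the within-gene posterior softmax; the M-step is
an exact conditional-logit maximization (BFGS with analytic gradient).  The
log marginal likelihood is asserted non-decreasing at every iteration.

Two deliberate simplifications relative to full hierarchical fine-mapping
approaches: a single causal SNP per gene (keeps the E-step closed-form and
matches standard fine-mapping practice), and no annotation tree structure.
The intercept of the annotation score cancels inside the per-gene softmax
(conditional-logit non-identifiability), so it is reported as 0.

Raw posteriors are min–max normalized to [0, 1] within each gene before the
penalty mapping: the mapping's domain is [0, 1], while raw posteriors scale
with cis-window size (a 200-SNP gene's largest posterior may be 0.05, a
2-SNP gene's 0.5).  A constant posterior vector maps to all-zeros, i.e. to
uniform penalties.

## Penalty rescaling

Priors map to penalty factors through a quadratic Bézier curve from
P0 = (0, 1) to P2 = (1, w_min) with one free control point P1 = (x1, y1),
subject to 0 ≤ x1 ≤ 1 and w_min ≤ y1 ≤ 1, which guarantees a monotone
bijection [0, 1] → [w_min, 1].  `x(t) = p` is solved in closed form (the
quadratic root), with a bisection solver kept as a numerical cross-check;
the two agree to < 1e-8 on a dense grid.  The control-point search is a
grid: w_min ∈ {0.1, …, 0.9} crossed with a lattice of (x1, y1) positions
inside the monotonicity region, scored by the mean cross-validated R²
improvement over uniform penalties on a set of tuning genes, ties broken
toward larger w_min (the weaker deviation from uniform penalties).  One
curve is selected per dataset, not per gene.  The synthetic studies use the
fixed default curve (w_min = 0.1, midpoint control point, i.e. the line
`v = 1 − 0.9 p`) so that measured improvements reflect the priors rather
than curve selection.

## Summary-statistic association

The gene-trait z-score from GWAS summary statistics, model weights `w_l`,
reference dosage SDs `σ_l` and reference LD `Σ` is

```
z_g = Σ_l w_l σ_l z_l / σ_g,   σ_g² = Σ_lm w_l w_m σ_l σ_m Σ_lm
```

with `σ_g` floored at 1e-8 and degenerate genes skipped.  Allele
harmonization: exact match keeps z, swapped effect/other alleles flips the
sign, any other mismatch drops the SNP; strand-ambiguous (A/T, C/G) SNPs
are kept by default with a drop flag available.  Genes with any model SNP
in the MHC region (chr6:25–35 Mb) are removed before BH adjustment, which
is computed per trait jointly over tissue × gene records (the pooled
reading; within-tissue adjustment is not exposed).  Novelty calls use
greedy LD clumping (index p ≤ 5e-8, clump p ≤ 5e-8, 250 kb window,
r² ≥ 0.1) with loci padded ±1 Mb; a gene is novel iff its body overlaps no
locus.  Cross-tissue direction labels are the majority z sign, with exact
ties labeled ambiguous.

## Downstream statistics

* **Enrichment**: one-sided Fisher (hypergeometric) tests against an
  explicit background (default: genes with a trained model), BH across
  sets, queries of ≤ 10 genes gated out.  Tissue specificity is the Pearson
  standardized residual `(n_ij − μ̂_ij)/√(μ̂_ij(1−p_i+)(1−p_+j))` with a
  χ² test of independence; trait columns whose expected count anywhere is
  ≤ 1 are dropped (iterating until stable).
* **Drug repurposing**: compound signatures are ranked gene lists; replicate
  lists merge by mean rank with lexicographic tie-breaks (a pragmatic
  reduction of the prototype-ranked-list merge).  The enrichment score is
  the signed KS running-sum extremum `a = max_j(j/t − p(j)/n)`,
  `b = max_j(p(j)/n − (j−1)/t)`, ES = a if a > b else −b; the connectivity
  score is `CS = (ES_up − ES_down)/2 ∈ [−1, 1]`, antisymmetric under
  up/down swap.  Significance: per-compound rank-shuffle permutations
  (each compound's list shuffled independently), two-tailed add-one
  estimator `(1 + #{|null| ≥ |CS|})/(n_perm + 1)`, BH across compounds.
  Queries take GTAs at FDR < 0.1, summarize multi-tissue genes by mean z,
  and require ≥ 5 genes per side.  Target–disease tests are two-sided
  Fisher against a 2802-gene drug-target background.
* **Trait networks**: GReX trait correlation is Spearman over shared genes
  gated at unadjusted p ≤ 0.05, Holm across pairs, ≥ 3 shared genes.
  Shared-gene edges require pred.perf q ≤ 0.005 and FDR ≤ 0.005, with the
  additional |z| ≥ mean |z| gate within same-category pairs.  Causal
  direction uses bi-directional OLS of one trait's gene z-scores on the
  other's over the predictor trait's significant genes (FDR ≤ 0.01), per
  tissue; both directions passing keeps the higher-degrees-of-freedom one;
  edge sign is the slope sign (negative = protective).  Genes significant
  in both traits are not excluded from the regressions (a flaggable
  choice).  Agonistic genes for pathway dissection are those moving
  concordantly (discordantly for protective edges) at p ≤ 0.05 in both
  traits.

## The synthetic data

The generator reproduces the structural features the pipeline assumes, and
its defaults are the study conditions:

* **Genotypes**: 500 samples (training), dosage = sum of two haplotypes;
  haplotypes use first-order uniform copying — each SNP's latent uniform is
  copied from the previous SNP with probability `ld_decay` (default 0.7) or
  redrawn — giving exact marginal MAF (drawn U(0.05, 0.5)) and adjacent
  correlation ≈ ld_decay.  30 cis-SNPs per gene.  This is a deliberate
  fidelity trade-off against haplotype-resampling simulators: no
  recombination maps, no population structure, no long-range LD.
* **Architecture**: 3 causal SNPs per gene with effects N(0, 0.05²); a
  binary annotation at base rate 0.2 whose odds are multiplied by 5 for
  causal SNPs.  The effect SD was calibrated once so the uniform-penalty
  R²_CV spans roughly 0.6 → 0.02 across the noise grid — the "generally
  low" prediction regime in which penalty information can matter; with
  strong effects both arms hit a ceiling and the comparison is vacuous.
* **Expression**: `y = Xβ + level·ε`, ε ~ N(0, 0.3²) i.i.d., with the noise
  level swept over 0.1–1.0 (the level multiplies the noise exactly as
  written, scaling its SD to 0.3·level).
* **GWAS z-scores**: MVN(0, Σ) under the null with Σ from the reference
  panel (non-PSD inputs repaired by eigenvalue clipping); gene-mediated
  alternatives shift the mean by `λ·Σ·w`.
* **Compound libraries**: independent rank permutations per compound, with
  optional planted mimic/reverser compounds at controllable strength.
* **Trait pairs**: a planted A→B mediation regime in which A's gene effects
  propagate into B at slope 0.3 while B carries its own independent strong
  genes; the propagated effects sit mostly below B's significance
  threshold, which is precisely the regime where bi-directional regression
  can identify the direction.  When propagation is strong enough that B's
  significant set is itself dominated by propagated genes, both regressions
  fire and only the degrees-of-freedom tie-break decides — a known
  limitation of the estimator, not of the implementation.

What passing tests on these data do **not** establish: performance under
realistic LD (haplotype blocks, MAF-LD coupling), under population
stratification or expression confounding (the scan assumes residualized
expression), for genes whose causal architecture is polygenic within the
window, or for annotation structures richer than independent binary
features.  The synthetic comparisons establish internal correctness and the
direction of the method effect under the stated conditions, not effect
sizes transferable to real cohorts.

## Numerical choices

Coordinate descent converges at max coefficient change < 1e-7 (2000 sweep
cap); zero-variance predictors are carried with zero coefficients; constant
expression yields an intercept-only model.  Monomorphic SNPs in the eQTL
scan are emitted with β = 0, p = 1 and a flag; a perfect fit's SE is
floored so p underflows toward 0 rather than degenerating.  EM stops when
the log marginal likelihood gains < 1e-6 (100-iteration cap) and warns on
non-convergence.  Permutation p-values use the add-one estimator and are
therefore valid (stochastically ≥ uniform) by construction.  All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; derived seeds stay below 2³¹.

## Problem sizes in the shipped studies

The test suite runs the method comparison at 200 genes × 500 samples ×
noise levels {0.1, 0.5, 1.0}, prior recovery over 100 seeded replicates
(60 genes × 120 samples each), TWAS calibration over 5000 null GWAS
replicates, and causal-direction recovery over 100 planted and 100
decoupled trait pairs.  The acceptance script reports the same quantities
from a 80-gene × 2-level comparison, 50 prior-recovery replicates and 2000
TWAS replicates — sizes chosen to keep a full from-scratch rerun short
while leaving every conclusion unchanged.
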