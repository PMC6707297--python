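# epitwas

Epigenome-informed transcriptome imputation and TWAS toolkit.

Transcriptome-wide association studies (TWAS) test genetically predicted
gene expression against traits: a sparse linear model of cis-SNP dosages is
trained on a reference transcriptome, and the resulting weights link GWAS
signal to genes.  Power is bounded by prediction accuracy, so `epitwas`
lets regulatory annotations inform the predictor: SNPs that look functional
get shrunk less.  The package is aimed at statistical geneticists who want
the full pipeline — training, association, and the downstream analyses that
consume gene-trait associations — with a synthetic-data generator that
exercises every stage without access to individual-level cohort data.

## The model

Per gene, expression is predicted by a **weighted elastic net** over the
dosages `X` of cis-SNPs (±1 Mb of the TSS):

    min_{b0, b}  (1/2n)‖y − b0 − Xb‖² + λ Σ_s v_s (α|b_s| + (1−α)/2 b_s²)

where the per-SNP **penalty factor** `v_s ∈ (0, 1]` is produced in three
steps:

1. **SNP priors** — an empirical-Bayes EM combines each gene's marginal
   eQTL scan (as Wakefield approximate Bayes factors) with binary
   epigenomic annotations under a one-causal-SNP-per-gene softmax model,
   learning annotation weights γ and per-SNP posterior causal
   probabilities π_s;
2. **Bézier rescaling** — π_s (min–max normalized within gene) maps to
   `v_s ∈ [w_min, 1]` through a monotone quadratic Bézier curve from
   (0, 1) to (1, w_min), selected by cross-validated improvement over
   uniform penalties;
3. **weighted elastic-net training** — coordinate descent with nested
   cross-validation; `v_s ≡ 1` recovers the plain elastic-net baseline, so
   the prior-informed and uniform modes are always directly comparable on
   shared folds.

Association from GWAS summary statistics uses the standard summary-level
statistic `z_g = Σ_l w_l σ_l z_l / σ_g` with an LD reference, followed by
MHC masking, per-trait BH-FDR, LD-clump novelty calls and cross-tissue
direction labels.  Downstream modules provide Fisher gene-set enrichment,
tissue-specificity standardized residuals, connectivity-score drug
repurposing (`CS = (ES_up − ES_down)/2` with permutation p-values), GReX
trait correlation and bi-directional regression causal networks.  See
`docs/methods.md` for the full specification of every statistic.

## Worked example

`examples/01_train_models.py` simulates 30 genes (500 samples, annotation
enrichment 5 for causal SNPs), estimates priors from the panel's own eQTL
scan, and trains both modes on shared folds:

```
annotation weight gamma = 1.70 (planted log-odds = 1.61), EM iterations = 18
mean delta R2_CV (prior-informed - uniform) = +0.0036
genes improved/worsened = 19/2, one-sided sign test p = 0.000111
```

The EM recovers the planted annotation log-odds (log 5 ≈ 1.61), and the
prior-informed penalties improve cross-validated prediction for 19 of 21
genes with a non-zero delta — a small mean shift, but a consistent one,
which is exactly what the one-sided sign test measures.  The other
examples cover summary-statistic association (`02`), the drug screen with
a planted signature reverser (`03`), and causal-direction recovery between
two traits (`04`); each prints its numbers with a note on how to read
them.

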