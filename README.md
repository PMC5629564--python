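# xbcount

Background-aware differential expression and differential polyadenylation
testing for RNA-seq.

Conventional differential-expression (DE) tools treat every read mapped to a
gene's exons as signal. A measurable fraction of those reads is background —
sequencing error and misalignment — and it is not uniform across genes.
`xbcount` models the observed exonic count of gene *i* as a convolution

```
X_i = S_i + B_i,    S_i ~ NB(r_i, p_i),    B_i ~ Poisson(λ_i)
```

so that X_i follows a Delaporte distribution with gamma-mixing parameters
(α_i, β_i) — r_i = α_i, p_i = 1/(β_i+1) — and background mean λ_i, measured
from reads in non-exonic regions near each gene. On top of this model the
package provides:

- per-gene parameter estimation: a moment-matching route with across-gene
  dispersion-trend sharing (default) and a joint BFGS maximum-likelihood
  route for larger designs;
- two DE tests between two groups, routed per gene by pooled count size: a
  moderated exact test that enumerates all splits of the pooled total under
  an equal-signal-mean null, and a fast beta-distribution approximation for
  large counts (`big_count`, default 900);
- differential alternative-polyadenylation (APA) testing from PRE/POST
  region counts: the length-normalized ratio
  m/M = (l_post·r_pre)/(l_pre·r_post) − 1, the "roar" ratio of ratios as
  effect size, pairwise Fisher exact tests combined by Fisher's method;
- a read summarizer for SAM/BAM over GTF/BED annotations with
  featureCounts-default semantics (ambiguous reads discarded, fragments
  counted once);
- a seeded synthetic-experiment generator and benchmark harness (ROC AUC,
  false-discovery curves, power, expression strata) with a built-in
  `naive-nb` baseline that ignores the background.

Audience: anyone analyzing bulk RNA-seq count data who wants DE calls that
account for context-specific background noise, or who needs a reproducible
count-level simulation bench for comparing DE methods.

## Worked example

Simulate a 2000-gene two-group experiment (10% of genes differentially
expressed at 1.5-fold, 3 samples per group) and test it:

```python
from xbcount.simulate import SimConfig, simulate_experiment, truth_frames
from xbcount.detest import run_de, filter_results
from xbcount.evaluate import roc_auc

cfg = SimConfig(n_genes=2000, M=40, seed=7)
truth = simulate_experiment(cfg, rep=0)
X, B, _ = truth_frames(truth)          # observed counts and measured background
res = run_de(X, B, truth.groups)       # moment estimation, exact/beta routing
print(res.head(6).round(4))
```

```
            mean_A    mean_B  log2FC    pval    padj   test
gene_id
gene_0    346.2149  240.8702 -0.5234  0.0000  0.0000   beta
gene_1   1059.0827  811.5797 -0.3840  0.0000  0.0000   beta
gene_2     66.7618   94.2308  0.4972  0.1736  0.4018  exact
gene_3    108.3274  157.1200  0.5365  0.1537  0.3677  exact
gene_4    377.8724  268.6574 -0.4921  0.0000  0.0000   beta
gene_5    363.0737  317.3369 -0.1942  0.7996  1.0000   beta
```

`mean_A`/`mean_B` are depth-normalized group means, `log2FC` their log2
ratio, and `test` says which route the gene took (pooled counts ≤ 900 →
exact enumeration, larger → beta approximation; the beta p-values are a
ranking statistic and run hot, see `docs/methods.md`). Filtering with the
standard thresholds and scoring against the known truth:

```python
sig = filter_results(res, fc_min=1.5, expr_quantile=0.5, padj_max=0.1)
print(len(sig))                                    # 179 genes called
print(roc_auc(res["pval"].to_numpy(), truth.de))   # 0.661
```

179 genes pass (|FC| ≥ 1.5, expression above the median, adjusted p < 0.1),
54 of them truly DE, and ranking all genes by p-value separates DE from
non-DE with AUC 0.661 under this (deliberately hard: dispersion ≈ 0.1–0.2,
n = 3) simulation regime.

The same pipeline runs from the shell:

```
xbcount count  --bam s1.bam --bam s2.bam --gtf genes.gtf \
               --background bg.bed --apa apa.bed --out-prefix counts
xbcount detest --counts counts.X.tsv --background counts.B.tsv \
               --groups A,A,A,B,B,B --big-count 900 --out de.tsv
xbcount apa    --apa-counts counts.apa.tsv --apa-bed apa.bed \
               --groups s1=T,s2=N --out apa.tsv
xbcount benchmark --nf 20 --reps 20 --seed 1 --out report.tsv
```

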