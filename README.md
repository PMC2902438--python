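# icemod

Co-expression module analysis for bulk transcriptomics: build a thresholded
gene co-expression network, extract **relatively independent maximal
cliques** as modules with the Iterative Clique Enumeration (ICE) algorithm,
screen the modules for monotone association with an ordered phenotype
(e.g. tumor grade), and characterize them by gene-set over-representation.

## Who this is for

Individual-gene expression signatures are notoriously irreproducible across
cohorts and hard to interpret. Module-based analysis treats tightly
co-expressed gene groups as the analysis unit instead. Clique-defined
modules guarantee that *every* pair of member genes is highly correlated —
the strongest co-expression requirement — but co-expression networks contain
billions of heavily overlapping maximal cliques, making full enumeration
useless. `icemod` is for analysts who want a small, manageable set of
clique-modules from an expression matrix, plus the downstream statistics
(trend test, FDR, enrichment, cross-cohort reproducibility) to use them as
biomarkers.

## The core algorithm

Given graph `G` and minimum core size `c_min` (default 10), ICE iterates on
residual graphs `G_i` (`G` minus all earlier modules' nodes):

1. `C_i` ← maximum clique of `G_i` (exact branch and bound with
   greedy-coloring bounds; deterministic lexicographic tie-break);
2. stop when `|C_i| < c_min`;
3. `C_i'` ← largest maximal clique of `G` containing `C_i`
   (= `C_i` ∪ maximum clique of the common-neighbor subgraph);
4. emit module `(C_i, C_i')`, remove `C_i'`'s nodes from the residual.

Cores are pairwise disjoint — each module contributes at least `c_min`
previously unseen genes — while expansion allows bounded overlap, the
property real biological modules show.

Downstream, a module's **overall expression** in a sample is the mean of
its genes' z-scores, tested for trend across `s` ordered categories with
the Jonckheere-Terpstra statistic
`W = Σ_{i<j} #(X_iα < X_jβ)` (ties ½), using
`E[W] = (N² − Σn_i²)/4` and
`Var[W] = [N²(2N+3) − Σn_i²(2n_i+3)]/72`,
Benjamini-Hochberg adjusted across modules. Enrichment of a module
(n genes, overlap k with a K-gene set among N reference genes) is the upper
hypergeometric tail `P(X ≥ k)` computed in log space, Bonferroni-adjusted.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

The built-in generator plants five 12-gene modules (within-module
correlation 0.9, mixed up/down trends across three ordered grades) among
2,000 background genes:

```python
import icemod as im
from icemod.network import _top_fraction_threshold

expr, pheno, truth = im.generate(im.SyntheticSpec(seed=7))
corr = im.pairwise_correlation(expr)
cand = im.threshold_candidates(corr)
net = im.build_network(corr, cand.top01pct_r)
result = im.ice_enumerate(net, c_min=10)
screened = im.screen_modules(expr, result.module_gene_sets(), pheno, fdr_cut=0.01)
```

which prints (via the obvious formatting):

```
threshold candidates: bonferroni=0.3410 top1%=0.1394 top0.1%=0.1867
network: 1712 nodes, 2120 edges, clustering coefficient 0.04
ICE: 5 modules, sizes [12, 12, 12, 12, 12]
module 0: z=+5.37 fdr=1.99e-07 significant=True
module 1: z=+3.88 fdr=1.05e-04 significant=True
module 2: z=+5.66 fdr=7.47e-08 significant=True
module 3: z=-4.75 fdr=3.45e-06 significant=True
module 4: z=-4.21 fdr=3.18e-05 significant=True
```

ICE recovers exactly the five planted cliques at the top-0.1% threshold;
the trend screen flags all five (three rising, two falling with grade) and
nothing else. Two scalar utilities used throughout module interpretation:

```python
>>> im.expected_overlap(19803, 144, 13)   # genes expected by chance in a
0.0945...                                 # 144-gene region, 13 drawn of 19,803
>>> im.reproducibility(19, 17).percentage # 17 of 19 modules validate
89.47
```

The same pipeline is available from the shell:

```bash
icemod synth --out-prefix fix_ --seed 7
icemod network --expr fix_expression.tsv --quantile 0.001 --out edges.tsv
icemod ice --network edges.tsv --cmin 10 --out modules.tsv
icemod trend --expr fix_expression.tsv --modules modules.tsv \
             --pheno fix_phenotype.tsv --order 1,2,3 --out trend.tsv
icemod enrich --modules modules.tsv --gmt sets.gmt --reference ref.txt --out enr.tsv
```

(`icemod preprocess` collapses probe-level matrices; `icemod simcurve`
computes the GO-similarity-vs-correlation curve that guides threshold
choice.)

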