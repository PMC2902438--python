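# Methods

## Overview

`icemod` identifies co-expression modules in bulk transcriptomic data as
*relatively independent maximal cliques* of a thresholded gene co-expression
network, screens the modules for monotone association with an ordered
phenotype such as tumor grade, and characterizes them by gene-set
over-representation. The pipeline is: preprocess → (semantic-similarity
guided) threshold selection → network → iterative clique enumeration (ICE)
→ trend screening → enrichment. A synthetic-data generator with planted
modules makes every stage testable without any external download.

## Preprocessing

Probe-level matrices are collapsed to one row per gene by the per-sample
median over the gene's probe sets, then each gene row is z-standardized,
`(x - mean) / sd`, with the sample standard deviation (divisor n-1). The
divisor is a convention choice only — Pearson correlation is invariant to
affine rescaling of rows, so the downstream network is unaffected.
Zero-variance rows are removed (correlation with a constant is undefined)
rather than zero-filled. Probes mapping to several genes contribute to each
of them; unmapped probes are dropped. The preprocessing contract requires a
complete matrix (standard array summarization output has no missing
values); missing-data imputation is out of scope.

## Threshold selection by functional similarity

For threshold guidance, the per-term information content is
`IC(t) = -ln(count(t)/count(root))`, where `count(t)` is the number of
annotated genes reaching `t` after propagating annotations to ancestors
along `is_a` edges (`part_of` optional, off by default; biological_process
namespace only). Resnik similarity of two terms is the IC of their most
informative common ancestor; gene-level similarity aggregates term pairs by
the maximum (best-match average available as an option — the maximum is the
most common Resnik gene-level convention and is monotone under added
annotations, which makes it property-testable). Natural log is used; the
curve is read for its shape, so the log base is immaterial.

Gene-pair correlations are binned into 0.1-wide, right-closed intervals on
[-1, 1] (lowest bin closed on both ends) and the mean similarity of
scorable pairs is reported per bin; pairs involving an unannotated gene are
excluded, not scored as zero. The intended reading: pick the threshold
where mean functional similarity rises sharply. Three candidates are
computed over the *signed* correlation distribution — the Bonferroni 0.01
correlation-significance point (from the t statistic of r with m-2 df) and
the top-1% / top-0.1% quantiles, with the top-k cut defined as the k-th
largest value, k = max(1, floor(fraction × n_pairs)). Final selection
remains a user decision; the CLI defaults to the top-0.1% candidate.
Thresholding is signed (`r >= t`, inclusive `>=`; strongly negative
correlations do not track functional similarity), with an `--absolute`
option off by default. Inclusive vs exclusive comparison is immaterial at
floating-point granularity. Nodes left without edges are excluded from the
network.

## ICE

Given graph `G` and minimum core size `c_min` (default 10):

1. Find the maximum clique `C_i` of the residual graph `G_i` (initially `G`).
2. If `|C_i| < c_min`, stop.
3. Expand `C_i` to the largest maximal clique `C_i'` of `G` containing it:
   `C_i'` = `C_i` plus a maximum clique of the subgraph induced on the
   common neighbors of all `C_i` nodes.
4. Emit `(C_i, C_i')`; remove the nodes of `C_i'` from the residual; repeat.

Cores are found in residual graphs and are therefore pairwise disjoint —
every module brings at least `c_min` previously unseen genes — while
expansion allows bounded overlap with earlier modules. Each iteration
removes at least `c_min` nodes, bounding the module count by `|V|/c_min`.
A module is emitted only when its *core* reaches `c_min`, making `c_min` a
uniform contract for every module including the first.

The maximum-clique search is exact: Tomita-style branch and bound with
greedy-coloring upper bounds. A heuristic mode is deliberately refused —
core exactness is part of the module definition. Ties between maximum
cliques are resolved to the lexicographically smallest sorted node-label
sequence (the clique number is established first, then members are chosen
greedily smallest-first, each choice validated by a bounded existence
search), so runs are bit-reproducible with no randomness anywhere.
Exhaustive maximal-clique enumeration of genome-scale networks is exactly
the problem ICE avoids; full enumeration (via networkx's Bron-Kerbosch)
appears only as a small-graph test oracle.

## Trend screening

Module overall expression is the per-sample mean of the module genes'
standardized values; genes absent from the matrix (e.g. a different
validation platform) are skipped and counted, and a module with no present
gene is untestable. The Jonckheere-Terpstra statistic is
`W = sum_{i<j} #(X_i < X_j)` over ordered category pairs, ties counted 1/2
(computed per pair via midranks). Normal approximation:
`E[W] = (N^2 - Σn_i^2)/4`, `Var[W] = [N^2(2N+3) - Σn_i^2(2n_i+3)]/72`,
two-sided p from `z = (W - E[W])/sqrt(Var[W])`. Two-sided because modules
may rise or fall with grade. The variance is the no-tie form: module
expression over continuous data is effectively tie-free, and an exact
permutation option (full enumeration, intended for N ≤ 12) is the fallback
for tiny samples; simulation shows the normal approximation's rejection
decisions at α = 0.05 agree with the exact test on ≳ 90% of random N = 9
instances, and its null type-I error is calibrated for balanced groups of
15. Samples with missing phenotype are dropped per test. P-values are
Benjamini-Hochberg adjusted across all modules tested in the run (the
family is the run), with significance called at FDR < 0.01 by default.
Cross-cohort reproducibility of a biomarker set is the percentage of
discovery-significant biomarkers that remain significant in an independent
cohort, reported to two decimals; validation is evaluated only on
discovery-significant biomarkers present on the validation platform.

## Enrichment

Over-representation of a module (n genes) against a gene set (K of N
reference genes) with overlap k uses the upper hypergeometric tail
`P(X >= k)`, inclusive of k — the standard over-representation convention.
The tail is summed in log space (log-gamma binomials + logsumexp) so that
p-values far below the underflow threshold of individual factors stay
accurate; the expected overlap is `nK/N`. The reference is all genes on the
platform after preprocessing. Bonferroni adjustment multiplies by the
number of sets actually tested for the module (those with nonzero overlap;
configurable to all sets), and B-adjp < 0.05 is the conventional call.
GO, transcription-factor-binding-motif, and positional (cytoband)
collections all enter as GMT files — one mechanism, three collections.
Motif sets are merged per transcription factor (union of targets) and
motifs with no known factor are dropped before testing.

## Synthetic data

Gene `g` of planted module `m` in sample `s` of ordered category `c`:

    x = sqrt(rho) * f_m(s) + sqrt(1 - rho) * eps_g(s) + delta_m * rank(c)

with shared factor `f_m ~ N(0,1)` and private noise `eps_g ~ N(0,
noise_sd^2)`; background genes are i.i.d. noise; the matrix is then
z-standardized. The latent-factor construction (rather than a covariance
Cholesky) scales to thousands of genes and makes the within-module
correlation analytically `rho` at `delta = 0`, `noise_sd = 1`. The trend
enters as a per-category shift of the shared signal, so module overall
expression inherits exactly the monotone pattern the JT test targets.

Defaults emulate a graded discovery cohort: five modules of 12 genes at
`rho = 0.9` over 2,000 background genes, grade sizes 31/113/136 (the usable
grade annotations of a ~350-specimen cohort). Trend deltas default to
mixed directions, +0.4 for three modules and -0.4 for two, mirroring real
grade-correlated programs that rise (proliferation, immune response) or
fall (adhesion) with grade. The magnitude is a design compromise with a
sharp constraint behind it: all trending modules share the single
deterministic rank vector, so two same-direction modules acquire baseline
cross-correlation `delta^2 var(rank) / (1 + delta^2 var(rank))` — about
0.10 at delta 0.5, close enough to the top-0.1% network threshold
(~0.19 under the default dimensions) that an incidental correlation
between two latent factors can fuse two planted cliques into one. At ±0.4
the induced cross-correlation (~0.07) stays clear of the threshold while
module expression still shifts ~0.4 SD per grade step (JT z ≈ 4.5 per
module). What the generator does *not* emulate: probe-level noise, batch
effects, platform differences, correlated background structure, or
non-monotone trends — so passing recovery tests demonstrates algorithmic
correctness under the stated model, not robustness to real microarray
artifacts.

## Numerical and degenerate-input choices

- Correlations are computed block-wise from unit-normalized rows; the
  contract is exactness (equal to a dense corrcoef to ~1e-12), block size
  only bounds memory.
- An all-tied JT input yields z = 0, p = 1; a single non-empty category is
  an error; var = 0 designs are errors.
- `hypergeom_tail` at k = 0 returns exactly 1; log-space sums are clipped
  at 0 before exponentiation.
- Empty similarity-curve bins report NaN means, not zeros.
- An empty graph has an empty maximum clique; a threshold above every
  correlation returns an empty network with a warning.
- Constant expression rows are dropped with a warning naming the genes.

## Problem sizes in the test suite

Tests run on deliberately small instances chosen to keep the full suite
fast while still exercising every contract: clique oracles on 18-node
random graphs (exhaustive Bron-Kerbosch is the reference), exact JT
permutation up to N = 9, hypergeometric enumeration up to C(12,5) draws,
and 20 seeds of the full pipeline at the default generator dimensions
(2,060 genes × 280 samples). Scaling the network stage to genome-scale
inputs is a matter of runtime, not of algorithm changes.

## Known limitations

- ICE is greedy: a maximum clique spanning two overlapping true modules is
  emitted as one module, and the leftovers may fall below `c_min`. This is
  inherent to the algorithm, not an implementation artifact.
- The normal JT approximation is anti-conservative for very small or very
  unbalanced designs; use the exact option there.
- The similarity curve's absolute level depends on the annotation corpus;
  only its shape should inform threshold choice.
- Bonferroni over "sets tested" is mildly anti-conservative relative to
  "all sets"; both are available.
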