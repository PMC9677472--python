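# Methods

## Overview

trsnmatch implements a pipeline with four computational stages: (1)
preprocessing of TF-binding regions, (2) two-group differential expression
with empirical-Bayes moderation, (3) binding/expression integration into
TF-centered, condition-specific regulatory sub-networks (TRSNs), and (4)
sparse matching of query profiles against a library of TRSNs. A fifth
module generates synthetic inputs with planted ground truth so every stage
is testable without external downloads.

## Binding-region preprocessing

BED input is 0-based half-open; all internal arithmetic keeps that
convention. Overlapping *and abutting* intervals are merged (the
bedtools-merge default at distance 0) — abutting regions carry no
information that would justify keeping a boundary, and the downstream
regulatory-potential sum is insensitive to the choice except through peak
midpoints. Chromosome ordering is natural (chr1 < chr2 < chr10); this is
presentational only and affects no score. Strand columns on peaks are
ignored: TF binding events are strandless. Pooling peak files across
experiments of one cell line is an explicit caller action (`pool_peaks`);
TF identity is never silently discarded.

## Differential expression

The model is the standard two-group comparison on log2-scale values:
log2FC = mean(treated) − mean(control), pooled within-group variance s²
on d = n_t + n_c − 2 degrees of freedom, requiring ≥ 2 replicates per
group. Variances are moderated by

  s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),

with (d₀, s₀²) estimated by method-of-moments on log s² under the scaled-F
model s² ~ s₀²·F(d, d₀): with z = log s², E[z] and Var[z] have closed
forms in digamma/trigamma functions, so d₀ solves ψ′(d₀/2) = Var̂[z] −
mean ψ′(d/2) (infinite when the observed spread of log-variances does not
exceed sampling noise) and s₀² follows from the mean. The moderated
t = log2FC / √(s̃²(1/n_t + 1/n_c)) is referred to t(d₀ + d). One test
cross-checks the whole pipeline — d₀, s₀², t, p, adjusted p — against
Bioconductor limma on a shared fixture; agreement is at machine precision
(~1e−15 observed during development, asserted at 1e−6/1e−9).

Edge cases: genes with zero variance and zero log2FC report t = 0, p = 1;
zero variance with nonzero log2FC raises rather than emitting ±inf. The
DEG filter is strict on both thresholds (|log2FC| > 0.5, adjusted
p < 0.01), so boundary values are excluded. BH adjustment delegates to
statsmodels and is verified against a brute-force step-up oracle.

## TRSN construction

Regulatory potential uses an exponential decay over peak midpoints within
100 kb of the TSS: rp = Σ exp(−(0.5 + 4Δ)), Δ = distance/window ∈ [0, 1].
A peak on the TSS contributes e^−0.5 ≈ 0.607, one at the window edge
e^−4.5 ≈ 0.011; rp is additive over peaks and strictly decreasing in
distance. Window (100 kb) and decay (4) are configurable.

Candidates for a direction are genes with rp > 0 passing the DEG filter
in that direction. Two rankings — rp descending, and DE significance
(adjusted p ascending, then |log2FC| descending) — are combined by rank
product (rp_rank/N)·(de_rank/N); smaller is better; all ties break
lexicographically by symbol so output is deterministic. The top 200 genes
per direction form the TRSN (cap configurable). A flag
(`prefilter_top_degs`) instead restricts to the 200 most significant DEGs
per direction *before* integration; the default caps the integrated
ranking, which uses the binding evidence to choose among more than 200
qualifying DEGs. The TF must itself be differentially expressed under the
condition, in either direction; the TF's own gene may appear as a target
if it qualifies. Annotations with several TSSs per symbol keep the most 5′
TSS by strand.

## Library assembly and matching

Up/down TRSNs sharing (condition, cell line, TF) — exactly one of each —
merge into a single column whose members are the (necessarily disjoint)
union; a gene in both halves is contradictory and raises. Rows are the
lexicographic union of member genes, columns sort by network id, so the
matrix and its MatrixMarket serialization are reproducible byte-for-byte
from the same inputs. Round-trip persistence (MTX + rows.tsv +
columns.tsv + meta.yaml) is lossless and version-checked.

Matching solves min ‖Ax − b‖², card(x) ≤ s (default s = 10), with adaptive
FoBa. The forward step computes, for every unselected column, the exact
RSS reduction of adding it with a full refit — implemented as the squared
projection of the residual onto the component of the column orthogonal to
the current support's span (QR-based), which equals the refit improvement.
After each forward step with gain δ, any selected column whose removal
costs less than backward_factor·δ (default 0.5, the classical
half-the-last-gain rule) is pruned, cheapest first. The search stops at
|support| = s or when the best forward gain falls below min_gain
(default 1e−8, a numerical floor). Final coefficients are the restricted
least-squares refit on the support. Ties on forward gain break toward the
lowest column index.

Columns are not standardized by default: the library stores raw log2FC
values and the reported score is coefficient-scale. A `standardize` option
unit-normalizes columns for the search and maps coefficients back.
Matching score = −x̂_j under the default convention, so a query moving with
a TRSN's own direction scores negative and a counter-directional query
positive; `raw` reports x̂_j unchanged. Queries are used as-is, with no DEG
filtering; query genes absent from the library are dropped and counted.

Numerical behavior worth knowing: with the 1e−8 floor the search will keep
adding columns that explain pure noise until s is reached — that is the
intended "up to s most correlated" semantics. When the goal is exact
recovery of a planted support, min_gain should sit above the noise floor
(gains on null columns are ~σ²·χ²₁); the recovery tests use this classical
adaptive stopping. On small signal-bearing instances (≤ 12 columns,
s ≤ 3) FoBa's final RSS agrees with exhaustive best-subset in ≥ 95% of
seeded trials; on pure-noise queries agreement is lower (~80% observed),
which is expected for any greedy method and immaterial to the ranking use
case.

## Synthetic data

Generators are pure functions of their parameters and a seed. Defaults
model a small two-group screen: 3 replicates per arm, planted |log2FC| =
1.5, Gaussian log2-scale noise SD 0.2, peaks of 300 bp jittered 5 kb
around target TSSs (clipped to the 100 kb window), background peaks ≥ 2×
window from every TSS so ground truth is unambiguous, TSSs ≥ 1 kb apart.
Library generation draws member log2FCs as ±(0.5 + Exp(1)) — the DEG
floor plus an exponential tail — with paired up/down TRSNs on shared keys
and disjoint member sets.

What the generators do *not* emulate: probe-level structure, batch
effects, count-level noise, realistic peak-width or inter-gene correlation
structure, genome-scale annotation density. Passing recovery tests
therefore demonstrate the machinery is correct and well-calibrated under
its own assumptions (Gaussian log2 noise, independent genes), not
performance on real compendium data.

## Problem sizes and determinism

The test and acceptance runs use catalogue-scale bookkeeping (9553 TRSNs,
57 pairs) with 10-member TRSNs — pairing arithmetic and column counts do
not depend on member-set size — and matching instances of a few hundred
genes by a few dozen columns, sizes at which the exhaustive best-subset
oracle is tractable. All randomness flows through numpy Generator seeds;
identical seeds give bit-identical outputs.

## Known limitations

- Two-group designs only; no covariates, array weights, or trend/robust
  moderation variants.
- No motif-level evidence, CTCF-boundary truncation, or
  activating/repressive function testing; target lists are the product.
- No match p-values or FDR; scores are fitted coefficients.
- The FoBa solver densifies A; it is sized for libraries up to ~10⁴
  columns on a workstation, not for much larger compendia.
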