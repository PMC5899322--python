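# Methods

## Study design and data model

The analysis targets a two-condition, three-stage developmental study of
intestinal epithelial cells: conventionally raised (CONV-R) versus germ-free
(GF) mice at week 1 (W1), week 4 (W4) and week 12–16 (W12_16), five
biological replicates per cell (30 samples). Two data modalities are paired
per sample: gene-level RNA-seq read counts and per-CpG RRBS methylation
calls (methylated reads X out of total reads N). Alignment and methylation
calling are upstream of this package; inputs are count tables, Bismark-style
coverage files, a BED6 gene annotation and an optional SNP blacklist.

## Differential expression

Size factors are median-of-ratios against the geometric-mean reference gene
profile, rescaled to geometric mean 1; when fewer than 10 genes are positive
in every sample the factors fall back to total-count ratios. The median of
ratios is taken in linear space, so the defining property — the per-sample
median of normalized/reference equals a sample-independent constant — holds
exactly even with an even number of reference genes.

Per gene and stage, the model is NB with Var(K) = μ + α μ². The gene-wise α
comes from the pooled within-group variance of normalised counts via
Var(K/s) = μ/s + α μ², clamped to ≥ 1e−8, then shrunk 50/50 toward a least-
squares trend α(μ) = a₀ + a₁/μ (coefficients clamped non-negative). This
moment-plus-trend scheme deliberately avoids iterative ML fitting; the
contract is recovery of planted truth, not numerical identity with any
particular GLM implementation. The Wald statistic is
M / SE(M) with M = log2((μ̂₁ + ε)/(μ̂₂ + ε)), ε = 1e−8, M clamped to ±30 for
genes expressed in only one condition, and SE from the delta method with a
half-count floor on zero group means so the statistic stays finite. P-values
are two-sided normal, BH-adjusted over all tested genes; all-zero genes
report M = 0, p = 1. The regulated rule is strict: padj < 0.05 and |M| > 1.

With five replicates the normal reference (rather than t) is mildly liberal,
but the shrunk dispersion compensates: across twenty 2000-gene null
simulations the mean BH-significant fraction is ~2 × 10⁻⁴ (the suite asserts
≤ 10⁻²).

## Differential methylation

The arcsine link t = arcsin(2(X + 0.5)/(N + 1) − 1) uses the +0.5/+1
continuity correction, making t finite and strictly monotone in X for all
0 ≤ X ≤ N. Under a beta-binomial with mean p and dispersion φ — the
parameterisation Var(X/N) = p(1 − p)(1 + (N − 1)φ)/N — the delta method
gives Var(t) ≈ (1 + (N − 1)φ)/N, independent of p; this is what makes a
non-iterative GLS scheme workable.

Per site and stage:

1. entries with N < 5 are removed, blacklist positions dropped entirely, and
   the site must retain ≥ 2 covered samples per condition (missingness is
   handled per site; samples are never discarded wholesale);
2. φ is estimated by method of moments: with unweighted group means and
   heteroscedastic errors, E[Σ residual²] = Σ_g (1 − 1/n_g) Σ_i Var(t_i),
   which is linear in φ and solved in closed form, clamped to [0, 0.99];
3. the group contrast is GLS-weighted with w = N/(1 + (N − 1)φ); the
   statistic (t̄₁ − t̄₂)/√(1/ΣW₁ + 1/ΣW₂) is referred to N(0, 1);
4. BH adjustment is applied within stage (the global-vs-per-stage choice is
   not externally fixed; per stage matches the per-stage contrast structure).

`delta` is reported on the proportion scale as the weighted difference of
group mean X/N. At the package's reference conditions (coverage ≈ 30, n = 5,
φ = 0.05) the per-site sampling noise of delta has sd ≈ 0.08; the estimator
is unbiased (|bias| < 0.01 in the 500-site recovery benchmark) but
individual site estimates scatter accordingly, so accuracy guarantees are
stated about the bias, not per-site error. With φ fixed at 0 and equal N the
GLS statistic reduces exactly to the two-sample z statistic with variance
1/N per observation (unit-tested to 1e−10).

Direction is the sign of delta (hyper/hypo, undirected at exactly 0).
Genomic location uses precedence promoter > exon > intron > intergenic with
a ±1 kb promoter window around the TSS (annotation-tool-style default; the
window is a parameter). Genes without exon detail count as single exons.

## Hierarchical integration

For each regulated gene, tested CpGs within |pos − TSS| ≤ 5000 (symmetric
and strand-independent; the bound is inclusive) are merged into regions
wherever consecutive positions are ≤ 200 bp apart (a gap of exactly 200
merges). Regions containing less than 20% CpGs with stage-level padj < 0.05
are excluded — exactly 20% is retained. The second level pools the raw
p-values of all CpGs in retained regions (each position once, even when two
genes' windows share it) and BH-adjusts within that reduced pool; a coupled
locus is emitted per (gene, retained region) containing at least one CpG
significant after this second correction. This is the stricter of the two
readings of "differentially methylated and expressed" (a retained region
alone does not suffice). Genes sharing a window may both claim a region;
loci are reported per (gene, region) pair.

Coupling is canonical iff sign(M) · sign(mean delta over all region CpGs)
< 0; a zero mean delta is reported non-canonical with a warning.

## Co-expression grouping

The network is built on the union of regulated genes over the three stages,
using Spearman correlation over all samples; edges require rho ≥ 0.8
(positive co-expression only; `signed=True` admits |rho| for users who want
anti-correlated modules). Zero-variance genes are excluded with a warning;
network nodes are genes with at least one edge.

Condition Z-profiles standardise each gene's six condition means across
themselves with sample SD (denominator n − 1 = 5). A consequence worth
stating: since Σz² = 5 for any non-degenerate profile, patterns demanding
two entries above +1 *and* four below −1 (or one above +1 and five below −1)
are mathematically unattainable from real condition means — this affects
groups 1, 3 and 5 of the published criteria, which can therefore only fire
on profiles that do not arise from this normalisation. The assignment
function is nevertheless a pure function of the z map — any profile can be
scored — and is validated against a hand-coded truth table of
synthetic profiles. Groups are evaluated in ascending order with first-match
wins; the printed criteria for groups 3 and 4 coincide, so the rule emits
group 3 and group 4 is reserved. Enrichment uses the upper-tail
hypergeometric distribution with BH correction, validated by exhaustive
enumeration on small universes.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the sequences: NB counts (gamma-Poisson) with lognormal baseline means and
library-size factors; beta-binomial methylation with a bimodal Beta(0.8,
0.8) baseline level per CpG; coverage N = 5 + Poisson(mean − 5) with an
independent dropout mask that redraws a fraction of entries uniformly on
{0..4} (0 = site unobserved in that sample), reproducing RRBS's missing-site
structure and exercising the coverage filter. Effects are planted per stage
on disjoint gene/CpG sets: DE genes get ±2 log2 fold change on the CONV-R
mean (5% of genes per stage), DM CpGs a ±0.3 methylation shift on a 0.2
baseline, and 2/15 of DE genes receive a coupled DMR — a run of 3–6 CpGs
with gaps ≤ 200 bp within 5 kb of the TSS, with methylation sign opposing
expression with probability 0.57 (the canonical fraction observed in such
data). At the default scale (2000 genes, 20 000 CpGs) this plants 40 coupled
loci, allocated 14/13/13 across stages by largest remainder. Each generator
draws from its own RNG stream (master seed + fixed offset), so extending one
generator never shifts another's draws; identical seeds give byte-identical
outputs.

What the generator does *not* emulate: developmental (stage-wise) expression
trends shared across genes, CpG-island structure beyond TSS-proximal
clustering, read-level artefacts, or batch effects. Consequently the
co-expression network on default synthetic data is sparse (planted effects
touch only 5 of 30 samples per gene, which caps attainable Spearman rho),
and passing tests demonstrate correctness of the statistics and plumbing on
data satisfying the model assumptions — not robustness to violations found
in real RRBS/RNA-seq data.

## Problem sizes and numerical choices

The bundled benchmarks use 2000 genes / 20 000 CpGs for the end-to-end run,
2000 sites × 20 replicates for null calibration and 500 sites for effect
recovery — sizes at which every statistical property stabilises while a full
run of the suite stays interactive. Ties in p are broken by gene id (DE) or
(chrom, pos) (DM) for reproducible top-k lists; all thresholds are strict
inequalities at the published values (alpha 0.05, fold change 2, coverage 5,
window 5000, gap 200, fraction 20%, rho 0.8, Z ±1). φ is clamped to
[0, 0.99]; dispersion floors are 1e−8.

## Known limitations

- The DE and DM tests use normal reference distributions; at n = 5 this is
  slightly liberal in the extreme tail, mitigated but not removed by
  dispersion shrinkage (quantified in the null-calibration benchmarks).
- The hierarchical procedure inherits order-dependence from its filter
  sequence: a region's fate depends on stage-level adjusted p-values, so
  adding sites elsewhere on the genome can change region retention.
- Group criteria 1, 3 and 5 are unattainable under the six-cell Z
  normalisation (see above); on real or default synthetic data most genes
  are unassigned.
- The generator's defaults are plausible rather than calibrated to any
  particular RRBS dataset; empirical coverage and dispersion distributions
  vary between protocols.
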