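# Methods

## Selection screen (EHH / iHH / iHS)

For a core SNP, carriers of one core allele are followed outward one marker
at a time; EHH at distance x is the probability that two randomly chosen
carrier haplotypes are identical over the interval core..x, computed as
Σ<sub>g</sub> C(n<sub>g</sub>,2) / C(n,2) over distinct haplotype strings.
Groups are refined incrementally (new group = old group × 2 + allele), which
makes every curve non-increasing by construction; this is asserted in tests.

iHH integrates EHH over physical distance with the trapezoid rule, summed
over both sides of the core, truncated at the first marker where EHH drops
below the cutoff (default 0.05); the final trapezoid into that marker is
included. A core whose EHH never reaches the cutoff before a chromosome end
is flagged edge-truncated; by default flagged scores are kept (the flag is
recorded and a `drop_edge_truncated` switch discards them). The
unstandardized score is ln(iHH_ancestral / iHH_derived) — positive when
ancestral haplotypes are longer — and is standardized to mean 0, SD 1
(sample SD, n−1) within 20 equal-width derived-allele-frequency bins. Bins
with fewer than 3 scores or zero spread are flagged unstandardizable and
excluded downstream with a logged count. Only |iHS| is consumed by the
screen (strictly greater than 1.5 by default), so the sign convention is
inert. In VCF-ingest mode "derived" means the ALT allele; no ancestral-state
inference is attempted, which is fine for the synthetic generator (where the
derived state is known) but a caveat on real data.

Variants lacking an iHS score are dropped before screening with a count;
score tables can be matched to summary statistics by identifier (default)
or by chrom:pos.

## Gene-based association

SNPs are assigned to every gene whose interval (optionally extended by a
flank, default 0 bp, configurable to e.g. 50 kb) contains them. The gene
statistic is the sum of 1-df chi-square quantiles of the SNP p-values; its
null distribution under local LD is simulated by drawing z ~ MVN(0, Σ) with
Σ the reference-panel dosage correlation matrix (pairwise-complete Pearson,
repaired to positive semidefinite by eigenvalue clipping at zero and
re-normalization to unit diagonal; monomorphic SNPs are dropped). The gene
p-value uses the add-one estimator (1 + #{T* ≥ T_obs}) / (1 + n_sims), which
cannot be zero — required because the module search consumes the probit
weight Φ⁻¹(1 − p) (p additionally clipped to [1e-16, 1 − 1e-16] to stay
finite). Simulation is staged adaptively (10³ → 10⁴ → 10⁶ replicates,
escalating while the estimate sits below 10× the stage resolution), so only
genuinely small p-values pay for large simulations. Single-SNP genes
short-circuit to p_gene = p_snp exactly. Genes with zero screened SNPs are
absent from the output rather than set to p = 1: an unscored gene is
ineligible as a module seed and invisible to module growth.

Validation: with Σ = I the Monte-Carlo p matches the chi-square_k closed
form; under an exchangeable-correlation null (r = 0.5, 5 SNPs) the
empirical type-I error at α = 0.05 over 2,000 genes is within ±0.01.

## Dense-module search

Each scored gene on the PPI network seeds a greedy search. Candidates are
the scored direct neighbors of the current module (a distance-d
neighborhood, d configurable, attaches farther candidates together with a
shortest connecting path of scored genes so modules stay connected); the
candidate maximizing Z_m = Σz/√k is added only if
Z_new > Z_current × (1 + r), with r = 0.1 by default. Ties break
deterministically (higher weight, then lexicographic id). Raw scores are
normalized as Z_N = (Z_m − mean Z*)/sd Z* against uniformly random k-subsets
of all scored genes — connectivity is deliberately not required in the null,
matching the convention of dense-module GWAS tools; the null moments depend
only on k, so they are computed once per module size from a per-k seeded
substream (this also makes results independent of input ordering). When
C(universe, k) ≤ 10,000 exhaustive enumeration replaces sampling. Modules
with identical gene sets are deduplicated; the top 10 by Z_N (ties: higher
Z_m, then seed id) are merged into the trait gene network.

Known limitation: the per-step ×(1 + r) acceptance demands geometric score
growth, so modules stall at k ≈ 6 when weights are comparable, and a
planted-module gene whose weight landed well below its siblings tends to be
confined to lower-ranked modules. In planted-module simulations (10 genes
with z ~ N(4, 1) in a 1,000-gene scale-free graph, within-module edge
probability 0.8) the top-10 union recovers ≥ 8 of 10 planted genes in
roughly 7–8 of 10 seeds; the misses are the low-weight draws. Smaller r
(e.g. 0.02) recovers more at the cost of larger, noisier modules; r is
exposed in the configuration.

## Long-distance genotypic-LD screen

Variants in the trait gene network are pruned greedily in order of
ascending GWAS p: a variant is kept unless its squared dosage correlation
with an already-kept same-chromosome variant is strictly above 0.8 (r² is
computed as the integer-exact ratio (nΣab − ΣaΣb)²/(da·db), so the boundary
comparison is free of rounding artifacts). Candidate pairs are unordered
pairs on different chromosomes, or the same chromosome ≥ 10 Mb apart
(variant positions, boundary inclusive), with min(p_a, p_b) < 0.05 (the
"nominal significance" filter; α configurable) and in different genes —
between-gene dependence is the target, and at realistic gene sizes a
within-gene pair cannot be long-range anyway.

Each pair is tested for independence of the joint (≤ 3×3) genotype table
with the log-likelihood-ratio statistic G = 2 Σ o ln(o/e) (expected counts
from the margins, zero-observed cells contribute nothing). The null comes
from permuting one locus's genotypes across samples; p uses the add-one
estimator over 10,000 permutations by default. For n ≤ 7 complete samples
the test enumerates all distinct label arrangements exactly (this also
serves as the oracle for the sampled path in tests). Pairs with a locus
monomorphic among complete cases are untestable and reported with p = 1 and
a flag. This permutation G-test addresses the same null hypothesis as a
Markov-chain exact genotypic-LD test; it is desk-scale and directly
verifiable against exact enumeration.

q-values follow the Storey procedure: π̂₀(λ) = #{p > λ}/(m(1 − λ)) on
λ = 0.05…0.95 (step 0.05), smoothed by a least-squares natural cubic
regression spline with 3 df (knots at the λ-grid quantiles), evaluated at
λ = 0.95 and capped into (0, 1]; q is the cumulative minimum from the
largest p of π̂₀·m·p_(i)/i. With fewer than 100 tests π̂₀ defaults to 1,
reducing exactly to Benjamini–Hochberg (cross-checked against statsmodels).
Pairs with q strictly below 0.05 are significant.

The adaptation gene set is the multigraph whose nodes are genes carrying a
significant-pair variant, with LD edges labeled by the analysis of origin
and PPI edges among those genes as interaction evidence; gene p-values are
node attributes.

## Enrichment

One-sided upper-tail hypergeometric tests P(X ≥ a), X ~ Hypergeom(N, K, n),
equivalent to one-sided Fisher exact on the 2×2 table. Terms are
intersected with the background first; only terms with ≥ 2 study genes are
tested (the overlap floor is configurable), and the Bonferroni multiplier is
the number of terms actually tested, not the full collection — the
hypotheses actually evaluated. The background defaults to the annotation
genes present in the GMT universe, configurable to all scored genes.

## Synthetic data

The generator produces the statistical structure each stage assumes, not a
demographic model:

- **Panel.** Haplotype alleles are i.i.d. Bernoulli(freq), freq ~ Uniform
  over the minor-allele-frequency range (default 0.05–0.5), 2n haplotypes
  paired into Hardy–Weinberg genotypes. Defaults: 200 samples, 5
  chromosomes × 400 evenly spaced variants over 50 Mb.
- **Sweeps.** A partial sweep at a core variant sets an exact fraction f
  (default 0.5) of haplotypes as derived-allele carriers; each carrier
  copies a founder template outward from the core until an
  Exponential(ρ = 10⁻⁶/bp) breakpoint per side, with per-site copy errors
  at μ = 0.01. This founder-copy approximation is not a coalescent
  simulation — no background LD, no allele-frequency spectrum realism — but
  it produces the long shared haplotypes (elevated EHH/iHS) the screen
  needs. The default bundle plants one sweep in each of 10 planted trait
  genes (2 per chromosome, at 25% and 75% of the chromosome).
- **Summary statistics.** SNPs in planted genes draw two-sided p from
  z ~ Normal(4, 1); all others draw p ~ Uniform(0, 1].
- **PPI.** Preferential attachment (3 edges per node → ~3,000 edges on
  1,000 genes, heavy-tailed degrees, connected), with the planted module
  over-wired as Erdős–Rényi(q_in = 0.8).
- **Epistasis.** For each planted pair, variant b's genotype copies variant
  a's with probability 1 − ε (default ε = 0.1), else a fresh Hardy–Weinberg
  draw at b's original frequency; haplotypes are rewritten consistently.
  Pairs closer than 10 Mb in cis are rejected — invisible to the screen.
  The default bundle plants three cross-chromosome pairs between sweep
  cores.
- **Terms.** One true term (the planted genes) among 50 random background
  terms of 10–50 genes.
- The iHS table in a bundle is computed from the swept panel *before*
  epistasis planting, mirroring the real design in which selection scores
  and the LD reference panel come from different datasets; planting then
  perturbs only the genotype panel.

All draws flow from one seeded NumPy generator, so bundles are
bit-reproducible; pipeline runs are likewise pure functions of (inputs,
config, seed), with per-stage and per-gene substreams derived
deterministically (CRC-based keys, not Python string hashing).

Because background variants are unlinked, the null |iHS| distribution is
cleaner than in real data and the r²-pruning stage removes almost nothing;
passing tests demonstrate the statistics and their calibration, not
robustness to realistic LD structure, population stratification, or
genotyping error.

## Problem sizes and numerical choices

The validation suite runs on one CPU: null calibration uses 2,000 simulated
genes and 10,000 null genotype pairs (n = 100, 2,000 permutations); the FDR
mixture uses 10 planted + 200 null pairs over 20 seeds (n = 200, 2,000
permutations); module-recovery simulations use 1,000-gene graphs over 10
seeds with 2,000-permutation normalization. The default pipeline
configuration uses the larger production values (adaptive gene test to 10⁶,
100,000-permutation module normalization, 10,000-permutation LD tests).
Degenerate inputs fail loudly: empty score universes, modules spanning the
whole universe, and constant-weight nulls raise errors rather than emitting
±∞; empty intermediate pipeline results (nothing screened, nothing
significant) propagate as empty outputs.
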