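# Methods

## Scope and data model

`ribolens` operates on gene-level count matrices (genes × samples,
non-negative integers) for five omics layers — mRNA, ribosome-protected
footprints (RPF), miRNA, lncRNA, circRNA — tied to a sample sheet mapping
samples to ordered condition groups with replicates. The default design
mirrors a diet/genotype intervention study: four groups
Nor < AD < AD_HFD < H_H with three biological replicates each, analysed as
the adjacent contrasts (Nor, AD), (AD, AD_HFD), (AD_HFD, H_H). Group order
is taken from the sample sheet's declared order, never lexically, because
trend profiling depends on it. Genomic intervals are 0-based half-open
internally; GTF I/O converts at the boundary.

## Normalization and differential expression

Size factors are median-of-ratios: factor_j = median over genes positive
in every sample of count_gj / geometric-mean_g. When no gene is positive
everywhere the code falls back to total-count scaling with a logged
warning. The estimator agrees with the DESeq2 reference implementation to
~1e-5 (cross-checked in the test suite against pydeseq2).

Testing is a per-gene NB Wald test on normalized counts, applied
identically to every layer:

* log₂FC = log₂(μ̂₂ + 0.5) − log₂(μ̂₁ + 0.5) with group means of
  normalized counts and a 0.5 prior count against zero-count infinities.
* Dispersion α is a pooled within-group method-of-moments estimate
  (Var = μ·mean(1/s_j) + αμ² solved for α), shrunk arithmetically with
  weight 0.5 toward a lowess trend of raw dispersion versus log mean,
  floored at 1e-4. Arithmetic rather than geometric averaging because the
  3-replicate MoM estimate is ≤ 0 for roughly a third of genes; flooring
  those before a geometric average would bias dispersions low and inflate
  type-I error.
* The Wald statistic log₂FC / se uses a delta-method se from the NB
  variance of each group mean, referred to a t distribution with
  df = 2·(n₁ + n₂ − 2): the residual df plus an equal prior df
  contributed by the 50% shrinkage toward the trend (moderated-statistic
  logic). With a plain normal reference the measured type-I error at
  3 + 3 replicates is ~0.075; with this reference it is 0.03–0.05.
* Genes with base mean < 1 (independent low-count filter) are reported
  with NA statistics and direction `ns`.
* Significance gates on raw *P* < 0.05 AND |log₂FC| ≥ 0.585 (a 1.5-fold
  change); BH-adjusted *q* over tested genes is reported alongside and can
  be made the gate (`gate_on_q`).

The 0.585 threshold is deliberately applied to the point estimate, not a
shrunken one; at 3 replicates and dispersion 0.1 the estimate's sampling
sd is ≈ 0.37 log₂ units, so fold-change estimates for planted
|log₂FC| = 2 genes land within ±0.5 of truth only ~80% of the time — an
irreducible property of the design, not of the estimator.

## Ribo-seq QC, translation efficiency, joint classification

QC summarises an RPF read-feature table: modal read length (expected
28 nt), length histogram, and region occupancy fractions over CDS, 5′UTR,
3′UTR and other (non-CDS/non-UTR) signal. Level correlation is the
Pearson r of log₂(mean normalized abundance + 1) between mRNA and RPF
across genes detected (base mean ≥ 1) in both layers, per group.

Translation efficiency is footprint abundance relative to mRNA abundance.
Differential TE between groups is the contrast of contrasts
Δ = log₂FC(RPF) − log₂FC(mRNA), with se_Δ² = se²_RPF + se²_mRNA and a
two-sided z-test; significance uses the same P/fold-change rule applied to
Δ. A delta test on two independent contrasts was chosen over an
interaction GLM for transparent, testable error propagation. Genes absent
or untested in either layer carry NA records. The quadrant classifier is a
pure function of the two direction calls, yielding nine disjoint
categories; "changed at both levels" is the sum of the four
both-significant ones. The opposite screen returns genes significant in
both the TE and mRNA tests with sign(Δ) ≠ sign(log₂FC_mRNA).

Detection limits: the variance of Δ is bounded below by four
dispersion terms (two layers × two groups), so at α = 0.1 and n = 3 even
an oracle test with known dispersion has power ≈ 0.81 for |Δ| = 1.5 at
infinite depth, and ~0.75 at realistic abundance spreads; the implemented
test measures ~0.7 recall of planted TE shifts. Claims of higher recall
under these conditions are not attainable by any estimator.

## Trend profiles

For k ordered conditions, all 3^(k−1) − 1 non-flat step-direction
templates are enumerated (8 for k = 3), with dense ids in base-3 order of
the (step+1) digits and human-readable shape tags ("down-up" is the
V-shaped "callback" template). Tool-specific profile numberings vary, so
outputs are keyed by shape, not by any tool's index. Each gene in the
universe — the union of significant genes over the adjacent contrasts —
is assigned to the template with maximal Pearson correlation of its
centered log₂ group-mean vector; ties break to the lowest id,
zero-variance genes stay unassigned. Significance of a profile's
membership count is by permutation: each gene's sample labels are permuted
independently (the expected-count construction of the STEM family; a
single shared relabeling would admit only ~1680 distinct partitions at
3 × 3 samples, flooring attainable p around 0.01), the universe is
re-assigned, and p = (1 + #{perm count ≥ observed}) / (B + 1) with
B = 1000 by default, BH-adjusted across profiles.

## Enrichment

ORA is the upper-tail hypergeometric test of a hit set against each gene
set after universe intersection and size bounds (5–500), BH across sets.
GSEA ranks genes by sign(log₂FC)·(−log₁₀ P) (configurable to log₂FC),
with a stable (metric, gene id) tie-break, and computes the weighted
running-sum enrichment score (weight 1 by default; 0 recovers the classic
KS statistic). The null permutes gene labels, not phenotypes — with three
replicates per group a phenotype permutation admits too few distinct
relabelings to estimate tail probabilities. NES = ES / mean |null ES| of
the same sign; nominal p and FDR come from the sign-matched null with the
add-one estimator.

## lncRNA pairing and ceRNA network

Cis pairing emits (lncRNA, coding gene) pairs on the same chromosome with
gap ≤ 100 kb (window configurable; overlap counts as distance 0,
strand-agnostic). Antisense pairing requires opposite strands and a
positive interval overlap. Both are implemented as a per-chromosome sorted
sweep and verified against a brute-force all-pairs scan. Hybridization
energies are out of scope; a pass-through column accepts externally
computed values.

The ceRNA stage consumes a miRNA→target annotation (prediction is an
input, not computed here). Filters, in order: (1) retain miRNA–target
pairs with Spearman ρ ≤ −0.5 on normalized abundances over the contrast's
matched samples — the printed description of this filter in the source
study ("≤ 0.5") would admit uncorrelated pairs, so the repression-signed
reading is the default, configurable; (2) for every unordered pair of
differential non-miRNA RNAs sharing ≥ 1 retained miRNA, the shared count
s is tested against Hypergeom(M, m_a, m_b) with M = distinct miRNAs in
the retained table, p = P(X ≥ s), gated at p < 0.05 (raw, with BH
reported — whether the original analysis adjusted is unstated);
(3) pair co-expression Pearson r > 0.7 on log₂ normalized abundances over
the same samples. Passing pairs form a graph with nodes typed by layer
and shared miRNAs on edges, exported as GraphML plus edge and bipartite
TSVs.

## Synthetic data generator

The simulator is the package's test bed and defines its study conditions;
per-layer gene counts (2000 mRNA/RPF, 300 lncRNA, 300 circRNA, 150
miRNA), library sizes (1e6 coding layers, 2e5 small layers), NB dispersion
0.1 (gene-shared), and 3 replicates × 4 ordered groups are defaults.

* Baseline relative abundances are log-normal (sd 2.0 log₂ units). RPF
  baselines are the mRNA baselines times a per-gene TE jitter of sd 2.3
  log₂, chosen so the gene-level mRNA–footprint correlation lands near
  the moderate values typical of tissue data (measured ≈ 0.62–0.64 per
  group at defaults).
* Library sizes are jittered uniformly in [0.7, 1.3]× so size-factor
  recovery is non-trivial.
* DE planting: 100 mRNA genes per adjacent contrast (small layers scaled
  by gene count) at |log₂FC| = 2 with alternating signs; effects apply
  from the contrast's second group onward and persist, so each contrast's
  planting stays out of the other contrasts' null.
* TE planting: 50 genes per contrast at |Δlog₂TE| = 1.5 — half pure
  (mRNA flat, RPF shifted), half buffered (mRNA shifted ∓2 with TE
  opposing it).
* Trend planting: 30 genes each on the V ("down-up") and mirrored
  ("up-down") templates over the first three groups, step size 1.5 log₂.
* ceRNA triplets: 20 triplets (miRNA; two target RNAs cycling over
  mRNA/lncRNA/circRNA pairings). Targets are planted up and the miRNA
  down on the middle contrast, plus a shared per-sample latent factor
  (sd 0.5 log₂, sign-flipped for the miRNA) adding within-group
  co-variation; members are drawn from genes with baseline expected
  count ≥ 50, where this correlation structure is expressible above
  Poisson noise. The target table adds 400 random decoy edges.
* RPF reads: lengths from a discretized Gaussian (mode 28 nt, sd 1.5,
  range 20–40); regions multinomial with CDS 0.88, each UTR 0.025, other
  0.07 (UTR fractions stay below 3%, matching published footprint
  occupancy profiles).
* Annotation: coding genes tiled on chr1; lncRNAs rotate through cis
  (50 kb downstream), antisense (opposite-strand overlap) and distal
  (chr2) placements; gene sets include one set ≥ 50% planted DE genes.

What the generator does *not* emulate: genomic sequence, codon-level
ribosome occupancy, batch effects, correlated gene-gene backgrounds
beyond the planted triplets, GC/length biases, or isoform structure.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated noise model, not performance on
real libraries.

## Reproducibility and numerics

All randomized procedures derive per-stage sub-seeds deterministically
(crc32-based) from one integer seed; identical config + seed reproduces
every output byte-for-byte (asserted in the suite by hashing two full
pipeline runs). Result TSVs carry a `#` comment header with the config.
Degenerate inputs have defined behavior: all-zero genes are `ns` with NA
statistics, zero-variance genes are unassigned in trend profiling,
empty ceRNA candidate sets yield an empty network with a warning, and an
empty miRNA target table is a configuration error for the ceRNA stage.

## Benchmark sizes

The recovery benchmarks run at the full default conditions: type-I error
over three null simulations of 2000 genes; DE power over the three
contrasts of one simulation; TE recall over two simulations × three
contrasts; ceRNA recall over ten simulations; the trend permutation test
at B = 1000. These sizes keep the whole benchmark under a minute while
holding Monte-Carlo error on each reported rate below ~0.03.
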