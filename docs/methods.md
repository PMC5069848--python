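# Methods

## The scientific question and the pipeline's shape

Given diploid multilocus genotypes, per-individual metadata (ecotype,
geographic zone, capture depth) and a trait table, the pipeline asks two
linked questions: (1) which grouping factor organizes the neutral genetic
variance (hierarchical AMOVA, ranked by Fct); (2) whether quantitative
trait divergence among the depth-defined groups exceeds the neutral
expectation set by Fst (Pst–Fst). The stages run in the order diversity →
AMOVA ranking → differentiation → Mantel/PCoA → phenotype → Pst–Fst, and
the grouping factor chosen downstream is the top-ranked significant AMOVA
source (falling back to depth stratum when the top source is a factor
crossing, which cannot serve as a single grouping axis).

## Estimators and numerical choices

**Weir–Cockerham θ.** Per locus and allele, the among-group (a),
between-individual (b) and within-individual (c) variance components are
accumulated; θ = Σa / Σ(a+b+c) over alleles and loci. Negative estimates
are reported as computed: the weak-differentiation regime this pipeline
targets (pairwise values of order 0.002–0.012) would be systematically
biased by truncation at zero. Groups with no typed individuals at a locus
drop out of that locus's component sums. Permutation P-values for
pairwise θ shuffle whole individuals between the two groups; all
permutation P-values use the (hits + 1)/(B + 1) convention and are
therefore bounded below by 1/(B + 1).

**Fis.** Within a single group the same variance-component algebra
reduces to small f = 1 − Σc/Σ(b+c). The permutation null shuffles allele
copies among individuals within the group (a Hardy–Weinberg null within
groups, matching the classical FSTAT behaviour); permuting whole
genotypes would test random mating among groups instead, a different
hypothesis. The test is two-sided on |f|.

**Jost's Dest.** Per locus, Hs and Ht use the small-sample estimators
with the harmonic-mean sample size (Hs_est = 2ñ/(2ñ−1)·Hs, Ht_est = Ht +
Hs_est/(2ñr)); Dest = (Ht_est − Hs_est)/(1 − Hs_est) · r/(r−1). Loci are
combined by the variance-adjusted (delta-method) harmonic mean
1/(1/μ + σ²/μ³), falling back to the arithmetic mean when μ ≤ 0, where
the harmonic form is undefined. Significance uses a bootstrap null that
resamples each group's genotypes from the pooled-pair allele distribution
under Hardy–Weinberg — a deliberate semantic match to the DEMEtics-style
test rather than a label permutation.

**AMOVA.** The inter-individual distance is the allele-count
(number-of-different-alleles) metric, computed as squared Euclidean
distance on per-locus allele-copy vectors scaled by 1/√2; missing calls
are mean-imputed per locus so the sum-of-squares identity (SS_total =
SS_among + SS_within, verified on every run in tests) holds exactly.
Variance components follow the standard unbalanced one-level design
(n₀-weighted); Fct = σ²_a/(σ²_a + σ²_w); the permutation test permutes
whole individuals across groups. Factor crossings join the two labels;
empty cells never materialize as groups, so the crossing's degrees of
freedom are (#non-empty cells − 1) automatically.

**Rarefaction.** Ar(g) and PAr(g) use exact hypergeometric expectations
(the probability an allele is missed by a g-gene subsample is a single
hypergeometric point mass), not Monte-Carlo subsampling — deterministic,
fast, and exactly the published closed forms. PAr multiplies the focal
group's detection probability by every other group's miss probability at
the same g. Note that PAr(g) > 0 is possible even for alleles shared at
full sample size (another group's subsample can miss a shared allele);
PAr is zero for shared-only groups only at g = full sample.

**Mantel.** r_m is the Pearson correlation over upper-triangle entries;
the null permutes rows and columns of one matrix simultaneously. For ≤ 6
points the full n! set is enumerated and P is exact — with six depth
categories this makes the isolation-by-depth test deterministic. The
genetic matrix default is linearized θ/(1−θ) among depth-category groups
and the environmental matrix is |depth difference| in metres; both are
arguments, since neither metric is canonical. At least four points are
required. An optional neighbor-mean interpolation switch
(`interpolate_index`) lets the analyst replace one named putative-outlier
point's genetic distances with the mean over the remaining points before
testing; it is off by default because no objective outlier criterion is
imposed — the analyst names the point, and raw and interpolated results
should be reported side by side.

**PCoA.** Gower double-centering of the squared genotypic distance
matrix, symmetric eigendecomposition, coordinates on positive-eigenvalue
axes. Negative eigenvalues are retained in the result for inspection and
excluded from the explained-variance denominator. An all-zero distance
matrix is flagged degenerate rather than raising.

**Size adjustment.** log10(trait) is regressed on log10(SL) — allometry
is multiplicative, so the log-log dialect is the default, with raw-SL
regression available (`log_sl=False`) since the regressor's scale is a
genuine dialect choice; the choice is recorded in the run manifest.
Residuals are internally studentized (the common statistics-package
default labelled "studentized"), with external studentization switchable.
A perfect-fit guard returns exact zeros when the residual sum of squares
is at floating-point dust level, where 0/0 studentization would amplify
noise. Life-history traits (Lmax, ω, K, L0, t0) and shape PC scores
bypass size adjustment: they are not length measurements of a body part.

**Pst.** σ²B and σ²W come from method-of-moments one-way random-effects
components (negative σ²B truncated to zero — the estimate, not the
statistic, is variance-like); Pst = σ²B/(σ²B + 2h²σ²W) with h² a global
default of 1.0, overridable. h² = 1 makes the classification conservative
(prone to missing selection, not to inventing it). The bootstrap unit is
the individual within its group, preserving group sizes; percentile
intervals, 1000 replicates by default.

**R-matrix.** Traits are standardized by pooled within-group SD; group
means are centred on the sample-size-weighted grand mean; the
codivergence matrix is scaled by 1/(1 − Σw²) so that, in the balanced
one-trait case, its weighted diagonal mean is exactly σ̂²B/σ̂²W. The
diagonal bias correction subtracts each group mean's exact sampling
variance under weighted centring, ((1−wᵢ)²/nᵢ + Σ_{j≠i} wⱼ²/nⱼ)/(1−Σw²)
— simulation shows the corrected global estimate has smaller bias at
n = 30/group, and with the correction the R-matrix global Pst equals the
variance-component Pst exactly in the one-trait equal-n h²=1 case (an
internal cross-validation enforced in tests). After scaling by 1/(2h²)
the matrix is renormalized by 1/(1+g), g = Σwᵢrᵢᵢ, so the reported
diagonal's weighted mean equals global Pst = g/(1+g). D²ᵢⱼ = rᵢᵢ + rⱼⱼ −
2rᵢⱼ, clipped at zero against correction-induced small negatives, with
bootstrap SEs. Exact numerical parity with legacy R-matrix software is
not claimed; the scaling and correction here are fixed by the algebra
above and by neutral-simulation checks.

**Multiple testing.** SGoF declares the binomial excess of sub-alpha
results (sequentially testing the observed count of p ≤ α against
Bin(n, α) at level α), assigning discoveries to the smallest p-values;
Bonferroni is p ≤ α/n. Fisher's LSD P-values are left unadjusted by
design — that is what LSD is — and the post-hoc table is produced only
when the omnibus F-test rejects.

## The synthetic generator: what it emulates and what it does not

Genotypes follow the Balding–Nichols construction (group frequencies ~
Dirichlet(p(1−F)/F) around flat-Dirichlet ancestral frequencies), which
matches an island-model Fst target analytically; a stepping-stone variant
chains the draws along the depth order so divergence grows with depth
separation (the regime the Mantel stage detects). target_fst = 0 uses a
single shared frequency vector. One RNG stream is split per locus, so
changing the locus count leaves earlier loci untouched. Defaults emulate
the study system: 18 loci with 3–20 alleles (mean 11.5), three strata of
83/217/71 genotyped fish at depths 40/75/120 m, six net-depth categories
(40, 50, 80, 90, 100, >120 m), ecotype labels drawn independently of
genotype at the observed relative abundances.

Traits are a·SL^b·exp(δ_g + e) on a lognormal SL (additive on the natural
scale for PC scores and buoyancy); group shifts are normalized so their
sample variance equals σ²B *exactly*, making simulated truth the stated
truth rather than a draw around it — without this, three-group datasets
would carry a 2-df chi-square wobble in realized Pst and coverage tests
would test the wrong thing. Buoyancy is realized through the
in-air/in-water weight pair so the buoyancy formula inverts exactly, and
ω = Lmax × K holds identically. The generator makes no claim of
mutational realism (no stepwise-mutation or infinite-allele dynamics, no
linkage, no coalescent genealogies), models no null alleles or scoring
error beyond uniform missingness, and draws traits with Gaussian
residuals only — so passing tests demonstrate estimator correctness and
calibration under the stated model, not robustness to those real-data
complications.

## Problem sizes and defaults

Permutation defaults follow classical practice (10,000 for AMOVA/Fst/Fis,
9,999 for Mantel, 10,000 bootstrap resamples for Dest); the orchestrated
`run_all` and the acceptance script use 499–999 permutations and 300–1000
bootstrap replicates, which give P-value granularity of ~0.002–0.001 —
ample for effects at the 0.01–0.05 significance scale this design
produces. Calibration tests use 199 permutations per replicate so that
the rejection rule P ≤ 0.05 is exactly attainable (10/200). Rarefaction
in `run_all` standardizes to 80% of the smallest group's gene count by
default, leaving headroom for missing calls; the gene count is always an
explicit argument.

## Known limitations

- AMOVA is one-level (factor or factor-crossing vs within); fully nested
  three-level designs are not implemented.
- Dest's harmonic-mean combination is undefined at μ ≤ 0 and falls back
  to the arithmetic mean; near-zero differentiation therefore reports a
  near-zero (possibly negative) D rather than a harmonic mean.
- The Fis permutation loop is exact but not vectorized across loci; very
  large panels with 10⁴ permutations take minutes, not seconds.
- classification of selection depends on bootstrap CI coverage; with
  three groups the between-group variance has few degrees of freedom and
  the CI reflects within-group resampling only (group effects are treated
  as fixed).
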