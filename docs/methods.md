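# Methods

## The estimation problem

Each diploid individual carries a genotype vector g ∈ {0, 1, 2, missing}ᴹ
(alternate-allele dosages). Given a reference matrix P ∈ [0, 1]^{M×K} of
allele frequencies for K source breeds at M panel sites, supervised
global admixture seeks the proportion vector q on the probability
simplex (qₖ ≥ 0, Σqₖ = 1) that best explains the individual's allele
frequencies under the linear mixing model F̂ = PQ:

  q̂ = argmin_{q ∈ Δ} Σ_{m called} ( gₘ/2 − Σₖ pₘₖ qₖ )².

For fixed P this is an independent convex quadratic program per sample.
An alternating-least-squares admixture solver run with P held fixed has
the same optimum; solving the per-sample problem directly makes the
result deterministic and certifiable. The solver here runs accelerated
projected gradient (FISTA with exact Euclidean projection onto the
simplex, step 1/L with L the largest eigenvalue of 2PᵀP), then polishes
on the detected support by solving the equality-constrained KKT system,
and certifies optimality: the gradient must be constant on the support
and no smaller off it, within 1e-6 (solver tolerance 1e-8). Residual
norm, number of called sites used, and the certificate are reported per
sample.

Numerical choices: genotypes are converted to observed frequencies
x = g/2; P is clipped to [1e-6, 1 − 1e-6] so exactly-fixed reference
columns cannot produce degenerate objectives; missing sites are dropped
from the sum (the simplest defensible treatment of missingness in
supervised mode); residuals are unweighted — no binomial variance
weighting — as the plainest reading of the least-squares model.

## Marker selection

Differentiation is measured per site with the Weir–Cockerham (1984)
variance components for r populations of unequal size: a (among
populations), b (among individuals within populations), c (within
individuals), θ̂ = a/(a+b+c). Missing genotypes leave their population's
counts; populations with zero calls drop out of a site's r; sites with
fewer than two populated clusters, an average sample size ≤ 1, or a
non-positive component sum are flagged undefined. Negative estimates are
reported unclamped (they never survive a positive selection threshold).

Two cluster schemes feed panel selection:

* **one-vs-rest** — the target breed against all other breeds pooled;
  the top-K sites per breed are taken, ties at the boundary broken by
  genomic order (the tie rule is a package convention; any deterministic
  rule works);
* **global** — all breeds as separate clusters; every site with
  θ̂ > 0.350 is added.

The union is deduplicated with per-site provenance recording which rules
selected it. Defaults are top-K = 10,000 and threshold 0.350, the
values used at full cohort scale; the scaled experiments in `analysis/`
use top-K = 500 against a 20,000-site genome, preserving the ratio of
panel to genome.

Stratified frequencies are **alt-allele oriented** for every breed at
every site. The mixing model requires a single orientation per site
across breeds, so per-breed minor-allele orientation is not an option;
the orientation is recorded on the panel object. A breed with zero calls
at a panel site receives the pooled-cohort frequency (logged), with a
drop-the-hole alternative available.

Query-side harmonization, when a query lacks panel sites, follows the
merge recipe: intersect the query's genotyped sites with the reference,
re-derive the global high-FST sites on the shared set, and concatenate
with the surviving breed-specific sites.

## Reference filters

MAF and genotyping-rate filtering precede selection: sites with minor
allele frequency < 0.01 or call rate < 20% are removed. The
genotyping-rate wording is read literally as a minimum call rate of
0.20; the alternative reading (at most 20% missingness, i.e. call rate
≥ 0.80) is one parameter away. LD pruning is greedy and windowed: a
pair is eligible only if within **both** 50 variants and 250 kb (the
conservative intersection of the two window conventions), and while any
eligible pair exceeds r² = 0.8 the lower-MAF member is removed (tie:
later position), the window advancing one site at a time. Dosage r² is
computed over samples called at both sites, with r² ≡ 0 for constant
vectors or fewer than two shared samples.

## Uncertainty

Bootstrap error bounds repeat the whole frequency-and-estimation stage
after removing n = 6 random reference individuals (about 2% of a
349-sample cohort), 100 times by default; draws that would empty a breed
are rejected and redrawn (logged). Per-(sample, breed) means and SDs are
reported. Re-selecting the panel inside each iteration is supported via
a caller-supplied panel builder; the default re-estimates frequencies
only, the cheaper and more common reading. With n = 0 the procedure is
deterministic, so the SD is exactly zero by construction.

## The simulator

The generator emulates the statistical structure the estimation
experiments assume, not dog genomes per se:

* **Breed differentiation** — ancestral frequency p ~ U(0.05, 0.95) per
  site; breed k's frequency p_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k)
  (Balding–Nichols), so E FST ≈ F_k; per-breed F mirrors the wide
  spread of real breed drift (near 0 for weakly drifted breeds, near 1
  for ancient isolates). F = 1 is available behind an explicit fixation
  flag (frequencies collapse to 0/1); the F → 0 limit reproduces the
  ancestral frequencies.
* **Purebreds** — dosage ~ Binomial(2, p_mk), independent across sites.
* **Admixed individuals** — each of two haplotypes is tiled by ancestry
  blocks with exponential genetic lengths (mean 0.1 Morgan by default,
  roughly ten generations of mixing) on a flat 1 cM/Mb map over a single
  synthetic chromosome with uniform 100 kb site spacing; block origins
  are i.i.d. from the individual's true q; alleles are Bernoulli draws
  from the origin breed's frequency. The block map is returned as truth,
  so local origin fractions can be audited against q. Two-breed
  scenarios pick two distinct breeds and a U(0, 1) split (the proportion
  law is an assumption — only "random proportions" is specified
  upstream — and is configurable).
* **Low coverage** — a genotype goes missing with the Poisson
  zero-coverage probability exp(−λ · fraction · D₀), D₀ = 2.5× by
  default to match a typical low-pass query sample. This is a
  genotype-level emulation of read downsampling: there is no
  genotype-error model at low depth and no read-level simulation, so
  robustness results speak to missingness, not to miscalling.

What passing tests on these cohorts do **not** show: tolerance to real
LD structure (simulated sites are exchangeable and nearly independent,
which is why LD pruning removes almost nothing in `analysis/01`), to
reference-bias artifacts (e.g. a reference genome drawn from one of the
breeds), to mislabelled reference animals, or to admixture older or more
complex than the block model. Absolute centroid distances are likewise
not comparable to real-cohort values because every simulated site
carries breed signal; only panel-versus-panel contrasts transfer.

### Calibration note

The Balding–Nichols statement "realized FST ≈ configured F" is a
multi-population statement, and the calibration test verifies it with
the global (all-breeds) estimator: at F = 0.2, 20 breeds × 20, the
median per-site global θ̂ measures ≈ 0.19. The per-site **one-vs-rest**
median is structurally much smaller (≈ 0.04 at the same design): WC's
n-weighted pooling of 19 breeds as the "rest" cluster dilutes the
between-group variance roughly five-fold, and the median of a
χ²-shaped per-site numerator sits at ~0.45× its mean besides.
One-vs-rest FST is therefore checked for monotonicity in F, which does
hold, rather than for equality with F.

## Structure diagnostics

The relationship product is the covariance-standardized GRM
R_ij = (1/M′) Σₘ (g_im − 2fₘ)(g_jm − 2fₘ)/(2fₘ(1−fₘ)) with
pairwise-complete missing handling and monomorphic sites excluded; the
distance product is the allele-count Hamming distance Σₘ |g_im − g_jm|.
Both carry explicit metric tags since "relationship/IBS matrix" is used
loosely in practice. Neighbor joining (Saitou–Nei, via scikit-bio)
returns an unrooted tree, negative branch lengths unclamped; on additive
distances it reconstructs the generating tree exactly, which the tests
exploit as an oracle. PCA standardizes sites by sqrt(2f(1−f)) with
mean imputation of missing genotypes. The centroid score — mean
Euclidean distance of samples to their breed centroid in an embedding —
is deliberately embedding-agnostic with deterministic 2-component PCA as
the default (externally computed 2-D coordinates, e.g. from a stochastic
UMAP, are accepted); panel comparisons, not absolute values, are the
scientific content.

## Problem sizes and defaults

The validation experiments run at a deliberate desk scale chosen once:
20 breeds, F ~ U(0.1, 0.3), 8 purebreds per breed (160 dogs), 20,000
sites, top-500-per-breed + global-0.350 panel (~8,400 sites), 50
two-breed queries, read fractions {1, 0.75, 0.5, 0.25, 0.10, 0.05} at a
2.5× baseline, bootstrap 6 × 100. A full-size cohort (hundreds of dogs,
millions of sites, 65 breeds) changes the constants — panel sizes in
the hundreds of thousands — but no algorithmic path.

## Known limitations

* One-vs-rest selection inherits WC's sensitivity to very unequal
  cluster sizes; rankings are still usable because they are
  within-breed, but cross-breed θ̂ magnitudes are not comparable
  between schemes.
* The solver estimates each sample independently; it does not share
  information across samples or model genotype sampling noise, so
  proportions for barely differentiated breed pairs are identifiable
  only weakly (the error concentrates there in `analysis/04`).
* Imputing pooled frequencies for breed×site holes biases toward the
  cohort mean; with systematically missing breeds, prefer dropping the
  sites.
* VCF handling is GT-only and bi-allelic; multi-allelic records are
  skipped with a logged count rather than decomposed.
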