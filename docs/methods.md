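# Methods

`gradientscope` reimplements, on fully synthetic cohorts, a multimodal
connectome-gradient comparison between a patient and a control group:
subject-level functional connectivity (FC) and morphometric similarity
networks (MSN) are embedded into low-dimensional gradients by diffusion
maps, aligned across subjects, compared per canonical network, and the
resulting group-difference map is associated with regional gene expression
by partial least squares (PLS) with spatially corrected inference and
gene-set enrichment.

## The synthetic cohort model

Every region `i` carries a latent coordinate `g_i` on the
unimodal→transmodal axis, uniform on [−1, 1] and ordered along a contiguous
seven-network partition (visual, sensorimotor, dorsal/ventral attention,
limbic, frontoparietal, default). The population region-pair correlation is

    corr(i, j) = c0 · exp(−|g_i − g_j| / ℓ) + c1 · 1[same network],

projected to the nearest valid correlation matrix, with c0 = 0.65,
c1 = 0.05, ℓ = 0.35. These constants were chosen so that the smooth
latent-axis decay dominates the within-network elevation: if the elevation
dominates, the top-10% row graph splits into per-network components and no
global gradient exists. Patient regions use the transformed axis
`g·compression + shift(network)`; with no transform both groups follow the
identical law (the null).

Subject time series are multivariate Gaussian draws from the group
correlation plus independent white measurement noise (`noise_sd`, default
1.0 — noise on the scale of the signal, deliberately conservative for a
single parcel-level BOLD correlation). No temporal autocorrelation is
modelled: every downstream quantity depends only on the spatial correlation
structure, and the scan is summarized by its number of usable volumes
(default 140).

Morphometry assigns each region a two-axis latent profile — the group axis
and an offset, damped smooth secondary field — and produces the five
features (GM volume, cortical thickness, surface area, intrinsic and mean
curvature) as fixed unit-norm staggered-angle mixtures of that profile plus
noise at 0.3× the time-series noise scale (parcel-level morphometric
features are vertex averages and far less noisy than a single correlation
estimate). The offset keeps the profile direction away from the origin so
that feature-vector similarity decays smoothly with latent distance rather
than flipping sign; without it the MSN similarity graph can split in half.

Gene expression places regions on a half-circle arc of radius 100
(arbitrary mm-like units) so Euclidean distance is monotone in latent
distance, and draws each gene as a Gaussian field with exponential spatial
covariance `exp(−d/λ)` (default λ = 30). Planted signal genes add
`β · standardized(true difference map)` (default β = 2) before column
z-scoring. Gene sets are one planted pathway (all signal genes, padded)
plus random sets, written as GMT.

What the generator does *not* emulate: hemodynamics, temporal
autocorrelation, motion or scanner artifacts, heavy-tailed expression
noise, donor-level AHBA structure, or realistic 3-D cortical geometry.
Passing tests therefore certify the statistical machinery — embedding,
alignment, calibration, inference — under a known generative law, not
performance on real MRI or transcriptome data.

## Gradients

Per subject: the connectivity matrix is row-sparsified to the top 10% of
off-diagonal entries per row (ties broken by value, then lower region
index), converted to a nonnegative cosine-similarity affinity (negative
cosines clipped at 0), and embedded by diffusion maps: anisotropic
normalization `W' = D^−α W D^−α` with α = 0.5, Markov operator `P`,
eigendecomposition through the symmetric conjugate
`S = D'^−1/2 W' D'^−1/2` (numerically stable, guaranteed real spectrum).
Eigenvectors are normalized to unit length in the stationary-distribution
inner product — the convention under which the trivial eigenvector is
all-ones — and component `k` is scaled by `λ_k / (1 − λ_k)` at diffusion
time 0. Variance fractions are reported as `λ_k / Σ retained λ`, an
internal-consistency convention rather than a claim about total
connectivity variance.

The group template embeds the element-wise mean matrix over *all* subjects
(both groups, for symmetric treatment) and then fixes a sign convention:
each template gradient is flipped to correlate positively with region
index. Eigenvector signs are arbitrary, so without a convention the
orientation of any group difference flips from cohort to cohort; this is
the synthetic analogue of orienting real gradients anatomically
(sensory → transmodal). Individual embeddings are then aligned by
generalized Procrustes: column-centered, rotated (orthogonal, no scaling)
to the evolving mean reference, iterated until the reference change falls
below 1e−8, with a final re-rotation to the converged reference and
per-column sign fixing against it.

A practical limit worth knowing: because correlations depend only on
latent *differences*, per-network mean shifts are expressed in the
embedding only through boundary geometry. Small shifts (below the decay
length ℓ) move embedded positions smoothly and are recovered with the
correct sign; shifts much larger than ℓ tear the patient affinity graph
(empty-gap reorganization) and can make the induced difference
non-monotone. The analysis configuration uses shifts of 0.12–0.20.

## Group statistics

Network scores are unweighted means of member-region gradient values per
subject. Group comparisons are pooled-variance Student t-tests oriented
control − patient, with Benjamini–Hochberg FDR within one family = one
gradient × seven networks, Cohen's d with df-weighted pooled SD, and
analytic power from the noncentral t distribution
(δ = |d|·√(n1·n2/(n1+n2)), df = n1+n2−2, α = 0.05 two-sided; the lower
tail uses the symmetric form `sf(t_crit, df, −δ)` because `nct.cdf`
underflows at large δ). The region-wise z-map standardizes per-region t
values with the sample (n−1) SD.

## PLS and spatial inference

PLS1 with deflation: component weights are `X_dᵀ y_d` normalized (the
closed-form single-response solution), scores deflate both X and y, and
R² in y is computed by regressing y on the cumulative scores. X columns
and y are z-scored internally. Component significance uses
variogram-matched permutations: each surrogate rank-matches the observed
map's values to a Gaussian field drawn from an exponential-covariance
family over the region coordinates, trying a 20-length-scale grid
(including a near-white scale, which handles i.i.d. maps) × 3 random draws
and keeping the permutation whose realized 10-bin variogram has the
smallest mean relative error against the observed map's. Matching to the
*realized* variogram per surrogate, not to a fixed family scale, is what
calibrates the test: the observed map's realized smoothness varies between
realizations, and a fixed-scale null is anticonservative (rejection ~0.2
in pilots vs ~0.05 with per-surrogate matching). Permutation p-values use
the add-one rule and can never be zero.

In the packaged analysis, expression is planted against the *measured*
z-map (generated at the PLS stage), not against the latent group
difference. The two are deliberately distinct: region-wise differences of
aligned embeddings reflect eigenvector-shape changes as much as per-region
mean shifts, so the measured map correlates only moderately with the
latent truth (≈0.26 at the configured effect sizes in our runs). Planting
against the analyzed map validates the transcriptomic machinery — PLS,
permutation inference, bootstrap ranking, VIP, enrichment — under known
truth; the imaging-side distortion is reported as a property of the
pipeline, not hidden inside the gene-recovery result.

Gene contributions: regions are resampled with replacement, the PLS refit,
replicate weights sign-aligned to the original by dot product, and
`boot_z = weight / bootstrap SE`; genes are ranked by |boot_z|. VIP scores
follow the standard definition (squared VIPs average to 1 across genes)
and genes with VIP > 1 form the selection for enrichment, which is a
one-sided hypergeometric tail over the scored-gene universe with BH-FDR
across sets.

## Numerical and design choices

- Diagonals of connectivity matrices are stored as exactly 0 so
  row-thresholding never selects self-connections; no Fisher z anywhere.
- Sparsification keeps signed values; strong negatives are dropped by the
  top-k rule itself and any surviving negative cosine is clipped at 0.
- Degenerate inputs fail loudly: zero-variance series/features name the
  offending region or feature, disconnected affinity graphs report
  component sizes, constant t-vectors and zero bootstrap SEs are errors.
- A single global seed expands into fixed per-component substreams
  (time series, morphometry, expression, gene sets), so components are
  reproducible in isolation.
- Test problem sizes are reduced relative to the 400-region defaults
  (70–140 regions, 20–74 subjects per group, 150–200 genes), chosen as the
  smallest sizes at which the tested properties are stable; the
  null-calibration checks are size-insensitive by construction. Replicate
  counts and thresholds (50 replicates, 95%/90% recovery rates, 400
  comparisons, 0.05 ± 0.04 calibration band) follow the stated contracts.

## Known limitations

- The variogram self-check holds as a 20% *mean* relative error across the
  10 bins; individual extreme-distance bins of a single realized map can
  deviate more, which no stationary permutation family can remove.
- "Flags only the shifted network" is not attainable for planted
  one-network effects at high power: column-centered alignment makes the
  complement shift oppositely (a sum-zero constraint), and that
  compensatory displacement becomes significant at cohort-scale n. The
  attainable property — shifted network detected, with the largest effect
  size and the correct sign — is what the tests assert.
- Variance-explained percentages are eigenvalue ratios over retained
  components and are not comparable to any published "% of total
  connectivity variance" without the original data.
- The region-wise z-map is a distorted estimate of the latent group
  difference (embedding shape effects dominate at small planted shifts),
  so genes tracking the latent truth are only partially detectable from
  it; gene-recovery guarantees in this package are therefore stated
  relative to the map the transcriptomic stage actually analyzes.
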