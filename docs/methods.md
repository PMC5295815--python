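# Methods

Statistical background, model assumptions and numerical choices for the
`goldmim` toolkit. The package analyses a community of insects and spiders
sharing a golden-on-black colour pattern ("the golden complex") and asks
three questions: how many mimicry rings the complex contains, whether the
golden signal honestly advertises defence, and how much predation pressure
the mimics actually experience.

## Colour patterns and ring detection

Each species is summarised by the mean RGB triple of eight dorsal body
parts plus each part's length. Raw RGB means can be recalibrated against
white/black references (`standardize_rgb`, a linear map sending the black
reference to 0 and the white reference to 255 per channel).

Because large body parts dominate the visual impression, each part's three
colour features are multiplied by the part's share of the species' total
part length (`weighted_colour_matrix`). Species dissimilarity is
Bray–Curtis on those 24 features; ordination is non-metric MDS (Kruskal
stress-1, SMACOF majorization with isotonic regression of disparities,
best of 20 random starts; backed by scikit-learn's `MDS`).

The number of rings is chosen by scanning k-means partitions over a range
of k and selecting the k with the maximal **simple structure index**
(ssi). The implemented formula is the weighted variant reported by the
cascaded-k-means literature: per feature, the span between the extreme
cluster centres, damped by `exp(−|mean-centre deviation|)` and weighted by
the geometric mean of the two extreme clusters' sizes, normalised by the
number of features and the larger extreme-cluster size. It was verified
numerically against the R vegan implementation on shared input. Ties
prefer the smaller k. All-identical inputs are rejected rather than
clustered.

## Unpalatability index

For trait matrix `x` (species j, traits i):

```
u_j = Σ_i x_ij / max_j(x_ij)
```

Max-scaling puts binary flags (communal attack, chemical spraying),
counts (spines) and continuous measures (spine length, cuticle thickness,
gland area) on a comparable 0–1 scale before summation. All-zero trait
columns are excluded (they carry no information, and 0/0 is undefined).
Gland area is computed from two perpendicular diameters as a regular
ellipse, `π(d1/2)(d2/2)`.

Traits that cannot be measured for every species are interpolated by OLS
from body-part proxies: gland area and sting length from gaster length,
cuticle thickness from thorax length. Each fit requires at least three
complete species; predictions are floored at zero; observed cells are
never overwritten. Every species carries a **weight** equal to its
fraction of directly observed traits, used as a case weight downstream.

Variance homogeneity between groups of species (e.g. rings) is checked
with Bartlett's test (scipy implementation, with explicit guards for group
size and zero variance).

## Phylogenetic GLS and Pagel's λ

Under Brownian motion the tip covariance is `V[a,b] =` shared
root-to-MRCA path length. Pagel's transform keeps the diagonal and scales
off-diagonals: `V(λ) = λV + (1−λ)diag(V)`. λ above 1 is admitted up to the
largest value keeping `V(λ)` positive semidefinite — the minimum
eigenvalue of this linear matrix pencil is concave in λ, so the bound is
found by bisection. Empirical signal estimates can exceed 1, so capping at
1 would bias them.

Case weights w enter as `Σ = W⁻¹VW⁻¹` with `W = diag(w)`: a species with
weight 1 keeps its Brownian variance, a half-observed species has its
variance inflated fourfold. Fits whiten by the Cholesky factor of Σ and
solve by least squares; the F statistic compares the full model to the
intercept-only model in the whitened space. λ is estimated by profiling
the ML Gaussian likelihood over a 0.01 grid on the feasible interval plus
a local bounded refinement; a flat profile (range < 1e-6) returns the
lower bound with an explicit warning rather than a spurious interior
optimum.

The signal-honesty model regresses golden patch area on `u` and `u²`
(`golden_area_model`), testing both terms jointly; the Brownian
correlation absorbs shared ancestry (and with it much of body size, which
is strongly phylogenetically structured).

## Killing values and the capture-probability discount

A predator species i found with mimic j in a fraction `f_ij` of screened
individuals contributes `−log(1 − f_ij)` to the mimic's **killing value**

```
K_j = Σ_i −log(1 − f_ij).
```

On this log-survival scale independent mortality sources are additive, and
K is monotone in every frequency. Natural log is the default; a base-10
option is provided because classical killing-value usage is decimal —
ranks are base-invariant. A frequency of exactly 1 (infinite K) is
rejected with the offending position named.

For size-limited predators that may only have eaten juveniles, raw
frequencies are discounted by a logistic capture probability in the
prey/predator size ratio, `p = 1/(1 + exp(−1.99 + 2.11·ratio))` — fitted
across spider guilds; `p = 0.5` exactly at ratio `1.99/2.11` and
`p(0) ≈ 0.88`. Only predators flagged `size_limited` are adjusted, and the
adjustment is multiplicative.

Predators are classified as specialised ant-eaters when strictly more than
10% of individuals test positive for the ant-targeting primer. Observed
capture counts are compared against environmental availability with a
Pearson chi-square.

### Smooth regression of log K on u

The relationship between predation pressure and unpalatability is fitted
as a penalized cubic regression spline of `log K` on `u` (quantile knots,
default 5). Zero killing values are handled as `log(K + ε)` with ε equal
to half the smallest positive K — a documented sensitivity choice, the
fitted ε is reported. The design matrix uses B-splines; the penalty is the
exact curvature Gram matrix `∫B″B″ᵀ` (3-point Gauss–Legendre per knot
interval, exact for the piecewise-linear second derivatives), so exactly
the linear functions are unpenalised. The smoothing parameter minimises
GCV over a log-spaced grid with an inflated complexity cost
(`gcv_gamma = 2.0`): plain GCV undersmooths badly at the n ≈ 13 scale of
the gut-screen data, which made the approximate F test of the smooth term
anti-conservative (measured type-I error 0.14 plain and 0.11 at the
conventional γ = 1.4, versus 0.068 at γ = 2.0 over 500 null replicates,
with no loss of power on strong monotone signals). The smooth is tested
with an approximate F on (edf − 1, n − edf) degrees of freedom against the
intercept-only model.

## Staged trials

Each trial presents one prey to one predator individual and records
capture (0/1) and, when captured, an ordinal post-attack reaction — eaten
(0), eaten with mouth-cleaning (1), spat out (2) — rescaled to an aversion
score 0/0.5/1. Capture rates across matched prey are compared with
Cochran's Q (implemented in closed form; the statsmodels implementation
serves as an independent oracle in the tests). The aversion score is
regressed on unpalatability with a binomial logit GLM; because the scores
are non-integer, the slope is tested with a deviance-based quasi-F on
(1, n−2) degrees of freedom and perfect separation is flagged rather than
raised. Repeated use of predator individuals is deliberately left to
off-the-shelf marginal models (GEE); the module exposes the per-prey
capture-frequency summaries those models consume.

## Spatial overlap and the Mantel test

Occurrence records are projected with a spherical Lambert azimuthal
equal-area projection centred on Australia (134°E, 27°S; hand-rolled,
~10 lines, since no projection library is assumed) and binned into square
half-open cells (default 400 km; a record exactly on a boundary belongs to
the lower-left cell). Range overlap is Bray–Curtis on the binary presence
rows; colour distance is Euclidean on the weighted colour features. The
Mantel statistic is the Pearson correlation of the upper off-diagonal
triangles; the null distribution permutes rows and columns of one matrix
jointly, with `p = (1 + #extreme) / (n_perm + 1)` (two-sided default). An
exhaustive-enumeration variant exists for n ≤ 7 and anchors the
permutation test in the suite.

## Synthetic data generators

The generators produce data with exactly the structure the analyses
assume, at the study's native scale (defaults: 100 species, 13 predators
in three guilds, 5 trial prey, 26 predator individuals):

- **Tree + trait**: a pure-birth tree; because the birth–death sampler
  stops at the n-th speciation event (zero pendant edges → singular
  covariance), all pendant edges are extended by the exponential waiting
  time to the next birth, i.e. the process is sampled between events. The
  tip trait is one MVN draw from `σ²·V(λ)` at the configured λ.
- **Traits**: continuous defences share a latent body-size factor at the
  configured Pearson correlation (linear-normal construction, exact in
  expectation); proxies are noisy fractions of body length.
- **Golden area**: quadratic in the true index plus Gaussian noise,
  clipped at zero.
- **Colour rings**: cluster centres sit on a randomly rotated regular
  simplex in the 24-dimensional feature space, so *every* pair of planted
  rings is separated by exactly `cluster_separation`; ring sizes are
  balanced. (With irregular centre spacing, the ssi criterion — including
  the reference R implementation — over-splits a large fraction of runs,
  which says the geometry violates the well-separated-blobs premise, not
  that the scan is broken.) The planted structure lives in the raw
  features; relative-length weighting adds multiplicative per-part noise
  that blurs it, so recovery checks cluster the raw features.
- **Gut screens**: detection probability declines exponentially with
  max-scaled unpalatability for visually hunting guilds and is flat for
  non-visual ones; frequencies are binomial.
- **Trials**: Bernoulli captures with probabilities decreasing in
  unpalatability; post-attack ranks from a cumulative-logit model whose
  linear predictor increases with unpalatability. `mullerian_first`
  reproduces a constrained presentation order (best-defended prey first).

All randomness flows from a single mandatory seed through salted
`numpy.random.default_rng((seed, salt))` streams, so every generator is
bit-reproducible and independent of the others.

## What the generators do not emulate

Observation error in RGB measurement, spatial autocorrelation between
ranges, phylogenetic structure in the colour features themselves,
predator-individual heterogeneity beyond the marginal capture
probabilities, and seasonal variation in gut-screen detectability. The
calibration claims (type-I error, recovery rates) hold under the stated
generative models only.

## Verification strategy

Every claim is tested by a route independent of the implementation:
Bray–Curtis against a double loop, the tip covariance against brute-force
MRCA depths, GLS against OLS/statsmodels at identity covariance, Cochran's
Q against statsmodels, the Mantel statistic against scikit-bio and against
exhaustive enumeration, Bartlett against the textbook formula, the index
against a spreadsheet-style plain-csv oracle, and the calibrations against
their nominal levels on seeded null simulations (`tests/test_acceptance.py`,
reproducible via `scripts/acceptance.py`).
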