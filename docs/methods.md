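# Methods

This note documents the models and numerical conventions implemented in
`turbicomp`, the choices made where several defensible designs exist, and
what the synthetic fixtures do and do not emulate.

## 3D complexity indices

Both indices compare a triangle mesh to its 3D convex hull (computed by
quickhull via `scipy.spatial.ConvexHull`, with a joggle fallback for the
near-degenerate vertex sheets voxel-derived meshes produce; duplicate
vertices are merged before hulling).

- **CHAR = SA / CHSA.** SA is the total area of all supplied triangles —
  for a closed thin shell both sides of the bone count once each, and the
  toolkit makes no attempt to extract a mid-surface; the convention is
  simply "total face area of the supplied mesh" and must be applied
  consistently across specimens. CHAR is defined for open and closed
  meshes alike (an area ratio needs no enclosed volume) and is ≥ 1 for
  closed meshes because the hull is the smallest convex envelope.
- **CHNSI = F·√SA/∛CHV**, `F = ∛(4π/3)/(2√π)`. Substituting a sphere's
  SA = 4πr² and CHV = (4/3)πr³ shows F cancels everything: a sphere scores
  1 at any radius, and a unit cube scores F·√6 ≈ 1.1139. CHNSI *requires*
  a closed mesh (every edge shared by exactly two faces); open meshes are
  refused with an explicit error rather than silently hulled.

Units are carried opaquely (areas in squared mesh units); the indices are
dimensionless, scale- and rigid-motion-invariant, which the test suite
checks to 1e-9 relative.

Grouped analyses (respiratory vs olfactory turbinals) are performed by
merging the element meshes with `merge_meshes` *before* computing the
index, so the hull encloses the whole group.

## 2D box-counting complexity

`Db` is the least-squares slope of log N(s) vs log(1/s). Counting uses
axis-aligned grids at several offsets per size (default 4: origin plus
half-box shifts in x, y and the diagonal) and keeps the minimum count —
the tightest cover among the tried placements. The default size series is
dyadic, 2–128 px. Exact legacy tool settings (FracLac) are unpublished;
all three knobs (sizes, offsets, frame) are arguments.

The full slice protocol (`slice_complexity`) records the raw foreground
area (a size proxy, reported alongside Db and usable as a downstream
covariate — never divided into Db, since the published phrase "used as a
size proxy to scale complexity values" does not specify an operation),
skeletonises the shape to a single-pixel contour (Zhang–Suen thinning),
scales and centres it onto a 300 × 300 black frame (nearest-neighbour
resampling then a 0.5 threshold, keeping the image strictly binary, with
a 5 px margin), and counts. The counting/fitting primitive
`fractal_dimension` deliberately does **not** skeletonise: calibration
bodies of known dimension (a filled square is 2-dimensional; its skeleton
would be ~1-dimensional) must be measured as supplied.

**Finite-depth fractals and the inner cutoff.** A depth-d approximation
of a fractal is self-similar only down to its elementary cell (8 px for a
depth-6 Sierpinski gasket in a 512 px frame); boxes smaller than the cell
probe solid blocks and bias the slope upward. Calibration therefore uses
the dyadic series starting at the rendering cell, which recovers
log 3/log 2 exactly for the gasket; the depth-5 Koch curve's smallest
segments (~2 px) already sit inside the default window.

## Trait tables

Specimen rows carry per-element areas (nt, mt, ls, ft1, ft2, it, it2,
etI–III), SKL/SNL/SNW and diet/lifestyle labels. Species averaging is the
arithmetic mean on the raw scale (log transforms, where used, are applied
after averaging; natural logs throughout). ft2/it2 occur in a minority of
taxa and contribute zero when absent rather than erroring. The
nasoturbinal carries both epithelium types, so composites are computed
under an explicit `nt_assignment` switch; TotSA and the partition
identity RelatRespiSA + RelatOlfaSA = 1 hold under either assignment.
Relative snout metrics are SNL/SKL and SNW/SKL.

## PGLS and group tests

GLS with covariance σ²V, V from: identity ("none"), Brownian motion
(shared root-to-MRCA path lengths), root-conditioned Ornstein–Uhlenbeck
`V_ij = e^{−α d_ij}(1 − e^{−2α t_ij})/(2α)` (chosen over the pure
stationary form `e^{−α d_ij}` because it converges to the Brownian
covariance as α → 0, making the OU family a genuine BM superset), or
Grafen's transform (node heights from descendant-tip counts, normalised,
raised to ρ). α and ρ are profiled by ML on a bounded log scale
(α ∈ [1e-8, 50/tree depth], ρ ∈ [0.01, 10]; a coarse grid seeds a bounded
Brent refinement). `model="auto"` fits all four structures and keeps the
lowest AIC, attaching the candidate table.

All fitting is ML (not REML) so AIC and likelihood-ratio comparisons
remain valid across different fixed-effect structures. Coefficient SEs
use the unbiased residual scale rss/(n−p) and t with n−p df — a
finite-sample convention, documented as such; with V = I this reproduces
OLS coefficients, SEs and R² to machine precision.

Diet structure after size correction is tested two ways: (i) one-way
ANOVA and Tukey HSD (studentized range) on PGLS residuals — quick, but
subject to the residuals-as-data caveat, which the fit objects surface in
their metadata; (ii) phylogenetic ANCOVA: nested group-intercept GLS
models (no groups / omnivore-vs-all-carnivore / full diet) compared by
AIC and chi-square LRT, the recommended primary route. Slope
heterogeneity uses an F-type comparison of common-slope vs
separate-slopes GLS fits plus pairwise slope contrasts.

## The BM/OU ladder

Multi-optimum OU with a single α and σ² and one optimum θ per painted
regime. Tip expectations use exact per-lineage occupancy integrals: a
lineage segment in regime r over [t0, t1] contributes weight
`e^{−α(T−t1)} − e^{−α(T−t0)}`, and the root (assumed at the root regime's
optimum) contributes `e^{−αT}`. Given α, optima and rate have closed-form
GLS solutions, so fitting is a 1-D profile over log α (13-point grid plus
bounded refinement). Parameter counts: BM 2 (root, σ²), OU with m optima
m + 2; models are ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1). OU fitting
requires an ultrametric tree (within 1e-6 relative depth) because the
root-conditioned covariance assumes contemporaneous tips; BM does not.

Regime paintings come from tip states by Fitch parsimony with an
ACCTRAN-style top-down pass (a node keeps its parent's state whenever the
Fitch set allows, placing changes early; ties break to the
lowest-sorted state), by an equal-rates Markov ML reconstruction, or are
user-supplied and validated for completeness. Provenance is recorded.

## Ancestral states and Stayton convergence

Ancestral states are BM ML (GLS) estimates: the conditional mean of
internal nodes given the tips with the GLS root estimate plugged in,
equivalent to the edge-weighted least-squares (re-rooted weighted
average) construction — the suite verifies both routes agree to 1e-10.
Continuous maps interpolate linearly along each edge.

For a focal tip pair, Dtip is the (Euclidean, optionally multivariate)
distance between tip phenotypes; Dmax the maximum distance between any
cross pair of states — tips or reconstructed ancestors — on the two
lineages back to their MRCA; Ltot.clade the summed parent-to-child
phenotypic change over every branch of the MRCA's clade. C1 = 1 −
Dtip/Dmax (the "inverse ratio" reading that keeps C1 in [0, 1]),
C2 = Dmax − Dtip, C3 = C2/Ltot.clade. Multiple focal tips are aggregated
as the mean over pairs, with per-pair values retained. Traits are used as
supplied; a `standardize` flag z-scores columns when mixing areas,
complexity indices and linear measurements in one test. p-values come
from re-measuring the indices on BM datasets simulated with the ML rate
(co)variance of the observed data: p = (1 + #{sim ≥ obs})/(1 + nsim),
1,000 simulations by default. Published "modified convevol" analyses may
differ in unstated details; this implementation follows the published
index definitions.

## Synthetic clades

The default `CladeSimSpec` mirrors the target study design: a pure-birth
ultrametric tree with 55 tips (pendant edges extended by one extra
exponential waiting time so none is zero-length; depth rescaled to 1),
diets in exact 23/18/14 counts with the derived diets (carnivory,
vermivory) assigned to whole clades of ≤ 8 tips — several independent
origins each, as in the real radiations — and vermivores split evenly
terrestrial / semi-fossorial. RelatOlfaSA evolves under three-optimum OU
(α = 2 per unit depth, stationary SD 0.03 around an omnivorous optimum of
0.55); snout width ratio under four-optimum OU (semi-fossorial vermivores
narrowest); total area follows skull length with log–log slope 2.25 plus
Brownian residuals; specimens (1–3 per species) add 4% lognormal
measurement noise. Effect sizes are stated as *realized* tip-level shifts
in stationary-SD units: optimum offsets are inflated by the inverse mean
regime occupancy, so "a 3 SD vermivore shift" is what the vermivorous
tips actually express, not a latent optimum displacement discounted by
finite time in the regime. Signs follow the qualitative biology
(vermivores: larger/more complex olfactory turbinals, narrower snouts);
magnitudes are free parameters of the spec, not estimates.

What passing tests on these fixtures show: the estimators recover the
generating process and the pipeline's error rates are calibrated under
its assumptions. What they do not show: robustness to the things real CT
data add — segmentation error correlated across elements, non-ultrametric
phylogenetic uncertainty, diet misclassification, and trait distributions
that are not Gaussian on any convenient scale.

## Problem sizes and numerical conventions

Simulation-based checks use 64–128-tip trees with 100–500 replicates and
150–1,000 null simulations — sizes chosen so the full suite documents
calibration without requiring a cluster. Degenerate inputs error
explicitly rather than warn: coplanar hulls, open meshes for CHNSI,
empty images, zero-variance traits, zero branch lengths on reconstruction
paths, non-nested ANCOVA groupings. Near-singular correlation matrices
(e.g. extreme Grafen ρ) receive a 1e-10 relative ridge inside GLS solves;
profile points that remain infeasible are treated as −∞ likelihood.
All randomness flows through explicit seeds; simulations are
reproducible bit-for-bit.
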