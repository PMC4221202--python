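# Methods

## Outline representation

An outline is an ordered polyline starting at a fixed homologous
landmark (for the premaxilla: the left maxilla–premaxilla suture on the
ventrolateral margin) and sweeping the ventral profile to its
right-side counterpart. Outlines are therefore treated as **open**
curves; a closed-contour mode exists but is off by default. Resampling
places p semilandmarks (default 100, i.e. 200 shape variables) at arc
positions k·L/(p−1), k = 0…p−1, with linear interpolation between input
vertices: at p = 100 the difference from spline interpolation is below
digitising noise, and linear interpolation is deterministic and
checkable against a brute-force arc-length table. Resampling an
already-uniform p-point outline is a no-op, so inputs may be raw
digitisations or pre-resampled semilandmarks. No semilandmark sliding
is performed anywhere.

## Superimposition

Classical generalized Procrustes analysis in shape space: each
configuration is centred, scaled **once** to unit centroid size
(CS = √Σ‖xᵢ − x̄‖²; no iterative rescaling, since the analysis is of
shape, not form), rotated to the first specimen, and then iteratively
rotated to the consensus. The convergence criterion — "distance between
successive mean configurations" — is implemented as the partial
Procrustes distance between consecutive consensus shapes, with
tolerance 10⁻⁴ by default and a 1000-iteration cap (convergence is
linear, so very tight tolerances need hundreds of iterations).
Reflections are excluded (proper rotations only): all specimens are
digitised in the same ventral view, and an improper rotation would
fabricate a left/right inversion. PCA acts on the superimposed
coordinates directly, without tangent-space projection; at the shape
ranges involved the curvature correction is negligible and omitting it
preserves the partial Procrustes distances exactly.

## Ordination

Covariance PCA (divisor n − 1) of the flattened (x₀,y₀,x₁,y₁,…)
coordinates. The PCA is fitted on the known-guild specimens only;
unknowns are projected afterwards, whereas the GPA includes all
specimens jointly so that every specimen shares one consensus frame.
Three axes are retained for the CVA by default (configurable).
Eigenvector sign is fixed by making the largest-magnitude loading
positive, so outputs are identical across linear-algebra backends.

The phylogenetic PCA uses the Brownian-motion covariance C (shared
root-to-MRCA path lengths; no λ transform), the GLS root mean
â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X, and eigendecomposes the evolutionary covariance
E = (X − 1âᵀ)ᵀC⁻¹(X − 1âᵀ)/(n − 1); scores are the root-centred data on
E's eigenvectors. With a star tree (C = I) this reduces exactly to the
ordinary PCA. Like the raw variant, it is fitted on knowns (tree pruned
accordingly) with unknowns projected afterwards.

## Discriminant analysis and the φ statistic

With two groups a single canonical axis exists: the leading eigenvector
of W⁻¹B (W pooled within-group SSCP, B between-group SSCP), computed by
a nonsymmetric eigendecomposition and scaled so the pooled within-group
variance of canonical scores is 1 — under that scaling, distance along
the axis is Mahalanobis distance, so nearest-centroid assignment uses
plain 1-D distance with no prior probabilities or group-size weights.
The axis is oriented so the alphabetically first group's centroid is
positive. Group distinctiveness is summarised by Wilks'
Λ = det W / det(W + B) and φ = −(n − 1 − (k + g)/2)·ln Λ (Bartlett's
scaling, g = 2), evaluated against χ² with k df; the unscaled −n·ln Λ
variant is available behind a flag. φ is invariant to any affine
recoding applied identically to both groups' score columns.

Two randomization nulls, 1,000 pseudo-replicates by default:

* **Monte Carlo** — each replicate draws n×k values column-wise iid
  normal with the pooled (group-blind) mean and variance, keeps the
  observed group sizes as labels, and records φ.
* **Bootstrap** — each replicate resamples the n observed score rows
  with replacement and assigns the first n₁ rows to group 1 (a
  without-replacement permutation variant is available), destroying the
  group structure while keeping the empirical score distribution.

p is reported both as #{φᵣ ≥ φ_obs}/R and as the conservative
(count+1)/(R+1). Null loops use a determinant-only fast path for Λ/φ
(no eigenvector needed), which keeps the 1,000-replicate runs under a
second. Replicate streams derive from a single seed by SeedSequence
spawning.

Classification quality is reported as resubstitution and leave-one-out
(jackknife) confusion matrices (the holdout is projected through a CVA
refitted on the remaining n − 1). Unknown specimens are mapped
aligned-coordinates → PC scores → canonical score → nearest centroid,
with distances to both centroids; specimens falling outside both
groups' observed canonical ranges are flagged as assignments that
cannot be justified from the fitted space.

## Shape models

Each axis is modelled at five positions: the observed score extremes
(not ±k·SD — the models depict the data's own range), the two
half-extremes, and zero, whose model is exactly the consensus. A PC
position s maps to mean + s·eigenvector; a canonical position c maps
back into PC space as c·v/(vᵀv) (the right inverse of the
unit-within-variance scaling, so re-projection recovers c exactly) and
then through the eigenvectors. Strobe plots are SVG by default
(structurally inspectable and byte-reproducible with a fixed hash
salt); PNG works through the same call.

## Phylogenetic signal

**Blomberg's K**: with â the GLS mean, MSE0 = (x−â1)ᵀ(x−â1)/(n−1),
MSE = (x−â1)ᵀC⁻¹(x−â1)/(n−1),
K = (MSE0/MSE) ÷ [(tr C − n/(1ᵀC⁻¹1))/(n−1)]. K = 1 exactly on a star
tree, and E(K) ≈ 1 for Brownian traits on any tree. Significance comes
from tip-label permutations (999 by default) using K itself as the
statistic; some packages permute a contrast-variance statistic instead,
which can give different p-values — the choice here keeps the test
statistic and the effect size identical.

**Pagel's λ**: C(λ) multiplies the off-diagonals of C by λ; the
likelihood profiles out the GLS mean and ML rate σ̂² = rᵀC(λ)⁻¹r/n.
λ is maximised over [0, 1] (values above 1 can break positive
definiteness) by bounded scalar search with both boundary values
checked explicitly. The reported p is a likelihood-ratio test against
λ = 0 (χ²₁) — i.e. "is there any tree structure in this trait" — with
a test against λ = 1 available.

**Independent contrasts**: Felsenstein pruning — contrast
(x_a − x_b)/√(v_a + v_b), parent value the variance-weighted average,
parent branch lengthened by v_a·v_b/(v_a + v_b); polytomies are
resolved arbitrarily with zero-length branches and logged. Because
contrast signs depend on the arbitrary ordering of sister lineages,
rank correlations positivise the first contrast set's signs and flip
the second in tandem before computing Spearman's ρ or Kendall's τ
(two-sided).

**Mass residuals**: the shape score is regressed (OLS) on log₁₀ body
mass and the residuals carried into the signal tests. The score is the
response — residualising the shape variable is the direction under
which "signal in the shape scores" remains meaningful. Mass arrives in
grams and is log-transformed before any analysis.

## Synthetic data

The generator is the package's test bed and defines the study
conditions. The template family is a fixed analytic curve: half-width
profile over an axial coordinate, blended between a blunt end member
(s = 0: wider than long, distally flattened with a medial concavity)
and a pointed one (s = 1: roughly twice as long as wide, convex distal
end, medial lateral compression), mirrored about the midline (exact
bilateral symmetry by construction) and sampled to p equal-arc
semilandmarks. The end members sit ≈ 0.75 partial-Procrustes units
apart — comfortably discriminable — and the family is frozen in code so
regression values are stable.

Default study design: 34 browsers + 34 grazers + 57 unknowns (125
species), group s means 0.2/0.8, within-group s.d. 0.1, coordinate
noise 1% of the template's bounding-box diagonal, nuisance rotation
U(0, 2π), log-normal scale (sd 0.2), Gaussian translation. Body mass is
exp(ln 10⁵ + 1.0·s + N(0, 0.5)) grams — a mild allometric coupling
around a 100 kg mid-range ruminant, chosen once as a realistic effect
that makes the raw shape–mass correlation detectable without dominating
shape. The phylogeny is a pure-birth (Yule) tree over all species
(rate 1), written in-package on numpy Generator streams so that a
single seed reproduces the entire study; Brownian traits evolve along
its branches for the K/λ recovery checks.

What the generator does **not** emulate: real cranial anatomy,
digitising operator error structure (noise is iid Gaussian), ecological
misclassification of the "known" guilds, and any true coupling between
the simulated tree and the shape parameter (guild membership is not
heritable in the simulation, so phylogenetic signal in simulated shape
scores is expected to be weak). Passing tests therefore demonstrate
the correctness and calibration of the machinery, not biological
claims about real ruminants.

## Problem sizes and numerical choices

The test suite and the acceptance script use deliberately compact
problem sizes chosen to exercise every property at comfortable
statistical power: 500 outer trials × 200 Monte Carlo replicates for
the type-I error of the φ test, 200 Brownian replicates on 32-tip Yule
trees for the K/λ calibration (mean K within [0.9, 1.1], median λ̂ at
the Brownian boundary), and 30 + 30 specimens at 100 semilandmarks for
end-to-end recovery. GPA uses tolerance 10⁻⁴ (tests tighten it to
10⁻¹⁰ where oracle comparisons demand); covariance eigendecompositions
use symmetric eigensolvers with eigenvalues clipped at 0; Wilks' Λ uses
log-determinants; the λ likelihood uses Cholesky factorisations and
returns −∞ for non-positive-definite C(λ). Classification ties break
to the alphabetically first group and are flagged. Degenerate inputs
(coincident points, rank-0 configurations, singular W or C, empty
species intersections) raise informative errors rather than warnings.

## Known limitations

* Strictly two-group discrimination; no priors or posterior
  probabilities.
* 2-D outlines only; no missing-landmark estimation; no sliding or
  curvature-weighted semilandmarks; no tangent-space projection (a
  deliberate omission at these shape ranges).
* Phylogenetic PCA assumes plain Brownian motion (no λ optimisation in
  the ordination step) and a strictly bifurcating or
  arbitrarily-resolved tree.
* The jackknife refits share the retained-axis count k with the full
  fit; axis-number selection itself is not cross-validated.
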