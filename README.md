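# snoutshape

Geometric-morphometric analysis of ruminant snout (premaxilla) profile
shape, built around the classic ecomorphological question: can a
species' feeding guild — browser (dicot browse) versus grazer (grass) —
be read off the ventral outline of its snout, and does that distinction
survive phylogenetic control?

The package takes three inputs — per-specimen outline coordinates, a
trait table (feeding class, body mass), and a Newick phylogeny — and
runs the full pipeline:

1. **Semilandmarks** — each outline is resampled to *p* = 100 points at
   equal arc-length intervals from a fixed homologous start landmark
   (no semilandmark sliding).
2. **Procrustes superimposition (GPA)** — configurations are centred,
   scaled to unit centroid size, and iteratively rotated to the
   consensus until the partial Procrustes distance between successive
   consensus shapes falls below 10⁻⁴; the analysis proceeds in shape
   space.
3. **Ordination** — covariance-based PCA of the superimposed
   coordinates of the known-guild specimens (3 axes retained by
   default), or phylogenetic PCA of the evolutionary covariance
   (X − 1âᵀ)ᵀC⁻¹(X − 1âᵀ)/(n − 1) under a Brownian-motion tree
   covariance C.
4. **Discriminant analysis** — two-group CVA on the retained scores.
   Group distinctiveness is summarised by Wilks' Λ = det W / det(W + B)
   and the log-likelihood-ratio index
   φ = −(n − 1 − (k + g)/2)·ln Λ, tested three ways: χ² with k degrees
   of freedom, a Monte Carlo null (column-wise normal pseudo-replicates
   with the pooled mean and variance), and a bootstrap null (rows
   resampled so the group structure is destroyed), each with 1,000
   pseudo-replicates by default.
5. **Classification** — nearest group centroid along the canonical
   axis; resubstitution and leave-one-out (jackknife) confusion
   matrices; unknown-guild specimens projected into the fitted space
   and provisionally assigned.
6. **Shape models** — each axis modelled at five positions (extremes,
   half-extremes, centre) and back-projected into landmark space for
   "strobe" overlay plots.
7. **Phylogenetic signal** — Blomberg's K (tip-permutation test) and
   Pagel's λ (maximum likelihood, LRT against λ = 0) on the
   mass-residualised PC scores, plus Felsenstein independent contrasts
   correlating shape with log₁₀ body mass.

A synthetic-study generator (`snoutshape.simulate`) produces the full
three-file input from an analytic blunt↔pointed template family with
nuisance transforms, allometric body mass, and a Yule phylogeny, so
every stage is testable end to end without any external data.

## Worked example

```
python examples/01_simulate_and_classify.py
```

prints (seed 1, 34 + 34 known specimens, 57 unknowns):

```
3 PC axes carry 96.47% of shape variance
Wilks' Lambda = 0.0630, phi = 178.30
p (chi2) = 2.05e-38; p (Monte Carlo) = 0.0; p (bootstrap) = 0.0
resubstitution accuracy = 100.00%, jackknife = 100.00%
unknown assignments: {'browser': 22, 'grazer': 35}
```

Three PC axes capture nearly all shape variance along the
blunt↔pointed continuum; φ far above every null replicate (both
randomization p-values 0) means the browser/grazer centroid separation
cannot be explained by sampling error or dataset dimensionality, and
the jackknifed accuracy confirms the discriminant space generalises.
The unknown split reports which guild each unclassified species most
resembles. The other `examples/` scripts cover shape-model strobe
plots, the phylogenetic-signal statistics, and the phylogenetically
controlled pipeline; a thin CLI (`snoutshape simulate`,
`snoutshape run-all`) drives the same code from the shell.

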