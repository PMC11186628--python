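# Methods

This note records the model, the algorithmic and numerical choices, and the
limits of what the test suite demonstrates.

## Model and assumptions

The matcher treats each study as a finite metric space: points are features,
distances are computed between feature-intensity vectors across that study's
samples. Its core assumption is that a compound shared by two studies keeps
its intensity-correlation fingerprint, so the intra-study distances between
shared features agree across studies. This holds best when the two study
populations are comparable; aligning studies with very different populations
(where correlation structure itself shifts) violates the assumption and is a
known limitation.

Distances default to the normalized Euclidean distance d(u,v) = ‖u−v‖/√n.
Intensities are centered and scaled per feature (population convention,
divisor n) before distance computation by default; on standardized rows the
normalized Euclidean distance equals √(2·cosine distance) of the raw rows,
so the default pipeline is scale- and offset-invariant across studies.
Standardization uses the population standard deviation precisely so that
‖u‖² = n and this identity is exact (it is asserted in the test suite).
Inputs must be complete; imputation is upstream preprocessing, and the
readers refuse missing intensities rather than guessing.

## Unbalanced Gromov–Wasserstein stage

The distortion E(Π) = Σ Πᵢⱼ Πₖₗ c(dxᵢₖ, dyⱼₗ) is relaxed with marginal KL
penalties (weight ρ, default 0.05) toward uniform reference marginals
a = 1/p₁, b = 1/p₂ and an entropic KL penalty (weight ε, default 0.005)
toward the product measure. ρ controls how much of the feature sets gets
matched — mass grows with ρ — and ε trades sharpness for numerical
stability. The defaults are the smallest values at which the solver is
reliably stable, and in practice they rarely need touching. The reference
marginals are taken as uniform probability vectors (rather than ones
vectors); the choice is exposed as `marginals="ones"` for the unnormalized
convention.

Per-entry cost: the solver defaults to the squared difference
c = (dx − dy)², which is what the tensorized local-cost factorization
(Peyré-style decomposition) requires for O(p³) updates. An
absolute-difference mode |dx − dy| exists behind `cost="abs"` for small
problems via a dense 4-way tensor; on toy fixtures both modes produce the
same matchings (tested), and the squared cost is the default used
throughout.

Optimization is two-block alternating minimization on the bilinear
relaxation L(π, γ): freezing one factor makes the other an unbalanced
entropic linear OT problem with cost assembled from the frozen factor,
solved in the log domain by unbalanced Sinkhorn updates
(f ← ρ̂/(ρ̂+ε̂) · softmin, with ε̂ = ε·m(γ), ρ̂ = ρ·m(γ)), followed by the
optimal mass rescaling √(m(γ)/m(π)). Each block update can only decrease
L(π, γ), so the recorded objective trace is non-increasing up to the inner
tolerance; this is asserted on random problems. At a fixed point π = γ and
the relaxation coincides with the original objective.

The m/z window (default 0.01 Da absolute, inclusive; a ppm mode is
provided) is enforced structurally: incompatible cells get a prohibitive
local cost each iteration and are hard-zeroed afterwards, so the invariant
holds regardless of solver state. Rows and columns with no compatible
partner at all are dropped from the iterations entirely (they provably
carry zero mass), which makes the solve scale with the number of
m/z-compatible features rather than the full table sizes.

Numerical details: log-domain throughout, exponent clipping at ±700,
potentials warm-started across outer iterations; outer convergence when the
max-abs change of the coupling falls below `tol` (1e−6) or after
`max_outer` (200) iterations; inner Sinkhorn capped at `max_inner` (500).
A fully masked problem returns the exact zero coupling, whose objective is
2ρ + ε under uniform reference marginals. Non-finite intermediates raise an
error advising a larger ε.

## RT drift estimation and filtering

The drift f: RT₁ → RT₂ is a cubic B-spline (order configurable) fitted to
the coupling's support pairs under the weighted L1 loss
Σ Πᵢⱼ |f(RTᵢ) − RTⱼ|. L1 is minimized by iteratively reweighted least
squares (3 rounds, weight w/max(|r|, 1e−6)) on the B-spline design matrix;
a plain weighted-least-squares mode exists and agrees with IRLS on
noiseless fixtures (tested). Interior knots sit at weighted quantiles of
the support RTs; the knot count is selected from {3, 5, 7, 10, 15} by
10-fold cross-validation (folds by seeded shuffling of support pairs,
CV error the same L1 loss used for fitting). Evaluation outside the fitted
RT range clamps to the range boundary.

Filtering uses residuals r = |f(RT₁) − RT₂| over the support: two
preliminary rounds discard pairs with r > μᵣ + PI (PI = 1.96·std, population
convention; μᵣ the median residual), then a final round applies the stricter
r > μᵣ + 2·MAD. Survival is inclusive (r ≤ threshold + 1e−12) so an exact
fit keeps all pairs. Each round's threshold is additionally floored at
0.01 min: residual differences below chromatographic time resolution are
not informative, and on (near-)noiseless data the MAD collapses to the
spline approximation error (~10⁻³ min) and would otherwise discard valid
pairs. Under the benchmark's RT noise levels (0.2–1 min) the data-driven
thresholds are orders of magnitude larger and the floor never binds.

## Matching extraction and pooling

The optional τ-threshold removes entries below τ·max(Π̂) (τ = 0.3 in the
GMT preset; τ = 0 in GM). One-to-one extraction keeps entries that are the
strict maximum of both their row and their column; tied maxima are dropped
entirely rather than broken arbitrarily, preserving the at-most-one
invariant. Multi-candidate information is still available to exploratory
users via the pre-extraction coupling support; no ranking beyond the
coupling weights is imposed. Pooling stacks donor-study samples onto the
reference study's features, with NaN columns where a reference feature has
no match in a donor study.

## Synthetic validation data

The generator emulates the standard split-and-perturb validation design:
samples divide disjointly ⌊n/2⌋ / ⌈n/2⌉; a fraction λ of features is shared
and the remainder divides equally so p₁ = p₂ (s = round(λp), decremented by
one if the remainder is odd; explicit n₁/p₁/p₂ overrides allow unbalanced
variants). Study 2 receives uniform m/z noise on [−σ_M, σ_M] (σ_M = 0.01 Da),
the nonlinear drift f(x) = 1.1x + 1.3·sin(1.2x) applied to RTs *before*
uniform RT noise on [−σ_RT, σ_RT], and both studies receive independent
Gaussian intensity noise N(0, σ_FI²) added after the split on raw
intensities. Standard noise levels are (σ_RT, σ_FI) = (0.2, 0.1), (0.5,
0.5), (1, 1) for low/medium/high, with overlaps λ ∈ {0.25, 0.5, 0.75}. One
master seed spawns named independent streams per noise source, so enabling
one source never shifts another.

When no real base table is supplied, one is fabricated. Intensities follow
a block factor model: each feature loads on one of `n_blocks` latent
Gaussian factors (loading² uniform in [0.3, 0.9], unit total variance, plus
a per-feature baseline offset), giving the within-block correlation
structure the matcher exploits. m/z values are uniform on [70, 1000] Da
with pairwise gaps guaranteed above 2σ_M, except for a *collision fraction*
(default 0.3) of features placed within 1.5σ_M of another feature —
mimicking the near-isobaric clusters (isotopologues, adducts) that make
real m/z windows ambiguous. RTs are uniform on [0.5, 12] min. The defaults
(800 features → 100 blocks) are chosen as a realistic miniature of an
untargeted plasma dataset.

What the fabricated table does *not* emulate: real m/z mass-defect
clustering at full study scale (thousands of features), heavy-tailed and
heteroskedastic intensity distributions, structured missingness, and batch
effects. Consequently, passing benchmarks here demonstrate correct
mechanics and robustness ordering across noise/overlap conditions, not
field performance on any particular cohort. In particular, at this reduced
m/z density the false-positive rate under high noise is lower (precision
higher) than what full-scale runs on real data exhibit, because far fewer
m/z-confusable candidate pairs exist for the drift filter to mis-admit.

## Problem sizes and determinism

The shipped validation study runs 800 features × 400 samples with 5
repetitions per condition — a deliberate miniature chosen so the whole
study completes in minutes on a laptop core while preserving the design's
structure (the full-scale design uses thousands of features and 20
repetitions). All randomness flows from explicit seeds; solver runs are
deterministic (product-measure initialization), and repeated runs with the
same seed are bit-identical.

## Known limitations

- Two studies at a time; multi-study pooling aligns each donor to a chosen
  reference rather than solving a joint problem.
- The correlation-preservation assumption degrades across dissimilar
  populations.
- The absolute-difference distortion mode is restricted to small problems
  (dense 4-way tensor).
- Ties in the extraction stage are dropped, which can under-match in
  degenerate couplings (e.g., exactly duplicated features).
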