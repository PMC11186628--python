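# otmatch

Automatic alignment of metabolic features between two untargeted LC-MS
studies, using unbalanced Gromov–Wasserstein optimal transport on the
feature-intensity correlation structure, an m/z compatibility window, and a
learned retention-time drift.

## The problem

An untargeted LC-MS study produces a table of thousands of unannotated
*features*, each characterized by a mass-to-charge ratio (m/z), a retention
time (RT), and an intensity per biological sample. Pooling two studies
requires deciding which feature in study 1 is the same compound as which
feature in study 2 — but m/z carries measurement noise, RT shifts between
instruments by an unknown, often nonlinear *drift*, and the studies share
only a subset of their features. `otmatch` is for metabolomics researchers
and bioinformaticians who need this cross-study matching automated, with few
hyperparameters and no curated anchor set.

## The method

The key assumption is that a compound keeps its intensity-correlation
fingerprint across studies: if features *i, k* in study 1 are the same
compounds as *j, l* in study 2, then d(Xᵢ, Xₖ) ≈ d(Yⱼ, Yₗ) for a suitable
distance *d* between intensity vectors (here the normalized Euclidean
distance, which equals the cosine distance up to a constant on standardized
rows). The matcher therefore seeks a nonnegative coupling matrix Π over
feature pairs minimizing the distortion

E(Π) = Σᵢₖⱼₗ Πᵢⱼ Πₖₗ cost(dx(i,k), dy(j,l)),

relaxed by three KL terms (marginal relaxation ρ toward uniform reference
marginals a = 1/p₁, b = 1/p₂, allowing *partial* matching; entropic
smoothing ε enabling Sinkhorn iterations):

L(Π) = E(Π) + ρ·KL(Π₁⊗Π₁ ∥ a⊗a) + ρ·KL(Π₂⊗Π₂ ∥ b⊗b) + ε·KL(Π⊗Π ∥ (a⊗b)⊗²).

Entries with |m/zᵢ − m/zⱼ| beyond a gap (default 0.01 Da) are forced to
zero. The optimization runs a two-block alternating minimization with a
log-domain unbalanced Sinkhorn inner loop. The coupling then drives a
weighted cubic B-spline regression of the RT drift (L1 loss, knot count by
10-fold cross-validation); pairs whose residuals exceed robust thresholds
(two rounds at the 95% prediction interval 1.96·std, one final round at
2×MAD) are removed. Finally, entries that are the strict maximum of both
their row and column become the one-to-one matching. Presets: `gm` (no
thresholding) and `gmt` (drop entries below 0.3·max(Π) first).

Performance against known ground truth is scored by precision, recall and
F1, with Wilson score intervals for small validation subsets.

## Worked example

Split a correlated synthetic study into two noisy overlapping halves with a
known ground truth, then realign them:

```python
from otmatch import SplitConfig, generate_base_table, make_ground_truth_pair, score_matching
from otmatch.aligner import gm_aligner

base = generate_base_table(p=300, n=200, seed=7)
pair = make_ground_truth_pair(
    base, SplitConfig(overlap_lambda=0.5, sigma_rt=0.5, sigma_fi=0.5, seed=7)
)
aligner = gm_aligner(seed=0).fit(pair.study1, pair.study2)
scores = score_matching(aligner.matching_, pair.m_star)
print("matched pairs:", aligner.matching_.n_matches)
print("precision: %.3f  recall: %.3f" % (scores["precision"], scores["recall"]))
```

prints

```
matched pairs: 149
precision: 0.987  recall: 0.980
```

The two pseudo-studies here are 225 features × 100 samples each with 150
truly shared features; the aligner recovers 147 of them correctly (recall
0.980) with 2 false pairs (precision 0.987), despite the nonlinear RT drift
f(x) = 1.1x + 1.3·sin(1.2x) and moderate m/z, RT and intensity noise.
`aligner.matches(pair.study1, pair.study2)` tabulates the pairs with both
studies' m/z, RT and the coupling weight.

The same pipeline is available from the shell:

```bash
otmatch match study1.csv study2.csv --preset gm --out-dir results/
otmatch benchmark --synthetic --overlap 0.5 --noise medium --reps 5
```

Input CSVs need `feature_id`, `mz`, `rt` columns plus one column per sample
(complete intensities; impute upstream).

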