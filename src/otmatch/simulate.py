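"""Ground-truth simulation: dataset splitting, noise model, benchmarking.

Curated cross-study matchings are scarce, so alignment methods are
validated by *splitting* one real (or fabricated) feature table into two
overlapping pseudo-studies with a known ground-truth matching:

* samples are divided disjointly, floor(n/2) versus ceil(n/2);
* a random fraction lambda of the features is shared by both studies and
  the remainder is divided equally, so both studies keep the same feature
  count;
* study 2's m/z values receive uniform noise on [-sigma_m, sigma_m] (Da),
  its RTs are deviated by the nonlinear drift f(x) = 1.1 x + 1.3 sin(1.2 x)
  and then perturbed by uniform noise on [-sigma_rt, sigma_rt] (minutes),
  and both studies' intensities receive independent Gaussian noise of
  standard deviation sigma_fi.

A base table can also be fabricated from scratch: intensities follow a
block factor model (features within a block share a latent factor, giving
the correlation structure the matcher exploits), m/z values are mostly
well separated with a configurable fraction of near-isobaric "collision"
features mimicking the isotopologue/adduct clusters of real data, and RTs
are uniform over a typical chromatographic range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .aligner import gm_aligner
from .io import FeatureTable
from .matching import MatchingMatrix, extract_matching, threshold_coupling
from .metrics import score_matching

__all__ = [
    "SplitConfig",
    "GroundTruthPair",
    "rt_drift_function",
    "split_dataset",
    "apply_noise",
    "make_ground_truth_pair",
    "generate_base_table",
    "run_benchmark",
    "summarize_benchmark",
    "split_sizes",
    "NOISE_LEVELS",
    "OVERLAP_LEVELS",
]

# noise presets from the validation design: (sigma_rt, sigma_fi)
NOISE_LEVELS = {"low": (0.2, 0.1), "medium": (0.5, 0.5), "high": (1.0, 1.0)}
OVERLAP_LEVELS = {"low": 0.25, "medium": 0.5, "high": 0.75}


@dataclass(frozen=True)
class SplitConfig:
    """Parameters of one simulated study pair.

    ``overlap_lambda`` is the fraction of base features shared by both
    studies; sigma_m (Da), sigma_rt (min) and sigma_fi are the half-widths /
    standard deviation of the m/z, RT and intensity noise. ``n1``/``p1``/
    ``p2`` optionally override the balanced split sizes.
    """

    overlap_lambda: float = 0.5
    sigma_m: float = 0.01
    sigma_rt: float = 0.5
    sigma_fi: float = 0.5
    apply_drift: bool = True
    seed: int = 0
    n1: int | None = None
    p1: int | None = None
    p2: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_lambda <= 1.0:
            raise ValueError("overlap_lambda must lie in [0, 1]")
        if min(self.sigma_m, self.sigma_rt, self.sigma_fi) < 0:
            raise ValueError("noise magnitudes must be nonnegative")


@dataclass(frozen=True)
class GroundTruthPair:
    study1: FeatureTable
    study2: FeatureTable
    m_star: MatchingMatrix


def rt_drift_function(x: np.ndarray) -> np.ndarray:
    """The systematic inter-study RT deviation f(x) = 1.1 x + 1.3 sin(1.2 x)."""
    x = np.asarray(x, dtype=float)
    return 1.1 * x + 1.3 * np.sin(1.2 * x)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named independent random streams, so adding one never shifts another."""
    names = (
        "samples", "features", "order1", "order2",
        "mz_noise", "rt_noise", "fi_noise1", "fi_noise2",
    )
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def split_sizes(p: int, overlap_lambda: float) -> tuple[int, int]:
    """Shared-feature count s and per-study feature count p1 = p2.

    s = round(lambda * p), decremented by one when p - s is odd so the
    study-specific remainder divides equally.
    """
    s = int(round(overlap_lambda * p))
    if (p - s) % 2:
        s -= 1
    if s < 0:
        raise ValueError("overlap too small for this feature count")
    return s, s + (p - s) // 2


def split_dataset(base: FeatureTable, config: SplitConfig) -> GroundTruthPair:
    """Divide a base table into two sample-disjoint, feature-overlapping studies.

    Returns the noise-free pair; apply :func:`apply_noise` afterwards.
    """
    p, n = base.n_features, base.n_samples
    if p < 4:
        raise ValueError("need at least 4 features to split")
    streams = _streams(config.seed)

    n1 = n // 2 if config.n1 is None else config.n1
    sample_perm = streams["samples"].permutation(n)
    samples1, samples2 = np.sort(sample_perm[:n1]), np.sort(sample_perm[n1:])

    s, p_each = split_sizes(p, config.overlap_lambda)
    feat_perm = streams["features"].permutation(p)
    shared = feat_perm[:s]
    rest = feat_perm[s:]
    if config.p1 is not None or config.p2 is not None:
        k1 = (config.p1 or p_each) - s
        k2 = (config.p2 or p_each) - s
        if k1 < 0 or k2 < 0 or k1 + k2 > rest.size:
            raise ValueError("p1/p2 overrides incompatible with overlap")
    else:
        k1 = k2 = rest.size // 2
    only1, only2 = rest[:k1], rest[k1 : k1 + k2]

    feats1 = np.concatenate([shared, only1])
    feats2 = np.concatenate([shared, only2])
    order1 = streams["order1"].permutation(feats1.size)
    order2 = streams["order2"].permutation(feats2.size)
    feats1, feats2 = feats1[order1], feats2[order2]

    def build(feats: np.ndarray, samples: np.ndarray, tag: str) -> FeatureTable:
        sub = base.subset(feats, samples)
        return replace(
            sub,
            feature_ids=tuple(f"{tag}_{fid}" for fid in sub.feature_ids),
        )

    study1 = build(feats1, samples1, "S1")
    study2 = build(feats2, samples2, "S2")

    pos2 = {feat: j for j, feat in enumerate(feats2)}
    m = np.zeros((feats1.size, feats2.size), dtype=bool)
    for i, feat in enumerate(feats1):
        j = pos2.get(feat)
        if j is not None:
            m[i, j] = True
    return GroundTruthPair(study1=study1, study2=study2, m_star=MatchingMatrix(m=m))


def apply_noise(pair: GroundTruthPair, config: SplitConfig) -> GroundTruthPair:
    """Perturb the pair per the noise model; the ground truth is unchanged.

    Study 2's m/z get uniform noise on [-sigma_m, sigma_m]; its RTs are
    passed through the drift (if enabled) and then get uniform noise on
    [-sigma_rt, sigma_rt]; both studies' intensities get independent
    N(0, sigma_fi^2) noise.
    """
    streams = _streams(config.seed)
    t1, t2 = pair.study1, pair.study2

    mz2 = t2.mz + streams["mz_noise"].uniform(-config.sigma_m, config.sigma_m, t2.n_features)
    rt2 = rt_drift_function(t2.rt) if config.apply_drift else t2.rt.copy()
    rt2 = rt2 + streams["rt_noise"].uniform(-config.sigma_rt, config.sigma_rt, t2.n_features)
    rt2 = np.maximum(rt2, 0.0)

    int1 = t1.intensities + streams["fi_noise1"].normal(0.0, config.sigma_fi, t1.intensities.shape) \
        if config.sigma_fi > 0 else t1.intensities
    int2 = t2.intensities + streams["fi_noise2"].normal(0.0, config.sigma_fi, t2.intensities.shape) \
        if config.sigma_fi > 0 else t2.intensities

    return GroundTruthPair(
        study1=replace(t1, intensities=int1),
        study2=replace(t2, mz=mz2, rt=rt2, intensities=int2),
        m_star=pair.m_star,
    )


def make_ground_truth_pair(base: FeatureTable, config: SplitConfig) -> GroundTruthPair:
    """Split then perturb: the full generative step for one validation pair."""
    return apply_noise(split_dataset(base, config), config)


def generate_base_table(
    p: int,
    n: int,
    n_blocks: int | None = None,
    seed: int = 0,
    collision_fraction: float = 0.3,
    sigma_m: float = 0.01,
    mz_range: tuple[float, float] = (70.0, 1000.0),
    rt_range: tuple[float, float] = (0.5, 12.0),
) -> FeatureTable:
    """Fabricate a correlated base feature table.

    Intensities follow a block factor model: each feature loads (uniform
    loading in [0.3, 0.9]) on one of ``n_blocks`` latent Gaussian factors,
    plus idiosyncratic noise, for unit total variance and a per-feature
    baseline offset.  A ``collision_fraction`` of the features is placed
    within 1.5 * sigma_m of another feature's m/z (near-isobaric clusters);
    the rest keep pairwise m/z gaps above 2 * sigma_m.
    """
    if p < 2 or n < 2:
        raise ValueError("need p, n >= 2")
    if n_blocks is None:
        n_blocks = max(1, p // 8)
    rng = np.random.default_rng(seed)

    block = rng.integers(0, n_blocks, size=p)
    factors = rng.normal(size=(n_blocks, n))
    loading = rng.uniform(0.3, 0.9, size=p)
    noise = rng.normal(size=(p, n))
    intensities = (
        np.sqrt(loading)[:, None] * factors[block]
        + np.sqrt(1.0 - loading)[:, None] * noise
        + rng.normal(0.0, 1.0, size=p)[:, None]
    )

    n_coll = int(round(collision_fraction * p))
    n_sep = p - n_coll
    gap = 2.5 * sigma_m
    lo, hi = mz_range
    u = np.sort(rng.uniform(lo, hi - gap * n_sep, size=n_sep))
    mz_sep = u + gap * np.arange(n_sep)
    partners = rng.integers(0, n_sep, size=n_coll)
    mz_coll = mz_sep[partners] + rng.uniform(-1.5 * sigma_m, 1.5 * sigma_m, size=n_coll)
    mz = np.concatenate([mz_sep, mz_coll])
    order = rng.permutation(p)
    mz = mz[order]

    rt = rng.uniform(rt_range[0], rt_range[1], size=p)
    return FeatureTable(
        feature_ids=tuple(f"F{i:05d}" for i in range(p)),
        mz=mz,
        rt=rt,
        intensities=intensities,
        sample_ids=tuple(f"S{j:04d}" for j in range(n)),
    )


def _method_matchings(
    methods: list,
    pair: GroundTruthPair,
    seed: int,
) -> dict[str, MatchingMatrix]:
    """Run each requested method on the pair.

    The named presets ``"gm"`` and ``"gmt"`` share one solver/drift run
    (they differ only in the final thresholding), so requesting both costs
    a single fit.  Entries may also be ``(name, callable)`` where the
    callable maps (table1, table2) to a MatchingMatrix.
    """
    out: dict[str, MatchingMatrix] = {}
    preset_names = [m for m in methods if m in ("gm", "gmt")]
    if preset_names:
        aligner = gm_aligner(seed=seed).fit(pair.study1, pair.study2)
        if "gm" in preset_names:
            out["gm"] = aligner.matching_
        if "gmt" in preset_names:
            out["gmt"] = extract_matching(threshold_coupling(aligner.coupling_, 0.3))
    for entry in methods:
        if entry in ("gm", "gmt"):
            continue
        name, fn = entry
        out[name] = fn(pair.study1, pair.study2)
    return out


def run_benchmark(
    base: FeatureTable,
    grid: list[SplitConfig],
    n_reps: int = 20,
    methods: list | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Score methods against ground truth across conditions and repetitions.

    Returns one row per (condition, repetition, method) with the confusion
    counts and precision/recall/F1 against the planted matching.
    """
    methods = methods or ["gm", "gmt"]
    rows = []
    for cond_idx, config in enumerate(grid):
        for rep in range(n_reps):
            rep_seed = int(
                np.random.SeedSequence((seed, cond_idx, rep)).generate_state(1)[0] % (2**31)
            )
            cfg = replace(config, seed=rep_seed)
            pair = make_ground_truth_pair(base, cfg)
            for name, matching in _method_matchings(methods, pair, rep_seed).items():
                scores = score_matching(matching, pair.m_star)
                rows.append(
                    {
                        "condition": cond_idx,
                        "overlap": config.overlap_lambda,
                        "sigma_rt": config.sigma_rt,
                        "sigma_fi": config.sigma_fi,
                        "rep": rep,
                        "method": name,
                        "n_matches": matching.n_matches,
                        **scores,
                    }
                )
    return pd.DataFrame(rows)


def summarize_benchmark(report: pd.DataFrame) -> pd.DataFrame:
    """Per-condition, per-method mean precision/recall/F1."""
    return (
        report.groupby(["condition", "overlap", "sigma_rt", "sigma_fi", "method"])[
            ["precision", "recall", "f1"]
        ]
        .mean()
        .reset_index()
    )
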