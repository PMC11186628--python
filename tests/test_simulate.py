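import numpy as np
import pytest

from otmatch.simulate import (
    SplitConfig,
    apply_noise,
    generate_base_table,
    make_ground_truth_pair,
    rt_drift_function,
    run_benchmark,
    split_dataset,
    split_sizes,
    summarize_benchmark,
)


class TestSplitSizes:
    @pytest.mark.parametrize(
        "p, lam, s_expected, p_each",
        [
            (4712, 0.5, 2356, 3534),
            (100, 0.25, 24, 62),   # 25 shared leaves odd remainder, parity drops to 24
            (100, 1.0, 100, 100),
            (8, 0.5, 4, 6),
        ],
    )
    def test_arithmetic(self, p, lam, s_expected, p_each):
        s, pe = split_sizes(p, lam)
        assert s == s_expected and pe == p_each
        assert (p - s) % 2 == 0


class TestSplitDataset:
    def test_sample_halves(self):
        base = generate_base_table(40, 499, seed=0)
        pair = split_dataset(base, SplitConfig(seed=1))
        assert pair.study1.n_samples == 249
        assert pair.study2.n_samples == 250

    def test_sample_disjointness_and_feature_overlap(self):
        base = generate_base_table(60, 30, seed=0)
        pair = split_dataset(base, SplitConfig(overlap_lambda=0.5, seed=2))
        s, p_each = split_sizes(60, 0.5)
        assert pair.study1.n_features == pair.study2.n_features == p_each
        assert pair.m_star.n_matches == s
        # sample-disjoint: the two studies share no base sample columns
        assert not set(pair.study1.sample_ids) & set(pair.study2.sample_ids)

    def test_full_overlap_is_permutation_matching(self):
        base = generate_base_table(20, 12, seed=0)
        pair = split_dataset(base, SplitConfig(overlap_lambda=1.0, seed=3))
        assert pair.m_star.n_matches == 20
        assert np.all(pair.m_star.m.sum(axis=0) == 1)
        assert np.all(pair.m_star.m.sum(axis=1) == 1)

    def test_matched_features_share_base_values(self):
        base = generate_base_table(30, 16, seed=5)
        pair = split_dataset(base, SplitConfig(overlap_lambda=0.5, seed=4))
        for i, j in pair.m_star.pairs:
            assert pair.study1.mz[i] == pair.study2.mz[j]
            assert pair.study1.rt[i] == pair.study2.rt[j]

    def test_unbalanced_overrides(self):
        base = generate_base_table(40, 20, seed=0)
        cfg = SplitConfig(overlap_lambda=0.5, seed=1, n1=7, p1=25, p2=27)
        pair = split_dataset(base, cfg)
        assert pair.study1.n_samples == 7 and pair.study2.n_samples == 13
        assert pair.study1.n_features == 25 and pair.study2.n_features == 27


class TestApplyNoise:
    def test_zero_noise_no_drift_is_identity(self):
        base = generate_base_table(20, 10, seed=0)
        cfg = SplitConfig(sigma_m=0, sigma_rt=0, sigma_fi=0, apply_drift=False, seed=6)
        pair = split_dataset(base, cfg)
        noisy = apply_noise(pair, cfg)
        np.testing.assert_array_equal(noisy.study2.mz, pair.study2.mz)
        np.testing.assert_array_equal(noisy.study2.rt, pair.study2.rt)
        np.testing.assert_array_equal(noisy.study1.intensities, pair.study1.intensities)

    def test_drift_function_value(self):
        assert rt_drift_function(1.0) == pytest.approx(1.1 + 1.3 * np.sin(1.2), abs=1e-4)
        assert rt_drift_function(1.0) == pytest.approx(2.3116, abs=1e-4)

    def test_mz_noise_bounded_by_sigma(self):
        base = generate_base_table(50, 10, seed=0)
        cfg = SplitConfig(sigma_m=0.01, sigma_rt=0, sigma_fi=0, apply_drift=False, seed=7)
        pair = split_dataset(base, cfg)
        noisy = apply_noise(pair, cfg)
        assert np.max(np.abs(noisy.study2.mz - pair.study2.mz)) <= 0.01
        assert np.any(noisy.study2.mz != pair.study2.mz)

    def test_drift_applied_before_rt_noise(self):
        base = generate_base_table(30, 10, seed=0)
        cfg = SplitConfig(sigma_m=0, sigma_rt=0.2, sigma_fi=0, apply_drift=True, seed=8)
        pair = split_dataset(base, cfg)
        noisy = apply_noise(pair, cfg)
        resid = noisy.study2.rt - rt_drift_function(pair.study2.rt)
        assert np.max(np.abs(resid)) <= 0.2 + 1e-12

    def test_ground_truth_unchanged(self):
        base = generate_base_table(30, 10, seed=0)
        cfg = SplitConfig(seed=9)
        pair = split_dataset(base, cfg)
        noisy = apply_noise(pair, cfg)
        np.testing.assert_array_equal(noisy.m_star.m, pair.m_star.m)

    def test_reproducible_from_seed(self):
        base = generate_base_table(25, 12, seed=0)
        cfg = SplitConfig(seed=11)
        a = make_ground_truth_pair(base, cfg)
        b = make_ground_truth_pair(base, cfg)
        np.testing.assert_array_equal(a.study2.mz, b.study2.mz)
        np.testing.assert_array_equal(a.study1.intensities, b.study1.intensities)
        np.testing.assert_array_equal(a.m_star.m, b.m_star.m)


class TestGenerateBaseTable:
    def test_deterministic(self):
        a = generate_base_table(50, 40, seed=21)
        b = generate_base_table(50, 40, seed=21)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        np.testing.assert_array_equal(a.mz, b.mz)

    def test_block_count_controls_correlation(self):
        dense = generate_base_table(60, 200, n_blocks=1, seed=3)
        sparse = generate_base_table(60, 200, n_blocks=25, seed=3)

        def mean_abs_corr(t):
            c = np.corrcoef(t.intensities)
            return np.mean(np.abs(c[np.triu_indices_from(c, 1)]))

        assert mean_abs_corr(dense) > mean_abs_corr(sparse)

    def test_valid_feature_table(self):
        t = generate_base_table(80, 30, seed=1)
        assert t.n_features == 80 and t.n_samples == 30
        assert np.all(t.mz > 0) and np.all(t.rt >= 0)

    def test_separated_fraction_has_guaranteed_gaps(self):
        t = generate_base_table(100, 10, seed=2, collision_fraction=0.0, sigma_m=0.01)
        gaps = np.diff(np.sort(t.mz))
        assert np.min(gaps) > 0.02

    def test_collisions_present_by_default(self):
        t = generate_base_table(200, 10, seed=2)
        gaps = np.diff(np.sort(t.mz))
        assert np.min(gaps) < 0.02  # near-isobaric cluster exists


@pytest.fixture(scope="module")
def small_report():
    base = generate_base_table(60, 60, seed=13)
    grid = [
        SplitConfig(overlap_lambda=1.0, sigma_m=0.0, sigma_rt=0.0, sigma_fi=0.0, apply_drift=False)
    ]
    return run_benchmark(base, grid, n_reps=2, methods=["gm", "gmt"], seed=5)


class TestRunBenchmark:
    def test_exact_recovery_on_clean_full_overlap(self, small_report):
        assert np.all(small_report["precision"] == 1.0)
        assert np.all(small_report["recall"] == 1.0)

    def test_report_shape(self, small_report):
        assert len(small_report) == 1 * 2 * 2  # grid x reps x methods

    def test_deterministic_given_seed(self):
        base = generate_base_table(50, 40, seed=13)
        grid = [SplitConfig(overlap_lambda=0.5)]
        r1 = run_benchmark(base, grid, n_reps=2, methods=["gm"], seed=7)
        r2 = run_benchmark(base, grid, n_reps=2, methods=["gm"], seed=7)
        assert r1.equals(r2)

    def test_summary_means(self, small_report):
        s = summarize_benchmark(small_report)
        assert set(s["method"]) == {"gm", "gmt"}
        assert np.all(s["precision"] == 1.0)
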