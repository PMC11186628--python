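import numpy as np
import pytest

from otmatch.drift import (
    DriftError,
    compute_residual_stats,
    drift_filter_pipeline,
    filter_coupling,
    fit_drift,
)
from otmatch.simulate import rt_drift_function
from otmatch.ugw import Coupling


def identity_coupling(p, weight=None):
    w = 1.0 / p if weight is None else weight
    return Coupling(pi=np.eye(p) * w, a=np.full(p, 1.0 / p), b=np.full(p, 1.0 / p))


def sorted_rts(p, seed=1, lo=0.5, hi=12.0):
    return np.sort(np.random.default_rng(seed).uniform(lo, hi, p))


class TestFitDrift:
    def test_identity_drift_recovered(self):
        rt = sorted_rts(100)
        model = fit_drift(identity_coupling(100), rt, rt, seed=0)
        grid = np.linspace(rt.min(), rt.max(), 300)
        assert np.max(np.abs(model.predict(grid) - grid)) < 1e-3

    def test_nonlinear_drift_recovered_within_tolerance(self):
        rt = sorted_rts(200)
        model = fit_drift(identity_coupling(200), rt, rt_drift_function(rt), seed=0)
        interior = np.linspace(np.quantile(rt, 0.05), np.quantile(rt, 0.95), 500)
        err = np.max(np.abs(model.predict(interior) - rt_drift_function(interior)))
        assert err < 0.05

    def test_zero_weight_pairs_do_not_influence_fit(self):
        p = 80
        rt_x = sorted_rts(p)
        rt_y = rt_x.copy()
        pi = np.eye(p) / p
        cpl_a = Coupling(pi=pi, a=np.full(p, 1 / p), b=np.full(p, 1 / p))
        # perturb the RT of a pair that has zero coupling weight
        rt_y_perturbed = rt_y.copy()
        pi_b = pi.copy()
        pi_b[3, 3] = 0.0
        rt_y_b = rt_y.copy()
        rt_y_b[3] += 100.0
        cpl_b = Coupling(pi=pi_b, a=cpl_a.a, b=cpl_a.b)
        m_a = fit_drift(Coupling(pi=pi_b, a=cpl_a.a, b=cpl_a.b), rt_x, rt_y_perturbed, seed=0)
        m_b = fit_drift(cpl_b, rt_x, rt_y_b, seed=0)
        np.testing.assert_allclose(m_a.coefficients, m_b.coefficients, atol=1e-10)

    def test_l1_and_l2_agree_on_noiseless_data(self):
        rt = sorted_rts(150)
        rt_y = rt_drift_function(rt)
        cpl = identity_coupling(150)
        grid = np.linspace(rt.min(), rt.max(), 200)
        m1 = fit_drift(cpl, rt, rt_y, seed=0, loss="l1")
        m2 = fit_drift(cpl, rt, rt_y, seed=0, loss="l2")
        np.testing.assert_allclose(m1.predict(grid), m2.predict(grid), atol=1e-3)

    def test_too_few_pairs_raises(self):
        rt = sorted_rts(5)
        with pytest.raises(DriftError, match="rho"):
            fit_drift(identity_coupling(5), rt, rt, seed=0)


class TestResidualStats:
    def test_small_example_arithmetic(self):
        # residuals {0, 0, 0, 10}: population std 4.330, PI 8.487, median 0, MAD 0
        p = 4
        rt_x = np.array([1.0, 2.0, 3.0, 4.0])
        rt_y = np.array([1.0, 2.0, 3.0, 14.0])

        class Flat:
            def predict(self, x):
                return np.asarray(x, dtype=float)

        stats = compute_residual_stats(Flat(), identity_coupling(p), rt_x, rt_y)
        np.testing.assert_allclose(np.sort(stats.residuals), [0, 0, 0, 10])
        assert stats.mu_r == 0.0
        assert stats.PI == pytest.approx(1.96 * 4.330127, rel=1e-6)
        assert stats.MAD == 0.0

    def test_constant_residuals(self):
        rt_x = np.array([1.0, 2.0, 3.0])
        rt_y = rt_x + 2.0

        class Flat:
            def predict(self, x):
                return np.asarray(x, dtype=float)

        stats = compute_residual_stats(Flat(), identity_coupling(3), rt_x, rt_y)
        assert stats.mu_r == pytest.approx(2.0) and stats.MAD == 0.0

    def test_empty_support_raises(self):
        cpl = Coupling(pi=np.zeros((3, 3)), a=np.full(3, 1 / 3), b=np.full(3, 1 / 3))

        class Flat:
            def predict(self, x):
                return np.asarray(x, dtype=float)

        with pytest.raises(DriftError, match="empty"):
            compute_residual_stats(Flat(), cpl, np.ones(3), np.ones(3))


class TestFilterCoupling:
    def _stats(self, residuals):
        from otmatch.drift import ResidualStats

        r = np.asarray(residuals, dtype=float)
        mu = float(np.median(r))
        return ResidualStats(
            pairs=np.column_stack([np.arange(len(r)), np.arange(len(r))]),
            residuals=r,
            PI=1.96 * float(np.std(r)),
            MAD=float(np.median(np.abs(r - mu))),
            mu_r=mu,
        )

    def test_pi_threshold_removes_only_outlier(self):
        stats = self._stats([0, 0, 0, 10])
        cpl = identity_coupling(4)
        out = filter_coupling(cpl, stats, r_thresh=stats.PI)
        assert out.pi[3, 3] == 0.0
        assert np.all(np.diag(out.pi)[:3] > 0)

    def test_zero_threshold_keeps_exact_fits(self):
        stats = self._stats([0.0, 0.0, 0.0])
        out = filter_coupling(identity_coupling(3), stats, r_thresh=0.0)
        assert np.all(np.diag(out.pi) > 0)

    def test_infinite_threshold_is_identity(self):
        stats = self._stats([1.0, 5.0, 9.0])
        cpl = identity_coupling(3)
        out = filter_coupling(cpl, stats, r_thresh=np.inf)
        np.testing.assert_array_equal(out.pi, cpl.pi)

    def test_surviving_entries_unchanged(self):
        stats = self._stats([0, 0, 0, 10])
        cpl = identity_coupling(4, weight=0.123)
        out = filter_coupling(cpl, stats, r_thresh=stats.PI)
        np.testing.assert_allclose(np.diag(out.pi)[:3], 0.123)


class TestPipeline:
    def test_noiseless_drift_removes_nothing(self):
        rt = sorted_rts(120)
        cpl = identity_coupling(120)
        out, model = drift_filter_pipeline(cpl, rt, rt_drift_function(rt), seed=0)
        assert out.support.shape[0] == 120

    def test_planted_outliers_removed_clean_retained(self):
        p = 200
        rng = np.random.default_rng(4)
        rt_x = sorted_rts(p, seed=4)
        rt_y = rt_drift_function(rt_x)
        out_idx = rng.choice(p, 10, replace=False)
        rt_y[out_idx] += 5.0
        filtered, _ = drift_filter_pipeline(identity_coupling(p), rt_x, rt_y, seed=0)
        kept = set(filtered.support[:, 0])
        assert all(i not in kept for i in out_idx)
        clean = [i for i in range(p) if i not in out_idx]
        assert sum(i in kept for i in clean) >= 0.95 * len(clean)

    def test_support_shrinks_monotonically(self):
        p = 150
        rng = np.random.default_rng(9)
        rt_x = sorted_rts(p, seed=9)
        rt_y = rt_drift_function(rt_x) + rng.uniform(-0.5, 0.5, p)
        cpl = identity_coupling(p)
        out, _ = drift_filter_pipeline(cpl, rt_x, rt_y, seed=0)
        in_support = set(map(tuple, cpl.support))
        assert set(map(tuple, out.support)) <= in_support
        # surviving weights unchanged
        for i, j in out.support:
            assert out.pi[i, j] == cpl.pi[i, j]

    def test_permutation_invariance(self):
        p = 100
        rt_x = sorted_rts(p, seed=2)
        rt_y = rt_drift_function(rt_x)
        perm = np.random.default_rng(0).permutation(p)
        cpl = identity_coupling(p)
        out, _ = drift_filter_pipeline(cpl, rt_x, rt_y, seed=0)
        pi_perm = cpl.pi[perm][:, perm]
        out_perm, _ = drift_filter_pipeline(
            Coupling(pi=pi_perm, a=cpl.a, b=cpl.b), rt_x[perm], rt_y[perm], seed=0
        )
        np.testing.assert_allclose(out_perm.pi, out.pi[perm][:, perm], atol=1e-12)
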