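"""Retention-time drift estimation and residual-based match filtering.

Chromatographic retention times shift between studies, often nonlinearly.
The drift f mapping study-1 RT to study-2 RT is estimated from the coupling
by weighted B-spline regression under an L1 loss,

    min_{f in splines(order, knots)}  sum_ij Pi_ij |f(RT_i^x) - RT_j^y|,

so that confidently coupled pairs dominate the fit.  The spline order is
cubic by default; the interior knot count is chosen by weighted k-fold
cross-validation over a small grid, with knots placed at weighted quantiles
of the support RTs.  The L1 objective is minimized by iteratively reweighted
least squares (IRLS) on the B-spline basis.

Pairs inconsistent with the fitted drift are then discarded: with residuals
r_ij = |f(RT_i^x) - RT_j^y| over the coupling support, the 95% prediction
interval PI = 1.96 * std(r), the median mu_r, and the median absolute
deviation MAD = median(|r - mu_r|) give thresholds.  A pair survives when
r <= mu_r + r_thresh (with a tiny additive floor so an exact fit, where all
residuals and the MAD are zero, keeps every pair).  The standard pipeline
runs two preliminary fit/filter rounds at r_thresh = PI and a final, more
stringent round at r_thresh = 2 * MAD.

The pipeline additionally floors each round's threshold at a minimum RT
tolerance (default 0.01 min, about half a second): residual differences
below chromatographic time resolution carry no information, and without
the floor the data-driven thresholds collapse to the spline approximation
error on (near-)noiseless data and discard valid pairs.  Under realistic
RT noise the data-driven thresholds are far larger and the floor is inert.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import BSpline

from .ugw import Coupling

__all__ = [
    "DriftModel",
    "ResidualStats",
    "DriftError",
    "fit_drift",
    "compute_residual_stats",
    "filter_coupling",
    "drift_filter_pipeline",
]

_SURVIVAL_FLOOR = 1e-12  # keeps exact fits (MAD = 0) from discarding everything
_IRLS_ROUNDS = 3
_IRLS_DELTA = 1e-6


class DriftError(RuntimeError):
    pass


@dataclass(frozen=True)
class DriftModel:
    """Fitted B-spline drift map from study-1 RT to study-2 RT (minutes)."""

    order: int
    knots: np.ndarray  # interior knots
    coefficients: np.ndarray
    cv_score: float
    x_range: tuple[float, float]

    def _bspline(self) -> BSpline:
        lo, hi = self.x_range
        t = np.concatenate(
            [np.full(self.order + 1, lo), self.knots, np.full(self.order + 1, hi)]
        )
        return BSpline(t, self.coefficients, self.order)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the drift; inputs are clamped to the fitted RT range."""
        lo, hi = self.x_range
        return self._bspline()(np.clip(np.asarray(x, dtype=float), lo, hi))

    __call__ = predict


@dataclass(frozen=True)
class ResidualStats:
    """Residuals of the coupling support against a drift model."""

    pairs: np.ndarray  # (k, 2) support index pairs
    residuals: np.ndarray
    PI: float
    MAD: float
    mu_r: float


def _support(coupling: Coupling) -> tuple[np.ndarray, np.ndarray]:
    pairs = coupling.support
    weights = coupling.pi[pairs[:, 0], pairs[:, 1]]
    return pairs, weights


def _design(x: np.ndarray, interior: np.ndarray, order: int, lo: float, hi: float) -> np.ndarray:
    t = np.concatenate([np.full(order + 1, lo), interior, np.full(order + 1, hi)])
    return BSpline.design_matrix(np.clip(x, lo, hi), t, order).toarray()


def _wls_l1(B: np.ndarray, y: np.ndarray, w: np.ndarray, l1: bool) -> np.ndarray:
    """Weighted least squares, optionally IRLS-reweighted toward the L1 loss."""
    weights = w.copy()
    coef = None
    rounds = _IRLS_ROUNDS if l1 else 1
    for _ in range(rounds):
        sw = np.sqrt(weights)
        coef, *_ = np.linalg.lstsq(B * sw[:, None], y * sw, rcond=None)
        if l1:
            res = np.abs(B @ coef - y)
            weights = w / np.maximum(res, _IRLS_DELTA)
    return coef


def _weighted_quantile_knots(x: np.ndarray, w: np.ndarray, k: int, lo: float, hi: float) -> np.ndarray:
    order_idx = np.argsort(x)
    xs, ws = x[order_idx], w[order_idx]
    cw = np.cumsum(ws)
    cw = cw / cw[-1]
    q = (np.arange(1, k + 1)) / (k + 1)
    knots = np.interp(q, cw, xs)
    knots = knots[(knots > lo) & (knots < hi)]
    return np.unique(knots)


def fit_drift(
    coupling: Coupling,
    rt_x: np.ndarray,
    rt_y: np.ndarray,
    order: int = 3,
    knot_grid: tuple[int, ...] = (3, 5, 7, 10, 15),
    cv_folds: int = 10,
    seed: int = 0,
    loss: str = "l1",
) -> DriftModel:
    """Fit the RT drift spline on the coupling support, selecting knots by CV.

    Only pairs with positive coupling weight enter the fit, each weighted by
    its coupling coefficient.  ``loss="l2"`` switches to plain weighted least
    squares (the two agree on noiseless data).
    """
    rt_x = np.asarray(rt_x, dtype=float)
    rt_y = np.asarray(rt_y, dtype=float)
    pairs, weights = _support(coupling)
    n_pairs = pairs.shape[0]
    min_needed = order + max(knot_grid) + 1
    if n_pairs < max(min_needed, cv_folds):
        raise DriftError(
            f"only {n_pairs} coupled pairs support the drift fit; "
            "relaxing rho or eps yields a denser coupling"
        )
    x = rt_x[pairs[:, 0]]
    y = rt_y[pairs[:, 1]]
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise DriftError("degenerate RT support: all support RTs identical")
    l1 = loss == "l1"

    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(n_pairs) % cv_folds

    best = None
    for k in knot_grid:
        interior = _weighted_quantile_knots(x, weights, k, lo, hi)
        try:
            fold_losses = []
            for fold in range(cv_folds):
                tr = fold_of != fold
                te = ~tr
                if te.sum() == 0 or tr.sum() <= len(interior) + order + 1:
                    continue
                xtr = x[tr]
                # knots must bracket training data for the design matrix
                kn = interior[(interior > xtr.min()) & (interior < xtr.max())]
                B_tr = _design(xtr, kn, order, lo, hi)
                coef = _wls_l1(B_tr, y[tr], weights[tr], l1)
                B_te = _design(x[te], kn, order, lo, hi)
                err = np.abs(B_te @ coef - y[te]) if l1 else (B_te @ coef - y[te]) ** 2
                fold_losses.append(float(np.sum(weights[te] * err) / np.sum(weights[te])))
            if not fold_losses:
                continue
            score = float(np.mean(fold_losses))
        except np.linalg.LinAlgError:
            continue
        if best is None or score < best[0]:
            best = (score, interior)
    if best is None:
        raise DriftError("no knot configuration admitted a stable spline fit")
    score, interior = best
    B = _design(x, interior, order, lo, hi)
    coef = _wls_l1(B, y, weights, l1)
    return DriftModel(
        order=order,
        knots=interior,
        coefficients=coef,
        cv_score=score,
        x_range=(lo, hi),
    )


def compute_residual_stats(
    drift: DriftModel, coupling: Coupling, rt_x: np.ndarray, rt_y: np.ndarray
) -> ResidualStats:
    """Absolute drift residuals over the coupling support with PI/MAD statistics."""
    rt_x = np.asarray(rt_x, dtype=float)
    rt_y = np.asarray(rt_y, dtype=float)
    pairs, _ = _support(coupling)
    if pairs.shape[0] == 0:
        raise DriftError("empty coupling support: no residuals to compute")
    r = np.abs(drift.predict(rt_x[pairs[:, 0]]) - rt_y[pairs[:, 1]])
    mu_r = float(np.median(r))
    pi95 = 1.96 * float(np.std(r))  # population convention
    mad = float(np.median(np.abs(r - mu_r)))
    return ResidualStats(pairs=pairs, residuals=r, PI=pi95, MAD=mad, mu_r=mu_r)


def filter_coupling(coupling: Coupling, stats: ResidualStats, r_thresh: float) -> Coupling:
    """Zero out support pairs whose residual exceeds mu_r + r_thresh."""
    if r_thresh < 0:
        raise ValueError("r_thresh must be nonnegative")
    keep = stats.residuals <= stats.mu_r + r_thresh + _SURVIVAL_FLOOR
    pi = coupling.pi.copy()
    drop = stats.pairs[~keep]
    pi[drop[:, 0], drop[:, 1]] = 0.0
    return replace(coupling, pi=pi)


def drift_filter_pipeline(
    coupling: Coupling,
    rt_x: np.ndarray,
    rt_y: np.ndarray,
    order: int = 3,
    knot_grid: tuple[int, ...] = (3, 5, 7, 10, 15),
    cv_folds: int = 10,
    seed: int = 0,
    loss: str = "l1",
    min_r_thresh: float = 0.01,
) -> tuple[Coupling, DriftModel]:
    """Two PI-threshold rounds of fit/filter, then one final 2*MAD round.

    ``min_r_thresh`` (minutes) floors each round's threshold; see the module
    docstring.
    """
    fit_kw = dict(order=order, knot_grid=knot_grid, cv_folds=cv_folds, loss=loss)
    current = coupling
    drift = None
    for round_idx, thresh_kind in enumerate(("PI", "PI", "MAD")):
        drift = fit_drift(current, rt_x, rt_y, seed=seed + round_idx, **fit_kw)
        stats = compute_residual_stats(drift, current, rt_x, rt_y)
        r_thresh = stats.PI if thresh_kind == "PI" else 2.0 * stats.MAD
        current = filter_coupling(current, stats, max(r_thresh, min_r_thresh))
    return current, drift
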