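"""The alignment estimator tying the pipeline together.

:class:`UGWFeatureAligner` is a scikit-learn style estimator: construct it
with hyperparameters, call ``fit(table_x, table_y)``, then read the fitted
attributes (``coupling_``, ``drift_``, ``matching_``).  The pipeline is

1. optionally center and scale each study's feature intensities,
2. compute intra-study distance matrices,
3. solve the masked unbalanced Gromov-Wasserstein problem for a coupling,
4. estimate the RT drift and filter drift-incompatible pairs,
5. optionally threshold small coupling weights (tau), and
6. extract a one-to-one matching.

Two named presets mirror the method's published variants: ``gm`` (no
thresholding) and ``gmt`` (tau = 0.3).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .distances import pairwise_distance
from .drift import drift_filter_pipeline
from .io import AlignmentConfig, FeatureTable, center_scale, matches_dataframe
from .matching import MatchingMatrix, extract_matching, threshold_coupling
from .ugw import build_mz_mask, ugw_solve

__all__ = ["UGWFeatureAligner", "gm_aligner", "gmt_aligner", "align", "PRESETS"]


class UGWFeatureAligner(BaseEstimator):
    """Match features of two LC-MS studies by unbalanced Gromov-Wasserstein.

    Parameters
    ----------
    metric : {"normalized_euclidean", "cosine"}
        Intra-study distance between feature-intensity vectors.
    center_scale : bool
        Standardize each feature row (mean 0, population SD 1) before
        computing distances; robust to cross-study intensity-scale shifts.
    rho : float
        Marginal-relaxation weight; larger values push more features to match.
    eps : float
        Entropic smoothing; larger values are more stable but less sharp.
    m_gap : float
        m/z compatibility window (Daltons for ``mz_mode="absolute"``,
        parts-per-million for ``mz_mode="ppm"``).
    tau : float in [0, 1]
        Coupling threshold before extraction; 0 disables (GM), 0.3 is GMT.
    drift_filter : bool
        Run the RT-drift estimation and PI/MAD filtering stage.
    seed : int
        Seeds the drift cross-validation shuffling (the solver itself is
        deterministic).

    Attributes
    ----------
    raw_coupling_ : Coupling
        Solver output before drift filtering.
    coupling_ : Coupling
        Coupling after drift filtering (and before tau-thresholding).
    drift_ : DriftModel or None
        Fitted RT drift map (None when drift filtering is disabled or the
        coupling is empty).
    matching_ : MatchingMatrix
        Final one-to-one partial matching.
    report_ : SolverReport
        Objective trace and convergence information of the solver.
    """

    def __init__(
        self,
        *,
        metric: str = "normalized_euclidean",
        center_scale: bool = True,
        rho: float = 0.05,
        eps: float = 0.005,
        m_gap: float = 0.01,
        mz_mode: str = "absolute",
        tau: float = 0.0,
        drift_filter: bool = True,
        spline_order: int = 3,
        knot_grid: tuple[int, ...] = (3, 5, 7, 10, 15),
        cv_folds: int = 10,
        max_outer: int = 200,
        max_inner: int = 500,
        tol: float = 1e-6,
        cost: str = "sqr",
        seed: int = 0,
    ) -> None:
        self.metric = metric
        self.center_scale = center_scale
        self.rho = rho
        self.eps = eps
        self.m_gap = m_gap
        self.mz_mode = mz_mode
        self.tau = tau
        self.drift_filter = drift_filter
        self.spline_order = spline_order
        self.knot_grid = knot_grid
        self.cv_folds = cv_folds
        self.max_outer = max_outer
        self.max_inner = max_inner
        self.tol = tol
        self.cost = cost
        self.seed = seed

    @classmethod
    def from_config(cls, config: AlignmentConfig, **overrides) -> "UGWFeatureAligner":
        params = {
            "metric": config.metric,
            "center_scale": config.center_scale,
            "rho": config.rho,
            "eps": config.eps,
            "m_gap": config.m_gap,
            "mz_mode": config.mz_mode,
            "tau": config.tau,
            "spline_order": config.spline_order,
            "knot_grid": config.knot_grid,
            "cv_folds": config.cv_folds,
            "max_outer": config.max_outer,
            "max_inner": config.max_inner,
            "tol": config.tol,
            "cost": config.cost,
            "seed": config.seed,
        }
        params.update(overrides)
        return cls(**params)

    def fit(self, X: FeatureTable, y: FeatureTable) -> "UGWFeatureAligner":
        """Align study X (rows of the matching) with study y (columns)."""
        t1, t2 = X, y
        if self.center_scale:
            t1, t2 = center_scale(t1), center_scale(t2)
        Dx = pairwise_distance(t1.intensities, metric=self.metric)
        Dy = pairwise_distance(t2.intensities, metric=self.metric)
        mask = build_mz_mask(t1.mz, t2.mz, self.m_gap, mode=self.mz_mode)
        self.raw_coupling_, self.report_ = ugw_solve(
            Dx,
            Dy,
            mask=mask,
            rho=self.rho,
            eps=self.eps,
            max_outer=self.max_outer,
            max_inner=self.max_inner,
            tol=self.tol,
            cost=self.cost,
            seed=self.seed,
        )
        self.drift_ = None
        coupling = self.raw_coupling_
        if self.drift_filter and coupling.mass > 0:
            coupling, self.drift_ = drift_filter_pipeline(
                coupling,
                t1.rt,
                t2.rt,
                order=self.spline_order,
                knot_grid=self.knot_grid,
                cv_folds=self.cv_folds,
                seed=self.seed,
            )
        self.coupling_ = coupling
        self.matching_ = extract_matching(threshold_coupling(coupling, self.tau))
        return self

    def predict(self, X: FeatureTable, y: FeatureTable) -> MatchingMatrix:
        """Fit on the pair and return the matching (fit-and-return shorthand)."""
        return self.fit(X, y).matching_

    def matches(self, X: FeatureTable, y: FeatureTable):
        """DataFrame of matched pairs for the tables the estimator was fit on."""
        return matches_dataframe(self.matching_, self.coupling_, X, y)


def gm_aligner(**overrides) -> UGWFeatureAligner:
    """The default pipeline without thresholding (preset GM)."""
    return UGWFeatureAligner(**{"tau": 0.0, **overrides})


def gmt_aligner(**overrides) -> UGWFeatureAligner:
    """The pipeline with the tau = 0.3 thresholding step (preset GMT)."""
    return UGWFeatureAligner(**{"tau": 0.3, **overrides})


PRESETS = {"gm": gm_aligner, "gmt": gmt_aligner}


def align(
    table_x: FeatureTable,
    table_y: FeatureTable,
    preset: str = "gm",
    **overrides,
) -> MatchingMatrix:
    """One-call alignment of two feature tables with a named preset."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return PRESETS[preset](**overrides).fit(table_x, table_y).matching_
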