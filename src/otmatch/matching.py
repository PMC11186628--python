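"""Coupling post-processing: thresholding, one-to-one extraction, pooling.

The filtered coupling can still contain small weights and multiple
candidates per feature.  An optional thresholding step removes entries
below a fraction tau of the largest coupling weight; the final matching
keeps only pairs (i, j) whose weight is the strict maximum of both its row
and its column, yielding a binary partial matching with at most one match
per feature.  Matched studies can then be pooled into a single wide table,
reference features by rows, with missing markers where a feature has no
match in a donor study.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import FeatureTable
from .ugw import Coupling

__all__ = [
    "MatchingMatrix",
    "PooledTable",
    "threshold_coupling",
    "extract_matching",
    "pool_datasets",
]


@dataclass(frozen=True)
class MatchingMatrix:
    """Binary partial matching: at most one nonzero per row and per column."""

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m)
        if m.dtype != bool:
            if not np.isin(m, (0, 1)).all():
                raise ValueError("matching matrix must be binary")
            m = m.astype(bool)
        object.__setattr__(self, "m", m)
        if np.any(m.sum(axis=1) > 1) or np.any(m.sum(axis=0) > 1):
            raise ValueError("matching must have at most one match per row and column")

    @property
    def n_matches(self) -> int:
        return int(self.m.sum())

    @property
    def pairs(self) -> np.ndarray:
        """Matched index pairs, shape (n_matches, 2)."""
        return np.argwhere(self.m)


@dataclass(frozen=True)
class PooledTable:
    """Reference-study features pooled with matched samples from other studies."""

    intensities: np.ndarray  # p_ref x (n_ref + sum n_other), NaN where unmatched
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    study_of_sample: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{s}:{c}" for s, c in zip(self.study_of_sample, self.sample_ids)]
        return pd.DataFrame(self.intensities, index=list(self.feature_ids), columns=cols)


def threshold_coupling(coupling: Coupling, tau: float) -> Coupling:
    """Zero out entries below tau * max(Pi); tau = 0 leaves the coupling unchanged."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    if tau == 0.0:
        return coupling
    cutoff = tau * coupling.pi.max()
    pi = np.where(coupling.pi >= cutoff, coupling.pi, 0.0)
    return replace(coupling, pi=pi)


def extract_matching(coupling: Coupling | np.ndarray) -> MatchingMatrix:
    """Keep pairs whose weight is the strict maximum of both its row and column.

    Tied maxima are dropped entirely (no arbitrary winner), which preserves
    the at-most-one-per-row/column invariant.
    """
    pi = coupling.pi if isinstance(coupling, Coupling) else np.asarray(coupling, dtype=float)
    if np.any(pi < 0):
        raise ValueError("coupling must be nonnegative")
    if pi.size == 0 or pi.max() == 0:
        return MatchingMatrix(m=np.zeros(pi.shape, dtype=bool))
    row_max = pi.max(axis=1, keepdims=True)
    col_max = pi.max(axis=0, keepdims=True)
    at_row_max = (pi == row_max) & (pi > 0)
    at_col_max = (pi == col_max) & (pi > 0)
    unique_in_row = at_row_max.sum(axis=1, keepdims=True) == 1
    unique_in_col = at_col_max.sum(axis=0, keepdims=True) == 1
    m = at_row_max & at_col_max & unique_in_row & unique_in_col
    return MatchingMatrix(m=m)


def pool_datasets(
    reference: FeatureTable,
    others: list[FeatureTable],
    matchings: list[MatchingMatrix],
    study_labels: list[str] | None = None,
) -> PooledTable:
    """Assemble the pooled intensity matrix across the reference and donor studies.

    Rows are the reference study's features.  For each donor study, a matched
    reference feature receives the donor feature's intensities in that study's
    sample columns; unmatched reference features get missing values there.
    """
    if len(others) != len(matchings):
        raise ValueError("need one matching per donor study")
    labels = study_labels or [f"study{k + 2}" for k in range(len(others))]
    p_ref = reference.n_features
    blocks = [reference.intensities]
    sample_ids = list(reference.sample_ids)
    study_of = ["reference"] * reference.n_samples
    for table, matching, label in zip(others, matchings, labels):
        if matching.m.shape != (p_ref, table.n_features):
            raise ValueError(
                f"matching shape {matching.m.shape} inconsistent with reference "
                f"({p_ref}) and donor ({table.n_features})"
            )
        block = np.full((p_ref, table.n_samples), np.nan)
        for i, j in matching.pairs:
            block[i] = table.intensities[j]
        blocks.append(block)
        sample_ids.extend(table.sample_ids)
        study_of.extend([label] * table.n_samples)
    return PooledTable(
        intensities=np.hstack(blocks),
        feature_ids=reference.feature_ids,
        sample_ids=tuple(sample_ids),
        study_of_sample=tuple(study_of),
    )
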