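"""Feature tables and delimited-file I/O.

An untargeted LC-MS study is represented here as a :class:`FeatureTable`:
one row per metabolic feature, each carrying a mass-to-charge ratio (m/z,
Daltons), a retention time (RT, minutes) and a vector of intensities across
that study's biological samples.  Tables are read from and written to plain
CSV (comma-separated, UTF-8, header row required).

Intensity matrices must be complete: imputation is an upstream
preprocessing concern and the readers refuse tables with missing cells
rather than silently filling them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "AlignmentConfig",
    "FormatError",
    "ValidationError",
    "read_feature_table",
    "write_feature_table",
    "center_scale",
    "write_matches",
    "matches_dataframe",
]


class FormatError(ValueError):
    """A delimited input file does not have the expected layout."""


class ValidationError(ValueError):
    """A table violates a FeatureTable invariant."""


@dataclass(frozen=True)
class FeatureTable:
    """One study's feature table.

    Parameters
    ----------
    feature_ids : sequence of str, length p
        Opaque feature identifiers, kept verbatim.
    mz : array, shape (p,)
        Mass-to-charge ratios in Daltons; strictly positive.
    rt : array, shape (p,)
        Retention times in minutes; nonnegative.
    intensities : array, shape (p, n)
        Feature intensities, one column per sample. No missing values.
    sample_ids : sequence of str, length n
    """

    feature_ids: tuple[str, ...]
    mz: np.ndarray
    rt: np.ndarray
    intensities: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "rt", np.asarray(self.rt, dtype=float))
        object.__setattr__(
            self, "intensities", np.atleast_2d(np.asarray(self.intensities, dtype=float))
        )
        self._validate()

    def _validate(self) -> None:
        p, n = self.intensities.shape
        if not (len(self.feature_ids) == len(self.mz) == len(self.rt) == p):
            raise ValidationError(
                f"inconsistent feature dimensions: {len(self.feature_ids)} ids, "
                f"{len(self.mz)} m/z, {len(self.rt)} RT, {p} intensity rows"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} intensity columns"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError(
                "intensity matrix contains missing or non-finite values; "
                "impute upstream before alignment"
            )
        if not np.all(self.mz > 0):
            raise ValidationError("m/z values must be strictly positive")
        if not np.all(self.rt >= 0) or not np.all(np.isfinite(self.rt)):
            raise ValidationError("RT values must be finite and nonnegative")
        if len(set(self.feature_ids)) != p:
            raise ValidationError("feature ids must be unique")

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def subset(self, rows: np.ndarray, cols: np.ndarray | None = None) -> "FeatureTable":
        """Return a new table restricted to the given feature rows (and sample columns)."""
        rows = np.asarray(rows)
        cols = np.arange(self.n_samples) if cols is None else np.asarray(cols)
        return FeatureTable(
            feature_ids=tuple(self.feature_ids[i] for i in rows),
            mz=self.mz[rows],
            rt=self.rt[rows],
            intensities=self.intensities[np.ix_(rows, cols)],
            sample_ids=tuple(self.sample_ids[j] for j in cols),
        )

    def to_frame(self, mz_col: str = "mz", rt_col: str = "rt", id_col: str = "feature_id") -> pd.DataFrame:
        df = pd.DataFrame({id_col: list(self.feature_ids), mz_col: self.mz, rt_col: self.rt})
        return pd.concat(
            [df, pd.DataFrame(self.intensities, columns=list(self.sample_ids))], axis=1
        )


@dataclass(frozen=True)
class AlignmentConfig:
    """Hyperparameters of the alignment pipeline.

    ``rho`` weighs the KL relaxation of the coupling marginals (larger values
    push more features to be matched), ``eps`` the entropic smoothing of the
    coupling; both default to the smallest values under which the solver is
    stable (0.05 and 0.005).  ``m_gap`` is the m/z compatibility window in
    Daltons (``mz_mode="ppm"`` reinterprets it as parts-per-million).  ``tau``
    is the optional coupling threshold applied before one-to-one extraction:
    0 disables it (the GM preset); 0.3 is the GMT preset.
    """

    metric: str = "normalized_euclidean"
    center_scale: bool = True
    rho: float = 0.05
    eps: float = 0.005
    m_gap: float = 0.01
    mz_mode: str = "absolute"
    tau: float = 0.0
    spline_order: int = 3
    knot_grid: tuple[int, ...] = (3, 5, 7, 10, 15)
    cv_folds: int = 10
    max_outer: int = 200
    max_inner: int = 500
    tol: float = 1e-6
    cost: str = "sqr"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.eps <= 0:
            raise ValueError("rho and eps must be positive")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        if self.metric not in ("normalized_euclidean", "cosine"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.mz_mode not in ("absolute", "ppm"):
            raise ValueError(f"unknown mz_mode {self.mz_mode!r}")


def read_feature_table(
    path: str | Path,
    mz_col: str = "mz",
    rt_col: str = "rt",
    id_col: str = "feature_id",
) -> FeatureTable:
    """Read a feature table from CSV.

    The named columns carry the feature metadata; every remaining column is
    treated as one sample, in file order.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in (id_col, mz_col, rt_col):
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} not found")
    sample_cols = [c for c in df.columns if c not in (id_col, mz_col, rt_col)]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns found")
    intensities = df[sample_cols].to_numpy(dtype=float)
    if np.isnan(intensities).any():
        bad = int(np.isnan(intensities).sum())
        raise ValidationError(
            f"{path}: {bad} missing intensity value(s); impute before alignment"
        )
    return FeatureTable(
        feature_ids=tuple(df[id_col].astype(str)),
        mz=df[mz_col].to_numpy(dtype=float),
        rt=df[rt_col].to_numpy(dtype=float),
        intensities=intensities,
        sample_ids=tuple(sample_cols),
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def center_scale(table: FeatureTable) -> FeatureTable:
    """Standardize each feature's intensity row to mean 0, standard deviation 1.

    Uses the population convention (divisor n), so a standardized row u has
    ||u||^2 = n and the normalized Euclidean distance between two standardized
    rows equals sqrt(2 * cosine distance) of the raw rows.
    """
    mean = table.intensities.mean(axis=1, keepdims=True)
    std = table.intensities.std(axis=1, keepdims=True)  # population (ddof=0)
    zero = np.flatnonzero(std.ravel() == 0)
    if zero.size:
        names = ", ".join(table.feature_ids[i] for i in zero[:5])
        raise ValidationError(
            f"zero-variance feature(s) cannot be scaled: {names}"
            + ("..." if zero.size > 5 else "")
        )
    return replace(table, intensities=(table.intensities - mean) / std)


def matches_dataframe(matching, coupling, t1: FeatureTable, t2: FeatureTable) -> pd.DataFrame:
    """Tabulate matched pairs with both studies' m/z, RT and the coupling weight."""
    m = np.asarray(matching.m if hasattr(matching, "m") else matching)
    pi = np.asarray(coupling.pi if hasattr(coupling, "pi") else coupling)
    if m.shape != (t1.n_features, t2.n_features) or pi.shape != m.shape:
        raise ValidationError(
            f"matching shape {m.shape} / coupling shape {pi.shape} inconsistent with "
            f"tables ({t1.n_features}, {t2.n_features})"
        )
    rows_i, rows_j = np.nonzero(m)
    return pd.DataFrame(
        {
            "feature_id_1": [t1.feature_ids[i] for i in rows_i],
            "feature_id_2": [t2.feature_ids[j] for j in rows_j],
            "mz_1": t1.mz[rows_i],
            "mz_2": t2.mz[rows_j],
            "rt_1": t1.rt[rows_i],
            "rt_2": t2.rt[rows_j],
            "weight": pi[rows_i, rows_j],
        }
    )


def write_matches(matching, coupling, t1: FeatureTable, t2: FeatureTable, path: str | Path) -> None:
    """Write one CSV row per matched feature pair (ids, m/z, RT, coupling weight)."""
    matches_dataframe(matching, coupling, t1, t2).to_csv(path, index=False)
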