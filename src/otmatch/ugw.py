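"""Unbalanced Gromov-Wasserstein solver with an m/z compatibility mask.

The matcher seeks a nonnegative coupling matrix Pi (p1 x p2) that puts weight
on feature pairs whose intra-study distance patterns agree:

    E(Pi) = sum_{i,k,j,l} Pi_ij Pi_kl cost(Dx_ik, Dy_jl)

relaxed by three KL penalties (marginal relaxation rho on rows and columns,
entropic smoothing eps toward the product reference measure a x b):

    L(Pi) = E(Pi) + rho KL(Pi_1 x Pi_1 | a x a)
                  + rho KL(Pi_2 x Pi_2 | b x b)
                  + eps KL(Pi x Pi | (a x b)^2)

with uniform reference marginals a_i = 1/p1, b_j = 1/p2 and the generalized
KL divergence KL(mu|nu) = sum mu ln(mu/nu) - sum mu + sum nu (0 ln 0 := 0).
Relaxing the marginals is what permits *partial* matching: features present
in only one study simply carry little or no coupling mass.

Optimization is by two-block alternating minimization on the bilinear
relaxation L(pi, gamma) (the two factors of the quadratic objective are
decoupled; at a fixed point pi = gamma and the relaxation coincides with
L(Pi)).  With one factor frozen, the problem in the other is an unbalanced
entropic linear OT problem with a tensorized local cost, solved by a
log-domain unbalanced Sinkhorn loop followed by the optimal mass-rescaling
step; each block update can only decrease L(pi, gamma), so the recorded
objective trace is non-increasing up to the inner solver tolerance.  Pairs
whose m/z differ by more than the compatibility gap are excluded by adding
a prohibitive constant to the local cost and hard-zeroing both factors
after every outer iteration.

The default per-entry cost is the squared difference (dx - dy)^2, which is
what the tensorized update factorizes; an absolute-difference mode |dx - dy|
is available for small problems via a dense 4-way tensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .distances import DistanceMatrix

__all__ = [
    "Coupling",
    "MzMask",
    "SolverReport",
    "SolverError",
    "build_mz_mask",
    "ugw_objective",
    "ugw_solve",
]

_MASK_COST = 1e9  # prohibitive local cost at m/z-incompatible cells


class SolverError(RuntimeError):
    """Numerical failure during Sinkhorn iterations.

    Usually remedied by increasing the entropic weight eps, which smooths the
    coupling and stabilizes the iterations.
    """


@dataclass(frozen=True)
class MzMask:
    """Boolean matrix of m/z-compatible feature pairs."""

    allowed: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "allowed", np.asarray(self.allowed, dtype=bool))


@dataclass(frozen=True)
class Coupling:
    """Soft matching weights Pi with the uniform reference marginals a, b."""

    pi: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if np.any(pi < 0):
            raise ValueError("coupling entries must be nonnegative")
        if not np.all(np.isfinite(pi)):
            raise ValueError("coupling entries must be finite")

    @property
    def mass(self) -> float:
        return float(self.pi.sum())

    @property
    def support(self) -> np.ndarray:
        """Index pairs (i, j) with nonzero weight, shape (k, 2)."""
        return np.argwhere(self.pi > 0)


@dataclass
class SolverReport:
    objective_trace: list = field(default_factory=list)
    n_outer_iterations: int = 0
    converged: bool = False
    final_mass: float = 0.0


def build_mz_mask(mz_x: np.ndarray, mz_y: np.ndarray, m_gap: float, mode: str = "absolute") -> MzMask:
    """Mark feature pairs whose m/z values are compatible.

    ``mode="absolute"`` compares |mx - my| <= m_gap in Daltons (inclusive);
    ``mode="ppm"`` compares the relative gap |mx - my| / mx * 1e6 <= m_gap.
    """
    if m_gap <= 0:
        raise ValueError("m_gap must be positive")
    mx = np.asarray(mz_x, dtype=float)[:, None]
    my = np.asarray(mz_y, dtype=float)[None, :]
    diff = np.abs(mx - my)
    # inclusive boundary, robust to float representation of Da-scale values
    if mode == "absolute":
        allowed = diff <= m_gap + 1e-12
    elif mode == "ppm":
        allowed = diff <= m_gap * 1e-6 * mx + 1e-12
    else:
        raise ValueError(f"unknown mz mode {mode!r}")
    return MzMask(allowed=allowed)


def _gkl(mu: np.ndarray, nu: np.ndarray, nu_total: float | None = None) -> float:
    """Generalized KL divergence sum mu ln(mu/nu) - sum mu + sum nu, 0 ln 0 := 0.

    ``nu_total`` overrides sum(nu) when mu covers only the support of a larger
    reference measure (entries of nu outside mu's support enter only through
    their total mass).
    """
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    pos = mu > 0
    total_nu = float(nu.sum()) if nu_total is None else float(nu_total)
    entropy = float(np.sum(mu[pos] * np.log(mu[pos] / nu[pos])))
    return entropy - float(mu.sum()) + total_nu


def _quad_kl(mu: np.ndarray, nu: np.ndarray, nu_total: float) -> float:
    """KL(mu x mu | nu x nu) = 2 m(mu) KL(mu|nu) + (m(mu) - m(nu))^2."""
    m = float(mu.sum())
    return 2.0 * m * _gkl(mu, nu, nu_total) + (m - nu_total) ** 2


def _abs_cost_tensor(Dx: np.ndarray, Dy: np.ndarray) -> np.ndarray:
    p1, p2 = Dx.shape[0], Dy.shape[0]
    if p1 * p2 > 10_000:
        raise ValueError("absolute-cost mode builds a dense 4-way tensor; use it on small problems only")
    # shape (p1, p2, p1, p2): |Dx_ik - Dy_jl|
    return np.abs(Dx[:, None, :, None] - Dy[None, :, None, :])


def _distortion(pi: np.ndarray, Dx: np.ndarray, Dy: np.ndarray, cost: str) -> float:
    if cost == "sqr":
        p1 = pi.sum(axis=1)
        p2 = pi.sum(axis=0)
        local = (Dx**2 @ p1)[:, None] + (Dy**2 @ p2)[None, :] - 2.0 * (Dx @ pi @ Dy)
        return float(np.sum(pi * local))
    if cost == "abs":
        T = _abs_cost_tensor(Dx, Dy)
        return float(np.einsum("ij,ijkl,kl->", pi, T, pi))
    raise ValueError(f"unknown cost {cost!r}")


def ugw_objective(
    coupling: Coupling,
    Dx: DistanceMatrix | np.ndarray,
    Dy: DistanceMatrix | np.ndarray,
    rho: float,
    eps: float,
    cost: str = "abs",
) -> float:
    """Evaluate the relaxed objective L(Pi) at a coupling.

    By default the distortion term uses the absolute-difference cost
    |dx - dy|; pass ``cost="sqr"`` for the squared cost the fast solver
    minimizes.
    """
    Dx = Dx.values if isinstance(Dx, DistanceMatrix) else np.asarray(Dx, dtype=float)
    Dy = Dy.values if isinstance(Dy, DistanceMatrix) else np.asarray(Dy, dtype=float)
    pi = coupling.pi
    a, b = coupling.a, coupling.b
    ma, mb = float(a.sum()), float(b.sum())
    obj = _distortion(pi, Dx, Dy, cost)
    obj += rho * _quad_kl(pi.sum(axis=1), a, ma)
    obj += rho * _quad_kl(pi.sum(axis=0), b, mb)
    ab = a[:, None] * b[None, :]
    obj += eps * _quad_kl(pi.ravel(), ab.ravel(), ma * mb)
    return obj


def _local_cost(
    pi: np.ndarray,
    Dx: np.ndarray,
    Dy: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    rho: float,
    eps: float,
    cost: str,
    abs_tensor: np.ndarray | None,
) -> np.ndarray:
    """Tensorized cost of the linear OT subproblem at the current iterate."""
    mu = pi.sum(axis=1)
    nu = pi.sum(axis=0)
    if cost == "sqr":
        lcost = (Dx**2 @ mu)[:, None] + (Dy**2 @ nu)[None, :] - 2.0 * (Dx @ pi @ Dy)
    else:
        lcost = np.einsum("ijkl,kl->ij", abs_tensor, pi)
    pos = mu > 0
    lcost = lcost + rho * float(np.sum(mu[pos] * np.log(mu[pos] / a[pos])))
    pos = nu > 0
    lcost = lcost + rho * float(np.sum(nu[pos] * np.log(nu[pos] / b[pos])))
    ppos = pi > 0
    ab = a[:, None] * b[None, :]
    lcost = lcost + eps * float(np.sum(pi[ppos] * np.log(pi[ppos] / ab[ppos])))
    return lcost


def _sinkhorn(
    lcost: np.ndarray,
    log_a: np.ndarray,
    log_b: np.ndarray,
    eps_hat: float,
    rho_hat: float,
    f: np.ndarray,
    g: np.ndarray,
    max_inner: int,
    inner_tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-domain unbalanced Sinkhorn for the local linear problem."""
    lam = rho_hat / (rho_hat + eps_hat)
    C = lcost / eps_hat
    for _ in range(max_inner):
        g_new = -lam * eps_hat * logsumexp(
            (f / eps_hat)[:, None] - C + log_a[:, None], axis=0
        )
        f_new = -lam * eps_hat * logsumexp(
            (g_new / eps_hat)[None, :] - C + log_b[None, :], axis=1
        )
        delta = np.max(np.abs(f_new - f))
        f, g = f_new, g_new
        if delta < inner_tol:
            break
    return f, g


def ugw_solve(
    Dx: DistanceMatrix | np.ndarray,
    Dy: DistanceMatrix | np.ndarray,
    mask: MzMask | None = None,
    rho: float = 0.05,
    eps: float = 0.005,
    max_outer: int = 200,
    max_inner: int = 500,
    tol: float = 1e-6,
    cost: str = "sqr",
    seed: int | None = None,
    marginals: str = "uniform",
) -> tuple[Coupling, SolverReport]:
    """Minimize the relaxed objective, returning the coupling and a report.

    Rows and columns without any m/z-compatible partner carry no coupling
    mass; the solver restricts the Sinkhorn iterations to the remaining
    active block, which makes the cost scale with the number of compatible
    features rather than the full table sizes.  ``seed`` is accepted for API
    symmetry; the solver is deterministic (product-measure initialization).

    ``marginals="uniform"`` (default) uses a_i = 1/p1, b_j = 1/p2;
    ``marginals="ones"`` uses the unnormalized ones vectors.
    """
    Dx = Dx.values if isinstance(Dx, DistanceMatrix) else np.asarray(Dx, dtype=float)
    Dy = Dy.values if isinstance(Dy, DistanceMatrix) else np.asarray(Dy, dtype=float)
    if rho <= 0 or eps <= 0:
        raise ValueError("rho and eps must be positive")
    p1, p2 = Dx.shape[0], Dy.shape[0]
    if marginals == "uniform":
        a_full = np.full(p1, 1.0 / p1)
        b_full = np.full(p2, 1.0 / p2)
    elif marginals == "ones":
        a_full = np.ones(p1)
        b_full = np.ones(p2)
    else:
        raise ValueError(f"unknown marginals {marginals!r}")

    allowed = np.ones((p1, p2), dtype=bool) if mask is None else mask.allowed
    if allowed.shape != (p1, p2):
        raise ValueError("mask shape inconsistent with distance matrices")

    report = SolverReport()
    rows = np.flatnonzero(allowed.any(axis=1))
    cols = np.flatnonzero(allowed.any(axis=0))
    if rows.size == 0 or cols.size == 0:
        # the feasible set is {0}
        pi0 = np.zeros((p1, p2))
        report.converged = True
        coupling = Coupling(pi=pi0, a=a_full, b=b_full)
        report.objective_trace.append(ugw_objective(coupling, Dx, Dy, rho, eps, cost="sqr"))
        return coupling, report

    Dxs = Dx[np.ix_(rows, rows)]
    Dys = Dy[np.ix_(cols, cols)]
    sub_mask = allowed[np.ix_(rows, cols)]
    a = a_full[rows]
    b = b_full[cols]
    ma, mb = float(a_full.sum()), float(b_full.sum())
    log_a = np.log(a)
    log_b = np.log(b)
    abs_tensor = _abs_cost_tensor(Dxs, Dys) if cost == "abs" else None

    pi = np.where(sub_mask, a[:, None] * b[None, :], 0.0)
    ga = pi.copy()
    f_pi = np.zeros(rows.size)
    g_pi = np.zeros(cols.size)
    f_ga = f_pi.copy()
    g_ga = g_pi.copy()
    ab = a[:, None] * b[None, :]

    def _bilinear_kl(mu: np.ndarray, nu: np.ndarray, alpha: np.ndarray, m_alpha: float) -> float:
        # KL(mu x nu | alpha x alpha) for possibly different factors
        mm, mn = float(mu.sum()), float(nu.sum())
        return (
            mn * _gkl(mu, alpha, m_alpha)
            + mm * _gkl(nu, alpha, m_alpha)
            + (mm - m_alpha) * (mn - m_alpha)
        )

    def pair_objective(p: np.ndarray, g: np.ndarray) -> float:
        if cost == "sqr":
            g1, g2 = g.sum(axis=1), g.sum(axis=0)
            local = (Dxs**2 @ g1)[:, None] + (Dys**2 @ g2)[None, :] - 2.0 * (Dxs @ g @ Dys)
            obj = float(np.sum(p * local))
        else:
            obj = float(np.einsum("ij,ijkl,kl->", p, abs_tensor, g))
        obj += rho * _bilinear_kl(p.sum(axis=1), g.sum(axis=1), a, ma)
        obj += rho * _bilinear_kl(p.sum(axis=0), g.sum(axis=0), b, mb)
        obj += eps * _bilinear_kl(p.ravel(), g.ravel(), ab.ravel(), ma * mb)
        return obj

    def block_update(other: np.ndarray, f: np.ndarray, g: np.ndarray):
        """Exact minimization over one factor with the other frozen."""
        m_other = float(other.sum())
        lcost = _local_cost(other, Dxs, Dys, a, b, rho, eps, cost, abs_tensor)
        lcost[~sub_mask] = _MASK_COST
        eps_hat = eps * m_other
        rho_hat = rho * m_other
        f, g = _sinkhorn(lcost, log_a, log_b, eps_hat, rho_hat, f, g, max_inner, tol * eps_hat)
        log_new = (f[:, None] + g[None, :] - lcost) / eps_hat + log_a[:, None] + log_b[None, :]
        new = np.exp(np.clip(log_new, -745.0, 700.0))
        new[~sub_mask] = 0.0
        m_new = float(new.sum())
        if m_new > 0:
            new *= np.sqrt(m_other / m_new)
        return new, f, g

    report.objective_trace.append(pair_objective(pi, ga))
    with np.errstate(over="raise", divide="ignore", under="ignore", invalid="raise"):
        for it in range(max_outer):
            if float(ga.sum()) <= 0 or float(pi.sum()) <= 0:
                pi = np.zeros_like(pi)
                ga = np.zeros_like(ga)
                report.converged = True
                break
            pi_prev = pi
            try:
                pi, f_pi, g_pi = block_update(ga, f_pi, g_pi)
                ga, f_ga, g_ga = block_update(pi, f_ga, g_ga)
            except FloatingPointError as exc:  # pragma: no cover - defensive
                raise SolverError(
                    "non-finite values during Sinkhorn iterations; "
                    "increasing eps improves numerical stability"
                ) from exc
            if not (np.all(np.isfinite(pi)) and np.all(np.isfinite(ga))):
                raise SolverError(
                    "non-finite coupling during iteration; "
                    "increasing eps improves numerical stability"
                )
            report.objective_trace.append(pair_objective(pi, ga))
            report.n_outer_iterations = it + 1
            delta = max(
                float(np.max(np.abs(pi - pi_prev))), float(np.max(np.abs(pi - ga)))
            )
            if delta < tol:
                report.converged = True
                break
    pi = ga  # last block update; equals pi within tol at convergence

    pi_full = np.zeros((p1, p2))
    pi_full[np.ix_(rows, cols)] = pi
    pi_full[~allowed] = 0.0
    report.final_mass = float(pi_full.sum())
    return Coupling(pi=pi_full, a=a_full, b=b_full), report
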