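"""Maximum-entropy bipartite binary configuration model (BiCM).

The BiCM is the canonical-ensemble null model for a binary bipartite
network: among all probability distributions over matrices with the same
shape, it is the maximum-entropy one whose *expected* degree sequence
equals the observed degree sequence (a soft constraint — individual draws
fluctuate around it).  The solution factorizes over entries, with
connection probabilities

    p_ij = x_i * y_j / (1 + x_i * y_j)

controlled by one positive Lagrange multiplier per node (x_i for plant
rows, y_j for fungal columns; equivalently theta_i = -log x_i on the
exponential scale).  The multipliers solving the expected-degree equations
also maximize the Bernoulli log-likelihood of the observed matrix, so the
fit is a maximum-likelihood estimate.

Solver strategy: nodes whose degree equals the size of the opposite layer
(or whose remaining degree hits zero during peeling) are handled exactly —
their probabilities are forced to 1 (or 0) by the p <= 1 bound and they
are removed from the interior system.  The interior is reduced to one
unknown per distinct degree (degree-class reduction), solved by the
fixed-point iteration x_i <- k_i / sum_j y_j / (1 + x_i y_j), with a
quasi-Newton least-squares refinement in log-parameter space if the
residual stalls.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize

from .incidence import BipartiteIncidence, IncidenceError

__all__ = [
    "BiCMFit",
    "ConvergenceError",
    "connection_probability",
    "fit_bicm",
    "expected_degrees",
    "log_likelihood",
    "sample_ensemble",
    "iter_ensemble",
]


class ConvergenceError(RuntimeError):
    """Solver failed to reach the degree-residual tolerance."""

    def __init__(self, message: str, residual_trace: list[float]):
        super().__init__(message)
        self.residual_trace = residual_trace


def connection_probability(x, y):
    """Connection probability p = x*y / (1 + x*y) of the BiCM.

    Accepts scalars or arrays; monotone increasing in each argument,
    always in [0, 1) for finite inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("multipliers must be non-negative")
    xy = x * y
    with np.errstate(invalid="ignore"):
        p = np.where(np.isinf(xy), 1.0, xy / (1.0 + xy))
    return float(p) if p.ndim == 0 else p


@dataclasses.dataclass(frozen=True)
class BiCMFit:
    """Fitted BiCM: multipliers, connection probabilities, diagnostics.

    ``x`` and ``y`` hold the per-node multipliers; nodes whose
    probabilities were forced by the bounds carry the limiting values
    ``inf`` (all-ones row/column) or ``0`` (remaining degree zero after
    peeling).  ``p`` is the dense probability matrix, ``residual`` the max
    absolute difference between expected and observed degrees,
    ``degenerate`` flags a fit whose entire matrix is forced (the null
    ensemble then contains a single matrix).
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray
    p: np.ndarray
    residual: float
    iterations: int
    loglik: float
    degenerate: bool

    @property
    def theta(self) -> np.ndarray:
        """Row multipliers on the exponential scale, theta_i = -log x_i."""
        with np.errstate(divide="ignore"):
            return -np.log(self.x)

    @property
    def shape(self) -> tuple[int, int]:
        return self.p.shape


def _peel_forced(
    entries: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Iteratively fix probabilities forced by the 0 <= p <= 1 bounds.

    Returns ``(forced_p, active_rows, active_cols, row_limit, col_limit)``.
    ``forced_p`` holds 0/1 where forced and NaN on the remaining interior
    block.  A row whose remaining degree equals the number of active
    columns forces p = 1 across them (and decrements those columns'
    remaining degrees); a node whose remaining degree reaches 0 forces
    p = 0.  ``row_limit``/``col_limit`` record the multiplier limit of
    each peeled node (+inf for the full case, 0 for the empty case, NaN
    for interior nodes).
    """
    n_r, n_c = entries.shape
    forced = np.full((n_r, n_c), np.nan)
    row_limit = np.full(n_r, np.nan)
    col_limit = np.full(n_c, np.nan)
    active_r = np.ones(n_r, dtype=bool)
    active_c = np.ones(n_c, dtype=bool)
    rem_k = entries.sum(axis=1).astype(np.int64)
    rem_d = entries.sum(axis=0).astype(np.int64)
    changed = True
    while changed:
        changed = False
        n_ac, n_ar = int(active_c.sum()), int(active_r.sum())
        for i in np.flatnonzero(active_r):
            if rem_k[i] == n_ac and n_ac > 0:
                forced[i, active_c] = 1.0
                rem_d[active_c] -= 1
                row_limit[i] = np.inf
                active_r[i] = False
                changed = True
                break
            if rem_k[i] == 0:
                forced[i, active_c] = 0.0
                row_limit[i] = 0.0
                active_r[i] = False
                changed = True
                break
        if changed:
            continue
        for j in np.flatnonzero(active_c):
            if rem_d[j] == n_ar and n_ar > 0:
                forced[active_r, j] = 1.0
                rem_k[active_r] -= 1
                col_limit[j] = np.inf
                active_c[j] = False
                changed = True
                break
            if rem_d[j] == 0:
                forced[active_r, j] = 0.0
                col_limit[j] = 0.0
                active_c[j] = False
                changed = True
                break
    return forced, active_r, active_c, row_limit, col_limit


def _solve_interior(
    k: np.ndarray, d: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, int, list[float]]:
    """Solve the expected-degree equations on the interior block.

    Degree-class reduction: one unknown per distinct row degree and per
    distinct column degree (equal-degree nodes provably share a
    multiplier).  Fixed-point iteration with a least-squares fallback.
    """
    kc, k_inv, k_mult = np.unique(k, return_inverse=True, return_counts=True)
    dc, d_inv, d_mult = np.unique(d, return_inverse=True, return_counts=True)
    e = float(k.sum())
    x = kc / np.sqrt(e)
    y = dc / np.sqrt(e)

    def residual(x, y):
        p = np.outer(x, y)
        p /= 1.0 + p
        row_err = (p * d_mult).sum(axis=1) - kc
        col_err = (p.T * k_mult).sum(axis=1) - dc
        return max(np.abs(row_err).max(), np.abs(col_err).max())

    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        xy = np.outer(x, y)
        x = kc / ((d_mult * y) / (1.0 + xy)).sum(axis=1)
        xy = np.outer(x, y)
        y = dc / ((k_mult * x)[:, None] / (1.0 + xy)).sum(axis=0)
        res = residual(x, y)
        trace.append(res)
        if res <= tol:
            return x[k_inv], y[d_inv], it, trace
        # stall detection: negligible progress over a 50-iteration window
        if it >= 50 and it % 50 == 0 and trace[-50] - res < 1e-13:
            break

    # quasi-Newton refinement in log space (guarantees positivity)
    def fun(z):
        xv, yv = np.exp(z[: len(kc)]), np.exp(z[len(kc) :])
        p = np.outer(xv, yv)
        p /= 1.0 + p
        return np.concatenate(
            [(p * d_mult).sum(axis=1) - kc, (p.T * k_mult).sum(axis=1) - dc]
        )

    z0 = np.concatenate([np.log(x), np.log(y)])
    sol = optimize.least_squares(fun, z0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    x, y = np.exp(sol.x[: len(kc)]), np.exp(sol.x[len(kc) :])
    res = residual(x, y)
    trace.append(res)
    if res > tol:
        raise ConvergenceError(
            f"BiCM solver stalled at residual {res:.3e} (tol {tol:.1e})", trace
        )
    return x[k_inv], y[d_inv], it + int(sol.nfev), trace


def fit_bicm(
    inc: BipartiteIncidence, tol: float = 1e-8, max_iter: int = 5000
) -> BiCMFit:
    """Fit the BiCM to an incidence matrix.

    Requires a matrix with no all-zero rows or columns (apply
    :func:`bipnull.incidence.drop_empty_nodes` first).  On return the row
    and column sums of the probability matrix match the observed degrees
    to within ``tol`` (exactly, for forced structure).

    Raises
    ------
    ConvergenceError
        If the solver cannot reach ``tol`` within ``max_iter`` iterations;
        carries the residual trace for diagnosis.
    """
    k_obs, d_obs = inc.row_degrees, inc.col_degrees
    if (k_obs == 0).any() or (d_obs == 0).any():
        raise IncidenceError(
            "matrix has all-zero rows or columns; apply drop_empty_nodes first"
        )
    entries = np.asarray(inc.entries, dtype=np.int64)
    forced, active_r, active_c, row_limit, col_limit = _peel_forced(entries)

    p = forced.copy()
    x = np.where(np.isnan(row_limit), 0.0, row_limit)
    y = np.where(np.isnan(col_limit), 0.0, col_limit)
    iterations = 0
    degenerate = not (active_r.any() and active_c.any())
    if degenerate:
        # whole matrix forced: the ensemble contains exactly one matrix
        p = np.where(np.isnan(p), 0.0, p)
    else:
        sub = entries[np.ix_(active_r, active_c)]
        x_int, y_int, iterations, _ = _solve_interior(
            sub.sum(axis=1), sub.sum(axis=0), tol, max_iter
        )
        x[active_r] = x_int
        y[active_c] = y_int
        interior = np.outer(x_int, y_int)
        p[np.ix_(active_r, active_c)] = interior / (1.0 + interior)

    residual = float(
        max(
            np.abs(p.sum(axis=1) - k_obs).max(),
            np.abs(p.sum(axis=0) - d_obs).max(),
        )
    )
    fit = BiCMFit(
        row_labels=inc.row_labels,
        col_labels=inc.col_labels,
        x=x,
        y=y,
        p=p,
        residual=residual,
        iterations=iterations,
        loglik=0.0,
        degenerate=degenerate,
    )
    object.__setattr__(fit, "loglik", log_likelihood(fit, inc))
    return fit


def expected_degrees(fit: BiCMFit) -> tuple[np.ndarray, np.ndarray]:
    """Row and column sums of the probability matrix.

    Under a successful fit these reproduce the observed degree sequences —
    the numerical check that the soft constraint holds on average.
    """
    return fit.p.sum(axis=1), fit.p.sum(axis=0)


def log_likelihood(fit: BiCMFit, inc: BipartiteIncidence) -> float:
    """Bernoulli log-likelihood of ``inc`` under the fitted probabilities.

    Uses the convention 0*log(0) = 0 for forced entries.  An impossible
    observation (a = 1 where p = 0, or a = 0 where p = 1) yields ``-inf``
    rather than an exception.
    """
    if fit.p.shape != inc.shape:
        raise IncidenceError("fit and matrix shapes differ")
    a = np.asarray(inc.entries, dtype=float)
    p = fit.p
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(a == 1, np.log(p), 0.0)
        term0 = np.where(a == 0, np.log1p(-p), 0.0)
    total = term1.sum() + term0.sum()
    return float(total) if np.isfinite(total) else float("-inf")


def iter_ensemble(fit: BiCMFit, n_samples: int, seed: int):
    """Yield ``n_samples`` matrices drawn entrywise Bernoulli(p_ij).

    Sample ``s`` uses an RNG substream derived from ``(seed, s)``, so the
    sequence is reproducible and samples are independent of each other and
    of how many are drawn.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    for s in range(n_samples):
        rng = np.random.default_rng([seed, s])
        entries = (rng.random(fit.p.shape) < fit.p).astype(np.int8)
        yield BipartiteIncidence(fit.row_labels, fit.col_labels, entries)


def sample_ensemble(fit: BiCMFit, n_samples: int = 999, seed: int = 0):
    """Materialized list of null-ensemble matrices (see :func:`iter_ensemble`)."""
    return list(iter_ensemble(fit, n_samples, seed))
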