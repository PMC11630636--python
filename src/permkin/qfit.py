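"""Rate-matrix estimation by penalized matrix-exponential fitting.

Given a (possibly lumped) transition matrix at a Markovian lagtime, the
generator is recovered by minimizing

    f = || T - expm(Q dt) ||_F  +  lambda * | I_T - I_Q |

over valid rate matrices (non-negative off-diagonals, zero row sums), where
I_T is the discrete-time current of T and I_Q the rate-flux current of the
candidate Q.  The current term (lambda > 0) regularizes the otherwise
multi-minimum landscape.  Off-diagonal rates are parameterized as
exponentials of free variables, so positivity is structural; the search is
initialized from the projected real matrix logarithm of T and repeated from
a few seeded perturbations, keeping the best optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm, logm
from scipy.optimize import minimize

from .currents import current_from_rates, current_from_transition
from .flux import FluxMatrix
from .msm import (LagTransitionMatrix, ProbabilityVector, RateMatrix,
                  stationary_distribution, validate_rate_matrix)

__all__ = ["FitResult", "fit_rate_matrix"]

_LOG_FLOOR = -40.0  # free variables below this pin a rate to ~0


@dataclass
class FitResult:
    Q_fit: RateMatrix
    objective: float
    residual_norm: float
    current_mismatch_pA: float | None
    lam: float
    converged: bool
    iterations: int


def _assemble(x: np.ndarray, free_ij: tuple, n: int) -> np.ndarray:
    Q = np.zeros((n, n))
    Q[free_ij] = np.exp(x)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def fit_rate_matrix(
    T_red: LagTransitionMatrix,
    F_red: FluxMatrix | None = None,
    lam: float = 0.0,
    sparsity_mask: np.ndarray | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 2000,
    F_lag: FluxMatrix | None = None,
) -> FitResult:
    """Fit a generator to ``T_red`` at its lagtime.

    ``sparsity_mask`` (boolean, True = free) pins selected off-diagonal rates
    to zero, imposing a model topology.  The current-mismatch term
    (``lam > 0``) compares two genuine current estimates of the same model:
    the discrete-time current of ``T_red`` with a flux matrix at its own
    lagtime (``F_lag``; defaults to ``F_red`` when the lagtimes agree, e.g.
    a matching composite flux), against the rate-form current of the
    candidate generator with the short-lagtime reduced flux ``F_red``.
    Mixing those roles lets the optimizer satisfy the penalty with
    meaningless generators, so they are kept distinct.  Deterministic for
    fixed ``seed``/``n_restarts``.
    """
    n = T_red.n
    dt = T_red.lagtime_s
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam > 0 and F_red is None:
        raise ValueError("current regularization (lambda > 0) requires F_red")
    if F_lag is None and F_red is not None and \
            abs(F_red.lagtime_ns - T_red.lagtime_ns) \
            <= 1e-9 * T_red.lagtime_ns:
        F_lag = F_red
    if lam > 0 and F_lag is None:
        raise ValueError(
            "current regularization needs a flux matrix at T_red's lagtime "
            "(pass F_lag, e.g. the composite flux at that lagtime)"
        )
    off = ~np.eye(n, dtype=bool)
    if sparsity_mask is None:
        free = off
    else:
        free = np.asarray(sparsity_mask, dtype=bool) & off
        if not free.any():
            raise ValueError("sparsity mask leaves no free rates")
    free_ij = np.nonzero(free)

    # initialization: projected real matrix logarithm of T
    with np.errstate(invalid="ignore"):
        L = np.real(logm(T_red.values)) / dt
    rate0 = np.clip(L[free_ij], 0.0, None)
    floor = max(1.0, np.max(rate0) * 1e-8) if np.max(rate0) > 0 else 1.0
    x0 = np.log(np.maximum(rate0, floor))

    if lam > 0:
        I_T = current_from_transition(T_red, F_lag).value_pA

    def objective(x):
        Q = _assemble(x, free_ij, n)
        resid = np.linalg.norm(T_red.values - expm(Q * dt))
        if lam == 0:
            return resid
        try:
            Pq = stationary_distribution(
                LagTransitionMatrix(expm(Q * dt), T_red.labels, T_red.lagtime_ns)
            )
            I_Q = current_from_rates(
                RateMatrix(Q, T_red.labels), F_red, Pinf=Pq
            ).value_pA
        except ValueError:
            return resid + lam * 1e3  # degenerate chain: penalize heavily
        return resid + lam * abs(I_T - I_Q)

    rng = np.random.default_rng(seed)
    best = None
    total_iter = 0
    # rates far above 100/dt saturate T and only destabilize expm
    log_ceil = float(np.log(100.0 / dt))
    for k in range(max(1, n_restarts)):
        xs = x0 if k == 0 else x0 + rng.normal(0.0, 0.5, size=x0.shape)
        res = minimize(
            objective, np.minimum(xs, log_ceil), method="L-BFGS-B",
            bounds=[(_LOG_FLOOR, log_ceil)] * len(xs),
            options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-12},
        )
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res

    Q = _assemble(best.x, free_ij, n)
    Q[np.abs(Q) < np.max(np.abs(Q)) * 1e-14] = 0.0
    Q_fit = validate_rate_matrix(Q, T_red.labels)
    resid = float(np.linalg.norm(T_red.values - expm(Q_fit.values * dt)))
    mismatch = None
    if F_red is not None and F_lag is not None:
        I_T = current_from_transition(T_red, F_lag).value_pA
        I_Q = current_from_rates(Q_fit, F_red).value_pA
        mismatch = float(abs(I_T - I_Q))
    return FitResult(
        Q_fit=Q_fit,
        objective=float(best.fun),
        residual_norm=resid,
        current_mismatch_pA=mismatch,
        lam=lam,
        converged=bool(best.success),
        iterations=int(total_iter),
    )
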