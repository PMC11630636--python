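"""Single-channel current estimators.

The steady-state current is the elementary charge times the net rate at which
full permeation charges cross the pore.  Several equivalent routes exist:

* boundary form -- net probability flow across one designated edge of a
  single-cycle kinetic scheme, from the rate matrix;
* rate-flux form -- sum of stationary rate flows weighted by the base charge
  flux, valid for arbitrary entry/exit topologies;
* transition-flux form -- the discrete-time analogue using T and F at a
  common lagtime (exact in the short-lagtime limit with the base F, exact at
  any lagtime with the matching composite F);
* direct counting -- accumulate the per-step flux along a discrete
  trajectory and divide by elapsed time (the simulation ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .flux import FluxMatrix
from .msm import (LagTransitionMatrix, ProbabilityVector, RateMatrix,
                  stationary_distribution, transition_from_rates)
from .occupancy import DiscreteTrajectory

__all__ = [
    "E0",
    "CurrentEstimate",
    "current_boundary",
    "current_from_rates",
    "current_from_transition",
    "current_from_trajectory",
]

E0 = 1.602176634e-19  # elementary charge carried by one K ion, coulomb
_NS = 1e-9
_A_TO_PA = 1e12


@dataclass
class CurrentEstimate:
    value_pA: float
    method: str
    lagtime_ns: float | None = None
    stderr_pA: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.value_pA):
            raise ValueError("current estimate must be finite")
        if self.stderr_pA is not None and self.stderr_pA < 0:
            raise ValueError("standard error must be non-negative")


def _stationary_of_rates(Q: RateMatrix) -> ProbabilityVector:
    # a tiny lagtime keeps expm well-conditioned; the stationary vector is
    # lagtime-independent
    scale = np.max(np.abs(np.diag(Q.values)))
    dt_ns = 1e-3 / max(scale * _NS, 1e-30)
    return stationary_distribution(transition_from_rates(Q, dt_ns))


def current_boundary(
    Q: RateMatrix,
    edge: tuple[str, str],
    Pinf: ProbabilityVector | None = None,
) -> CurrentEstimate:
    """Net entrance rate across one edge: I = e0 (P_i Q_ij - P_j Q_ji).

    Meaningful for single-cycle schemes where every permeation crosses the
    designated edge exactly once.
    """
    a, b = edge
    for s in (a, b):
        if s not in Q.labels.index:
            raise KeyError(f"unknown state {s!r}")
    if Pinf is None:
        Pinf = _stationary_of_rates(Q)
    i, j = Q.labels.index[a], Q.labels.index[b]
    amps = E0 * (Pinf.values[i] * Q.values[i, j] - Pinf.values[j] * Q.values[j, i])
    return CurrentEstimate(amps * _A_TO_PA, method="boundary_rate")


def current_from_rates(
    Q: RateMatrix,
    F: FluxMatrix,
    Pinf: ProbabilityVector | None = None,
) -> CurrentEstimate:
    """Rate-flux form: I = e0 sum_ij P_i Q_ij F_ij (diagonal F is zero)."""
    if Q.labels != F.labels:
        raise ValueError("Q and F state labels do not match")
    if Pinf is None:
        Pinf = _stationary_of_rates(Q)
    off = ~np.eye(Q.n, dtype=bool)
    amps = E0 * float(np.sum(Pinf.values[:, None] * Q.values * F.values, where=off))
    return CurrentEstimate(amps * _A_TO_PA, method="rate_flux")


def current_from_transition(
    T: LagTransitionMatrix,
    F: FluxMatrix,
    Pinf: ProbabilityVector | None = None,
) -> CurrentEstimate:
    """Discrete-time form: I = (e0 / dt) sum_ij P_i T_ij F_ij.

    T and F must share labels and lagtime.  With a base F this is accurate
    only at short lagtimes; with the matching composite F it is accurate at
    any lagtime (for the composite kind matching how T was obtained).
    """
    if T.labels != F.labels:
        raise ValueError("T and F state labels do not match")
    if abs(T.lagtime_ns - F.lagtime_ns) > 1e-9 * T.lagtime_ns:
        raise ValueError(
            f"lagtime mismatch: T at {T.lagtime_ns} ns, F at {F.lagtime_ns} ns"
        )
    if Pinf is None:
        Pinf = stationary_distribution(T)
    amps = E0 / T.lagtime_s * float(
        np.sum(Pinf.values[:, None] * T.values * F.values)
    )
    method = ("transition_flux" if F.kind == "base"
              else "transition_composite_flux")
    return CurrentEstimate(amps * _A_TO_PA, method=method, lagtime_ns=T.lagtime_ns)


def current_from_trajectory(
    traj: DiscreteTrajectory | Sequence[DiscreteTrajectory],
    F_base: FluxMatrix,
) -> CurrentEstimate:
    """Direct counting: accumulate base flux over successive frames.

    I = e0 * (sum_t F[s_t, s_{t+1}]) / elapsed time.  Pairs spanning a gap
    are skipped (and their time excluded).  With several replicas the mean is
    weighted by replica duration and the standard error comes from the
    between-replica spread.
    """
    trajs = [traj] if isinstance(traj, DiscreteTrajectory) else list(traj)
    if not trajs:
        raise ValueError("no trajectories supplied")
    idx = F_base.labels.index
    n_int = len(F_base.labels[0]) + 1 if F_base.labels[0] else 7
    per, weights = [], []
    for t in trajs:
        try:
            codes = t.codes(F_base.labels)
        except KeyError as exc:
            raise KeyError(f"trajectory state {exc.args[0]!r} not in flux labels")
        a, b = codes[:-1], codes[1:]
        ok = (a >= 0) & (b >= 0)
        if not np.any(ok):
            continue
        step_flux = F_base.values[a[ok], b[ok]]
        if np.any(np.abs(step_flux) > 3.0 / n_int + 1e-12):
            import warnings
            warnings.warn(
                "some single-frame transitions carry |flux| > 3 intervals; "
                "the frame interval may be too coarse for direct counting",
                stacklevel=2,
            )
        elapsed_s = np.count_nonzero(ok) * t.frame_interval_ns * _NS
        per.append(E0 * float(step_flux.sum()) / elapsed_s * _A_TO_PA)
        weights.append(elapsed_s)
    if not per:
        raise ValueError("no countable frame pairs in the supplied trajectories")
    per = np.asarray(per)
    w = np.asarray(weights) / np.sum(weights)
    mean = float(np.sum(w * per))
    se = None
    if len(per) > 1:
        var = float(np.sum(w * (per - mean) ** 2) / (1.0 - np.sum(w**2)))
        se = float(np.sqrt(var / len(per)))
    return CurrentEstimate(mean, method="trajectory_count", stderr_pA=se)
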