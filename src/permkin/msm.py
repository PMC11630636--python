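"""Core Markov-state-model objects and operations.

A permeation MSM is specified either by a rate matrix ``Q`` (the generator of a
continuous-time Markov chain, off-diagonal entries in s^-1, rows summing to
zero) or by a row-stochastic transition matrix ``T`` tagged with the lagtime at
which its probabilities are defined.  The two are linked by
``T(dt) = expm(Q * dt)``.  All public interfaces take and report lagtimes in
nanoseconds (the natural unit for channel kinetics); rates stay in s^-1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import expm

logger = logging.getLogger("permkin")

NS = 1e-9  # seconds per nanosecond

__all__ = [
    "StateLabelSet",
    "RateMatrix",
    "LagTransitionMatrix",
    "ProbabilityVector",
    "CkReport",
    "validate_rate_matrix",
    "transition_from_rates",
    "rates_from_transition_limit",
    "propagate",
    "stationary_distribution",
    "chapman_kolmogorov_test",
]


class StateLabelSet:
    """Ordered set of unique state labels; the canonical row/column order of
    every matrix that shares it."""

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(x) for x in labels)
        if not labels:
            raise ValueError("state label set must be non-empty")
        if len(set(labels)) != len(labels):
            raise ValueError("state labels must be unique")
        self.labels = labels
        self.index = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __getitem__(self, i: int) -> str:
        return self.labels[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, StateLabelSet) and self.labels == other.labels

    def __repr__(self) -> str:
        return f"StateLabelSet({list(self.labels)!r})"

    def subset_indices(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.index[l] for l in labels], dtype=int)


@dataclass
class RateMatrix:
    """Generator of a continuous-time chain; values in s^-1, rows sum to 0."""

    values: np.ndarray
    labels: StateLabelSet

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class LagTransitionMatrix:
    """Row-stochastic transition-probability matrix at a given lagtime (ns)."""

    values: np.ndarray
    labels: StateLabelSet
    lagtime_ns: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.lagtime_ns > 0:
            raise ValueError("lagtime must be positive")
        rows = self.values.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > 1e-9:
            raise ValueError("transition matrix rows must sum to 1 within 1e-9")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-9:
            raise ValueError("transition probabilities must lie in [0, 1]")

    @property
    def lagtime_s(self) -> float:
        return self.lagtime_ns * NS

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class ProbabilityVector:
    """State-occupancy vector; non-negative, sums to 1."""

    values: np.ndarray
    labels: StateLabelSet

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("probability vector must sum to 1 within 1e-9")
        if self.values.min() < -1e-12:
            raise ValueError("probability vector must be non-negative")


@dataclass
class CkReport:
    """Chapman-Kolmogorov comparison: T_base^n against observed T(n*dt).

    Reports element-wise deviations only; whether a deviation is acceptable is
    the caller's judgment (an advisory threshold is applied in the CLI).
    """

    base_lagtime_ns: float
    lagtimes_ns: list = field(default_factory=list)
    predicted: dict = field(default_factory=dict)   # lagtime_ns -> ndarray
    observed: dict = field(default_factory=dict)    # lagtime_ns -> ndarray
    max_deviation: dict = field(default_factory=dict)  # lagtime_ns -> float

    def worst(self) -> float:
        return max(self.max_deviation.values()) if self.max_deviation else 0.0


def validate_rate_matrix(values, labels: StateLabelSet | Sequence[str]) -> RateMatrix:
    """Validate a raw square array as a rate matrix.

    Off-diagonal entries must be non-negative.  If the diagonal is missing
    (NaN) or inconsistent with the zero-row-sum requirement beyond a tolerance
    of ``1e-6 * max|Q|``, it is recomputed as minus the off-diagonal row sum
    and a warning is logged.
    """
    if not isinstance(labels, StateLabelSet):
        labels = StateLabelSet(labels)
    values = np.array(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"rate matrix must be square, got shape {values.shape}")
    if values.shape[0] != len(labels):
        raise ValueError(
            f"rate matrix size {values.shape[0]} does not match "
            f"{len(labels)} state labels"
        )
    off = ~np.eye(len(labels), dtype=bool)
    neg = (values < 0) & off
    if np.any(neg):
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"negative off-diagonal rate Q[{labels[i]!r}, {labels[j]!r}] = "
            f"{values[i, j]!r}"
        )
    offdiag = np.where(off, values, 0.0)
    proper_diag = -offdiag.sum(axis=1)
    diag = np.diag(values)
    scale = np.max(np.abs(offdiag)) if np.any(offdiag) else 1.0
    tol = 1e-6 * max(scale, abs(diag[~np.isnan(diag)]).max(initial=0.0))
    if np.any(np.isnan(diag)) or np.max(np.abs(diag - proper_diag)) > tol:
        logger.warning(
            "rate-matrix diagonal absent or inconsistent with zero row sums; "
            "recomputed as negative off-diagonal row sum"
        )
    out = offdiag.copy()
    np.fill_diagonal(out, proper_diag)
    return RateMatrix(out, labels)


def transition_from_rates(Q: RateMatrix, lagtime_ns: float) -> LagTransitionMatrix:
    """``T(dt) = expm(Q dt)`` (scaling-and-squaring Pade via scipy)."""
    if not lagtime_ns > 0:
        raise ValueError("lagtime must be positive")
    T = expm(Q.values * (lagtime_ns * NS))
    if not np.all(np.isfinite(T)):
        raise FloatingPointError(
            f"matrix exponential overflowed at lagtime {lagtime_ns} ns"
        )
    if T.min() < -1e-12:
        raise FloatingPointError(
            f"matrix exponential produced negative probabilities at lagtime "
            f"{lagtime_ns} ns"
        )
    T = np.clip(T, 0.0, None)
    T /= T.sum(axis=1, keepdims=True)
    return LagTransitionMatrix(T, Q.labels, lagtime_ns)


def rates_from_transition_limit(T: LagTransitionMatrix) -> RateMatrix:
    """First-order rate estimate ``Q ~= (T - I) / dt``.

    Valid only when the lagtime is short relative to the fastest relaxation;
    a warning is emitted when any diagonal of T drops below 0.5.
    """
    if np.any(np.diag(T.values) < 0.5):
        warnings.warn(
            "lagtime appears large relative to the fastest transitions "
            "(some diagonal of T < 0.5); (T - I)/dt is a first-order "
            "estimate only",
            stacklevel=2,
        )
    Q = (T.values - np.eye(T.n)) / T.lagtime_s
    off = ~np.eye(T.n, dtype=bool)
    Q = np.where(off, np.clip(Q, 0.0, None), 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(Q, T.labels)


def propagate(
    P0: ProbabilityVector, T: LagTransitionMatrix, n_steps: int
) -> list[ProbabilityVector]:
    """Evolve an occupancy vector: returns ``[P(0), P(dt), ..., P(n dt)]``
    with ``P(t + dt) = P(t) @ T``."""
    if P0.labels != T.labels:
        raise ValueError("state labels of P0 and T do not match")
    if n_steps < 1:
        raise ValueError("n_steps must be a positive integer")
    out = [P0]
    p = P0.values
    for _ in range(n_steps):
        p = p @ T.values
        p = p / p.sum()  # guard against drift over many steps
        out.append(ProbabilityVector(p, T.labels))
    return out


def stationary_distribution(T: LagTransitionMatrix) -> ProbabilityVector:
    """Equilibrium occupancy: the left eigenvector of T for eigenvalue 1,
    via eigen decomposition of the transpose.

    The chains of interest are driven (irreversible), so the spectrum is in
    general complex; the eigenvalue closest to 1+0i is selected and the
    corresponding eigenvector must be real to within 1e-8.
    """
    w, v = np.linalg.eig(T.values.T)
    order = np.argsort(np.abs(w - 1.0))
    if len(w) > 1 and abs(w[order[1]] - 1.0) < 1e-8:
        raise ValueError(
            "reducible chain: the unit eigenvalue is degenerate "
            "(multiplicity > 1 within 1e-8)"
        )
    vec = v[:, order[0]]
    # fix the arbitrary complex phase before checking realness
    k = np.argmax(np.abs(vec))
    vec = vec / vec[k]
    if np.max(np.abs(vec.imag)) > 1e-8:
        raise ValueError("stationary eigenvector has non-negligible imaginary part")
    p = vec.real
    p[np.abs(p) < 1e-10] = 0.0
    if p.min() < 0:
        if p.min() > -1e-10:
            p = np.clip(p, 0.0, None)
        else:
            raise ValueError("stationary eigenvector has negative components")
    p = p / p.sum()
    resid = np.max(np.abs(p @ T.values - p))
    if resid > 1e-8:
        raise ValueError(f"stationary vector residual |P T - P| = {resid:g} > 1e-8")
    return ProbabilityVector(p, T.labels)


def chapman_kolmogorov_test(
    T_base: LagTransitionMatrix, T_observed: Sequence[LagTransitionMatrix]
) -> CkReport:
    """Compare ``T_base^n`` with independently observed matrices at ``n*dt``.

    Each observed lagtime must be an integer multiple of the base lagtime.
    A large deviation at some lagtime means the model at the base lagtime has
    memory (is non-Markovian) on that horizon.
    """
    report = CkReport(base_lagtime_ns=T_base.lagtime_ns)
    for T_obs in T_observed:
        if T_obs.labels != T_base.labels:
            raise ValueError("observed matrix has mismatched state labels")
        ratio = T_obs.lagtime_ns / T_base.lagtime_ns
        n = int(round(ratio))
        if n < 1 or abs(ratio - n) > 1e-9 * max(1.0, ratio):
            raise ValueError(
                f"observed lagtime {T_obs.lagtime_ns} ns is not an integer "
                f"multiple of the base lagtime {T_base.lagtime_ns} ns"
            )
        pred = np.linalg.matrix_power(T_base.values, n)
        dev = float(np.max(np.abs(pred - T_obs.values)))
        lag = T_obs.lagtime_ns
        report.lagtimes_ns.append(lag)
        report.predicted[lag] = pred
        report.observed[lag] = T_obs.values
        report.max_deviation[lag] = dev
    return report
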