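"""State lumping and spectral coarse-graining.

Lumping merges microstates into macrostates while preserving (i) the
stationary occupancy of every remaining state, (ii) the in- and outgoing
probability fluxes, and (iii) the in- and outgoing charge fluxes -- so the
reduced model predicts exactly the same steady-state current at the lagtime
of its construction.  The reduced transition matrix is the stationary-
weighted row average combined with column summation; the reduced flux matrix
is the probability-flow-weighted charge average, including the charge
exchanged between lumped partners (which lands on the diagonal).

Macrostate candidates come from the spectrum of T: a gap in the sorted
eigenvalue moduli suggests the number of slowly mixing aggregates, and a
PCCA+-style inner-simplex rotation of the leading Schur vectors yields fuzzy
memberships.  Schur vectors (not eigenvectors) are used because driven
permeation chains are irreversible and their spectra are complex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import schur

from .flux import FluxMatrix
from .msm import (LagTransitionMatrix, ProbabilityVector, StateLabelSet,
                  logger)

__all__ = [
    "LumpingMap",
    "ReducedModel",
    "MembershipMatrix",
    "SpectrumReport",
    "lump_states",
    "eigen_spectrum",
    "fuzzy_macrostates",
    "crisp_partition",
]


class LumpingMap:
    """Total surjective map microstate label -> macrostate label."""

    def __init__(self, partition: Mapping[str, str],
                 macro_order: Sequence[str] | None = None):
        self.partition = dict(partition)
        if not self.partition:
            raise ValueError("empty lumping map")
        seen: dict = {}
        for m in self.partition.values():
            seen.setdefault(m, len(seen))
        if macro_order is None:
            macro_order = sorted(seen, key=seen.get)
        else:
            macro_order = list(macro_order)
            if set(macro_order) != set(seen):
                raise ValueError(
                    "macro_order must list exactly the macrostates of the map"
                )
        self.macro_labels = StateLabelSet(macro_order)

    def __getitem__(self, micro: str) -> str:
        return self.partition[micro]

    def members(self, macro: str) -> list[str]:
        return [k for k, v in self.partition.items() if v == macro]

    def compose(self, other: "LumpingMap") -> "LumpingMap":
        """This map followed by a further lumping of its macrostates."""
        return LumpingMap({k: other[v] for k, v in self.partition.items()},
                          macro_order=other.macro_labels.labels)


@dataclass
class ReducedModel:
    T_red: LagTransitionMatrix
    F_red: FluxMatrix
    Pinf_red: ProbabilityVector
    map: LumpingMap
    parent_Pinf: ProbabilityVector


@dataclass
class MembershipMatrix:
    """Fuzzy microstate-to-macrostate memberships; rows sum to 1."""

    values: np.ndarray
    micro_labels: StateLabelSet
    macro_labels: StateLabelSet

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.max(np.abs(self.values.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("membership rows must sum to 1 within 1e-9")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-9:
            raise ValueError("memberships must lie in [0, 1]")


@dataclass
class SpectrumReport:
    moduli: np.ndarray          # sorted descending, leading entry 1
    suggested_n_macro: int | None
    gap_ratio: float | None


def lump_states(
    T: LagTransitionMatrix,
    F: FluxMatrix,
    Pinf: ProbabilityVector,
    lmap: LumpingMap,
) -> ReducedModel:
    """Lump states by grouped sums (one pass over an arbitrary partition).

    Equivalent to repeated pairwise lumping:

    * ``T_red[X, Y] = sum_{i in X} P_i sum_{j in Y} T_ij / P_X``
      (stationary-weighted row average, column sum),
    * ``F_red[X, Y] = sum_{i in X, j in Y} P_i T_ij F_ij / sum P_i T_ij``
      (charge-flow conservation; the same formula on ``X = Y`` captures the
      intra-lump charge exchange on the diagonal),
    * ``P_red[X] = sum_{i in X} P_i`` exactly.

    Macrostate pairs with zero probability flow get flux 0 (flagged); they
    contribute nothing to any current sum.
    """
    labels = T.labels
    if F.labels != labels or Pinf.labels != labels:
        raise ValueError("T, F and Pinf must share one label set")
    missing = [l for l in labels if l not in lmap.partition]
    if missing:
        raise ValueError(f"lumping map does not cover states {missing!r}")
    macro = lmap.macro_labels
    M = len(macro)
    # micro -> macro index aggregation matrix
    memb = np.zeros((len(labels), M))
    for i, lab in enumerate(labels):
        memb[i, macro.index[lmap[lab]]] = 1.0
    p = Pinf.values
    p_red = memb.T @ p
    flow = memb.T @ (p[:, None] * T.values) @ memb          # P_i T_ij grouped
    charge = memb.T @ (p[:, None] * T.values * F.values) @ memb
    with np.errstate(invalid="ignore", divide="ignore"):
        F_red = np.where(flow > 0, charge / np.where(flow > 0, flow, 1.0), 0.0)
    n_zero = int(np.count_nonzero(flow <= 0))
    if n_zero:
        logger.warning(
            "%d macrostate pair(s) with zero probability flow; flux set to 0",
            n_zero,
        )
    T_red = np.empty((M, M))
    for X in range(M):
        if p_red[X] > 0:
            T_red[X] = flow[X] / p_red[X]
        else:
            logger.warning(
                "macrostate %r has zero stationary mass; kept as a self-loop",
                macro[X],
            )
            T_red[X] = np.eye(M)[X]
    T_red = LagTransitionMatrix(T_red, macro, T.lagtime_ns)
    return ReducedModel(
        T_red=T_red,
        F_red=FluxMatrix(F_red, macro, T.lagtime_ns, kind="reduced"),
        Pinf_red=ProbabilityVector(p_red / p_red.sum(), macro),
        map=lmap,
        parent_Pinf=Pinf,
    )


def eigen_spectrum(T: LagTransitionMatrix) -> SpectrumReport:
    """Sorted eigenvalue moduli and an advisory macrostate count.

    The suggestion is the k >= 2 maximizing ``moduli[k-1] / moduli[k]`` (the
    spectral gap).  When no meaningful gap exists (all ratios ~1, e.g. the
    identity matrix) the suggestion is None.
    """
    mod = np.sort(np.abs(np.linalg.eigvals(T.values)))[::-1]
    suggested, best = None, 1.0 + 1e-9
    for k in range(2, len(mod)):
        if mod[k] <= 0:
            ratio = np.inf
        else:
            ratio = mod[k - 1] / mod[k]
        if ratio > best:
            best, suggested = ratio, k
    return SpectrumReport(
        moduli=mod,
        suggested_n_macro=suggested,
        gap_ratio=None if suggested is None else float(best),
    )


def _simplex_vertices(X: np.ndarray) -> list[int]:
    """Greedy inner-simplex index search: rows of X that span the widest
    simplex (deterministic: first occurrence wins argmax ties)."""
    n, k = X.shape
    Y = X.copy()
    idx = [int(np.argmax(np.linalg.norm(Y, axis=1)))]
    Y = Y - Y[idx[0]]
    for _ in range(1, k):
        norms = np.linalg.norm(Y, axis=1)
        i = int(np.argmax(norms))
        if norms[i] < 1e-12:
            raise ValueError("degenerate Schur vectors: simplex collapsed")
        idx.append(i)
        v = Y[i] / norms[i]
        Y = Y - np.outer(Y @ v, v)
    return idx


def fuzzy_macrostates(T: LagTransitionMatrix, n_macro: int) -> MembershipMatrix:
    """Fuzzy macrostate memberships from the leading Schur vectors.

    The real Schur form of T is reordered so that the ``n_macro`` eigenvalues
    of largest modulus lead (complex pairs are kept together; if the cut
    would split a pair the reordering fails and an error names it).  The
    orthonormal basis of that invariant subspace is then mapped onto the
    probability simplex by the inner-simplex construction: the rows most
    spread out in Schur-vector space become the macrostate vertices and every
    microstate is expressed in (clipped, renormalized) barycentric
    coordinates relative to them.
    """
    N = T.n
    if not 2 <= n_macro < N:
        raise ValueError(f"n_macro must be in [2, {N - 1}], got {n_macro}")
    ev = np.linalg.eigvals(T.values)
    mod = np.sort(np.abs(ev))[::-1]
    thr = 0.5 * (mod[n_macro - 1] + mod[n_macro])
    if mod[n_macro - 1] - mod[n_macro] < 1e-12:
        raise ValueError(
            "cannot separate the leading Schur block: eigenvalue moduli "
            f"{n_macro} and {n_macro + 1} coincide"
        )
    _, Z, sdim = schur(
        T.values, output="real",
        sort=lambda re, im: np.hypot(re, im) > thr,
    )
    if sdim != n_macro:
        raise ValueError(
            f"Schur reordering selected {sdim} vectors instead of {n_macro} "
            "(a complex pair straddles the cut)"
        )
    X = Z[:, :n_macro]
    idx = _simplex_vertices(X)
    A = np.linalg.inv(X[idx, :])
    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    macro = StateLabelSet([f"M{k}" for k in range(n_macro)])
    return MembershipMatrix(chi, T.labels, macro)


def crisp_partition(M: MembershipMatrix) -> LumpingMap:
    """Assign each microstate to its argmax membership.

    Exact ties go to the lower macrostate index with a warning; macrostates
    left empty after assignment are dropped with a warning.
    """
    V = M.values
    assign = np.argmax(V, axis=1)
    top = V[np.arange(len(V)), assign]
    ties = np.sum(np.abs(V - top[:, None]) < 1e-12, axis=1) > 1
    if np.any(ties):
        warnings.warn(
            f"{int(ties.sum())} microstate(s) had tied memberships; "
            "assigned to the lower macrostate index",
            stacklevel=2,
        )
    used = set(assign.tolist())
    empty = [M.macro_labels[k] for k in range(V.shape[1]) if k not in used]
    if empty:
        warnings.warn(
            f"macrostate(s) {empty!r} received no microstates and were dropped",
            stacklevel=2,
        )
    partition = {M.micro_labels[i]: M.macro_labels[int(assign[i])]
                 for i in range(len(V))}
    order = [M.macro_labels[k] for k in range(V.shape[1]) if k in used]
    return LumpingMap(partition, macro_order=order)
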