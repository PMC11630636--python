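"""Charge-flux matrices for permeation MSMs.

Every transition between two occupancy states moves some net charge across
the pore.  With N binding sites bounded by two bulk reservoirs there are
N + 1 intervals, and a single ion hopping across one interval translocates
1/(N+1) of a full permeation charge (positive in the intracellular ->
extracellular direction).  The *base* flux matrix assigns to each ordered
state pair the charge moved along the pathway with the fewest elementary ion
moves; it is exactly antisymmetric and valid at short lagtimes only.  At a
lagtime n*dt the appropriate flux is a probability-weighted average over all
n-step pathways, built recursively either from the model itself (Markov
assumption) or from transition matrices observed at every intermediate
lagtime (no Markov assumption).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .msm import LagTransitionMatrix, StateLabelSet, logger
from .occupancy import project_ion_only

__all__ = [
    "FluxMatrix",
    "PathwayResult",
    "ion_configuration",
    "elementary_moves",
    "minimal_path_flux",
    "base_flux_matrix",
    "composite_flux_markov",
    "composite_flux_empirical",
]


@dataclass
class FluxMatrix:
    """Per-transition mean translocated charge, in units of one permeation.

    ``kind`` is ``"base"`` (minimal-path, antisymmetric, zero diagonal),
    ``"composite_markov"`` (recursion under the Markov assumption),
    ``"composite_empirical"`` (recursion on observed matrices) or
    ``"reduced"`` (state-lumped; its diagonal may be non-zero because lumped
    partners can exchange charge within a macrostate).
    """

    values: np.ndarray
    labels: StateLabelSet
    lagtime_ns: float
    kind: str = "base"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("flux matrix must be finite")
        if self.kind not in ("base", "composite_markov",
                             "composite_empirical", "reduced"):
            raise ValueError(f"unknown flux kind {self.kind!r}")
        if self.kind == "base":
            if np.max(np.abs(self.values + self.values.T)) > 1e-12:
                raise ValueError("base flux matrix must be antisymmetric")


@dataclass
class PathwayResult:
    """Minimal-pathway flux between two ion configurations."""

    flux: float
    n_moves: int
    ambiguous: bool = False


def ion_configuration(label: str) -> tuple:
    """Occupancy string -> per-site ion-presence booleans (B counts as ion)."""
    return tuple(c == "K" for c in project_ion_only(label))


def elementary_moves(config: Sequence[bool]) -> list[tuple[tuple, float]]:
    """All single-ion moves from an ion configuration.

    Moves are between adjacent compartments on the reservoir-site-...-site-
    reservoir chain.  Site index 0 is the most intracellular; a move toward
    larger index (or out the extracellular end) crosses one interval outward
    and carries +1/(n_sites + 1); the reverse carries the opposite.  Moves
    into an occupied site are excluded; the reservoirs accept and supply ions
    without limit.
    """
    config = tuple(bool(x) for x in config)
    n = len(config)
    step = 1.0 / (n + 1)
    out = []

    def with_(src=None, dst=None):
        c = list(config)
        if src is not None:
            c[src] = False
        if dst is not None:
            c[dst] = True
        return tuple(c)

    for k in range(n):
        if config[k]:
            if k + 1 < n and not config[k + 1]:
                out.append((with_(k, k + 1), +step))
            if k - 1 >= 0 and not config[k - 1]:
                out.append((with_(k, k - 1), -step))
    if config[0]:
        out.append((with_(src=0), -step))        # innermost site -> inner bulk
    else:
        out.append((with_(dst=0), +step))        # inner bulk -> innermost site
    if config[n - 1]:
        out.append((with_(src=n - 1), +step))    # outermost site -> outer bulk
    else:
        out.append((with_(dst=n - 1), -step))    # outer bulk -> outermost site
    return out


def minimal_path_flux(config_i, config_j) -> PathwayResult:
    """Net charge along a shortest elementary-move pathway from i to j.

    Breadth-first search over configurations.  If several shortest pathways
    disagree in net flux (possible for pathways of four or more moves), the
    smallest absolute flux is returned, a positive sign winning exact ties,
    and the result is flagged ambiguous.
    """
    a = tuple(bool(x) for x in config_i)
    b = tuple(bool(x) for x in config_j)
    if len(a) != len(b):
        raise ValueError("configurations must have the same number of sites")
    if a == b:
        return PathwayResult(0.0, 0)
    quantum = len(a) + 1
    # frontier: config -> set of accumulated interval counts (integers, so
    # the final flux is an exact multiple of the charge quantum)
    frontier: dict = {a: {0}}
    seen = {a}
    n_moves = 0
    while frontier:
        n_moves += 1
        nxt: dict = {}
        hits: set = set()
        for c, steps in frontier.items():
            for d, df in elementary_moves(c):
                k = round(df * quantum)
                if d == b:
                    hits.update(s + k for s in steps)
                if d not in seen:
                    nxt.setdefault(d, set()).update(s + k for s in steps)
        if hits:
            best = sorted(hits, key=lambda s: (abs(s), -s))[0]
            return PathwayResult(best / quantum, n_moves,
                                 ambiguous=len(hits) > 1)
        seen.update(nxt)
        frontier = nxt
    raise ValueError("configuration unreachable")  # cannot occur on a chain


def base_flux_matrix(
    labels: StateLabelSet | Sequence[str], lagtime_ns: float
) -> FluxMatrix:
    """Minimal-path flux for every ordered pair of states.

    Labels are projected to ion-only configurations first, so states that
    differ only in water placement get zero mutual flux.
    """
    if not isinstance(labels, StateLabelSet):
        labels = StateLabelSet(labels)
    cfgs = [ion_configuration(l) for l in labels]
    N = len(labels)
    F = np.zeros((N, N))
    n_amb = 0
    cache: dict = {}
    for i in range(N):
        for j in range(i + 1, N):
            key = (cfgs[i], cfgs[j])
            if key not in cache:
                cache[key] = minimal_path_flux(*key)
            res = cache[key]
            if res.ambiguous:
                n_amb += 1
                logger.warning(
                    "ambiguous minimal-path flux %s -> %s; smallest |flux| kept",
                    labels[i], labels[j],
                )
            F[i, j] = res.flux
            F[j, i] = -res.flux
    if n_amb:
        logger.info("%d state pair(s) had ambiguous minimal pathways", n_amb)
    return FluxMatrix(F, labels, lagtime_ns, kind="base")


def _composite_step(T_prev, T1, T_n, F_prev, F1):
    """One recursion level: pathway-probability-weighted charge average.

    F(n dt)_ij = sum_m T_prev_im T1_mj [F_prev_im + F1_mj] / T_n_ij
    where T_prev spans (n-1) dt and T_n spans n dt.  Entries with zero
    pathway probability get flux 0.
    """
    num = (T_prev * F_prev) @ T1 + T_prev @ (T1 * F1)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(T_n > 0, num / np.where(T_n > 0, T_n, 1.0), 0.0)
    return F


def composite_flux_markov(
    T_base: LagTransitionMatrix, F_base: FluxMatrix, n: int
) -> FluxMatrix:
    """Composite flux at n times the base lagtime, assuming Markovianity.

    Intermediate transition matrices are powers of the base matrix; exact for
    a truly Markovian model, systematically wrong when the base model has
    memory (e.g. after aggressive lumping).
    """
    if T_base.labels != F_base.labels:
        raise ValueError("T and F state labels do not match")
    if abs(T_base.lagtime_ns - F_base.lagtime_ns) > 1e-12 * T_base.lagtime_ns:
        raise ValueError("T and F lagtimes do not match")
    if n < 1:
        raise ValueError("n must be a positive integer")
    F = F_base.values.copy()
    T1 = T_base.values
    T_prev = np.eye(T_base.n)
    n_flagged = 0
    for k in range(2, n + 1):
        T_prev = T_prev @ T1            # T^(k-1)
        T_n = T_prev @ T1
        F = _composite_step(T_prev, T1, T_n, F, F_base.values)
        n_flagged += int(np.count_nonzero(T_n <= 0))
    if n_flagged:
        logger.debug("%d zero-probability entries assigned flux 0", n_flagged)
    return FluxMatrix(F, T_base.labels, n * T_base.lagtime_ns,
                      kind="composite_markov")


def composite_flux_empirical(
    T_star: Sequence[LagTransitionMatrix], F_base: FluxMatrix
) -> FluxMatrix:
    """Composite flux from observed transition matrices at every multiple of
    the base lagtime (no Markov assumption).

    ``T_star`` must hold matrices at lagtimes dt, 2 dt, ..., n dt, in any
    order; the recursion uses the observed (n-1) dt matrix in place of the
    Markovian power and the observed n dt matrix as the pathway normalizer.
    Reduces to the Markov form when the observed matrices are exact powers.
    """
    if not T_star:
        raise ValueError("no observed transition matrices supplied")
    base = min(t.lagtime_ns for t in T_star)
    if abs(base - F_base.lagtime_ns) > 1e-12 * base:
        raise ValueError("base flux lagtime must equal the smallest observed lagtime")
    by_mult: dict[int, LagTransitionMatrix] = {}
    for t in T_star:
        if t.labels != F_base.labels:
            raise ValueError("observed matrix has mismatched state labels")
        m = int(round(t.lagtime_ns / base))
        if abs(t.lagtime_ns - m * base) > 1e-9 * t.lagtime_ns:
            raise ValueError(
                f"lagtime {t.lagtime_ns} ns is not a multiple of the base {base} ns"
            )
        by_mult[m] = t
    n = max(by_mult)
    missing = sorted(set(range(1, n + 1)) - set(by_mult))
    if missing:
        raise ValueError(
            f"missing observed transition matrices at multiples {missing} "
            f"of the base lagtime"
        )
    F = F_base.values.copy()
    T1 = by_mult[1].values
    for k in range(2, n + 1):
        F = _composite_step(by_mult[k - 1].values, T1, by_mult[k].values,
                            F, F_base.values)
    return FluxMatrix(F, F_base.labels, n * base, kind="composite_empirical")
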