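"""Selectivity-filter occupancy alphabet, frame classification and counting.

A K-channel selectivity filter is modelled as a chain of binding sites
(default S5..S0, intracellular to extracellular).  Each simulation frame is
reduced to a fixed-length occupancy string, one character per site:

* ``K`` -- a potassium ion occupies the site,
* ``W`` -- only water occupies the site,
* ``O`` -- the site is empty,
* ``B`` -- ion and water coexist (allowed only at the wide outer sites,
  default S1/S0).

The default alphabet is the regular language ``[KW][KWO][KWO][KWO][KWOB][KWOB]``:
the innermost site never reports ``O`` because the cavity below it is always
hydrated.  Discrete trajectories of such strings are the raw material for
transition-matrix estimation (sliding-window counting).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .msm import LagTransitionMatrix, StateLabelSet, logger

__all__ = [
    "SiteChain",
    "FrameRecord",
    "DiscreteTrajectory",
    "CountMatrix",
    "default_site_chain",
    "classify_frame",
    "encode_trajectory",
    "count_transitions",
    "estimate_transition_matrix",
    "project_ion_only",
    "GAP",
]

GAP = None  # sentinel for an unclassifiable frame inside a trajectory


@dataclass
class SiteChain:
    """Geometry of the binding-site chain.

    ``boundaries[i]`` is the half-open axial interval ``[lower, upper)`` of
    site ``site_names[i]`` in Angstrom, with z increasing from the
    intracellular to the extracellular side.  ``radial_cutoffs[i]`` is the
    maximal distance from the pore axis at which a particle is assigned to the
    site (4 A for the filter sites, 8 A for the wide innermost site).
    ``b_allowed`` lists the sites where ion + water coexistence (``B``) is
    representable.  The number of charge-translocation intervals is the site
    count plus one (the two bulk reservoirs bound the chain).
    """

    site_names: tuple = ("S5", "S4", "S3", "S2", "S1", "S0")
    boundaries: tuple = ((-8.0, 0.0), (0.0, 3.0), (3.0, 6.0), (6.0, 9.0),
                         (9.0, 12.0), (12.0, 15.0))
    radial_cutoffs: tuple = (8.0, 4.0, 4.0, 4.0, 4.0, 4.0)
    b_allowed: frozenset = frozenset({"S1", "S0"})

    def __post_init__(self):
        if len(self.boundaries) != len(self.site_names):
            raise ValueError("one axial interval per site is required")
        if len(self.radial_cutoffs) != len(self.site_names):
            raise ValueError("one radial cutoff per site is required")
        if any(r <= 0 for r in self.radial_cutoffs):
            raise ValueError("radial cutoffs must be positive")
        lows = [b[0] for b in self.boundaries]
        ups = [b[1] for b in self.boundaries]
        if any(l >= u for l, u in self.boundaries):
            raise ValueError("each axial interval needs lower < upper")
        if any(ups[i] > lows[i + 1] + 1e-12 for i in range(len(lows) - 1)):
            raise ValueError("axial intervals must be ordered and non-overlapping")

    @property
    def n_sites(self) -> int:
        return len(self.site_names)

    @property
    def n_intervals(self) -> int:
        """Charge-translocation intervals: sites + 1 (reservoir to reservoir)."""
        return self.n_sites + 1

    @property
    def pattern(self) -> re.Pattern:
        parts = []
        for i, name in enumerate(self.site_names):
            if i == 0:
                parts.append("[KW]")
            elif name in self.b_allowed:
                parts.append("[KWOB]")
            else:
                parts.append("[KWO]")
        return re.compile("".join(parts))


def default_site_chain() -> SiteChain:
    return SiteChain()


# A frame record is any mapping/table with columns species ("K" or "water"),
# z (axial position, A) and r (distance from the pore axis, A).
FrameRecord = pd.DataFrame


class UnclassifiableFrame(ValueError):
    """Raised when a frame cannot be expressed in the occupancy alphabet."""


def classify_frame(frame: FrameRecord, chain: SiteChain | None = None) -> str:
    """Reduce one frame to its occupancy string.

    Per site: ``K`` if at least one potassium lies inside the site's axial
    interval within its radial cutoff, else ``W`` if at least one water does,
    else ``O``; ``B`` when ion and water coexist and the site allows it.  The
    innermost site reports ``K`` or ``W`` only -- with neither particle kind
    present a cavity water is assumed and ``W`` is recorded.  Two ions in one
    site are not representable and raise :class:`UnclassifiableFrame`.
    """
    chain = chain or default_site_chain()
    frame = pd.DataFrame(frame)
    bad = set(frame["species"]) - {"K", "water"}
    if bad:
        raise ValueError(f"unknown species {sorted(bad)!r}")
    z = frame["z"].to_numpy(dtype=float)
    r = frame["r"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(r))):
        raise UnclassifiableFrame("non-finite particle coordinates")
    is_k = (frame["species"] == "K").to_numpy()
    chars = []
    for i, name in enumerate(chain.site_names):
        lo, up = chain.boundaries[i]
        inside = (z >= lo) & (z < up) & (r <= chain.radial_cutoffs[i])
        n_ion = int(np.count_nonzero(inside & is_k))
        n_wat = int(np.count_nonzero(inside & ~is_k))
        if n_ion > 1:
            raise UnclassifiableFrame(
                f"{n_ion} potassium ions in site {name}: not representable "
                "in the occupancy alphabet"
            )
        if i == 0:
            if n_ion:
                chars.append("K")
            else:
                if not n_wat:
                    logger.debug(
                        "site %s empty; cavity water assumed (recorded as W)", name
                    )
                chars.append("W")
        elif n_ion and n_wat and name in chain.b_allowed:
            chars.append("B")
        elif n_ion:
            chars.append("K")
        elif n_wat:
            chars.append("W")
        else:
            chars.append("O")
    state = "".join(chars)
    if not chain.pattern.fullmatch(state):
        raise UnclassifiableFrame(f"state {state!r} violates the occupancy alphabet")
    return state


@dataclass
class DiscreteTrajectory:
    """Per-frame state labels at a fixed frame interval (ns).

    ``states`` may contain ``None`` entries marking unclassifiable frames;
    counting windows never span such a gap.
    """

    states: list
    frame_interval_ns: float
    replica_id: str | int = 0

    def __post_init__(self):
        if len(self.states) == 0:
            raise ValueError("trajectory must be non-empty")
        if not self.frame_interval_ns > 0:
            raise ValueError("frame interval must be positive")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def duration_ns(self) -> float:
        return (len(self.states) - 1) * self.frame_interval_ns

    def codes(self, labels: StateLabelSet) -> np.ndarray:
        """Integer codes of the states under a label set (gaps -> -1).

        The most recent conversion is cached: counting at many lagtimes
        re-uses one pass over the frames.
        """
        cached = getattr(self, "_codes_cache", None)
        if cached is not None and cached[0] is labels:
            return cached[1]
        idx = labels.index
        codes = np.fromiter(
            (idx[s] if s is not GAP else -1 for s in self.states),
            dtype=np.int64, count=len(self.states),
        )
        self._codes_cache = (labels, codes)
        return codes


def encode_trajectory(
    frames: Sequence[FrameRecord],
    chain: SiteChain | None = None,
    frame_interval_ns: float = 1.0,
    replica_id: str | int = 0,
) -> DiscreteTrajectory:
    """Classify every frame; unclassifiable frames become gaps."""
    if len(frames) == 0:
        raise ValueError("no frames supplied")
    chain = chain or default_site_chain()
    states: list = []
    n_gaps = 0
    for k, fr in enumerate(frames):
        try:
            states.append(classify_frame(fr, chain))
        except UnclassifiableFrame as exc:
            logger.warning("frame %d unclassifiable (%s); recorded as gap", k, exc)
            states.append(GAP)
            n_gaps += 1
    if n_gaps == len(states):
        raise ValueError("all frames unclassifiable")
    return DiscreteTrajectory(states, frame_interval_ns, replica_id)


@dataclass
class CountMatrix:
    """Integer transition counts at a lagtime (sliding/overlapping windows)."""

    values: np.ndarray
    labels: StateLabelSet
    lagtime_ns: float
    total_frames: int

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("count matrix entries must be integers")
        if self.values.min() < 0:
            raise ValueError("count matrix entries must be non-negative")


def count_transitions(
    traj: DiscreteTrajectory | Sequence[DiscreteTrajectory],
    lag_frames: int,
    labels: StateLabelSet | None = None,
) -> CountMatrix:
    """Sliding-window transition counts at a lag of ``lag_frames`` frames.

    Every window ``(t, t + lag)`` with both ends inside the same gap-free
    segment contributes one count (stride 1, overlapping).  A list of
    trajectories accumulates counts across replicas; their frame intervals
    must agree.  The label set defaults to the union of observed states in
    first-appearance order.
    """
    trajs = [traj] if isinstance(traj, DiscreteTrajectory) else list(traj)
    if not trajs:
        raise ValueError("no trajectories supplied")
    h = trajs[0].frame_interval_ns
    if any(abs(t.frame_interval_ns - h) > 1e-12 for t in trajs):
        raise ValueError("all replicas must share one frame interval")
    if lag_frames < 1:
        raise ValueError("lag must be a positive number of frames")
    if all(lag_frames >= len(t) for t in trajs):
        raise ValueError("lag is not shorter than any trajectory")

    if labels is None:
        seen: dict = {}
        for t in trajs:
            for s in t.states:
                if s is not GAP and s not in seen:
                    seen[s] = len(seen)
        labels = StateLabelSet(seen.keys())
    N = len(labels)
    counts = np.zeros((N, N), dtype=np.int64)
    for t in trajs:
        codes = t.codes(labels)
        if len(codes) <= lag_frames:
            continue
        a, b = codes[:-lag_frames], codes[lag_frames:]
        ok = (a >= 0) & (b >= 0)
        if lag_frames > 1:
            # a window is broken by any gap strictly inside it
            gap = (codes < 0).astype(np.int64)
            cs = np.concatenate([[0], np.cumsum(gap)])
            ok &= (cs[lag_frames + 1:] - cs[:-lag_frames - 1]) == 0
        counts += np.bincount(
            a[ok] * N + b[ok], minlength=N * N
        ).reshape(N, N)
    return CountMatrix(counts, labels, lag_frames * h,
                       total_frames=sum(len(t) for t in trajs))


def estimate_transition_matrix(C: CountMatrix) -> LagTransitionMatrix:
    """Row-normalize counts into a transition matrix.

    States never seen as a window origin (all-zero rows) cannot be normalized;
    they are removed together with their columns and a warning is logged.
    """
    V = C.values.astype(float)
    if V.sum() == 0:
        raise ValueError("empty count matrix")
    rows = V.sum(axis=1)
    keep = rows > 0
    if not np.all(keep):
        dropped = [C.labels[i] for i in np.nonzero(~keep)[0]]
        logger.warning(
            "dropping %d state(s) with no outgoing counts: %s",
            len(dropped), dropped,
        )
    labels = StateLabelSet(np.asarray(C.labels.labels, dtype=object)[keep])
    V = V[np.ix_(keep, keep)]
    T = V / V.sum(axis=1, keepdims=True)
    return LagTransitionMatrix(T, labels, C.lagtime_ns)


_PROJECT = {"K": "K", "B": "K", "W": "O", "O": "O"}


def project_ion_only(label: str) -> str:
    """Project an occupancy string onto ion presence/absence.

    ``K`` and ``B`` mean an ion is present (``K``); ``W`` and ``O`` mean it is
    not (``O``).  Water placement is irrelevant for charge accounting, so
    states differing only in water collapse onto one ion configuration.
    Idempotent.
    """
    try:
        return "".join(_PROJECT[c] for c in label)
    except KeyError as exc:
        raise ValueError(f"invalid occupancy character {exc.args[0]!r} in {label!r}")
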