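"""Plain-text file formats.

Matrices (rate, transition, flux) are delimited text: an optional block of
``# key: value`` header comments, then a header row of state labels, then one
row per state with the state label in the first column.  Values are written
with 17 significant digits so a write/read round trip is bit-stable.
Probability vectors and lumping maps are two-column delimited text.  Discrete
trajectories are one state label per line with ``NA`` marking gaps.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .flux import FluxMatrix
from .msm import (LagTransitionMatrix, ProbabilityVector, RateMatrix,
                  StateLabelSet, validate_rate_matrix)
from .occupancy import GAP, DiscreteTrajectory
from .reduction import LumpingMap, MembershipMatrix

__all__ = [
    "read_matrix", "write_matrix",
    "read_rate_matrix", "read_transition_matrix", "read_flux_matrix",
    "read_probability_vector", "write_probability_vector",
    "read_trajectory", "write_trajectory",
    "read_lumping_map", "write_lumping_map",
    "write_membership", "load_config",
]

_FMT = "%.17g"


def _parse_headers(path) -> tuple[dict, str]:
    meta: dict = {}
    body_lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
        else:
            body_lines.append(line)
    return meta, "\n".join(body_lines)


def _sniff_sep(text: str) -> str:
    first = text.splitlines()[0] if text.splitlines() else ""
    return "\t" if "\t" in first else ","


def read_matrix(path) -> tuple[np.ndarray, StateLabelSet, dict]:
    """Read a labeled square matrix; returns (values, labels, header dict)."""
    meta, body = _parse_headers(path)
    if not body.strip():
        raise ValueError(f"{path}: empty matrix file")
    df = pd.read_csv(_io.StringIO(body), sep=_sniff_sep(body), index_col=0,
                     float_precision="round_trip")
    labels = StateLabelSet(df.index.astype(str))
    if list(df.columns.astype(str)) != list(labels.labels):
        raise ValueError(f"{path}: row and column labels differ")
    return df.to_numpy(dtype=float), labels, meta


def write_matrix(path, values, labels: StateLabelSet, headers: dict | None = None,
                 sep: str = "\t") -> None:
    lines = []
    for k, v in (headers or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append(sep.join([""] + list(labels.labels)))
    for i, lab in enumerate(labels.labels):
        lines.append(sep.join([lab] + [_FMT % x for x in np.asarray(values)[i]]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_rate_matrix(path) -> RateMatrix:
    values, labels, _ = read_matrix(path)
    return validate_rate_matrix(values, labels)


def read_transition_matrix(path) -> LagTransitionMatrix:
    values, labels, meta = read_matrix(path)
    if "lagtime_ns" not in meta:
        raise ValueError(f"{path}: missing '# lagtime_ns:' header")
    return LagTransitionMatrix(values, labels, float(meta["lagtime_ns"]))


def read_flux_matrix(path) -> FluxMatrix:
    values, labels, meta = read_matrix(path)
    if "lagtime_ns" not in meta:
        raise ValueError(f"{path}: missing '# lagtime_ns:' header")
    return FluxMatrix(values, labels, float(meta["lagtime_ns"]),
                      kind=meta.get("kind", "base"))


def write_rate_matrix(path, Q: RateMatrix) -> None:
    write_matrix(path, Q.values, Q.labels, {"units": "s^-1"})


def write_transition_matrix(path, T: LagTransitionMatrix) -> None:
    write_matrix(path, T.values, T.labels, {"lagtime_ns": _FMT % T.lagtime_ns})


def write_flux_matrix(path, F: FluxMatrix) -> None:
    write_matrix(path, F.values, F.labels,
                 {"lagtime_ns": _FMT % F.lagtime_ns, "kind": F.kind})


def read_probability_vector(path) -> ProbabilityVector:
    meta, body = _parse_headers(path)
    df = pd.read_csv(_io.StringIO(body), sep=_sniff_sep(body), header=None,
                     float_precision="round_trip")
    return ProbabilityVector(df[1].to_numpy(dtype=float),
                             StateLabelSet(df[0].astype(str)))


def write_probability_vector(path, P: ProbabilityVector, sep: str = "\t") -> None:
    lines = [f"{lab}{sep}{_FMT % v}" for lab, v in zip(P.labels, P.values)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path) -> DiscreteTrajectory:
    meta, body = _parse_headers(path)
    states = [None if s == "NA" else s
              for s in (l.strip() for l in body.splitlines()) if s]
    return DiscreteTrajectory(
        states,
        frame_interval_ns=float(meta.get("frame_interval_ns", 1.0)),
        replica_id=meta.get("replica", 0),
    )


def write_trajectory(path, traj: DiscreteTrajectory) -> None:
    lines = [f"# frame_interval_ns: {_FMT % traj.frame_interval_ns}",
             f"# replica: {traj.replica_id}"]
    lines += ["NA" if s is GAP else s for s in traj.states]
    Path(path).write_text("\n".join(lines) + "\n")


def read_lumping_map(path) -> LumpingMap:
    meta, body = _parse_headers(path)
    df = pd.read_csv(_io.StringIO(body), sep=_sniff_sep(body), header=None,
                     float_precision="round_trip")
    return LumpingMap(dict(zip(df[0].astype(str), df[1].astype(str))))


def write_lumping_map(path, lmap: LumpingMap, sep: str = "\t") -> None:
    lines = [f"{k}{sep}{v}" for k, v in lmap.partition.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_membership(path, M: MembershipMatrix, sep: str = "\t") -> None:
    lines = [sep.join([""] + list(M.macro_labels.labels))]
    for i, lab in enumerate(M.micro_labels.labels):
        lines.append(sep.join([lab] + [_FMT % x for x in M.values[i]]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> dict:
    """Structured pipeline configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
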