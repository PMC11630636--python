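"""End-to-end model-building pipeline.

Orchestrates the five-step procedure for extracting a reduced, Markovian,
current-preserving permeation MSM from discrete trajectories (simulated here,
MD-derived in practice):

1. estimate transition matrices at the frame interval and at every ladder
   lagtime;
2. build the base charge-flux matrix at the shortest available lagtime and
   check its current against the direct trajectory count (a large mismatch
   means the lagtime is too coarse);
3. lump states (ion-only projection, explicit map, spectral clustering, or a
   chain of these) and re-verify the current of the reduced model;
4. Chapman-Kolmogorov-test the reduced model over the ladder, pick the
   smallest lagtime that behaves Markovian, and build the empirical composite
   flux there (observed matrices at every intermediate lagtime, no Markov
   assumption); re-verify the current;
5. fit a rate matrix at that lagtime and verify its rate-flux current.

Every stage appends a record with the current it predicts, so a failure of
any assumption is visible as a current that drifts away from the direct
count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .currents import current_from_rates, current_from_trajectory, \
    current_from_transition
from .flux import base_flux_matrix, composite_flux_empirical
from .msm import (LagTransitionMatrix, chapman_kolmogorov_test,
                  stationary_distribution, logger)
from .occupancy import (DiscreteTrajectory, count_transitions,
                        estimate_transition_matrix, project_ion_only)
from .qfit import fit_rate_matrix
from .reduction import LumpingMap, crisp_partition, eigen_spectrum, \
    fuzzy_macrostates, lump_states
from .synthetic import discretize, kcsa_toy_model, simulate_ctmc

__all__ = ["PipelineConfig", "RunReport", "build_reduced_msm"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see the example YAML in the repo)."""

    trajectories: list = field(default_factory=list)   # paths, or loaded objects
    simulator: dict | None = None
    lagtime_ladder_ns: list = field(default_factory=list)
    lumping: list = field(default_factory=list)        # ordered strategy stages
    ck_threshold: float = 0.01
    step2_mismatch_threshold: float = 0.10
    ck_multiples: tuple = (2, 3)
    fit_lambda: float = 1.0   # current-mismatch regularization of the fit
    fit_restarts: int = 5
    output_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        pc = cls(**cfg)
        if not pc.trajectories and not pc.simulator:
            raise ValueError("either trajectories or a simulator spec is required")
        if not pc.lagtime_ladder_ns:
            raise ValueError("a lagtime ladder is required")
        ladder = list(pc.lagtime_ladder_ns)
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("lagtime ladder must be strictly increasing")
        if not pc.lumping:
            raise ValueError("at least one lumping stage is required")
        pc.ck_multiples = tuple(pc.ck_multiples)
        return pc


@dataclass
class RunReport:
    records: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    halted: bool = False

    def add(self, stage: str, **kw) -> dict:
        rec = {"stage": stage, **kw}
        self.records.append(rec)
        logger.info("%s: %s", stage, json.dumps(kw, default=float))
        return rec

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)
        logger.warning(msg)

    def currents(self) -> dict:
        return {r["stage"]: r["current_pA"] for r in self.records
                if "current_pA" in r}

    def to_jsonl(self) -> str:
        out = [json.dumps(r, default=float) for r in self.records]
        out += [json.dumps({"stage": "warning", "message": m})
                for m in self.warnings]
        return "\n".join(out) + "\n"


def _load_trajectories(config: PipelineConfig) -> list[DiscreteTrajectory]:
    if config.trajectories:
        out = []
        for t in config.trajectories:
            out.append(t if isinstance(t, DiscreteTrajectory)
                       else pio.read_trajectory(t))
        return out
    sim = dict(config.simulator)
    if sim.get("rate_matrix", "toy") == "toy":
        Q = kcsa_toy_model().Q
    else:
        Q = pio.read_rate_matrix(sim["rate_matrix"])
    n_rep = int(sim.get("replicas", 1))
    dur = float(sim["duration_ns"])
    h = float(sim["frame_interval_ns"])
    trajs = []
    for r in range(n_rep):
        ev = simulate_ctmc(Q, dur, seed=config.seed + r)
        trajs.append(discretize(ev, h, replica_id=r))
    return trajs


def _lag_frames(lag_ns: float, h: float) -> int:
    n = int(round(lag_ns / h))
    if n < 1 or abs(lag_ns - n * h) > 1e-9 * max(lag_ns, h):
        raise ValueError(
            f"lagtime {lag_ns} ns is not an integer multiple of the frame "
            f"interval {h} ns"
        )
    return n


def _estimate(trajs, lag_ns, labels=None) -> LagTransitionMatrix:
    h = trajs[0].frame_interval_ns
    return estimate_transition_matrix(
        count_transitions(trajs, _lag_frames(lag_ns, h), labels=labels)
    )


def _apply_lumping(stages, T, F, Pinf, report) -> LumpingMap:
    """Compose the configured lumping stages into one map on T's labels."""
    current_labels = list(T.labels)
    maps = []
    for stage in stages:
        kind = stage["strategy"] if isinstance(stage, dict) else stage
        if kind == "ion_only":
            m = LumpingMap({l: project_ion_only(l) for l in current_labels})
        elif kind == "explicit":
            spec = stage["map"]
            mapping = spec if isinstance(spec, dict) \
                else pio.read_lumping_map(spec).partition
            m = LumpingMap({l: mapping.get(l, l) for l in current_labels})
        elif kind == "spectral":
            # lump what we have so far, then cluster the intermediate model
            lm = _compose(maps, T.labels) if maps else None
            Ti = lump_states(T, F, Pinf, lm).T_red if lm else T
            spec_rep = eigen_spectrum(Ti)
            n_macro = stage.get("n_macro") or spec_rep.suggested_n_macro
            if n_macro is None:
                raise ValueError(
                    "spectral stage: no eigenvalue gap found and no n_macro given"
                )
            report.add("spectral_gap",
                       moduli=[float(x) for x in spec_rep.moduli],
                       n_macro=int(n_macro))
            m = crisp_partition(fuzzy_macrostates(Ti, int(n_macro)))
        else:
            raise ValueError(f"unknown lumping strategy {kind!r}")
        maps.append(m)
        current_labels = list(m.macro_labels)
    return _compose(maps, T.labels)


def _compose(maps, micro_labels) -> LumpingMap:
    out = maps[0]
    for m in maps[1:]:
        out = out.compose(m)
    missing = [l for l in micro_labels if l not in out.partition]
    if missing:
        raise ValueError(f"lumping does not cover states {missing!r}")
    return out


def build_reduced_msm(config: PipelineConfig | dict,
                      output_dir: str | None = None) -> RunReport:
    """Run the five-step pipeline; returns the report and persists the model
    bundle when an output directory is configured."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    report = RunReport()
    out = Path(output_dir or config.output_dir) if (output_dir or
                                                    config.output_dir) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    trajs = _load_trajectories(config)
    h = trajs[0].frame_interval_ns
    total_ns = sum(t.duration_ns for t in trajs)
    report.add("input", replicas=len(trajs), total_ns=total_ns,
               frame_interval_ns=h)

    # -- step 1: transition matrices over the ladder (shared micro label set)
    C0 = count_transitions(trajs, 1)
    T_base = estimate_transition_matrix(C0)
    labels = T_base.labels
    ladder = list(config.lagtime_ladder_ns)
    T_ladder = {lag: _estimate(trajs, lag, labels=labels) for lag in ladder}
    report.add("estimate", n_states=len(labels), base_lagtime_ns=h,
               ladder_ns=ladder)

    # -- step 2: base flux at the shortest available lagtime + sanity current
    F_base = base_flux_matrix(labels, h)
    Pinf = stationary_distribution(T_base)
    I_model = current_from_transition(T_base, F_base, Pinf)
    I_direct = current_from_trajectory(trajs, F_base)
    report.add("direct_count", current_pA=I_direct.value_pA,
               stderr_pA=I_direct.stderr_pA)
    rec = report.add("full_model", current_pA=I_model.value_pA, lagtime_ns=h)
    mism = abs(I_model.value_pA - I_direct.value_pA) / max(
        abs(I_direct.value_pA), 1e-30)
    rec["relative_mismatch"] = mism
    if mism > config.step2_mismatch_threshold:
        report.warn(
            f"model current deviates {mism:.1%} from the direct count: "
            "the base lagtime appears too large for the minimal-path flux"
        )

    # -- step 3: lump and re-verify
    lmap = _apply_lumping(config.lumping, T_base, F_base, Pinf, report)
    red = lump_states(T_base, F_base, Pinf, lmap)
    I_red = current_from_transition(red.T_red, red.F_red, red.Pinf_red)
    report.add("reduced_model", current_pA=I_red.value_pA,
               n_states=len(red.T_red.labels), lagtime_ns=h)

    # reduced trajectories: relabel frames through the lumping map
    relabel = {k: v for k, v in lmap.partition.items()}
    red_trajs = [
        DiscreteTrajectory(
            [None if s is None else relabel[s] for s in t.states],
            t.frame_interval_ns, t.replica_id)
        for t in trajs
    ]
    red_labels = red.T_red.labels

    # -- step 4: Markovianity scan over the ladder
    chosen = None
    for lag in ladder:
        base = _estimate(red_trajs, lag, labels=red_labels)
        obs = []
        for m in config.ck_multiples:
            try:
                obs.append(_estimate(red_trajs, m * lag, labels=red_labels))
            except ValueError:
                continue
        if not obs:
            continue
        ck = chapman_kolmogorov_test(base, obs)
        dev = ck.worst()
        report.add("ck_test", lagtime_ns=lag, max_deviation=dev,
                   threshold=config.ck_threshold)
        if dev < config.ck_threshold:
            chosen = lag
            break
    if chosen is None:
        report.warn(
            "no ladder lagtime met the Chapman-Kolmogorov threshold "
            f"{config.ck_threshold}; pipeline halted after reduction"
        )
        report.halted = True
        if out:
            _persist(out, T_base, F_base, red, None, None, lmap, report)
        return report

    # empirical composite flux at the chosen lagtime (base = frame interval)
    n = _lag_frames(chosen, h)
    T_star = [red.T_red if k == 1 else _estimate(red_trajs, k * h,
                                                 labels=red_labels)
              for k in range(1, n + 1)]
    F_comp = composite_flux_empirical(T_star, red.F_red)
    I_comp = current_from_transition(T_star[-1], F_comp, red.Pinf_red)
    report.add("composite_model", current_pA=I_comp.value_pA,
               lagtime_ns=chosen)

    # -- step 5: rate-matrix fit at the chosen lagtime; the regularizer
    # compares the discrete-time current (composite flux at this lagtime)
    # with the rate-form current (short-lagtime reduced flux)
    fit = fit_rate_matrix(T_star[-1], F_red=red.F_red, F_lag=F_comp,
                          lam=config.fit_lambda,
                          n_restarts=config.fit_restarts, seed=config.seed)
    I_fit = current_from_rates(fit.Q_fit, red.F_red)
    report.add("fitted_rates", current_pA=I_fit.value_pA, lagtime_ns=chosen,
               residual=fit.residual_norm, converged=fit.converged)

    if out:
        _persist(out, T_base, F_base, red, F_comp, fit, lmap, report)
    return report


def _persist(out, T_base, F_base, red, F_comp, fit, lmap, report) -> None:
    pio.write_transition_matrix(out / "T_micro.tsv", T_base)
    pio.write_flux_matrix(out / "F_base.tsv", F_base)
    pio.write_transition_matrix(out / "T_reduced.tsv", red.T_red)
    pio.write_flux_matrix(out / "F_reduced.tsv", red.F_red)
    pio.write_probability_vector(out / "Pinf_reduced.tsv", red.Pinf_red)
    pio.write_lumping_map(out / "lumping_map.tsv", lmap)
    if F_comp is not None:
        pio.write_flux_matrix(out / "F_composite.tsv", F_comp)
    if fit is not None:
        pio.write_rate_matrix(out / "Q_fit.tsv", fit.Q_fit)
    (out / "report.jsonl").write_text(report.to_jsonl())
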